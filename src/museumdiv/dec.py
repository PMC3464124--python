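"""Time-stratified dispersal-extinction-cladogenesis (DEC) range evolution.

Geographic ranges are non-empty subsets of a fixed area list (bounded by
``maxareas``, minus explicitly excluded combinations), plus an absorbing
null range.  Along a branch, ranges evolve by a continuous-time Markov
chain: dispersal adds area b at rate ``d * sum_{a in R} m_s[a][b]`` (the
per-slice scaling matrix m_s encodes paleogeographic connectivity), and
local extinction removes area a at rate ``e``.  At a cladogenetic node an
ancestral range R is inherited as (R, R) when |R| = 1, or through
vicariance ({a}, R \\ {a}) and subset sympatry ({a}, R) scenarios —
ordered daughter assignments weighted uniformly — when |R| >= 2.

The likelihood is computed by Felsenstein pruning with per-branch
transition matrices that multiply matrix exponentials across the time
slices a branch spans.  ``dec_optimize`` fits the global dispersal and
extinction rates and reports, per internal node, every (range, split)
reconstruction whose constrained global log-likelihood is within 2 units
of that node's best, the conventional significance rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .phylo import TreeError, assert_binary, node_ages

__all__ = [
    "RangeStateSpace",
    "StratifiedDispersalModel",
    "DecFit",
    "build_state_space",
    "cladogenetic_scenarios",
    "build_q",
    "branch_transition",
    "dec_loglik",
    "dec_optimize",
    "range_label",
]

RATE_BOUNDS = (1e-9, 10.0)
OPT_TOL = 1e-7


def range_label(r: frozenset, areas: list[str]) -> str:
    if not r:
        return "0"
    return "".join(a for a in areas if a in r)


@dataclass(frozen=True)
class RangeStateSpace:
    """Permitted geographic ranges in a fixed, deterministic order.

    The null (empty) range sits at index 0 and exists only as an internal
    absorbing state; observable ranges are non-empty subsets of at most
    ``maxareas`` areas not listed in ``excluded``.
    """

    areas: tuple[str, ...]
    maxareas: int
    states: tuple[frozenset, ...]     # index 0 is the null range
    index: dict = field(repr=False, hash=False, compare=False, default=None)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def labels(self) -> list[str]:
        return [range_label(s, list(self.areas)) for s in self.states]


def build_state_space(
    areas: list[str], maxareas: int = 2, excluded: list | None = None
) -> RangeStateSpace:
    """Enumerate permitted ranges ordered by size then lexicographic areas."""
    if not 1 <= maxareas <= len(areas):
        raise ValueError("need 1 <= maxareas <= number of areas")
    excluded_sets = set()
    for ex in excluded or []:
        ex_set = frozenset(ex)
        if not ex_set <= set(areas):
            raise ValueError(f"excluded range {sorted(ex_set)} is not a subset "
                             f"of the area list")
        excluded_sets.add(ex_set)
    order = {a: i for i, a in enumerate(areas)}
    states = [frozenset()]
    for size in range(1, maxareas + 1):
        for combo in itertools.combinations(areas, size):
            s = frozenset(combo)
            if s not in excluded_sets:
                states.append(s)
    states_t = tuple(states)
    index = {s: i for i, s in enumerate(states_t)}
    return RangeStateSpace(
        areas=tuple(areas), maxareas=maxareas, states=states_t, index=index
    )


@dataclass(frozen=True)
class StratifiedDispersalModel:
    """Global DEC rates plus per-slice dispersal scaling matrices.

    ``boundaries`` are the slice edges in time units before present,
    strictly decreasing (e.g. [32, 23, 10, 7] delimits five slices: the
    first runs from the root — however old — down to 32, the last from 7
    to the present).  ``matrices[s]`` scales dispersal between area pairs
    during slice s (entries in [0, 1]); times older than the first
    boundary use the first slice's matrix.
    """

    areas: tuple[str, ...]
    boundaries: tuple[float, ...]
    matrices: tuple   # len(boundaries) + 1 arrays, oldest slice first
    d: float = 0.0    # global dispersal rate
    e: float = 0.0    # global per-area extinction rate

    def __post_init__(self):
        n = len(self.areas)
        bounds = tuple(float(b) for b in self.boundaries)
        mats = tuple(np.asarray(m, dtype=float) for m in self.matrices)
        object.__setattr__(self, "boundaries", bounds)
        object.__setattr__(self, "matrices", mats)
        if any(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("slice boundaries must be strictly decreasing")
        if len(mats) != len(bounds) + 1:
            raise ValueError(
                f"{len(bounds)} boundaries require {len(bounds) + 1} "
                f"scaling matrices, got {len(mats)}"
            )
        for m in mats:
            if m.shape != (n, n):
                raise ValueError(f"scaling matrix must be {n}x{n}")
            if np.any(m < 0) or np.any(m > 1):
                raise ValueError("scaling factors must lie within [0, 1]")
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")

    @property
    def n_slices(self) -> int:
        return len(self.matrices)

    def slice_at(self, t: float) -> int:
        """Index of the slice containing age t (older than all edges -> 0)."""
        for i, b in enumerate(self.boundaries):
            if t > b:
                return i
        return len(self.boundaries)

    def with_rates(self, d: float, e: float) -> "StratifiedDispersalModel":
        return StratifiedDispersalModel(
            areas=self.areas, boundaries=self.boundaries,
            matrices=self.matrices, d=d, e=e,
        )

    @classmethod
    def uniform(cls, areas, d=0.0, e=0.0):
        """Single-slice model with all dispersal scalings equal to 1."""
        n = len(areas)
        return cls(areas=tuple(areas), boundaries=(),
                   matrices=(np.ones((n, n)),), d=d, e=e)


def build_q(
    space: RangeStateSpace, model: StratifiedDispersalModel, slice_index: int
) -> np.ndarray:
    """Anagenetic rate matrix over ranges for one time slice."""
    m = model.matrices[slice_index]
    areas = list(space.areas)
    pos = {a: i for i, a in enumerate(areas)}
    S = space.n_states
    q = np.zeros((S, S))
    for i, r in enumerate(space.states):
        if not r:
            continue  # null range is absorbing
        # dispersal: gain area b at rate d * sum over occupied sources
        if len(r) < space.maxareas:
            for b in areas:
                if b in r:
                    continue
                target = r | {b}
                j = space.index.get(target)
                if j is None:
                    continue
                rate = model.d * sum(m[pos[a], pos[b]] for a in r)
                q[i, j] += rate
        # extinction: lose each occupied area at rate e
        for a in r:
            target = r - {a}
            j = space.index.get(target)
            if j is None:
                continue
            q[i, j] += model.e
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


def _slice_qs(space: RangeStateSpace, model: StratifiedDispersalModel):
    return [build_q(space, model, s) for s in range(model.n_slices)]


def branch_transition(
    model: StratifiedDispersalModel,
    space: RangeStateSpace,
    t_parent: float,
    t_child: float,
    qs: list | None = None,
) -> np.ndarray:
    """Transition probabilities along a branch spanning one or more slices.

    Returns P with ``P[i, j] = Pr(child range j | parent range i)``: the
    ordered (oldest-first) product of matrix exponentials over the pieces
    of the branch cut at slice boundaries.
    """
    if t_child > t_parent:
        raise ValueError("t_parent must be older (larger) than t_child")
    if qs is None:
        qs = _slice_qs(space, model)
    S = space.n_states
    if t_parent == t_child:
        return np.eye(S)
    cuts = [b for b in model.boundaries if t_child < b < t_parent]
    edges = [t_parent] + cuts + [t_child]
    P = np.eye(S)
    for hi, lo in zip(edges[:-1], edges[1:]):
        s = model.slice_at(0.5 * (hi + lo))
        P = P @ expm(qs[s] * (hi - lo))
    return P


# ---------------------------------------------------------------------------
# cladogenesis


def cladogenetic_scenarios(space: RangeStateSpace) -> dict:
    """Ordered daughter-range scenarios, uniformly weighted, per range.

    |R| = 1: identical inheritance (R, R).  |R| >= 2: vicariance
    ({a}, R \\ {a}) and subset sympatry ({a}, R) for every a, both
    daughter orders, deduplicated; scenarios whose parts are excluded from
    the state space are dropped.  Returns range index -> (list of ordered
    (i1, i2) state-index pairs, weight = 1 / count).
    """
    out = {}
    for i, r in enumerate(space.states):
        if not r:
            continue
        pairs = []
        if len(r) == 1:
            pairs.append((i, i))
        else:
            seen = set()
            for a in r:
                single = frozenset([a])
                rest = r - {a}
                for left, right in (
                    (single, rest), (rest, single),
                    (single, r), (r, single),
                ):
                    li = space.index.get(left)
                    ri = space.index.get(right)
                    if li is None or ri is None:
                        continue
                    if (li, ri) in seen:
                        continue
                    seen.add((li, ri))
                    pairs.append((li, ri))
        if pairs:
            out[i] = (pairs, 1.0 / len(pairs))
    return out


# ---------------------------------------------------------------------------
# pruning likelihood


def _prepare(tree, tip_ranges, model, space):
    assert_binary(tree, "DEC")
    ages = node_ages(tree)
    qs = _slice_qs(space, model)
    branch_p = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            branch_p[node] = branch_transition(
                model, space, ages[node.parent_node], ages[node], qs=qs
            )
    tips = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in tip_ranges:
            raise TreeError(f"no range coded for tip {label!r}")
        r = frozenset(tip_ranges[label])
        if not r or r not in space.index:
            raise TreeError(
                f"range {sorted(r)} of tip {label!r} is not in the state space"
            )
        tips[leaf] = space.index[r]
    return ages, branch_p, tips


def _pruning_lnl(tree, branch_p, tips, space, scenarios, root_prior,
                 constraint=None):
    """Log-likelihood by post-order pruning with cladogenetic mixing.

    ``constraint`` restricts one node's (range, scenario) sum:
    (node, range_index or None, ordered pair or None).
    """
    S = space.n_states
    partials = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(S)
            vec[tips[node]] = 1.0
        else:
            c1, c2 = node.child_nodes()
            up1 = branch_p[c1] @ partials[c1]
            up2 = branch_p[c2] @ partials[c2]
            vec = np.zeros(S)
            c_node, c_range, c_pair = (constraint or (None, None, None))
            for i, (pairs, w) in scenarios.items():
                if node is c_node and c_range is not None and i != c_range:
                    continue
                acc = 0.0
                for li, ri in pairs:
                    if node is c_node and c_pair is not None and (li, ri) != c_pair:
                        continue
                    acc += up1[li] * up2[ri]
                vec[i] = w * acc
            mx = vec.max()
            if mx <= 0:
                return -np.inf
            vec = vec / mx
            log_scale += np.log(mx)
        partials[node] = vec
    root_like = float(np.dot(root_prior, partials[tree.seed_node]))
    if root_like <= 0:
        return -np.inf
    return float(np.log(root_like) + log_scale)


def _root_prior(space: RangeStateSpace, root_range) -> np.ndarray:
    S = space.n_states
    prior = np.zeros(S)
    if root_range is None:
        prior[1:] = 1.0 / (S - 1)  # flat over permitted non-null ranges
    else:
        r = frozenset(root_range)
        if r not in space.index or not r:
            raise TreeError(f"root range {sorted(r)} not in state space")
        prior[space.index[r]] = 1.0
    return prior


def dec_loglik(
    tree: dendropy.Tree,
    tip_ranges: dict,
    model: StratifiedDispersalModel,
    space: RangeStateSpace,
    root_range=None,
) -> float:
    """DEC log-likelihood of tip ranges on a chronogram.

    ``root_range`` fixes the ancestral range at the root (the conventional
    reading of a root-area constraint); ``None`` averages over a flat
    prior on permitted ranges.
    """
    ages, branch_p, tips = _prepare(tree, tip_ranges, model, space)
    scenarios = cladogenetic_scenarios(space)
    prior = _root_prior(space, root_range)
    return _pruning_lnl(tree, branch_p, tips, space, scenarios, prior)


@dataclass
class DecFit:
    d: float
    e: float
    lnl: float
    node_table: list          # per internal node: dict with candidates
    boundary_warning: str | None = None


def dec_optimize(
    tree: dendropy.Tree,
    tip_ranges: dict,
    model: StratifiedDispersalModel,
    space: RangeStateSpace,
    root_range=None,
    node_table: bool = True,
    scenario_detail: bool = True,
) -> DecFit:
    """Maximum-likelihood (d, e) plus per-node ancestral-range support.

    Rates are fitted by bounded derivative-free search.  The per-node
    table re-evaluates the global likelihood with each candidate range
    (and, optionally, each ordered daughter split) fixed at that node,
    flagging candidates within 2 log-likelihood units of the node's best.
    """
    scenarios = cladogenetic_scenarios(space)
    prior = _root_prior(space, root_range)

    def lnl_of(d, e):
        m = model.with_rates(d, e)
        ages, branch_p, tips = _prepare(tree, tip_ranges, m, space)
        return _pruning_lnl(tree, branch_p, tips, space, scenarios, prior)

    def neg(v):
        val = lnl_of(float(v[0]), float(v[1]))
        return -val if np.isfinite(val) else 1e300

    d0 = model.d if model.d > 0 else 0.1
    e0 = model.e if model.e > 0 else 0.01
    best = minimize(neg, x0=np.array([d0, e0]), method="Powell",
                    bounds=[RATE_BOUNDS, RATE_BOUNDS],
                    options={"ftol": OPT_TOL, "xtol": 1e-8, "maxiter": 2000})
    d_hat, e_hat = float(best.x[0]), float(best.x[1])
    lnl = -float(best.fun)

    warning = None
    if d_hat <= RATE_BOUNDS[0] * 10:
        warning = "dispersal rate at lower bound: likelihood may be flat"

    table = []
    if node_table:
        m = model.with_rates(d_hat, e_hat)
        ages, branch_p, tips = _prepare(tree, tip_ranges, m, space)
        for node in tree.preorder_internal_node_iter():
            cands = []
            for i, (pairs, _) in scenarios.items():
                li_range = _pruning_lnl(
                    tree, branch_p, tips, space, scenarios, prior,
                    constraint=(node, i, None),
                )
                if np.isfinite(li_range):
                    cands.append({
                        "range": range_label(space.states[i], list(space.areas)),
                        "split": None,
                        "lnl": li_range,
                    })
                if scenario_detail and len(pairs) > 1:
                    for pair in pairs:
                        li = _pruning_lnl(
                            tree, branch_p, tips, space, scenarios, prior,
                            constraint=(node, i, pair),
                        )
                        if np.isfinite(li):
                            lab = "{}|{}".format(
                                range_label(space.states[pair[0]], list(space.areas)),
                                range_label(space.states[pair[1]], list(space.areas)),
                            )
                            cands.append({
                                "range": range_label(space.states[i], list(space.areas)),
                                "split": lab,
                                "lnl": li,
                            })
            best_lnl = max(c["lnl"] for c in cands)
            kept = [dict(c, significant=(c["lnl"] >= best_lnl - 2.0))
                    for c in cands if c["lnl"] >= best_lnl - 2.0]
            kept.sort(key=lambda c: -c["lnl"])
            tip_labels_below = sorted(
                leaf.taxon.label for leaf in node.leaf_iter()
            )[:2]
            table.append({
                "node": "|".join(tip_labels_below),
                "age": ages[node],
                "best_lnl": best_lnl,
                "candidates": kept,
            })
    return DecFit(d=d_hat, e=e_hat, lnl=lnl, node_table=table,
                  boundary_warning=warning)
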