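"""Single-threshold GMYC species delimitation on an ultrametric gene tree.

The general mixed Yule coalescent (GMYC) model assumes that branching
events older than a threshold age T arise from a diversification (Yule)
process among species, while events younger than T are coalescences
within the populations defined by the branches crossing T.  Branching
times partition the tree depth into inter-event intervals; interval i of
duration x_i carries total event rate

    b_i = lam1 * n_d,i**p1 + lam2 * sum_j [n_j,i (n_j,i - 1)]**p2

with n_d,i diversification lineages and n_j,i lineages of coalescent
cluster j, all counted during the interval.  Each interval terminated by
a branching event contributes the waiting-time density term
``log(b_i) - b_i x_i``; the final interval down to the present
contributes only the survival term ``-b_i x_i``.
The null model is a single process with rate ``lam1 * [n_i (n_i-1)]**p1``.
The two are compared by a likelihood-ratio test with 3 degrees of freedom
(the threshold model has parameters lam1, lam2, p1, p2, T; the null has
lam1, p1).

Entities (putative species) are the branches crossing the maximum
likelihood threshold; a confidence set collects all scanned thresholds
within 2 log-likelihood units of the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .phylo import TreeError, assert_binary, node_ages

__all__ = [
    "GmycParams",
    "IntervalTable",
    "GmycFit",
    "interval_table",
    "gmyc_loglik",
    "null_loglik",
    "gmyc_fit",
    "entities_at_threshold",
    "consensus_reduce",
]

LAMBDA_BOUNDS = (1e-8, 1e6)
P_BOUNDS = (0.0, 5.0)
LOGL_TOL = 1e-8


@dataclass(frozen=True)
class GmycParams:
    lam1: float       # diversification rate (1 / relative time)
    lam2: float       # coalescent rate
    p1: float         # diversification scaling exponent
    p2: float         # coalescent scaling exponent
    threshold: float  # T, age separating the two processes

    def as_array(self) -> np.ndarray:
        return np.array([self.lam1, self.lam2, self.p1, self.p2])


@dataclass(frozen=True)
class IntervalTable:
    """Inter-event intervals of a tree cut at threshold T.

    Intervals run from the crown to the present; ``durations`` sum to the
    crown age.  ``term_kind`` marks how each interval ends: 0 = no event
    (the cut at T, or the present), 1 = diversification event, 2 =
    coalescent event.  Cluster lineage counts are stored as a compact
    histogram: ``cluster_counts[i, k]`` clusters with ``cluster_sizes[k]``
    lineages during interval i.
    """

    threshold: float
    crown_age: float
    n_tips: int
    durations: np.ndarray       # (m,)
    n_div: np.ndarray           # (m,) diversification lineages per interval
    cluster_sizes: np.ndarray   # (s,) distinct cluster lineage counts >= 2
    cluster_counts: np.ndarray  # (m, s)
    term_kind: np.ndarray       # (m,) in {0, 1, 2}
    term_size: np.ndarray       # (m,) cluster size before a coalescent event

    @property
    def n_entities(self) -> int:
        return int(self._n_entities)

    _n_entities: int = field(default=0, repr=False)


def _crossing_branches(ages: dict, threshold: float) -> list[dendropy.Node]:
    """Branches alive at age ``threshold`` (parent older, node not older)."""
    out = []
    for node, age in ages.items():
        parent = node.parent_node
        if age <= threshold and (parent is None or ages[parent] > threshold):
            out.append(node)
    return out


def interval_table(tree: dendropy.Tree, threshold: float) -> IntervalTable:
    """Classify inter-event intervals at a threshold age.

    Events strictly older than T belong to the diversification process;
    branches crossing T found clusters; younger events are coalescences
    within their cluster.
    """
    assert_binary(tree, "GMYC")
    ages = node_ages(tree)
    root = tree.seed_node
    crown = ages[root]
    if not (0.0 <= threshold <= crown):
        raise TreeError(
            f"threshold {threshold!r} outside [0, crown age {crown!r}]"
        )
    n_tips = sum(1 for node in ages if node.is_leaf())

    crossing = _crossing_branches(ages, threshold)
    cluster_of: dict[dendropy.Node, int] = {}
    for cid, branch in enumerate(crossing):
        stack = [branch]
        while stack:
            node = stack.pop()
            cluster_of[node] = cid
            stack.extend(node.child_nodes())

    # stops: internal non-root events plus the cut at T, swept crown->present;
    # at equal ages the cut is handled first (events at exactly T are
    # coalescent, inside their cluster)
    stops = [
        (age, 0, node) for node, age in ages.items()
        if not node.is_leaf() and node is not root
    ]
    root_is_cluster = crown <= threshold
    if not root_is_cluster and threshold > 0:
        stops.append((threshold, 1, None))
    stops.sort(key=lambda s: (-s[0], -s[1]))

    n_div = 1 if root_is_cluster else 2
    cluster_n = {cid: 0 for cid in range(len(crossing))}
    if root_is_cluster:
        cluster_n[cluster_of[root]] = 2

    # rows: (duration, n_div, cluster histogram snapshot, kind, event size)
    # kind 0 = no event (cut / present), 1 = diversification, 2 = coalescent;
    # the recorded coalescent event size (count after the split, >= 2) is
    # bookkeeping for reports, not a likelihood input.
    rows = []
    t = crown
    for age, marker, node in stops:
        snapshot = dict(cluster_n)
        if marker == 1:  # the cut at T
            rows.append((t - age, n_div, snapshot, 0, 0))
            for cid in cluster_n:
                cluster_n[cid] = 1
            n_div = len(crossing)
        elif age > threshold:  # diversification event
            rows.append((t - age, n_div, snapshot, 1, 0))
            n_div += 1
        else:  # coalescent event within its cluster
            cid = cluster_of[node]
            after = cluster_n[cid] + 1
            rows.append((t - age, n_div, snapshot, 2, after))
            cluster_n[cid] = after
        t = age
    rows.append((t, n_div, dict(cluster_n), 0, 0))  # final interval to present

    durations = np.array([r[0] for r in rows])
    nd = np.array([r[1] for r in rows], dtype=float)
    kinds = np.array([r[3] for r in rows], dtype=int)
    sizes_term = np.array([r[4] for r in rows], dtype=float)

    all_sizes = sorted({v for r in rows for v in r[2].values() if v >= 2})
    size_index = {v: j for j, v in enumerate(all_sizes)}
    counts = np.zeros((len(rows), len(all_sizes)))
    for i, r in enumerate(rows):
        for v in r[2].values():
            if v >= 2:
                counts[i, size_index[v]] += 1

    table = IntervalTable(
        threshold=threshold,
        crown_age=crown,
        n_tips=n_tips,
        durations=durations,
        n_div=nd,
        cluster_sizes=np.array(all_sizes, dtype=float),
        cluster_counts=counts,
        term_kind=kinds,
        term_size=sizes_term,
        _n_entities=len(crossing),
    )
    return table


def _rate_components(table: IntervalTable, p1: float, p2: float):
    """Per-interval component weights A (diversification), B (coalescent)."""
    a = np.power(table.n_div, p1)
    vv = table.cluster_sizes * (table.cluster_sizes - 1.0)
    if vv.size:
        b = table.cluster_counts @ np.power(vv, p2)
    else:
        b = np.zeros(len(table.durations))
    return a, b


def gmyc_loglik(table: IntervalTable, params: GmycParams) -> float:
    """GMYC log-likelihood of an interval table (see module docstring).

    The total branching rate b_i enters both the survival term of every
    interval and the waiting-time (event) term of intervals terminated by
    a branching event; lineage counts are those holding during the
    interval.
    """
    lam1, lam2 = params.lam1, params.lam2
    if lam1 < 0 or lam2 < 0:
        raise ValueError("rates must be non-negative")
    a, b = _rate_components(table, params.p1, params.p2)
    total = lam1 * a + lam2 * b
    x = table.durations
    if np.any((total <= 0) & (x > 0) & (table.term_kind > 0)):
        return -np.inf
    ll = -float(np.dot(total, x))
    ev = table.term_kind > 0
    with np.errstate(divide="ignore"):
        ll += float(np.sum(np.log(total[ev])))
    return ll if np.isfinite(ll) else -np.inf


def _null_arrays(ages_desc: np.ndarray, n_tips: int):
    """Lineage counts and durations for the single-process null model."""
    bounds = np.concatenate([ages_desc, [0.0]])
    durations = -np.diff(bounds)
    counts = np.arange(2, n_tips + 1, dtype=float)
    return durations, counts


def null_loglik(tree_or_bt, lam: float, p: float) -> float:
    """Null (single process, rate lam * [n(n-1)]**p) log-likelihood.

    Counts are those holding during each interval (2..n); every interval
    except the final one down to the present ends in a branching event.
    This matches the threshold model's convention, so the null nests
    exactly in it at the crown cut.
    """
    durations, counts = _null_arrays_from(tree_or_bt)
    rate = lam * np.power(counts * (counts - 1.0), p)
    ll = -float(np.dot(rate, durations))
    ll += float(np.sum(np.log(rate[:-1])))
    return ll if np.isfinite(ll) else -np.inf


def _null_arrays_from(tree_or_bt):
    from .phylo import BranchingTimes, branching_times

    if isinstance(tree_or_bt, BranchingTimes):
        bt = tree_or_bt
    else:
        bt = branching_times(tree_or_bt)
    return _null_arrays(bt.ages, bt.n_tips)


def _profile_component(
    m_events: int, sum_log_weight_at_events: float, exposure_fn
) -> "callable":
    """Profile a process component's rate out of the likelihood.

    For fixed exponent p the component's log-likelihood
    ``m log(lam) + p * S - lam * E(p)`` is maximized at lam = m / E(p),
    giving the profile ``m (log(m / E(p)) - 1) + p S``; a component with
    no events contributes 0 (its rate's supremum is at lam -> 0).
    """
    def profile(p: float) -> tuple[float, float]:
        e = exposure_fn(p)
        if m_events == 0:
            return 0.0, 0.0
        if e <= 0:
            return -np.inf, np.inf
        lam = min(max(m_events / e, LAMBDA_BOUNDS[0]), LAMBDA_BOUNDS[1])
        val = m_events * math.log(lam) + p * sum_log_weight_at_events - lam * e
        return val, lam

    return profile


def _maximize_exponent(profile) -> tuple[float, float, float]:
    """Coarse grid + Brent refinement of a 1-D profile on the p bounds."""
    lo, hi = P_BOUNDS
    grid = np.linspace(lo, hi, 26)
    vals = [profile(p)[0] for p in grid]
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda p: -profile(p)[0], bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    cand = [(vals[i], grid[i]), (-res.fun, float(res.x))]
    f, p = max(cand)
    _, lam = profile(p)
    return p, lam, f


def fit_null(tree_or_bt) -> tuple[float, float, float]:
    """ML fit of the null model; returns (lam_hat, p_hat, logL)."""
    durations, counts = _null_arrays_from(tree_or_bt)
    weights = counts * (counts - 1.0)
    s = float(np.sum(np.log(weights[:-1])))  # counts during event intervals
    m = len(counts) - 1

    def exposure(p):
        return float(np.dot(np.power(weights, p), durations))

    profile = _profile_component(m, s, exposure)
    p_hat, lam_hat, f = _maximize_exponent(profile)
    return float(lam_hat), float(p_hat), float(f)


@dataclass
class GmycFit:
    """Result of the single-threshold GMYC scan."""

    params: GmycParams
    logl_gmyc: float
    logl_null: float
    null_params: tuple[float, float]
    lrt: float                       # 2 * (logl_gmyc - logl_null)
    df: int
    p_value: float
    n_entities: int
    clusters: dict[str, int]         # tip label -> cluster id
    cluster_types: dict[int, str]    # cluster id -> "cluster" | "singleton"
    confidence_set: list             # (threshold, logL, n_entities) within 2 lnL
    scanned: list = field(repr=False, default_factory=list)

    @property
    def entity_range(self) -> tuple[int, int]:
        ns = [n for _, _, n in self.confidence_set]
        return (min(ns), max(ns)) if ns else (self.n_entities, self.n_entities)


def entities_at_threshold(tree: dendropy.Tree, threshold: float):
    """Cluster assignment (tip -> cluster id) and types at a threshold."""
    ages = node_ages(tree)
    crossing = _crossing_branches(ages, threshold)
    clusters: dict[str, int] = {}
    types: dict[int, str] = {}
    for cid, branch in enumerate(crossing):
        tips = [branch] if branch.is_leaf() else list(branch.leaf_iter())
        for leaf in tips:
            clusters[leaf.taxon.label] = cid
        types[cid] = "singleton" if len(tips) == 1 else "cluster"
    return clusters, types


def _candidate_thresholds(internal_ages: np.ndarray) -> np.ndarray:
    """Midpoints between distinct event ages plus the two boundary cuts."""
    distinct = np.unique(internal_ages)  # ascending
    mids = 0.5 * (distinct[1:] + distinct[:-1])
    below = np.array([0.5 * distinct[0]])
    crown = distinct[-1]
    return np.concatenate([below, mids, [crown]])


def _rates_given_exponents(a, b, x, ev):
    """Maximize over (lam1, lam2) with exponents fixed: a concave problem.

    Objective sum(log(lam1 a_e + lam2 b_e)) - lam1 <a,x> - lam2 <b,x>.
    Returns (lam1, lam2, value).
    """
    sa = float(np.dot(a, x))
    sb = float(np.dot(b, x))
    ae, be = a[ev], b[ev]
    m = len(ae)
    if sb <= 0 or not np.any(be > 0):
        # coalescent component inert: closed-form single-rate optimum
        lam1 = m / sa if m else 0.0
        val = (m * math.log(lam1) + float(np.sum(np.log(ae))) - m) if m else 0.0
        return lam1, 0.0, val

    floor = 1e-12
    cap = LAMBDA_BOUNDS[1]
    log = np.log

    def fval(l1, l2):
        tot = l1 * ae + l2 * be
        return float(log(tot).sum()) - l1 * sa - l2 * sb

    # damped Newton on a concave 2-D objective, clipped to the positive
    # orthant; boundary optima (one component switched off) emerge as a
    # rate pinned at the floor
    l1, l2 = 0.5 * m / sa, 0.5 * m / sb
    f = fval(l1, l2)
    f_prev = -np.inf
    for _ in range(40):
        tot = l1 * ae + l2 * be
        r1 = ae / tot
        r2 = be / tot
        g1 = float(r1.sum()) - sa
        g2 = float(r2.sum()) - sb
        h11 = -float(r1 @ r1)
        h12 = -float(r1 @ r2)
        h22 = -float(r2 @ r2)
        det = h11 * h22 - h12 * h12
        if abs(det) < 1e-300:
            break
        s1 = -(h22 * g1 - h12 * g2) / det
        s2 = -(h11 * g2 - h12 * g1) / det
        step = 1.0
        improved = False
        for _ in range(25):
            c1 = min(max(l1 + step * s1, floor), cap)
            c2 = min(max(l2 + step * s2, floor), cap)
            fc = fval(c1, c2)
            if fc >= f:
                l1, l2, f_prev, f = c1, c2, f, fc
                improved = True
                break
            step *= 0.5
        if not improved or f - f_prev < 1e-10:
            break
    return float(l1), float(l2), f


def _fit_at_threshold(table: IntervalTable):
    """Maximize (lam1, lam2, p1, p2) for a fixed threshold.

    The rates are solved by a concave inner maximization for each
    exponent pair; the exponents are searched by bounded direction-set
    minimization from two starts.
    """
    x = table.durations
    ev = table.term_kind > 0

    def value(p1, p2):
        a, b = _rate_components(table, p1, p2)
        return _rates_given_exponents(a, b, x, ev)

    if not table.cluster_sizes.size:
        # no cluster ever has >= 2 lineages: pure diversification process
        m = int(np.sum(ev))
        s = float(np.sum(np.log(table.n_div[ev]))) if m else 0.0

        def exposure(p):
            return float(np.dot(np.power(table.n_div, p), x))

        p1, lam1, f = _maximize_exponent(_profile_component(m, s, exposure))
        return np.array([lam1, 0.0, p1, 1.0]), f

    lo, hi = P_BOUNDS

    def neg(p):
        p1 = min(max(p[0], lo), hi)
        p2 = min(max(p[1], lo), hi)
        return -value(p1, p2)[2]

    # coarse exponent grid, then simplex refinement from the best cell
    grid = np.arange(lo, hi + 0.5, 1.0)
    best_p, best_f = None, np.inf
    for p1 in grid:
        for p2 in grid:
            fv = neg((p1, p2))
            if fv < best_f:
                best_f, best_p = fv, (p1, p2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(neg, x0=np.array(best_p), method="Nelder-Mead",
                       options={"fatol": LOGL_TOL, "xatol": 1e-5,
                                "maxiter": 200})
    if res.fun < best_f:
        best_f, best_p = res.fun, tuple(res.x)
    p1 = min(max(best_p[0], lo), hi)
    p2 = min(max(best_p[1], lo), hi)
    lam1, lam2, f = value(p1, p2)
    return np.array([lam1, lam2, p1, p2]), f


def gmyc_fit(tree: dendropy.Tree, thresholds: np.ndarray | None = None) -> GmycFit:
    """Threshold scan + LRT of the single-threshold GMYC model.

    Candidate thresholds are midpoints between consecutive distinct node
    ages plus the two boundary cuts (all-diversification near the present
    and all-coalescent at the crown).  Ties in likelihood are broken toward
    the fewest entities (conservative splitting).
    """
    assert_binary(tree, "GMYC")
    ages = node_ages(tree)
    internal = np.array(sorted(a for nd, a in ages.items() if not nd.is_leaf()))
    if len(internal) < 3:
        raise TreeError("GMYC needs at least 4 tips")
    if thresholds is None:
        thresholds = _candidate_thresholds(internal)

    null_lam, null_p, logl_null = fit_null(tree)

    scanned = []
    best = None  # (logl, -entities) ordering
    for T in thresholds:
        table = interval_table(tree, float(T))
        x, f = _fit_at_threshold(table)
        if x is None:
            warnings.warn(f"GMYC optimizer failed at threshold {T:.6g}; skipped")
            continue
        scanned.append((float(T), float(f), table.n_entities, x))
        key = (f, -table.n_entities)
        if best is None or key > best[0]:
            best = (key, float(T), x, float(f))

    if best is None:
        raise TreeError("GMYC optimization failed at every threshold")

    _, best_T, best_x, best_logl = best
    # the crown cut with lam1 -> 0 reduces exactly to the null model, so the
    # scan maximum can never fall below the null optimum
    if best_logl < logl_null:
        best_T = float(internal[-1])
        best_x = np.array([0.0, null_lam, 1.0, null_p])
        best_logl = logl_null
        scanned.append((best_T, best_logl, 1, best_x))

    lrt = 2.0 * (best_logl - logl_null)
    p_value = float(chi2.sf(max(lrt, 0.0), df=3))
    clusters, types = entities_at_threshold(tree, best_T)
    conf = [(T, f, n) for T, f, n, _ in scanned if f >= best_logl - 2.0]
    params = GmycParams(
        float(best_x[0]), float(best_x[1]), float(best_x[2]), float(best_x[3]),
        best_T,
    )
    return GmycFit(
        params=params,
        logl_gmyc=best_logl,
        logl_null=logl_null,
        null_params=(null_lam, null_p),
        lrt=lrt,
        df=3,
        p_value=p_value,
        n_entities=len(types),
        clusters=clusters,
        cluster_types=types,
        confidence_set=conf,
        scanned=scanned,
    )


# ---------------------------------------------------------------------------
# Consensus reduction of an alignment to one sequence per entity

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
_EXPAND = {code: bases for bases, code in _IUPAC.items()}
_EXPAND.update({"U": frozenset("T")})


def consensus_reduce(
    alignment: dict[str, str], clusters: dict[str, int]
) -> dict[int, str]:
    """One consensus sequence per cluster from an aligned sequence dict.

    Per column: the unanimous base if all cluster members agree (gaps and
    N ignored), the IUPAC ambiguity code for the observed base set
    otherwise, and a gap for all-gap columns.
    """
    missing = sorted(set(clusters) - set(alignment))
    if missing:
        raise ValueError(f"tips missing from alignment: {missing}")
    lengths = {len(alignment[t]) for t in clusters}
    if len(lengths) > 1:
        raise ValueError("aligned sequences must have equal length")

    members: dict[int, list[str]] = {}
    for tip, cid in clusters.items():
        members.setdefault(cid, []).append(alignment[tip].upper())

    out: dict[int, str] = {}
    for cid, seqs in members.items():
        cols = []
        for column in zip(*seqs):
            bases: set[str] = set()
            for ch in column:
                if ch in ("-", ".", "N", "?"):
                    continue
                bases |= _EXPAND.get(ch, frozenset())
            if not bases:
                cols.append("-" if "-" in column or "." in column else "N")
            else:
                cols.append(_IUPAC[frozenset(bases)])
        out[cid] = "".join(cols)
    return out
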