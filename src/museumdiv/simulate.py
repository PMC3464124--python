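"""Seeded generators for every input the pipeline consumes, with ground truth.

These stand in for real specimen data: constant-rate chronograms for the
diversification null models, trees with GMYC structure (deep Yule species
branching over shallow within-species coalescents), rate-perturbed
phylograms for the dating step, DEC range histories evolved forward under
known rates, and Jukes-Cantor sequence alignments.  Every generator is
driven by a single numpy Generator so identical (parameters, seed) give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .dec import RangeStateSpace, StratifiedDispersalModel, cladogenetic_scenarios
from .phylo import TreeError, as_chronogram, node_ages

__all__ = [
    "sim_yule",
    "sim_bd",
    "sim_gmyc",
    "perturb_rates",
    "sim_dec_ranges",
    "sim_seqs",
    "DecSimResult",
]

BD_RETRY_CAP = 10_000


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# forward constant-rate tree simulation (flat arrays -> dendropy)


def _forward_yule(n: int, rate: float, rng: np.random.Generator):
    """Arrays (parent, left, right, split_time, present, tip ids).

    The present sits at the moment the (n+1)-th lineage would arise, so
    the final internode interval is exponential like all others.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    split = np.zeros(n_nodes)
    active = [1, 2]
    parent[1] = parent[2] = 0
    left[0], right[0] = 1, 2
    next_id = 3
    t = 0.0
    for k in range(2, n + 1):
        t += rng.exponential(1.0 / (k * rate))
        if k == n:
            break
        i = active.pop(int(rng.integers(len(active))))
        split[i] = t
        left[i], right[i] = next_id, next_id + 1
        parent[next_id] = parent[next_id + 1] = i
        active.extend((next_id, next_id + 1))
        next_id += 2
    return parent, left, right, split, t, np.array(active)


def _build_tree(left, right, split, present, keep, labels) -> dendropy.Tree:
    """Induced dendropy chronogram on the retained tip ids."""
    keep = set(int(i) for i in keep)
    taxa = dendropy.TaxonNamespace()

    def rec(i: int):
        if left[i] < 0:
            if i not in keep:
                return None
            node = dendropy.Node()
            node.taxon = taxa.require_taxon(label=labels[i])
            node.sim_age = 0.0
            return node
        a = rec(int(left[i]))
        b = rec(int(right[i]))
        if a is not None and b is not None:
            node = dendropy.Node()
            node.sim_age = present - split[i]
            node.add_child(a)
            a.edge.length = node.sim_age - a.sim_age
            node.add_child(b)
            b.edge.length = node.sim_age - b.sim_age
            return node
        return a if a is not None else b

    root = rec(0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def sim_yule(n: int, rate: float = 1.0, seed=0) -> dendropy.Tree:
    """Pure-birth chronogram conditioned on n extant tips."""
    if n < 2:
        raise ValueError("need n >= 2")
    if rate <= 0:
        raise ValueError("speciation rate must be positive")
    rng = _rng(seed)
    parent, left, right, split, present, tips = _forward_yule(n, rate, rng)
    labels = {int(i): f"t{j + 1}" for j, i in enumerate(sorted(tips))}
    tree = _build_tree(left, right, split, present, tips, labels)
    return as_chronogram(tree)


def sim_bd(n: int, lam: float, mu: float, seed=0) -> dendropy.Tree:
    """Birth-death chronogram with extinct lineages pruned, n extant tips.

    Forward Gillespie from two crown lineages; the present is placed at
    the first moment the extant count would reach n + 1; runs that go
    extinct first are retried (cap 10,000).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if lam <= 0 or not 0 <= mu < lam:
        raise ValueError("need lam > 0 and 0 <= mu < lam")
    rng = _rng(seed)
    for _ in range(BD_RETRY_CAP):
        parent = [-1, 0, 0]
        left = [1, -1, -1]
        right = [2, -1, -1]
        split = [0.0, 0.0, 0.0]
        active = [1, 2]
        t = 0.0
        failed = False
        while True:
            k = len(active)
            if k == 0:
                failed = True
                break
            total = k * (lam + mu)
            t += rng.exponential(1.0 / total)
            if rng.random() < lam / (lam + mu):  # birth
                if k == n:
                    break  # present: the (n+1)-th extant lineage never arises
                i = active.pop(int(rng.integers(k)))
                split[i] = t
                nid = len(parent)
                left[i], right[i] = nid, nid + 1
                parent.extend([i, i])
                left.extend([-1, -1])
                right.extend([-1, -1])
                split.extend([0.0, 0.0])
                active.extend((nid, nid + 1))
            else:  # death
                active.pop(int(rng.integers(k)))
        if failed or len(active) != n:
            continue
        # the induced tree on survivors may have lost one crown lineage
        labels = {int(i): f"t{j + 1}" for j, i in enumerate(sorted(active))}
        tree = _build_tree(
            np.array(left), np.array(right), np.array(split), t, active, labels
        )
        if sum(1 for _ in tree.leaf_node_iter()) == n:
            return as_chronogram(tree)
    raise RuntimeError(
        f"birth-death simulation failed to reach {n} extant tips in "
        f"{BD_RETRY_CAP} attempts"
    )


# ---------------------------------------------------------------------------
# GMYC-structured trees


def _coalescent_heights(m: int, theta: float, rng) -> tuple[list, float]:
    """Topology (nested tuples of sample indices) + ages for m samples.

    Pairwise coalescence rate is scaled so the expected TMRCA equals
    ``theta``.
    """
    c = 2.0 * (1.0 - 1.0 / m) / theta  # E[TMRCA] = (2/c)(1 - 1/m) = theta
    lineages = [(j, 0.0) for j in range(m)]  # (subtree, age)
    t = 0.0
    while len(lineages) > 1:
        j = len(lineages)
        t += rng.exponential(1.0 / (c * j * (j - 1) / 2.0))
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        b = lineages.pop(int(i2))
        a = lineages.pop(int(i1))
        lineages.append(((a, b), t))
    return lineages[0]


def _subtree_to_node(struct, age, taxa, label_fn) -> dendropy.Node:
    node = dendropy.Node()
    node.sim_age = age
    if isinstance(struct, tuple):
        (a_struct, a_age), (b_struct, b_age) = struct
        a = _subtree_to_node(a_struct, a_age, taxa, label_fn)
        b = _subtree_to_node(b_struct, b_age, taxa, label_fn)
        node.add_child(a)
        a.edge.length = age - a_age
        node.add_child(b)
        b.edge.length = age - b_age
    else:
        node.taxon = taxa.require_taxon(label=label_fn(struct))
    return node


def sim_coalescent(n: int, theta: float = 1.0, seed=0) -> dendropy.Tree:
    """Single-population Kingman coalescent chronogram with n sampled tips.

    The pairwise coalescence rate is scaled so the expected TMRCA equals
    ``theta``; this is the single-process null for threshold-model tests.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = _rng(seed)
    struct, height = _coalescent_heights(n, theta, rng)
    taxa = dendropy.TaxonNamespace()
    root = _subtree_to_node(struct, height, taxa, lambda j: f"t{j + 1}")
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return as_chronogram(tree)


def sim_gmyc(
    k_species: int,
    lam_sp: float = 1.0,
    m_per_species: int = 4,
    theta: float = 0.01,
    seed=0,
    crown_age: float | None = 1.0,
) -> tuple[dendropy.Tree, dict[str, int]]:
    """Tree with GMYC structure plus the true tip -> species map.

    A Yule species tree with ``k_species`` tips (rescaled to crown age
    ``crown_age`` unless None) carries, at each tip, a within-species
    coalescent of ``m_per_species`` samples with expected depth
    ``theta`` (same time units as the crown).  A coalescent
    deeper than the species' terminal branch would break the tree; such a
    subtree is rescaled to 90% of the available depth and the tree is
    flagged (``tree.gmyc_overlap_flagged``) since clusters may then be
    unidentifiable.
    """
    if k_species < 2 or m_per_species < 1:
        raise ValueError("need k_species >= 2 and m_per_species >= 1")
    rng = _rng(seed)
    sp_tree = sim_yule(k_species, lam_sp, rng)
    if crown_age is not None:
        height = node_ages(sp_tree)[sp_tree.seed_node]
        scale = crown_age / height
        for edge in sp_tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    ages = node_ages(sp_tree)
    flagged = False
    taxa = dendropy.TaxonNamespace()
    truth: dict[str, int] = {}

    for si, leaf in enumerate(list(sp_tree.leaf_node_iter())):
        parent_age = ages[leaf.parent_node]
        if m_per_species == 1:
            label = f"sp{si + 1}_1"
            truth[label] = si + 1
            leaf.taxon = taxa.require_taxon(label=label)
            continue
        struct, height = _coalescent_heights(m_per_species, theta, rng)
        if height >= parent_age:
            scale = 0.9 * parent_age / height
            struct, height = _rescale_struct(struct, scale), height * scale
            flagged = True

        def label_fn(j, si=si):
            label = f"sp{si + 1}_{j + 1}"
            truth[label] = si + 1
            return label

        sub = _subtree_to_node(struct, height, taxa, label_fn)
        parent = leaf.parent_node
        parent.remove_child(leaf)
        parent.add_child(sub)
        sub.edge.length = parent_age - height

    # rebuild under a single taxon namespace
    tree = dendropy.Tree.get(
        data=sp_tree.as_string(schema="newick"), schema="newick",
        rooting="default-rooted", preserve_underscores=True,
    )
    tree = as_chronogram(tree, snap=True)
    tree.gmyc_overlap_flagged = flagged
    return tree, truth


def _rescale_struct(struct, scale):
    if isinstance(struct, tuple):
        (a, aa), (b, ba) = struct
        return ((_rescale_struct(a, scale), aa * scale),
                (_rescale_struct(b, scale), ba * scale))
    return struct


# ---------------------------------------------------------------------------
# rate perturbation (clock-breaking)


def perturb_rates(tree: dendropy.Tree, sigma: float, seed=0) -> dendropy.Tree:
    """Multiply each branch by an independent lognormal factor of mean 1.

    ``sigma`` is the standard deviation of the underlying normal; the
    multiplier has mean exactly 1 (mu = -sigma^2 / 2).  sigma = 0 returns
    an identical tree.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = _rng(seed)
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma) if sigma else 1.0
            edge.length = edge.length * factor
    return out


# ---------------------------------------------------------------------------
# DEC forward simulation


@dataclass
class DecSimResult:
    tip_ranges: dict[str, frozenset]
    node_ranges: dict           # internal node key -> frozenset (true range)
    n_rejections: int
    n_branches: int

    @property
    def rejection_rate(self) -> float:
        total = self.n_rejections + self.n_branches
        return self.n_rejections / total if total else 0.0


def _evolve_branch(range_start, t_hi, t_lo, model, space, rng):
    """Gillespie simulation of one branch; returns end range (may be null)."""
    r = range_start
    t = t_hi
    pos = {a: i for i, a in enumerate(space.areas)}
    while t > t_lo and r:
        s = model.slice_at(t - 1e-12)
        m = model.matrices[s]
        slice_floor = max(
            [b for b in model.boundaries if b < t] + [t_lo]
        ) if model.boundaries else t_lo
        slice_floor = max(slice_floor, t_lo)
        moves, rates = [], []
        if len(r) < space.maxareas:
            for b in space.areas:
                if b in r:
                    continue
                target = r | {b}
                if target in space.index:
                    rate = model.d * sum(m[pos[a], pos[b]] for a in r)
                    if rate > 0:
                        moves.append(target)
                        rates.append(rate)
        for a in r:
            target = r - {a}
            if target in space.index:
                if model.e > 0:
                    moves.append(target)
                    rates.append(model.e)
        total = sum(rates)
        if total == 0:
            t = slice_floor
            if t <= t_lo:
                break
            continue
        dt = rng.exponential(1.0 / total)
        if t - dt < slice_floor:
            t = slice_floor
            continue
        t -= dt
        pick = rng.choice(len(moves), p=np.array(rates) / total)
        r = moves[int(pick)]
    return r


def sim_dec_ranges(
    tree: dendropy.Tree,
    model: StratifiedDispersalModel,
    space: RangeStateSpace,
    root_range,
    seed=0,
    branch_retry_cap: int = 1000,
) -> DecSimResult:
    """Evolve ranges forward along a chronogram under the stratified model.

    Cladogenetic splits are drawn uniformly from the permitted scenarios;
    a branch that hits the null range (all areas lost) is redrawn from its
    parent state so every tip is observable, and the rejection count is
    reported.  Aborts when the rejection rate exceeds 0.99.
    """
    rng = _rng(seed)
    root_range = frozenset(root_range)
    if root_range not in space.index or not root_range:
        raise TreeError("root range must be a permitted non-null range")
    ages = node_ages(tree)
    scenarios = cladogenetic_scenarios(space)
    state: dict = {tree.seed_node: root_range}
    node_ranges: dict = {}
    tip_ranges: dict[str, frozenset] = {}
    rejections = 0
    branches = 0

    for node in tree.preorder_node_iter():
        r = state[node]
        if node.is_leaf():
            tip_ranges[node.taxon.label] = r
            continue
        key = "|".join(sorted(
            leaf.taxon.label for leaf in node.leaf_iter()
        )[:2])
        node_ranges[key] = r
        pairs, _ = scenarios[space.index[r]]
        li, ri = pairs[int(rng.integers(len(pairs)))]
        starts = (space.states[li], space.states[ri])
        for child, start in zip(node.child_nodes(), starts):
            branches += 1
            end = None
            for _ in range(branch_retry_cap):
                end = _evolve_branch(
                    start, ages[node], ages[child], model, space, rng
                )
                if end:
                    break
                rejections += 1
                if rejections / (rejections + branches) > 0.99:
                    raise RuntimeError(
                        "DEC simulation rejection rate exceeded 0.99: "
                        "parameters imply near-certain range loss"
                    )
            if not end:
                raise RuntimeError("branch survival rejection cap exhausted")
            state[child] = end
    return DecSimResult(
        tip_ranges=tip_ranges,
        node_ranges=node_ranges,
        n_rejections=rejections,
        n_branches=branches,
    )


# ---------------------------------------------------------------------------
# Jukes-Cantor sequences


_BASES = np.array(list("ACGT"))


def sim_seqs(tree: dendropy.Tree, length: int, seed=0) -> dict[str, str]:
    """Jukes-Cantor sequences evolved along the tree (lengths in subs/site).

    Per site and branch of length t, a substitution to one of the three
    other bases occurs with total probability (3/4)(1 - exp(-4t/3)).
    """
    if length < 1:
        raise ValueError("need length >= 1")
    rng = _rng(seed)
    seqs: dict = {}
    root_states = rng.integers(0, 4, size=length)
    state: dict = {tree.seed_node: root_states}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            t = node.edge.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            parent_states = state[node.parent_node]
            changed = rng.random(length) < p_change
            new = parent_states.copy()
            if np.any(changed):
                shifts = rng.integers(1, 4, size=int(changed.sum()))
                new[changed] = (new[changed] + shifts) % 4
            state[node] = new
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(_BASES[state[node]])
    return seqs
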