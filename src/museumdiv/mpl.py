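"""Mean path length (MPL) dating: make a non-clocklike phylogram ultrametric.

The MPL age of an internal node is the mean path length from the node to
its descendant tips.  Raw MPL ages need not be monotone when substitution
rates vary across lineages, so ages are repaired tips-to-root
(``age(parent) = max(age(parent), age(child) + delta)``) and then rescaled
so the root takes a requested age (default 1, i.e. relative time).

A per-node clock test compares the MPL of the two daughter subtrees.
Under a Poisson model of substitutions the variance of a subtree MPL is
``sum over branches of (tips below branch / n)^2 * branch length``; the
two daughters share no branches, so the variance of the difference is the
sum of the two subtree variances.  The z statistic is referred to a
standard normal (two-tailed), with a tree-wide Bonferroni verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.stats import norm

from .phylo import TreeError, as_chronogram, assert_binary, write_newick

__all__ = ["MplResult", "ClockTestResult", "mpl_ultrametricize", "clock_test"]

#: Minimal parent-child age separation used by the monotone repair.
MONOTONE_DELTA = 1e-9


@dataclass
class MplResult:
    """Ultrametric tree with relative node ages plus per-node clock tests."""

    tree: dendropy.Tree
    root_age: float
    node_ages: dict = field(repr=False)
    clock: "ClockTestResult | None" = None

    def newick(self) -> str:
        return write_newick(self.tree)


@dataclass
class ClockTestResult:
    """Per-node z statistics/p-values; NaN where a daughter is a single tip."""

    statistics: np.ndarray
    p_values: np.ndarray
    alpha: float
    rejected: bool  # any node significant after Bonferroni

    @property
    def n_tested(self) -> int:
        return int(np.sum(~np.isnan(self.p_values)))


def _subtree_stats(node: dendropy.Node, cache: dict) -> tuple[int, float, float]:
    """(tip count, sum of tip path lengths from node, Poisson MPL variance).

    The variance accumulates (c_b / n)^2 * l_b over branches b below the
    node, with c_b tips below branch b; computed bottom-up in one pass.
    """
    if node in cache:
        return cache[node]
    if node.is_leaf():
        res = (1, 0.0, 0.0)
    else:
        n = 0
        total = 0.0
        var = 0.0
        for child in node.child_nodes():
            cn, ctot, cvar = _subtree_stats(child, cache)
            blen = child.edge.length or 0.0
            n += cn
            total += ctot + cn * blen
            # child subtree variance rescaled to this node's tip count later;
            # store unnormalized: sum over branches of c_b^2 * l_b
            var += cvar + cn * cn * blen
        res = (n, total, var)
    cache[node] = res
    return res


def mpl_ultrametricize(
    tree: dendropy.Tree, root_age: float = 1.0, with_clock_test: bool = True
) -> MplResult:
    """Transform a rooted phylogram into an ultrametric tree via MPL ages.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted phylogram with branch lengths in substitutions/site (any
        positive unit works: the output is invariant to rescaling input
        lengths).
    root_age : float
        Age assigned to the root after rescaling (default 1: relative time).

    Returns
    -------
    MplResult with a new ultrametric tree of identical topology.
    """
    if root_age <= 0:
        raise TreeError("root_age must be positive")
    work = tree.clone(depth=1)
    cache: dict = {}
    n_root, tot_root, _ = _subtree_stats(work.seed_node, cache)
    if n_root < 2:
        raise TreeError("need at least 2 tips")
    root_mpl = tot_root / n_root
    if root_mpl <= 0:
        raise TreeError("tree height is zero: cannot date a star of zero lengths")

    raw = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            raw[node] = 0.0
        else:
            n, tot, _ = cache[node]
            raw[node] = tot / n
            # monotone repair, tips-to-root
            for child in node.child_nodes():
                if raw[child] + MONOTONE_DELTA > raw[node]:
                    raw[node] = raw[child] + MONOTONE_DELTA

    scale = root_age / raw[work.seed_node]
    ages = {node: age * scale for node, age in raw.items()}
    for node in work.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[node.parent_node] - ages[node]
    as_chronogram(work)

    clock = None
    if with_clock_test:
        try:
            clock = clock_test(tree)
        except TreeError:
            clock = None  # polytomies: dating still works, test does not
    return MplResult(tree=work, root_age=root_age, node_ages=ages, clock=clock)


def clock_test(tree: dendropy.Tree, alpha: float = 0.05,
               sites: float = 1.0) -> ClockTestResult:
    """Per-node molecular-clock test on a rooted binary phylogram.

    For each internal node whose daughters both contain >= 2 tips, compares
    the daughters' mean path lengths with a z statistic whose variance
    follows the Poisson substitution model (see module docstring).  Branch
    lengths are taken as expected numbers of substitutions; when they are
    per-site distances, pass the alignment length as ``sites`` (the Poisson
    variance of a per-site length l is l/sites).  Returns NaN for
    untestable nodes and a tree-wide Bonferroni verdict at ``alpha``.
    """
    if sites <= 0:
        raise TreeError("sites must be positive")
    assert_binary(tree, "the clock test")
    cache: dict = {}
    _subtree_stats(tree.seed_node, cache)
    stats, pvals = [], []
    for node in tree.preorder_internal_node_iter():
        left, right = node.child_nodes()
        nl, totl, varl = cache[left]
        nr, totr, varr = cache[right]
        if nl < 2 or nr < 2:
            stats.append(math.nan)
            pvals.append(math.nan)
            continue
        bl = left.edge.length or 0.0
        br = right.edge.length or 0.0
        mpl_l = totl / nl + bl
        mpl_r = totr / nr + br
        var_l = varl / nl**2 + bl
        var_r = varr / nr**2 + br
        denom = math.sqrt((var_l + var_r) / sites)
        if denom == 0:
            z = 0.0
        else:
            z = (mpl_l - mpl_r) / denom
        stats.append(z)
        pvals.append(2 * norm.sf(abs(z)))
    stats_arr = np.array(stats)
    p_arr = np.array(pvals)
    tested = p_arr[~np.isnan(p_arr)]
    rejected = bool(len(tested)) and bool(np.min(tested) < alpha / len(tested))
    return ClockTestResult(statistics=stats_arr, p_values=p_arr, alpha=alpha,
                           rejected=rejected)
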