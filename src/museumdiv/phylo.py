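"""Tree data model and utilities shared by every analysis stage.

Trees are held as :class:`dendropy.Tree` objects.  This module adds the
conventions the rest of the package relies on:

* ages are measured backward from the present, tips at age 0;
* a *chronogram* is a rooted ultrametric tree (all root-to-tip path
  lengths equal within a relative tolerance of the tree height);
* analyses that assume binary trees reject polytomies explicitly.

Newick and NEXUS reading (translate tables, ``[&...]`` comments, quoted
labels) and pruning are delegated to dendropy; the helpers here validate
inputs and extract the derived quantities (node ages, branching times,
lineage-through-time curves) used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "BranchingTimes",
    "LttCurve",
    "read_tree",
    "parse_tree",
    "write_newick",
    "tip_labels",
    "is_binary",
    "assert_binary",
    "tree_height",
    "node_depths",
    "check_ultrametric",
    "node_ages",
    "as_chronogram",
    "branching_times",
    "prune_tips",
    "extract_clade",
    "ltt_curve",
    "ltt_table",
]

#: Relative ultrametricity tolerance (fraction of tree height).  MCC trees
#: from Bayesian dating software carry rounding noise at this scale.
ULTRAMETRIC_RTOL = 1e-6

#: Trees failing ultrametricity by no more than this relative amount may be
#: snapped back onto a clock by adjusting terminal branches (explicit flag).
SNAP_RTOL = 1e-3


class TreeError(ValueError):
    """Raised for malformed or contract-violating tree inputs."""


# ---------------------------------------------------------------------------
# I/O


def read_tree(source: str | Path, schema: str | None = None) -> dendropy.Tree:
    """Read a rooted tree from a newick or NEXUS file or literal string.

    The schema is auto-detected from a leading ``#NEXUS`` token unless given
    explicitly.  Bracketed metadata comments (``[&...]``) are stripped.
    Negative branch lengths are rejected.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and "(" not in source and Path(str(source)).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    if schema is None:
        schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=schema,
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeError(f"could not parse {schema} tree: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length {edge.length!r}")
    return tree


def parse_tree(text: str, schema: str | None = None) -> dendropy.Tree:
    """Parse a newick/NEXUS string (alias of :func:`read_tree` for strings)."""
    return read_tree(text, schema=schema)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single newick line (round-trips lengths)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,  # keep quoted labels intact on round-trip
        real_value_format_specifier=".12g",
    ).strip()


# ---------------------------------------------------------------------------
# Structure checks


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def n_tips(tree: dendropy.Tree) -> int:
    return sum(1 for _ in tree.leaf_node_iter())


def is_binary(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_node_iter():
        nc = len(node.child_nodes())
        if nc not in (0, 2):
            return False
    return True


def assert_binary(tree: dendropy.Tree, context: str = "this analysis") -> None:
    for node in tree.preorder_node_iter():
        nc = len(node.child_nodes())
        if nc not in (0, 2):
            raise TreeError(
                f"{context} requires a strictly binary tree; found a node "
                f"with {nc} children"
            )


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Root-to-node path lengths (missing edge lengths count as 0)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def check_ultrametric(
    tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL, snap: bool = False
) -> None:
    """Validate that all root-to-tip path lengths agree within ``rtol``.

    With ``snap=True``, trees off by at most :data:`SNAP_RTOL` (relative to
    height) have their terminal branches adjusted in place so every tip sits
    exactly at the maximum depth; larger violations still raise.
    """
    depths = node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    if not leaves:
        raise TreeError("tree has no tips")
    d = np.array([depths[leaf] for leaf in leaves])
    height = d.max()
    if height <= 0:
        raise TreeError("tree height is zero")
    spread = height - d.min()
    if spread <= rtol * height:
        return
    if snap and spread <= SNAP_RTOL * height:
        for leaf, di in zip(leaves, d):
            leaf.edge.length = (leaf.edge.length or 0.0) + (height - di)
        return
    hi = leaves[int(np.argmax(d))].taxon.label
    lo = leaves[int(np.argmin(d))].taxon.label
    raise TreeError(
        f"tree is not ultrametric: depth({hi}) = {d.max():.6g} vs "
        f"depth({lo}) = {d.min():.6g} (relative spread {spread / height:.3g} "
        f"exceeds tolerance {rtol:g})"
    )


def node_ages(
    tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL, snap: bool = False
) -> dict[dendropy.Node, float]:
    """Ages (time before present) for every node of an ultrametric tree.

    Tips are forced to age 0 exactly; internal ages are height minus depth.
    """
    check_ultrametric(tree, rtol=rtol, snap=snap)
    depths = node_depths(tree)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    ages = {}
    for node in tree.preorder_node_iter():
        ages[node] = 0.0 if node.is_leaf() else height - depths[node]
    return ages


def as_chronogram(
    tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL, snap: bool = False
) -> dendropy.Tree:
    """Validate a tree as a chronogram and annotate node ``age`` attributes."""
    ages = node_ages(tree, rtol=rtol, snap=snap)
    for node, age in ages.items():
        node.age = age
    return tree


# ---------------------------------------------------------------------------
# Branching times and LTT


@dataclass(frozen=True)
class BranchingTimes:
    """Internal-node ages of a binary chronogram, sorted descending."""

    n_tips: int
    ages: np.ndarray  # shape (n_tips - 1,), strictly positive, descending

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        if len(ages) != self.n_tips - 1:
            raise TreeError(
                f"binary tree with {self.n_tips} tips must have "
                f"{self.n_tips - 1} branching times, got {len(ages)}"
            )
        if np.any(ages <= 0):
            raise TreeError("branching times must be strictly positive")
        if np.any(np.diff(ages) > 0):
            raise TreeError("branching times must be sorted descending")

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    def internode_intervals(self) -> np.ndarray:
        """g_k = time during which exactly k lineages exist, k = 2..n.

        ``g[k-2]`` is the interval with k lineages; the last entry runs from
        the most recent branching event to the present.
        """
        bounds = np.concatenate([self.ages, [0.0]])
        return -np.diff(bounds)


@dataclass(frozen=True)
class LttCurve:
    """Lineage-count step function: ``counts[i]`` lineages from ``ages[i]``."""

    ages: np.ndarray    # descending event ages
    counts: np.ndarray  # 2, 3, ..., n_tips


def branching_times(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> BranchingTimes:
    """Extract sorted internal-node ages from a binary ultrametric tree."""
    assert_binary(tree, "branching-time extraction")
    leaves = sum(1 for _ in tree.leaf_node_iter())
    if leaves < 3:
        raise TreeError("need at least 3 tips for branching times")
    ages = node_ages(tree, rtol=rtol)
    internal = sorted(
        (age for node, age in ages.items() if not node.is_leaf()), reverse=True
    )
    return BranchingTimes(n_tips=leaves, ages=np.array(internal))


def ltt_curve(bt: BranchingTimes) -> LttCurve:
    """Lineages-through-time step curve from branching times."""
    n = bt.n_tips
    return LttCurve(ages=bt.ages.copy(), counts=np.arange(2, n + 1))


def ltt_table(bt: BranchingTimes):
    """LTT curve as a two-column pandas DataFrame (age, lineages)."""
    import pandas as pd

    curve = ltt_curve(bt)
    return pd.DataFrame({"age": curve.ages, "lineages": curve.counts})


# ---------------------------------------------------------------------------
# Pruning / clade extraction


def prune_tips(tree: dendropy.Tree, drop: Iterable[str]) -> dendropy.Tree:
    """Remove the named tips, suppressing resulting degree-2 nodes.

    Path lengths between retained tips are conserved.  Edge lengths of
    suppressed unifurcations are merged; a stale root stub survives as the
    new root's edge length (it does not affect tip-to-tip distances).
    """
    drop = set(drop)
    if not drop:
        return tree.clone(depth=1)
    have = set(tip_labels(tree))
    unknown = drop - have
    if unknown:
        raise TreeError(f"cannot prune unknown tip label(s): {sorted(unknown)}")
    keep = have - drop
    if len(keep) < 2:
        raise TreeError("pruning would leave fewer than 2 tips")
    pruned = tree.extract_tree_with_taxa_labels(keep)
    # fold a leftover root stub into the root edge, not into child branches
    pruned.seed_node.edge.length = None
    return pruned


def extract_clade(tree: dendropy.Tree, labels: Sequence[str]) -> dendropy.Tree:
    """Subtree rooted at the MRCA of the given tip labels."""
    labels = list(labels)
    have = set(tip_labels(tree))
    missing = [x for x in labels if x not in have]
    if missing:
        raise TreeError(f"tip label(s) not in tree: {missing}")
    mrca = tree.mrca(taxon_labels=labels)
    clade_tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    sub = tree.extract_tree_with_taxa_labels(clade_tips)
    sub.seed_node.edge.length = None
    return sub
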