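"""Branch-support utilities and gene concordance factors.

For each internal branch of the reference tree the four clade groups
around the branch (A,B on one side, C,D on the other) define a quartet.
A gene tree is *decisive* for the branch if it contains at least one
taxon from each group; among decisive trees the induced resolution is
classified as concordant (AB|CD), first alternative (AC|BD), second
alternative (AD|BC), or paraphyly/polytomy, and each class is reported
as a percentage of decisive trees (gCF / gDF1 / gDF2 / gDFP).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import skbio

from .core import Tree, read_newick_string

logger = logging.getLogger("baitforge")


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of a taxon universe; ``side`` is the smaller
    half (ties broken by sorted-tuple order)."""

    side: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.side or not (self.universe - self.side):
            raise ValueError("both sides of a bipartition must be non-empty")
        if not self.side <= self.universe:
            raise ValueError("side must be a subset of the universe")

    @classmethod
    def of(cls, side, universe) -> "Bipartition":
        side, universe = frozenset(side), frozenset(universe)
        other = universe - side
        if (len(other), tuple(sorted(other))) < (len(side), tuple(sorted(side))):
            side = other
        return cls(side, universe)

    def __str__(self) -> str:
        a = ",".join(sorted(self.side))
        b = ",".join(sorted(self.universe - self.side))
        return f"{a}|{b}"


def _neighbors(node) -> list:
    nb = list(node.child_nodes())
    if node.parent_node is not None:
        nb.append(node.parent_node)
    return nb


def _leaves_via(start, blocked) -> frozenset[str]:
    """Leaf labels reachable from ``start`` without passing ``blocked``."""
    seen = {blocked, start}
    stack = [start]
    labels = []
    while stack:
        node = stack.pop()
        if node.is_leaf():
            labels.append(node.taxon.label)
        for nb in _neighbors(node):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return frozenset(labels)


def _internal_edges(tree: Tree):
    """Internal edges of the unrooted view of a (possibly rooted) tree.

    Works on a derooted clone so a rooted input's root edge does not
    produce a spurious branch.
    """
    clone = tree.clone(depth=1)
    clone.deroot()
    for edge in clone.preorder_edge_iter():
        head = edge.head_node
        tail = edge.tail_node
        if tail is None or head.is_leaf():
            continue
        if tail.parent_node is None and len(tail.child_nodes()) < 3:
            continue  # degenerate rooted-root artifact
        yield clone, tail, head


def bipartitions(tree: Tree) -> list[Bipartition]:
    """Non-trivial bipartitions, one per internal branch (unrooted)."""
    universe = frozenset(
        leaf.taxon.label for leaf in tree.leaf_node_iter())
    out = []
    seen = set()
    for _, tail, head in _internal_edges(tree):
        side = _leaves_via(head, tail)
        if len(side) < 2 or len(universe - side) < 2:
            continue
        bp = Bipartition.of(side, universe)
        if bp not in seen:
            seen.add(bp)
            out.append(bp)
    return out


def collapse_low_support(tree: Tree, threshold: float = 30.0) -> Tree:
    """Contract internal branches with support below the threshold.

    Branches without a support value are untouched.  Leaf set is never
    changed; the result has at most as many internal branches.
    """
    out = tree.clone(depth=1)

    def _support(nd):
        s = getattr(nd, "support", None)
        if s is None and nd.label is not None:
            try:
                s = float(nd.label)
            except ValueError:
                s = None
        return s

    to_collapse = [
        nd for nd in out.preorder_node_iter()
        if (not nd.is_leaf() and nd.parent_node is not None
            and _support(nd) is not None and _support(nd) < threshold)
    ]
    for nd in to_collapse:
        nd.edge.collapse()
    logger.info("collapsed %d low-support branches", len(to_collapse))
    return out


@dataclass
class BranchConcordance:
    branch: Bipartition
    n_decisive: int
    gcf: Optional[float]
    gdf1: Optional[float]
    gdf2: Optional[float]
    gdfp: Optional[float]


def _branch_groups(tree: Tree):
    """Yield (bipartition-side groups) around each internal branch:
    (A, B, C, D) with A,B on the tail side and C,D on the head side.

    Requires a bifurcating reference tree (each side resolves into
    exactly two groups); polytomous branches are skipped with a warning.
    """
    universe = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    seen = set()
    for clone, tail, head in _internal_edges(tree):
        head_groups = [
            _leaves_via(w, head) for w in _neighbors(head) if w is not tail
        ]
        tail_groups = [
            _leaves_via(w, tail) for w in _neighbors(tail) if w is not head
        ]
        if len(head_groups) != 2 or len(tail_groups) != 2:
            logger.warning("skipping polytomous branch in reference tree")
            continue
        side = frozenset().union(*head_groups)
        if len(side) < 2 or len(universe - side) < 2:
            continue
        bp = Bipartition.of(side, universe)
        if bp in seen:
            continue
        seen.add(bp)
        yield bp, tail_groups[0], tail_groups[1], head_groups[0], head_groups[1]


def _gene_tree_splits(gene_tree: Tree) -> tuple[frozenset[str], set[frozenset[str]]]:
    """Taxa and canonical non-trivial splits of a gene tree.

    A split is stored as the side containing the lexicographically
    smallest taxon label of the gene tree.
    """
    taxa = frozenset(l.taxon.label for l in gene_tree.leaf_node_iter())
    anchor = min(taxa)
    splits = set()
    for bp in bipartitions(gene_tree):
        side = bp.side if anchor in bp.side else bp.universe - bp.side
        splits.add(side)
    return taxa, splits


def gene_concordance_factors(
    reference: Tree, gene_trees: Sequence[Tree]
) -> list[BranchConcordance]:
    """Per-branch gCF/gDF1/gDF2/gDFP over a set of gene trees.

    Gene-tree taxa must be a subset of the reference taxa.  Gene trees
    are treated as unrooted; their branch supports are ignored.  For a
    branch with no decisive gene trees the percentages are None.
    """
    ref_taxa = frozenset(l.taxon.label for l in reference.leaf_node_iter())
    cached = []
    for gt in gene_trees:
        taxa, splits = _gene_tree_splits(gt)
        extra = taxa - ref_taxa
        if extra:
            raise ValueError(
                f"gene-tree taxa not in reference: {sorted(extra)[:5]}")
        cached.append((taxa, splits))

    results = []
    for bp, A, B, C, D in _branch_groups(reference):
        n_dec = 0
        counts = {"gcf": 0, "gdf1": 0, "gdf2": 0, "gdfp": 0}
        for taxa, splits in cached:
            a, b_, c, d_ = A & taxa, B & taxa, C & taxa, D & taxa
            if not (a and b_ and c and d_):
                continue
            n_dec += 1
            anchor = min(taxa)
            def canon(side: frozenset[str]) -> frozenset[str]:
                return side if anchor in side else taxa - side
            if canon(a | b_) in splits:
                counts["gcf"] += 1
            elif canon(a | c) in splits:
                counts["gdf1"] += 1
            elif canon(a | d_) in splits:
                counts["gdf2"] += 1
            else:
                counts["gdfp"] += 1
        if n_dec:
            results.append(BranchConcordance(
                bp, n_dec,
                *(100.0 * counts[k] / n_dec
                  for k in ("gcf", "gdf1", "gdf2", "gdfp"))
            ))
        else:
            results.append(BranchConcordance(bp, 0, None, None, None, None))
    return results


def concordance_table(records: Sequence[BranchConcordance]) -> pd.DataFrame:
    return pd.DataFrame([
        {"branch": str(r.branch), "n_decisive": r.n_decisive,
         "gcf": r.gcf, "gdf1": r.gdf1, "gdf2": r.gdf2, "gdfp": r.gdfp}
        for r in records
    ])


def nj_tree(distances: pd.DataFrame) -> Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Deterministic for a given taxon order.  Negative off-diagonal
    entries are an error.  Fixture/smoke-test builder, not an inference
    tool.
    """
    if distances.shape[0] != distances.shape[1] or distances.shape[0] < 3:
        raise ValueError("need a square matrix of size >= 3")
    arr = distances.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(arr) != 0):
        raise ValueError("diagonal must be zero")
    off = arr[~np.eye(len(arr), dtype=bool)]
    if np.any(off < 0):
        raise ValueError("negative off-diagonal distances")
    dm = skbio.DistanceMatrix(arr, ids=[str(t) for t in distances.index])
    buf = io.StringIO()
    skbio.tree.nj(dm).write(buf, format="newick")
    return read_newick_string(buf.getvalue())
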