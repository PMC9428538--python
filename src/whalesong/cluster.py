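"""Average-linkage (UPGMA) clustering, cophenetic validation and Newick export.

UPGMA repeatedly merges the closest pair of clusters, where inter-cluster
dissimilarity is the unweighted arithmetic mean over all cross-pairs of the
original dissimilarities. The merge height of a node is the dissimilarity
at which its children fused; UPGMA heights are monotone from leaves to
root, so the tree is ultrametric. The cophenetic distance between two
leaves is the height of their lowest common ancestor, and the cophenetic
correlation coefficient (CCC) — the Pearson correlation between input and
cophenetic dissimilarities over all unordered pairs — measures how
faithfully the tree summarizes the matrix (conventionally "good" above
0.8).

Merge ties are broken deterministically by the lexicographically smallest
pair of cluster representative labels (a cluster is represented by its
smallest leaf label).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterator, Optional

import numpy as np
from scipy import stats

from .matrix import DissimilarityMatrix

__all__ = ["Node", "ClusterTree", "upgma", "cophenetic_matrix", "ccc", "to_newick", "cut_tree"]


@dataclass
class Node:
    """A node of a rooted binary merge tree.

    Leaves have ``label`` set and height 0; internal nodes have two
    ``children`` and the merge ``height``. ``support`` (set by the
    bootstrap module) carries AU/BP values for the node's leafset.
    """

    height: float
    leafset: frozenset[str]
    label: Optional[str] = None
    children: Optional[tuple["Node", "Node"]] = None
    order: int = -1  # merge sequence number; -1 for leaves
    support: Optional[Any] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def rep(self) -> str:
        return min(self.leafset)

    def walk(self) -> Iterator["Node"]:
        """Postorder traversal."""
        if self.children is not None:
            for c in self.children:
                yield from c.walk()
        yield self


@dataclass
class ClusterTree:
    """A rooted UPGMA tree over labelled items."""

    root: Node
    labels: tuple[str, ...]

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def splits(self, include_root: bool = False) -> list[Node]:
        """Internal nodes whose leafset is a proper, non-trivial subset."""
        return [n for n in self.internal_nodes()
                if include_root or len(n.leafset) < len(self.labels)]

    def leafsets(self) -> set[frozenset[str]]:
        return {n.leafset for n in self.splits()}

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (for dendrogram plotting)."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        merges = sorted(self.internal_nodes(), key=lambda n: n.order)
        ids: dict[int, Node] = {}
        Z = np.zeros((len(merges), 4))
        node_id: dict[int, int] = {}
        for leaf in self.leaves():
            node_id[id(leaf)] = index[leaf.label]
        for k, n in enumerate(merges):
            a, b = n.children
            Z[k, 0] = node_id[id(a)]
            Z[k, 1] = node_id[id(b)]
            Z[k, 2] = n.height
            Z[k, 3] = len(n.leafset)
            node_id[id(n)] = len(self.labels) + k
        return Z


def upgma(d: DissimilarityMatrix) -> ClusterTree:
    """Cluster a dissimilarity matrix by unweighted average linkage."""
    if not isinstance(d, DissimilarityMatrix):
        d = DissimilarityMatrix(d.labels, d.values)  # validates symmetry/sign
    labels = d.labels
    n = len(labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 items")
    D = d.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    nodes: list[Optional[Node]] = [
        Node(0.0, frozenset([lab]), label=lab) for lab in labels
    ]
    sizes = np.ones(n)
    for step in range(n - 1):
        m = D.min()
        ties = np.argwhere(D == m)
        best = None
        for i, j in ties:
            if i >= j:
                continue
            a, b = nodes[i], nodes[j]
            key = tuple(sorted((a.rep, b.rep)))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, i, j = best
        a, b = nodes[i], nodes[j]
        first, second = (a, b) if a.rep <= b.rep else (b, a)
        parent = Node(float(m), a.leafset | b.leafset, children=(first, second), order=step)
        # unweighted average linkage update
        for k in range(n):
            if nodes[k] is None or k in (i, j):
                continue
            D[i, k] = D[k, i] = (sizes[i] * D[i, k] + sizes[j] * D[j, k]) / (
                sizes[i] + sizes[j]
            )
        sizes[i] += sizes[j]
        nodes[i] = parent
        nodes[j] = None
        D[j, :] = np.inf
        D[:, j] = np.inf
        D[i, i] = np.inf
    root = next(nd for nd in nodes if nd is not None)
    return ClusterTree(root, labels)


def cophenetic_matrix(tree: ClusterTree) -> DissimilarityMatrix:
    """Pairwise merge height of the lowest common ancestor; ultrametric."""
    index = {lab: i for i, lab in enumerate(tree.labels)}
    n = len(tree.labels)
    values = np.zeros((n, n))
    for node in tree.internal_nodes():
        left, right = node.children
        li = [index[l] for l in left.leafset]
        ri = [index[l] for l in right.leafset]
        values[np.ix_(li, ri)] = node.height
        values[np.ix_(ri, li)] = node.height
    return DissimilarityMatrix(tree.labels, values)


def ccc(d: DissimilarityMatrix, tree: ClusterTree) -> float:
    """Cophenetic correlation coefficient of a tree against its input matrix.

    Pearson correlation between the strict-lower-triangle entries of ``d``
    and of the tree's cophenetic matrix. Raises if either vector has zero
    variance (degenerate clustering).
    """
    coph = cophenetic_matrix(tree).reorder(d.labels)
    x = d.condensed()
    y = coph.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("CCC undefined: zero variance in pairwise distances")
    return float(stats.pearsonr(x, y)[0])


def _format_support(support: Any) -> str:
    au = getattr(support, "au", None)
    bp = getattr(support, "bp", None)
    if au is None or bp is None:
        return ""
    return f"{au:.3f}/{bp:.3f}"


def to_newick(tree: ClusterTree, with_support: bool = True) -> str:
    """Newick string with branch lengths from merge heights.

    Heights are halved so that the path between two leaves equals their
    cophenetic distance (the usual ultrametric dendrogram convention: a
    2-leaf tree merging at 0.4 renders as ``(A:0.2,B:0.2);``). Internal
    node labels carry support as ``AU/BP`` when present.
    """

    def render(node: Node, parent_height: float) -> str:
        bl = (parent_height - node.height) / 2.0
        if node.is_leaf:
            return f"{node.label}:{bl:g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        label = _format_support(node.support) if with_support else ""
        return f"({inner}){label}:{bl:g}"

    root = tree.root
    inner = ",".join(render(c, root.height) for c in root.children)
    label = _format_support(root.support) if with_support else ""
    return f"({inner}){label};"


def cut_tree(tree: ClusterTree, k: int) -> dict[str, int]:
    """Flat partition into ``k`` clusters by undoing the k-1 highest merges.

    Ties between equal-height nodes are resolved by representative label.
    Returns a label -> cluster-id map; cluster ids are assigned in order of
    each cluster's representative label.
    """
    if not 1 <= k <= len(tree.labels):
        raise ValueError(f"k must be in [1, {len(tree.labels)}]")
    clusters: list[Node] = [tree.root]
    while len(clusters) < k:
        candidates = [n for n in clusters if not n.is_leaf]
        node = max(candidates, key=lambda n: (n.height, n.rep))
        clusters.remove(node)
        clusters.extend(node.children)
    clusters.sort(key=lambda n: n.rep)
    out: dict[str, int] = {}
    for cid, node in enumerate(clusters):
        for lab in node.leafset:
            out[lab] = cid
    return out
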