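"""Distance computation, neighbor-joining baseline, rooting and tree metrics.

The pipeline's bundled tree builder is classic neighbor joining over
p-distances; an externally computed tree (e.g. a maximum-likelihood newick)
can be imported instead wherever a tree is consumed. dendropy supplies the
tree container; the NJ agglomeration itself is implemented here because its
tie-breaking and branch-length conventions are part of the pipeline's
contract (deterministic row-major Q-minimum, negative lengths clamped to 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .seqio import AMINO_ACIDS, SequenceRecord

#: residue codes treated as missing under pairwise deletion
_AMBIGUOUS = set("XBZ-.")


@dataclass
class Alignment:
    """A multiple sequence alignment: ordered ids over equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(self.ids) < 2:
            raise ValueError("an alignment needs at least two rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        ncol = len(self.rows[0])
        if ncol < 1 or any(len(r) != ncol for r in self.rows):
            raise ValueError("alignment rows must share a positive length")
        self.rows = [r.upper() for r in self.rows]

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "Alignment":
        recs = list(records)
        return cls(ids=[r.seq_id for r in recs],
                   rows=[r.residues for r in recs])

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        index = {i: k for k, i in enumerate(self.ids)}
        return Alignment(ids=list(keep_ids),
                         rows=[self.rows[index[i]] for i in keep_ids])


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                fh.write(name + "\t" +
                         "\t".join(f"{x:.10g}" for x in self.values[i]) + "\n")


def _encode(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode rows; returns (codes, valid mask).

    U (selenocysteine) is folded into C so the 20-state model stays closed;
    X/B/Z and gaps are flagged invalid for pairwise deletion.
    """
    code_of = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    code_of["U"] = code_of["C"]
    n, L = alignment.n_rows, alignment.n_cols
    codes = np.zeros((n, L), dtype=np.int8)
    valid = np.zeros((n, L), dtype=bool)
    for i, row in enumerate(alignment.rows):
        for j, ch in enumerate(row):
            k = code_of.get(ch)
            if k is not None:
                codes[i, j] = k
                valid[i, j] = True
    return codes, valid


def p_distance(alignment: Alignment, gap_policy: str = "pairwise_deletion",
               ) -> DistanceMatrix:
    """Proportion of mismatching sites over pairwise-comparable columns.

    A column is comparable for a pair when both rows carry an unambiguous
    residue there. A pair with zero comparable columns is an error.
    """
    if gap_policy != "pairwise_deletion":
        raise ValueError(f"unsupported gap policy: {gap_policy!r}")
    codes, valid = _encode(alignment)
    v = valid.astype(np.float32)
    comparable = v @ v.T
    matches = np.zeros_like(comparable)
    for k in range(len(AMINO_ACIDS)):
        is_k = ((codes == k) & valid).astype(np.float32)
        matches += is_k @ is_k.T
    bad = np.argwhere((comparable == 0) & ~np.eye(alignment.n_rows, dtype=bool))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"no comparable columns between {alignment.ids[i]!r} and "
            f"{alignment.ids[j]!r}")
    with np.errstate(invalid="ignore"):
        d = 1.0 - matches / comparable
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(ids=list(alignment.ids), values=d.astype(float))


def jc20_correct(p: float) -> float:
    """Poisson (Jukes-Cantor-style) distance correction for 20 states.

    d = -(19/20) * ln(1 - (20/19) * p); saturates as p -> 19/20.
    """
    if not 0 <= p < 19 / 20:
        raise ValueError(f"p={p} outside [0, 0.95): distance saturated")
    return -(19 / 20) * math.log(1 - (20 / 19) * p)


# --------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbor joining (Saitou-Nei with the Studier-Keppler Q).

    Deterministic: the Q minimum is taken in row-major (row, column) order;
    negative branch-length estimates are clamped to 0. Returns an unrooted
    tree whose seed node is the final trifurcation.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError(f"neighbor joining needs >=3 taxa, got {n}")
    tns = dendropy.TaxonNamespace(dm.ids)
    nodes: list[dendropy.Node] = []
    for label in dm.ids:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    D = dm.values.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [(d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2,
               (d02 + d12 - d01) / 2]
    root = dendropy.Node()
    for node, length in zip(nodes, lengths):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# --------------------------------------------------------------------------
# rooting and path metrics

def _find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == label:
            return leaf
    raise KeyError(f"leaf {label!r} not present in tree")


def root_with_outgroup(tree: dendropy.Tree, outgroup_leaf: str) -> dendropy.Tree:
    """Root a tree at the midpoint of the outgroup's pendant edge.

    Operates on a clone; patristic distances between leaves are unchanged.
    """
    rooted = tree.clone(depth=1)
    leaf = _find_leaf(rooted, outgroup_leaf)
    edge = leaf.edge
    half = (edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(edge, length1=half, length2=half,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def _depths_from_root(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    return depth


def patristic_distance(tree: dendropy.Tree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths along the unique path between two leaves."""
    a, b = _find_leaf(tree, leaf_a), _find_leaf(tree, leaf_b)
    if a is b:
        return 0.0
    depth = _depths_from_root(tree)
    ancestors_a = {}
    node = a
    while node is not None:
        ancestors_a[node] = depth[node]
        node = node.parent_node
    node = b
    while node not in ancestors_a:
        node = node.parent_node
    return depth[a] + depth[b] - 2 * depth[node]


def leaf_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs patristic distances, computed once per tree."""
    leaves = [l for l in tree.leaf_node_iter()]
    labels = [l.taxon.label for l in leaves]
    depth = _depths_from_root(tree)
    n = len(leaves)
    # ancestor chains per leaf, then LCA depth via first shared node
    chains = []
    for leaf in leaves:
        chain = {}
        node = leaf
        while node is not None:
            chain[node] = depth[node]
            node = node.parent_node
        chains.append(chain)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            node = leaves[j]
            while node not in chains[i]:
                node = node.parent_node
            dij = depth[leaves[i]] + depth[leaves[j]] - 2 * depth[node]
            d[i, j] = d[j, i] = max(dij, 0.0)
    return DistanceMatrix(ids=labels, values=d)


def path_edge_count(tree: dendropy.Tree, leaf_a: str, leaf_b: str) -> int:
    """Number of edges on the leaf-to-leaf path (internal nodes = edges-1)."""
    a, b = _find_leaf(tree, leaf_a), _find_leaf(tree, leaf_b)
    if a is b:
        return 0
    steps_a = {}
    node, k = a, 0
    while node is not None:
        steps_a[node] = k
        node = node.parent_node
        k += 1
    node, k = b, 0
    while node not in steps_a:
        node = node.parent_node
        k += 1
    return steps_a[node] + k


def mrca(tree: dendropy.Tree, leaves: Sequence[str]) -> dendropy.Node:
    """Most recent common ancestor of a set of leaves (rooted trees only)."""
    if not tree.is_rooted:
        raise ValueError("MRCA is undefined on an unrooted tree")
    if not leaves:
        raise ValueError("need at least one leaf")
    nodes = [_find_leaf(tree, l) for l in leaves]
    if len(nodes) == 1:
        return nodes[0]
    ancestors = []
    node = nodes[0]
    while node is not None:
        ancestors.append(node)
        node = node.parent_node
    anc_set = set(ancestors)
    deepest = 0
    for other in nodes[1:]:
        node = other
        while node not in anc_set:
            node = node.parent_node
        deepest = max(deepest, ancestors.index(node))
    return ancestors[deepest]


def clade_leaves(tree: dendropy.Tree, node: dendropy.Node) -> set[str]:
    """Leaf labels descending from ``node`` (the node itself if a leaf)."""
    if node.is_leaf():
        return {node.taxon.label}
    return {l.taxon.label for l in node.leaf_iter()}


def rf_distance(tree1: dendropy.Tree, tree2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric difference of unrooted bipartitions."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=tree1.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns,
                          preserve_underscores=True)
    b = dendropy.Tree.get(data=tree2.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns,
                          preserve_underscores=True)
    la = {l.taxon.label for l in a.leaf_node_iter()}
    lb = {l.taxon.label for l in b.leaf_node_iter()}
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    a.is_rooted = b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))
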