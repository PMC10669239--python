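import dendropy
import numpy as np
import pytest

from mmphylo.seqio import SequenceRecord


def make_record(seq_id: str, residues: str, **kw) -> SequenceRecord:
    kw.setdefault("accession", seq_id)
    return SequenceRecord(seq_id=seq_id, residues=residues, **kw)


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       min_len: float = 0.05, max_len: float = 2.0,
                       ) -> dendropy.Tree:
    """Random binary tree topology with uniform branch lengths."""
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        node = dendropy.Node(taxon=tns.new_taxon(f"T{i}"))
        node.edge.length = float(rng.uniform(min_len, max_len))
        nodes.append(node)
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(0, len(nodes))))
        b = nodes.pop(int(rng.integers(0, len(nodes))))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(min_len, max_len))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def additive_matrix(tree: dendropy.Tree):
    """Path-length matrix computed by dendropy, independent of mmphylo."""
    from mmphylo.phylo import DistanceMatrix

    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    return DistanceMatrix(ids=labels, values=d)


@pytest.fixture(scope="session")
def default_dataset():
    """Simulator defaults at seed 1: the frozen curation fixture."""
    from mmphylo.synthetic import SimParams, generate_dataset

    return generate_dataset(SimParams(), seed=1)
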