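"""UPGMA, cophenetic distances, CCC and Newick export."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from helpers import upgma_oracle
from whalesong import DissimilarityMatrix, ccc, cophenetic_matrix, cut_tree, to_newick, upgma


def dmat(labels, entries):
    n = len(labels)
    v = np.zeros((n, n))
    for (i, j), x in entries.items():
        v[i, j] = v[j, i] = x
    return DissimilarityMatrix(tuple(labels), v)


@pytest.fixture
def three_leaf():
    # hand-computed: merge (A,B) at 0.2, then C at (0.6+0.8)/2 = 0.7
    return dmat("ABC", {(0, 1): 0.2, (0, 2): 0.6, (1, 2): 0.8})


def test_two_leaf_merge_height():
    t = upgma(dmat("AB", {(0, 1): 0.4}))
    assert t.root.height == pytest.approx(0.4)
    assert t.root.leafset == frozenset("AB")


def test_three_leaf_hand_oracle(three_leaf):
    t = upgma(three_leaf)
    heights = sorted((n.height, n.leafset) for n in t.internal_nodes())
    assert heights[0] == (pytest.approx(0.2), frozenset("AB"))
    assert heights[1] == (pytest.approx(0.7), frozenset("ABC"))
    coph = cophenetic_matrix(t).reorder(("A", "B", "C")).values
    assert coph[0, 1] == pytest.approx(0.2)
    assert coph[0, 2] == coph[1, 2] == pytest.approx(0.7)


def test_three_leaf_ccc_closed_form(three_leaf):
    # Pearson of (0.2, 0.6, 0.8) against (0.2, 0.7, 0.7): exact value
    # (1/6) / sqrt((42/225) * (1/6)) = 0.944911...
    t = upgma(three_leaf)
    assert ccc(three_leaf, t) == pytest.approx(0.9449111825230679, abs=1e-9)


def test_upgma_rejects_asymmetric_or_negative():
    with pytest.raises(ValueError):
        DissimilarityMatrix(("A", "B"), np.array([[0.0, 1.0], [0.5, 0.0]]))
    with pytest.raises(ValueError):
        DissimilarityMatrix(("A", "B"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_upgma_matches_bruteforce_reference_on_random_matrices(rng):
    for seed in range(100):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 8))
        v = r.uniform(0.05, 1.0, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        labels = tuple(f"L{k}" for k in range(n))
        t = upgma(DissimilarityMatrix(labels, v))
        got = sorted((n_.order, n_.height, n_.leafset) for n_ in t.internal_nodes())
        expected = upgma_oracle(labels, v)
        for (order, height, leafset), (eh, eset) in zip(got, expected):
            assert leafset == eset
            assert height == pytest.approx(eh)


def test_upgma_matches_scipy_average_linkage(rng):
    # independent library cross-check on a tie-free matrix
    v = rng.uniform(0.1, 1.0, size=(10, 10))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = tuple(f"L{k:02d}" for k in range(10))
    t = upgma(DissimilarityMatrix(labels, v))
    Z = hierarchy.linkage(squareform(v), method="average")
    ours = sorted(n.height for n in t.internal_nodes())
    assert np.allclose(ours, sorted(Z[:, 2]))
    scipy_coph = squareform(hierarchy.cophenet(Z))
    assert np.allclose(cophenetic_matrix(t).values, scipy_coph)


def test_upgma_invariant_under_label_permutation(rng):
    v = rng.uniform(0.1, 1.0, size=(7, 7))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = tuple(f"L{k}" for k in range(7))
    t1 = upgma(DissimilarityMatrix(labels, v))
    perm = rng.permutation(7)
    t2 = upgma(DissimilarityMatrix(tuple(labels[i] for i in perm), v[np.ix_(perm, perm)]))
    assert {(n.leafset, round(n.height, 12)) for n in t1.internal_nodes()} == \
        {(n.leafset, round(n.height, 12)) for n in t2.internal_nodes()}


def test_cophenetic_is_ultrametric(rng):
    v = rng.uniform(0.1, 1.0, size=(8, 8))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = tuple(f"L{k}" for k in range(8))
    coph = cophenetic_matrix(upgma(DissimilarityMatrix(labels, v))).values
    for i, j, k in itertools.permutations(range(8), 3):
        assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-12


def test_ccc_is_one_exactly_on_ultrametric_input(rng):
    v = rng.uniform(0.1, 1.0, size=(9, 9))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = tuple(f"L{k}" for k in range(9))
    ultra = cophenetic_matrix(upgma(DissimilarityMatrix(labels, v)))
    assert ccc(ultra, upgma(ultra)) == pytest.approx(1.0, abs=1e-12)


def test_ccc_affine_invariance_and_upgma_equivariance(three_leaf, rng):
    a, b = 2.5, 0.3
    scaled_values = a * three_leaf.values + b
    np.fill_diagonal(scaled_values, 0)
    scaled = DissimilarityMatrix(three_leaf.labels, scaled_values)
    t0, t1 = upgma(three_leaf), upgma(scaled)
    assert {n.leafset for n in t0.internal_nodes()} == {n.leafset for n in t1.internal_nodes()}
    for n0, n1 in zip(sorted(t0.internal_nodes(), key=lambda n: n.order),
                      sorted(t1.internal_nodes(), key=lambda n: n.order)):
        assert n1.height == pytest.approx(a * n0.height + b)
    assert ccc(scaled, t1) == pytest.approx(ccc(three_leaf, t0))


def test_ccc_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        d = dmat("ABC", {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5})
        ccc(d, upgma(d))


def test_newick_two_and_three_leaf_strings(three_leaf):
    t2 = upgma(dmat("AB", {(0, 1): 0.4}))
    assert to_newick(t2, with_support=False) == "(A:0.2,B:0.2);"
    t3 = upgma(three_leaf)
    assert to_newick(t3, with_support=False) == "((A:0.1,B:0.1):0.25,C:0.35);"


def test_newick_round_trips_through_dendropy(rng):
    v = rng.uniform(0.1, 1.0, size=(6, 6))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = tuple(f"L{k}" for k in range(6))
    t = upgma(DissimilarityMatrix(labels, v))
    parsed = dendropy.Tree.get(data=to_newick(t, with_support=False), schema="newick")
    bipartitions = set()
    for node in parsed.preorder_internal_node_iter():
        bipartitions.add(frozenset(leaf.taxon.label for leaf in node.leaf_iter()))
    assert bipartitions == {n.leafset for n in t.internal_nodes()}


def test_cut_tree_partitions(three_leaf):
    t = upgma(three_leaf)
    assert cut_tree(t, 1) == {"A": 0, "B": 0, "C": 0}
    two = cut_tree(t, 2)
    assert two["A"] == two["B"] != two["C"]
    assert len(set(cut_tree(t, 3).values())) == 3
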