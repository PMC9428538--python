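"""Song-level LSI and Dice similarity."""

import numpy as np
import pytest

from helpers import make_catalog
from whalesong import (
    DissimilarityMatrix,
    ccc,
    dsi,
    song_dsi_matrix,
    song_lsi_matrix,
    theme_set,
    upgma,
)


@pytest.mark.parametrize(
    "a, b, expected",
    [({1, 2, 3}, {1, 2, 3}, 1.0), ({1, 2}, {3, 4}, 0.0), ({1, 2, 3}, {2, 3, 4}, 2 * 2 / 6)],
)
def test_dsi_examples(a, b, expected):
    assert dsi(a, b) == pytest.approx(expected)
    assert dsi(b, a) == pytest.approx(expected)


def test_dsi_rejects_empty_and_is_one_iff_equal():
    with pytest.raises(ValueError):
        dsi(set(), {1})
    assert dsi({1, 2}, {1, 2}) == 1.0
    assert dsi({1, 2}, {1, 2, 3}) < 1.0


@pytest.fixture
def two_type_catalog():
    # singers x/y share a repertoire; z sings a different song type
    return make_catalog({
        "x": [("1", "a"), ("1", "a"), ("2", "b"), ("3", "c")],
        "y": [("1", "a"), ("2", "b"), ("2", "b"), ("3", "c")],
        "z": [("8", "q"), ("9", "r")],
    })


def test_song_lsi_matrix_values(two_type_catalog):
    m = song_lsi_matrix(two_type_catalog)
    i, j = m.labels.index("x"), m.labels.index("y")
    assert m.values[i, j] == 1.0  # identical compressed theme sequences
    k = m.labels.index("z")
    assert m.values[i, k] == 0.0  # disjoint themes, equal or shorter length


def test_song_lsi_sequence_example():
    cat = make_catalog({
        "p": [("1", "a"), ("2", "b"), ("3", "c")],
        "q": [("1", "a"), ("2", "b")],
    })
    m = song_lsi_matrix(cat)
    assert m.values[0, 1] == pytest.approx(1 - 1 / 3)


def test_song_dsi_matrix_matches_bruteforce(two_type_catalog):
    m = song_dsi_matrix(two_type_catalog)
    singers = two_type_catalog.included_singers()
    for i, a in enumerate(singers):
        for j, b in enumerate(singers):
            if i != j:
                assert m.values[i, j] == pytest.approx(dsi(theme_set(a), theme_set(b)))


def test_identical_repertoires_give_all_ones():
    cat = make_catalog({s: [("1", "a"), ("2", "b")] for s in ("s1", "s2", "s3")})
    assert np.allclose(song_dsi_matrix(cat).values, 1.0)


def test_dsi_ignores_order(two_type_catalog):
    m1 = song_dsi_matrix(two_type_catalog)
    reversed_cat = make_catalog({
        "x": [("3", "c"), ("2", "b"), ("1", "a"), ("1", "a")],
        "y": [("3", "c"), ("2", "b"), ("2", "b"), ("1", "a")],
        "z": [("9", "r"), ("8", "q")],
    })
    m2 = song_dsi_matrix(reversed_cat)
    assert np.allclose(m1.values, m2.values)


def test_excluded_singers_are_left_out(two_type_catalog):
    from dataclasses import replace

    singers = [replace(s, included=(s.singer_id != "z")) for s in two_type_catalog]
    cat = two_type_catalog.with_singers(singers)
    assert song_lsi_matrix(cat).labels == ("x", "y")


def test_hybrid_singer_positive_dsi_to_both_parent_types():
    cat = make_catalog({
        "pure1": [("1", "a"), ("2", "b"), ("3", "c")],
        "pure2": [("8", "q"), ("9", "r")],
        "hybrid": [("1", "a"), ("2", "b"), ("8", "q")],
    })
    m = song_dsi_matrix(cat)
    h = m.labels.index("hybrid")
    assert m.values[h, m.labels.index("pure1")] > 0
    assert m.values[h, m.labels.index("pure2")] > 0


def test_dice_factor_two_does_not_change_tree_or_ccc(rng):
    """1 - C/(A+B) is an affine map of 1 - 2C/(A+B): downstream UPGMA
    topology and CCC are identical with or without the classical factor 2."""
    for _ in range(5):
        n = 6
        s = rng.uniform(0, 1, size=(n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        labels = tuple(f"L{k}" for k in range(n))
        d_classic = DissimilarityMatrix(labels, 1 - s)
        half = 1 - s / 2
        np.fill_diagonal(half, 0.0)
        d_halved = DissimilarityMatrix(labels, half)
        t1, t2 = upgma(d_classic), upgma(d_halved)
        assert {x.leafset for x in t1.internal_nodes()} == {x.leafset for x in t2.internal_nodes()}
        assert ccc(d_classic, t1) == pytest.approx(ccc(d_halved, t2))
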