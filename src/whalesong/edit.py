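"""Levenshtein distance, length-standardized similarity (LSI) and set medians.

The Levenshtein distance between two token sequences is the minimum number
of single-token additions, deletions or substitutions converting one into
the other (all operations cost 1; token equality is exact-match only). The
Levenshtein similarity index standardizes it to a proportion::

    LSI(a, b) = 1 - d(a, b) / max(|a|, |b|)

so identical sequences score 1 and maximally different equal-length
sequences score 0. Sequences may be phrase-level strings of unit labels or
song-level strings of theme tokens — tokens are opaque here.

The *set median* of a group of sequences is the member maximizing the
summed LSI to all members (self included): the most representative actual
exemplar, as opposed to a consensus that may not have been sung.
"""

from __future__ import annotations

from typing import Hashable, Sequence, TypeVar

import numpy as np

from .matrix import SimilarityMatrix

__all__ = ["levenshtein_distance", "lsi", "pairwise_lsi", "set_median"]

T = TypeVar("T", bound=Hashable)


def levenshtein_distance(a: Sequence[T], b: Sequence[T]) -> int:
    """Unit-cost edit distance between two token sequences (empty allowed)."""
    if len(a) < len(b):  # iterate over the longer, keep the row short
        a, b = b, a
    if len(b) == 0:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, y in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y))
        prev = cur
    return prev[-1]


def lsi(a: Sequence[T], b: Sequence[T]) -> float:
    """Levenshtein similarity index in [0, 1]; undefined for empty sequences."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("LSI is undefined for empty sequences")
    return 1.0 - levenshtein_distance(a, b) / max(len(a), len(b))


def pairwise_lsi(items: Sequence[tuple[str, Sequence[T]]]) -> SimilarityMatrix:
    """Pairwise LSI over labelled token sequences.

    ``items`` is a sequence of (label, tokens) pairs with unique labels.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 items for a pairwise matrix")
    labels = tuple(lab for lab, _ in items)
    seqs = [tuple(seq) for _, seq in items]
    n = len(seqs)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = lsi(seqs[i], seqs[j])
    return SimilarityMatrix(labels, values)


def set_median(items: Sequence[Sequence[T]]) -> tuple[int, tuple[T, ...]]:
    """The member with the highest total LSI to all members (self included).

    Ties go to the earliest item in input order. Returns (index, sequence).
    """
    if len(items) == 0:
        raise ValueError("set_median of an empty group is undefined")
    seqs = [tuple(s) for s in items]
    n = len(seqs)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = lsi(seqs[i], seqs[j])
    totals = sim.sum(axis=1)
    # earliest index within numerical tolerance of the maximum, so exact
    # mathematical ties are broken by input position regardless of float
    # summation order
    best = int(np.flatnonzero(totals >= totals.max() - 1e-9)[0])
    return best, seqs[best]
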