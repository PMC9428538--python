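"""Independent reference implementations (oracles) used only by tests."""

from __future__ import annotations

import itertools
from fractions import Fraction
from functools import lru_cache

import numpy as np

from whalesong import Catalog, PhraseString, SingerRecord, ThemeToken


def levenshtein_oracle(a, b) -> int:
    """Plain recursive edit distance with memoisation (exhaustive DP)."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def set_median_oracle(items):
    """Exhaustive argmax of the summed-LSI objective in exact rational
    arithmetic; first index on ties."""
    seqs = [tuple(s) for s in items]

    def lsi_exact(a, b) -> Fraction:
        return 1 - Fraction(levenshtein_oracle(a, b), max(len(a), len(b)))

    totals = [sum(lsi_exact(s, t) for t in seqs) for s in seqs]
    best = max(range(len(seqs)), key=lambda i: (totals[i], -i))
    return best, seqs[best]


def upgma_oracle(labels, values):
    """Naive UPGMA: averages recomputed from the original matrix each merge.

    Ties broken by the lexicographically smallest pair of cluster
    representative (smallest-leaf) labels. Returns the merge list
    [(height, frozenset leafset), ...] in merge order.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters: list[frozenset] = [frozenset([lab]) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = float(np.mean([values[idx[x], idx[y]] for x in a for y in b]))
            key = (d, tuple(sorted((min(a), min(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        clusters.remove(a)
        clusters.remove(b)
        merged = a | b
        clusters.append(merged)
        merges.append((d, merged))
    return merges


def make_catalog(spec: dict[str, list[tuple[str, str]]], location: str = "X",
                 year: int = 2020, durations: dict[str, float] | None = None) -> Catalog:
    """Tiny catalog builder: {singer: [(theme_text, 'unit unit ...'), ...]}."""
    singers = []
    for sid, phrase_specs in spec.items():
        phrases = tuple(
            PhraseString(tuple(units.split()), ThemeToken.parse(theme))
            for theme, units in phrase_specs
        )
        dur = (durations or {}).get(sid)
        singers.append(SingerRecord(sid, location, year, phrases, dur))
    return Catalog.from_singers(singers)
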