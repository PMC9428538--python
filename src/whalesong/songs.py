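"""Song-level similarity: LSI over theme sequences, Dice over theme sets.

Two complementary views of how alike two singers' songs are:

* sequence view — LSI over each singer's *song string* (theme order with
  consecutive phrase repetitions collapsed); sensitive to theme order and
  to how many song cycles were recorded;
* repertoire view — Dice's similarity index (DSI) over the *sets* of theme
  tokens each singer produced, ``2|A∩B| / (|A|+|B|)``; ignores order
  entirely.

Theme tokens are compared at variant granularity (``7a`` and ``7b`` are
different phrase types, hence different repertoire elements).
"""

from __future__ import annotations

from typing import AbstractSet

import numpy as np

from .edit import pairwise_lsi
from .io import compress_to_song_string
from .matrix import SimilarityMatrix
from .types import Catalog, ThemeToken

__all__ = ["dsi", "theme_set", "song_lsi_matrix", "song_dsi_matrix"]


def theme_set(record_or_tokens) -> frozenset[ThemeToken]:
    """The set of theme tokens a singer produced (variant-level)."""
    tokens = getattr(record_or_tokens, "phrases", None)
    if tokens is not None:
        return frozenset(p.theme for p in record_or_tokens.phrases)
    return frozenset(record_or_tokens)


def dsi(a: AbstractSet, b: AbstractSet) -> float:
    """Dice's similarity index ``2|A∩B| / (|A|+|B|)`` in [0, 1]."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("DSI is undefined for an empty theme set")
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


def _included(catalog: Catalog):
    singers = catalog.included_singers()
    if len(singers) < 2:
        raise ValueError("need at least 2 included singers")
    return singers


def song_lsi_matrix(catalog: Catalog) -> SimilarityMatrix:
    """Pairwise LSI over all included singers' compressed theme sequences.

    The whole recorded sequence is compared per singer — no attempt is made
    to divide it into individual songs.
    """
    singers = _included(catalog)
    items = [(s.singer_id, compress_to_song_string(s)) for s in singers]
    return pairwise_lsi(items)


def song_dsi_matrix(catalog: Catalog) -> SimilarityMatrix:
    """Pairwise DSI over all included singers' theme-token sets."""
    singers = _included(catalog)
    sets = []
    for s in singers:
        ts = theme_set(s)
        if not ts:
            raise ValueError(f"singer {s.singer_id} has an empty theme set")
        sets.append(ts)
    n = len(sets)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dsi(sets[i], sets[j])
    return SimilarityMatrix(tuple(s.singer_id for s in singers), values)
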