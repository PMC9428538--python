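"""Bundled example dataset: a synthetic South Pacific song survey.

``south_pacific_2016_2018_synthetic.tsv`` is a *synthetic* reconstruction —
not field data — of a two-population humpback song survey (French
Polynesia "FP" and Ecuador "EC", 2016–2018). It was authored to satisfy
the published qualitative description of that system: 21 transcribed
singers of which 19 are included (two Ecuador-2017 recording sections fall
under the 10-minute rule); four song types with the documented
location/year memberships; 41 distinct theme tokens; two hybrid singers
(singer 7 mixing types 1+3 and sharing theme 22 with singer 9, singer 8
mixing types 1+2); exactly three theme tokens (1, 5, 7a) common to
French Polynesian type-1 song in all three years and Ecuadorian type-1
song in 2018, with themes 3, 4 and 8 confined to French Polynesia. The
per-singer theme sequences (cycle counts, omissions) are invented.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .types import Catalog, PhraseString, SingerRecord, ThemeToken
from . import simulate

__all__ = ["load_south_pacific", "south_pacific_song_strings", "south_pacific_catalog"]

_DATA = "south_pacific_2016_2018_synthetic.tsv"
MIN_MINUTES = 10.0


def load_south_pacific() -> pd.DataFrame:
    """The synthetic survey table: one row per transcribed singer.

    Columns: singer_id, location, year, song_type (``+``-joined for hybrid
    singers), duration_minutes, themes (space-separated theme tokens, the
    compressed song string).
    """
    with resources.files("whalesong.data").joinpath(_DATA).open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"song_type": str})
    df["year"] = df["year"].astype(int)
    return df


def south_pacific_song_strings(
    min_minutes: float = MIN_MINUTES,
) -> list[tuple[str, tuple[ThemeToken, ...]]]:
    """(singer_id, song string) for every included singer."""
    df = load_south_pacific()
    out = []
    for _, row in df.iterrows():
        if row["duration_minutes"] < min_minutes:
            continue
        tokens = tuple(ThemeToken.parse(t) for t in row["themes"].split())
        out.append((row["singer_id"], tokens))
    return out


def _canonical_units(token: ThemeToken, n_units: int = 4) -> tuple[str, ...]:
    # deterministic per-token phrase string so the expansion is reproducible
    seed = token.theme_number * 32 + (ord(token.variant) - ord("a") + 1 if token.variant else 0)
    rng = np.random.default_rng(seed)
    return tuple(rng.choice(simulate.UNIT_VOCABULARY, size=n_units))


def south_pacific_catalog(phrase_repeats: int = 2) -> Catalog:
    """Expand the survey table into a synthetic phrase-level Catalog.

    Each theme token in a singer's song string becomes ``phrase_repeats``
    consecutive copies of a deterministic synthetic canonical phrase, so
    the whole pipeline (parsing, theme validation, set medians, song-level
    similarity) can be demonstrated end to end. Compressing the phrases
    recovers the original song strings exactly.
    """
    df = load_south_pacific()
    singers = []
    for _, row in df.iterrows():
        tokens = [ThemeToken.parse(t) for t in row["themes"].split()]
        phrases = []
        for tok in tokens:
            units = _canonical_units(tok)
            for _ in range(phrase_repeats):
                phrases.append(PhraseString(units, tok))
        singers.append(
            SingerRecord(row["singer_id"], row["location"], int(row["year"]),
                         tuple(phrases), float(row["duration_minutes"]))
        )
    return Catalog.from_singers(singers)
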