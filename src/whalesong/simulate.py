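"""Synthetic song-culture generator with known ground truth.

Emulates the dynamics of a song culture like the humpback whale's so every
pipeline stage has a recoverable target without any field recordings:

* each population shares one *song type* (an ordered list of themes, each
  with a canonical phrase string) that all singers conform to;
* *progressive evolution* — the population's canonical phrase strings
  accumulate small per-unit edits each year, and everyone adopts them;
* *revolution* — on a scheduled year a population's whole repertoire is
  replaced by another type, copied in its current (evolved) state from the
  population that already sings it, which produces the characteristic one
  to two year lag between neighbouring populations;
* *hybrid singers* — during a revolution year some singers mix contiguous
  theme blocks of the old and new types;
* *transcription noise* — independent unit misclassification on every
  emitted phrase.

The generator is deterministic given its seed and emits the same TSV
formats the parser reads, plus a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .types import Catalog, PhraseString, SingerRecord, ThemeToken

__all__ = [
    "UNIT_VOCABULARY",
    "SongType",
    "CultureConfig",
    "simulate_culture",
    "make_song_type",
    "make_phrase_fixture",
    "write_ground_truth",
]

# A closed vocabulary of unit names in the style of field transcriptions.
UNIT_VOCABULARY: tuple[str, ...] = tuple(
    f"{mod}_{base}"
    for base in ("moan", "groan", "squeak", "shriek", "whistle", "cry", "purr", "grumble")
    for mod in ("ascending", "descending", "long", "short", "modulated")
)


@dataclass(frozen=True)
class SongType:
    """An ordered theme repertoire with canonical phrase strings."""

    id: str
    themes: tuple[tuple[ThemeToken, tuple[str, ...]], ...]
    origin_population: str = ""
    origin_year: int = 0

    def __post_init__(self) -> None:
        if len(self.themes) < 2:
            raise ValueError(f"song type {self.id} needs at least 2 themes")
        tokens = [t for t, _ in self.themes]
        if len(set(tokens)) != len(tokens):
            raise ValueError(f"song type {self.id} has duplicate theme tokens")

    def theme_order(self) -> tuple[ThemeToken, ...]:
        return tuple(t for t, _ in self.themes)


def make_song_type(
    type_id: str,
    n_themes: int,
    seed: int,
    start_number: int = 1,
    units_per_phrase: tuple[int, int] = (3, 7),
    vocabulary: Sequence[str] = UNIT_VOCABULARY,
    origin_population: str = "",
    origin_year: int = 0,
) -> SongType:
    """Random song type with themes numbered from ``start_number``."""
    rng = np.random.default_rng(seed)
    themes = []
    for i in range(n_themes):
        length = int(rng.integers(units_per_phrase[0], units_per_phrase[1] + 1))
        units = tuple(rng.choice(vocabulary, size=length))
        themes.append((ThemeToken(start_number + i), units))
    return SongType(type_id, tuple(themes), origin_population, origin_year)


@dataclass(frozen=True)
class CultureConfig:
    """Study conditions for a simulated song culture.

    Defaults mirror a two-population, three-year survey: three singers per
    population per year, two initial song types, and one revolution in
    which the second population adopts the first population's song in the
    final year (i.e. with a lag behind its origin).
    """

    populations: tuple[str, ...] = ("FP", "EC")
    years: tuple[int, int] = (2016, 2018)  # inclusive
    singers_per_population_per_year: int = 3
    song_types: tuple[SongType, ...] = ()
    initial_types: tuple[tuple[str, str], ...] = ()  # (population, song_type id)
    phrase_repeats: tuple[int, int] = (2, 5)
    unit_edit_rate: float = 0.05  # per unit per year, applied to the shared canon
    revolution_schedule: tuple[tuple[str, str, int], ...] = ()  # (type id, population, year)
    hybrid_probability: float = 0.1  # per switching singer, revolution year only
    noise: float = 0.02  # per-unit transcription misclassification
    duration_minutes: tuple[float, float] = (12.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("unit_edit_rate", "hybrid_probability", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")
        for tid, pop, year in self.revolution_schedule:
            if pop not in self.populations:
                raise ValueError(f"revolution population {pop!r} unknown")
            if not self.years[0] <= year <= self.years[1]:
                raise ValueError(f"revolution year {year} outside simulated range")

    def resolved(self) -> "CultureConfig":
        """Fill in default song types / assignments if none were given."""
        if self.song_types:
            return self
        types = tuple(
            make_song_type(f"T{i + 1}", n_themes=6, seed=1000 + i, start_number=1 + 10 * i)
            for i in range(len(self.populations))
        )
        initial = tuple((pop, types[i].id) for i, pop in enumerate(self.populations))
        schedule = self.revolution_schedule
        if not schedule and len(self.populations) >= 2 and self.years[1] > self.years[0]:
            # second population adopts the first population's type in the final year
            schedule = ((types[0].id, self.populations[1], self.years[1]),)
        return replace(self, song_types=types, initial_types=initial,
                       revolution_schedule=schedule)


def _evolve_canon(canon: dict[ThemeToken, list[str]], rate: float,
                  rng: np.random.Generator, vocabulary: Sequence[str]) -> None:
    """One year of progressive evolution applied in place to the shared canon."""
    if rate <= 0:
        return
    for token, units in canon.items():
        out: list[str] = []
        for u in units:
            if rng.random() >= rate:
                out.append(u)
                continue
            op = rng.integers(0, 3)
            if op == 0:  # substitution
                out.append(str(rng.choice(vocabulary)))
            elif op == 1:  # insertion (keeps the original unit too)
                out.append(u)
                out.append(str(rng.choice(vocabulary)))
            # op == 2: deletion — emit nothing
        if not out:  # a phrase cannot vanish entirely
            out.append(str(rng.choice(vocabulary)))
        canon[token] = out


def _noisy(units: Sequence[str], noise: float, rng: np.random.Generator,
           vocabulary: Sequence[str]) -> tuple[str, ...]:
    if noise <= 0:
        return tuple(units)
    out = []
    for u in units:
        if rng.random() < noise:
            choices = [v for v in vocabulary if v != u]
            out.append(str(rng.choice(choices)))
        else:
            out.append(u)
    return tuple(out)


def simulate_culture(cfg: CultureConfig) -> tuple[Catalog, pd.DataFrame]:
    """Simulate the configured song culture.

    Returns the transcript catalog and a ground-truth table with columns
    singer_id, population, year, true_song_types (``+``-joined), is_hybrid.
    """
    cfg = cfg.resolved()
    if cfg.singers_per_population_per_year < 1:
        raise ValueError("need at least one singer per population per year")
    if not cfg.song_types or not cfg.initial_types:
        raise ValueError("config must define song types and initial assignments")
    types = {t.id: t for t in cfg.song_types}
    assignment = dict(cfg.initial_types)
    for pop in cfg.populations:
        if pop not in assignment:
            raise ValueError(f"no initial song type for population {pop!r}")
    rng = np.random.default_rng(cfg.seed)
    vocabulary = tuple(sorted({u for t in cfg.song_types for _, units in t.themes for u in units}
                              | set(UNIT_VOCABULARY)))

    # mutable state per population: (type id, theme order, canon units per theme)
    state: dict[str, tuple[str, tuple[ThemeToken, ...], dict[ThemeToken, list[str]]]] = {}
    for pop in cfg.populations:
        t = types[assignment[pop]]
        state[pop] = (t.id, t.theme_order(), {tok: list(units) for tok, units in t.themes})

    singers: list[SingerRecord] = []
    truth_rows: list[dict] = []
    first_year = cfg.years[0]
    for year in range(cfg.years[0], cfg.years[1] + 1):
        if year > first_year:
            for pop in cfg.populations:
                _evolve_canon(state[pop][2], cfg.unit_edit_rate, rng, vocabulary)
        arrivals = {pop: tid for tid, pop, y in cfg.revolution_schedule if y == year}
        old_state = {}
        for pop, tid in arrivals.items():
            old_state[pop] = state[pop]
            source = next((p for p in cfg.populations
                           if p != pop and state[p][0] == tid), None)
            if source is not None:  # adopt the source population's evolved version
                _, order, canon = state[source]
                state[pop] = (tid, order, {tok: list(u) for tok, u in canon.items()})
            else:
                t = types[tid]
                state[pop] = (t.id, t.theme_order(), {tok: list(u) for tok, u in t.themes})
        for pop in cfg.populations:
            tid, order, canon = state[pop]
            for k in range(cfg.singers_per_population_per_year):
                sid = f"{pop}{year}_{k + 1}"
                is_hybrid = pop in arrivals and rng.random() < cfg.hybrid_probability
                if is_hybrid:
                    old_tid, old_order, old_canon = old_state[pop]
                    lo = int(rng.integers(0, len(old_order)))
                    hi = int(rng.integers(lo + 1, len(old_order) + 1))
                    split = int(rng.integers(1, len(order)))
                    seq = (list(order[:split])
                           + list(old_order[lo:hi])
                           + list(order[split:]))
                    canon_for = dict(canon)
                    canon_for.update({t: old_canon[t] for t in old_order[lo:hi]})
                    true_types = f"{tid}+{old_tid}"
                else:
                    seq = list(order)
                    canon_for = canon
                    true_types = tid
                phrases: list[PhraseString] = []
                for token in seq:
                    repeats = int(rng.integers(cfg.phrase_repeats[0], cfg.phrase_repeats[1] + 1))
                    for _ in range(repeats):
                        units = _noisy(canon_for[token], cfg.noise, rng, vocabulary)
                        phrases.append(PhraseString(units, token))
                duration = float(rng.uniform(*cfg.duration_minutes))
                singers.append(SingerRecord(sid, pop, year, tuple(phrases), duration))
                truth_rows.append({
                    "singer_id": sid,
                    "population": pop,
                    "year": year,
                    "true_song_types": true_types,
                    "is_hybrid": is_hybrid,
                })
    catalog = Catalog.from_singers(singers)
    truth = pd.DataFrame(truth_rows,
                         columns=["singer_id", "population", "year",
                                  "true_song_types", "is_hybrid"])
    return catalog, truth


def write_ground_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth.to_csv(path, sep="\t", index=False)


def make_phrase_fixture(
    n_themes: int,
    phrases_per_theme: int,
    alphabet_size: int,
    within_noise: int,
    seed: int,
    canon_length: int = 5,
) -> list[PhraseString]:
    """Labelled phrase strings with disjoint per-theme canonical alphabets.

    Each theme draws its canonical string from its own slice of the unit
    alphabet (so themes are perfectly separable at ``within_noise=0``);
    every copy is perturbed by ``within_noise`` random edits whose
    substituted/inserted units come from the full alphabet.
    """
    if alphabet_size < n_themes:
        raise ValueError("alphabet_size must be >= n_themes for disjoint canonical strings")
    rng = np.random.default_rng(seed)
    alphabet = [f"u{i:02d}" for i in range(alphabet_size)]
    phrases: list[PhraseString] = []
    for i in range(n_themes):
        lo = i * alphabet_size // n_themes
        hi = (i + 1) * alphabet_size // n_themes
        chunk = alphabet[lo:hi]
        canon = [str(rng.choice(chunk)) for _ in range(canon_length)]
        token = ThemeToken(i + 1)
        for _ in range(phrases_per_theme):
            units = list(canon)
            for _ in range(within_noise):
                op = int(rng.integers(0, 3))
                pos = int(rng.integers(0, len(units)))
                if op == 0:
                    units[pos] = str(rng.choice(alphabet))
                elif op == 1:
                    units.insert(pos, str(rng.choice(alphabet)))
                elif len(units) > 1:
                    del units[pos]
            phrases.append(PhraseString(tuple(units), token))
    return phrases
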