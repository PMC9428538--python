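"""Core data model for symbolic song transcripts.

Humpback whale song (like much birdsong) is hierarchical: the shortest
continuous vocalization is a *unit*; an ordered string of units is a
*phrase*; repeating phrases of the same class form a *theme* (numbered, with
lowercase letter suffixes for phrase-type variants of the same theme, e.g.
``7a``); and the ordered sequence of themes a male sings is his *song*.
These classes carry transcripts through the similarity pipeline without any
audio: a transcript is purely symbolic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "ThemeToken",
    "PhraseString",
    "SingerRecord",
    "Catalog",
    "TranscriptError",
]

_THEME_RE = re.compile(r"^([1-9][0-9]*)([a-z])?$")
_UNIT_RE = re.compile(r"^\S+$")


class TranscriptError(ValueError):
    """Raised for malformed transcripts or invalid catalog operations."""


@dataclass(frozen=True, order=True)
class ThemeToken:
    """A theme identifier: a positive number plus an optional variant letter.

    Variants of a theme (same melodic skeleton, slightly different units)
    are distinct sequence symbols: ``7a != 7b``. ``parse``/``str`` round-trip
    exactly.
    """

    theme_number: int
    variant: Optional[str] = None

    def __post_init__(self) -> None:
        if self.theme_number < 1:
            raise TranscriptError(f"theme number must be positive: {self.theme_number}")
        if self.variant is not None and not re.fullmatch(r"[a-z]", self.variant):
            raise TranscriptError(f"theme variant must be one lowercase letter: {self.variant!r}")

    @classmethod
    def parse(cls, text: str) -> "ThemeToken":
        m = _THEME_RE.match(text)
        if m is None:
            raise TranscriptError(f"malformed theme token: {text!r}")
        return cls(int(m.group(1)), m.group(2))

    def __str__(self) -> str:
        return f"{self.theme_number}{self.variant or ''}"


def validate_unit(unit: str) -> str:
    """Check a unit label: non-empty, no whitespace."""
    if not _UNIT_RE.match(unit or ""):
        raise TranscriptError(f"invalid unit label: {unit!r}")
    return unit


@dataclass(frozen=True)
class PhraseString:
    """One phrase: an ordered, non-empty string of unit labels plus its theme."""

    units: tuple[str, ...]
    theme: ThemeToken

    def __post_init__(self) -> None:
        if len(self.units) == 0:
            raise TranscriptError("phrase must contain at least one unit")
        for u in self.units:
            validate_unit(u)

    def __len__(self) -> int:
        return len(self.units)


@dataclass
class SingerRecord:
    """One singer's transcript plus recording metadata.

    ``included`` marks whether the singer enters comparative analyses;
    recordings that are too short to contain a representative song are
    retained in the catalog but flagged out (see
    :func:`whalesong.io.apply_inclusion_filter`).
    """

    singer_id: str
    location: str
    year: int
    phrases: tuple[PhraseString, ...] = ()
    duration_minutes: Optional[float] = None
    included: bool = True

    def __post_init__(self) -> None:
        if not self.singer_id:
            raise TranscriptError("singer_id must be non-empty")
        if self.duration_minutes is not None and self.duration_minutes < 0:
            raise TranscriptError(f"negative duration for {self.singer_id}")
        self.phrases = tuple(self.phrases)

    def theme_sequence(self) -> tuple[ThemeToken, ...]:
        """Raw (uncompressed) theme token per phrase, in singing order."""
        return tuple(p.theme for p in self.phrases)


@dataclass
class Catalog:
    """A collection of singers and the closed unit vocabulary they draw on."""

    singers: tuple[SingerRecord, ...] = ()
    unit_vocabulary: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.singers = tuple(self.singers)
        ids = [s.singer_id for s in self.singers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TranscriptError(f"duplicate singer_id(s): {dupes}")
        vocab = set(self.unit_vocabulary)
        for s in self.singers:
            for p in s.phrases:
                missing = set(p.units) - vocab
                if missing:
                    raise TranscriptError(
                        f"units of singer {s.singer_id} not in vocabulary: {sorted(missing)}"
                    )
        self.unit_vocabulary = frozenset(vocab)

    def __iter__(self) -> Iterator[SingerRecord]:
        return iter(self.singers)

    def __len__(self) -> int:
        return len(self.singers)

    @classmethod
    def from_singers(cls, singers: Iterable[SingerRecord]) -> "Catalog":
        singers = tuple(singers)
        vocab = frozenset(u for s in singers for p in s.phrases for u in p.units)
        return cls(singers, vocab)

    def included_singers(self) -> tuple[SingerRecord, ...]:
        return tuple(s for s in self.singers if s.included)

    def get(self, singer_id: str) -> SingerRecord:
        for s in self.singers:
            if s.singer_id == singer_id:
                return s
        raise KeyError(singer_id)

    def with_singers(self, singers: Sequence[SingerRecord]) -> "Catalog":
        return Catalog(tuple(singers), self.unit_vocabulary)

    def all_phrases(self, included_only: bool = True) -> list[tuple[str, PhraseString]]:
        """(phrase_id, phrase) pairs; phrase_id = '<singer>.<index>'."""
        out = []
        for s in self.singers:
            if included_only and not s.included:
                continue
            for i, p in enumerate(s.phrases):
                out.append((f"{s.singer_id}.{i}", p))
        return out
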