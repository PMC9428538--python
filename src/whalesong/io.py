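"""Transcript file I/O, inclusion filtering and song-string compression.

The on-disk transcript format is a TSV with one phrase per row::

    singer_id  location  year  phrase_index  theme  units

``phrase_index`` is 0-based and strictly increasing within a singer;
``theme`` is a theme token such as ``7`` or ``7a``; ``units`` is a
space-separated string of unit labels. Recording metadata (durations) lives
in a companion TSV: ``singer_id  duration_minutes  recorder  date``.
``write_transcripts(parse_transcripts(f)) == f`` byte-for-byte on canonical
files (singers in first-appearance order, contiguous phrase indices).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

from .types import Catalog, PhraseString, SingerRecord, ThemeToken, TranscriptError

__all__ = [
    "parse_transcripts",
    "write_transcripts",
    "parse_metadata",
    "write_metadata",
    "apply_inclusion_filter",
    "compress_to_song_string",
    "compress_theme_sequence",
    "write_song_strings",
    "read_song_strings",
]

logger = logging.getLogger(__name__)

TRANSCRIPT_COLUMNS = ("singer_id", "location", "year", "phrase_index", "theme", "units")
METADATA_COLUMNS = ("singer_id", "duration_minutes", "recorder", "date")

PathLike = Union[str, Path]


def _read_rows(path: PathLike, expected: Sequence[str]) -> list[tuple[int, list[str]]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise TranscriptError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header != list(expected):
        unknown = [c for c in header if c not in expected]
        raise TranscriptError(
            f"{path}: line 1: bad header {header!r}"
            + (f" (unknown column(s) {unknown})" if unknown else f" (expected {list(expected)})")
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(expected):
            raise TranscriptError(
                f"{path}: line {lineno}: expected {len(expected)} fields, got {len(fields)}"
            )
        rows.append((lineno, fields))
    return rows


def parse_transcripts(path: PathLike, metadata: Optional[PathLike] = None) -> Catalog:
    """Parse a transcript TSV (plus optional metadata TSV) into a Catalog.

    Every row is accounted for; duplicate singer ids, malformed theme
    tokens, empty unit strings and non-increasing phrase indices are
    rejected with the offending line number.
    """
    rows = _read_rows(path, TRANSCRIPT_COLUMNS)
    order: list[str] = []
    meta: dict[str, tuple[str, int]] = {}
    phrases: dict[str, list[PhraseString]] = {}
    last_index: dict[str, int] = {}
    current: Optional[str] = None
    for lineno, (sid, loc, year_s, idx_s, theme_s, units_s) in rows:
        try:
            year = int(year_s)
            idx = int(idx_s)
        except ValueError as e:
            raise TranscriptError(f"{path}: line {lineno}: {e}") from None
        if sid not in meta:
            meta[sid] = (loc, year)
            order.append(sid)
            phrases[sid] = []
            last_index[sid] = -1
            current = sid
        else:
            if sid != current:
                raise TranscriptError(
                    f"{path}: line {lineno}: duplicate singer_id {sid!r} (rows not contiguous)"
                )
            if meta[sid] != (loc, year):
                raise TranscriptError(f"{path}: line {lineno}: inconsistent metadata for {sid!r}")
        if idx <= last_index[sid]:
            raise TranscriptError(
                f"{path}: line {lineno}: phrase_index {idx} not strictly increasing for {sid!r}"
            )
        last_index[sid] = idx
        try:
            theme = ThemeToken.parse(theme_s)
            units = tuple(units_s.split())
            if not units:
                raise TranscriptError("empty unit sequence")
            phrase = PhraseString(units, theme)
        except TranscriptError as e:
            raise TranscriptError(f"{path}: line {lineno}: {e}") from None
        phrases[sid].append(phrase)

    singers = []
    for sid in order:
        loc, year = meta[sid]
        singers.append(SingerRecord(sid, loc, year, tuple(phrases[sid])))
    catalog = Catalog.from_singers(singers)
    if metadata is not None:
        catalog = parse_metadata(metadata, catalog)
    logger.info("parsed %d singers, %d phrases from %s",
                len(catalog), sum(len(s.phrases) for s in catalog), path)
    return catalog


def parse_metadata(path: PathLike, catalog: Catalog) -> Catalog:
    """Attach durations from a metadata TSV to the matching singers."""
    rows = _read_rows(path, METADATA_COLUMNS)
    durations: dict[str, float] = {}
    for lineno, (sid, dur_s, _rec, _date) in rows:
        if sid in durations:
            raise TranscriptError(f"{path}: line {lineno}: duplicate singer_id {sid!r}")
        if dur_s not in ("", "NA"):
            try:
                durations[sid] = float(dur_s)
            except ValueError:
                raise TranscriptError(f"{path}: line {lineno}: bad duration {dur_s!r}") from None
    singers = []
    for s in catalog:
        d = durations.get(s.singer_id, s.duration_minutes)
        singers.append(SingerRecord(s.singer_id, s.location, s.year, s.phrases, d, s.included))
    return catalog.with_singers(singers)


def write_transcripts(catalog: Catalog, path: PathLike) -> None:
    """Write the canonical transcript TSV (inverse of :func:`parse_transcripts`)."""
    lines = ["\t".join(TRANSCRIPT_COLUMNS)]
    for s in catalog:
        for i, p in enumerate(s.phrases):
            lines.append(
                "\t".join([s.singer_id, s.location, str(s.year), str(i), str(p.theme),
                           " ".join(p.units)])
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_metadata(catalog: Catalog, path: PathLike) -> None:
    lines = ["\t".join(METADATA_COLUMNS)]
    for s in catalog:
        dur = "" if s.duration_minutes is None else f"{s.duration_minutes:g}"
        lines.append("\t".join([s.singer_id, dur, "", ""]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def apply_inclusion_filter(catalog: Catalog, min_minutes: float = 10.0) -> Catalog:
    """Flag out singers whose recording is shorter than ``min_minutes``.

    Recordings below the threshold may not contain a representative full
    song, so they are excluded from comparative analyses — but never
    deleted. Singers with unknown duration are retained (and logged): only
    an explicit sub-threshold duration excludes.
    """
    if min_minutes < 0:
        raise ValueError("min_minutes must be >= 0")
    singers = []
    for s in catalog:
        if s.duration_minutes is None:
            logger.warning("singer %s has no duration; retained by inclusion filter", s.singer_id)
            included = s.included
        else:
            included = s.duration_minutes >= min_minutes
        singers.append(
            SingerRecord(s.singer_id, s.location, s.year, s.phrases, s.duration_minutes, included)
        )
    out = catalog.with_singers(singers)
    logger.info("inclusion filter (>=%g min): %d/%d singers included",
                min_minutes, len(out.included_singers()), len(out))
    return out


def compress_theme_sequence(themes: Sequence[ThemeToken]) -> tuple[ThemeToken, ...]:
    """Collapse consecutive runs of identical theme tokens to one token.

    Tokens with the same theme number but different variant letters are
    different tokens and are both retained. Idempotent.
    """
    if len(themes) == 0:
        raise TranscriptError("cannot compress an empty theme sequence")
    out = [themes[0]]
    for t in themes[1:]:
        if t != out[-1]:
            out.append(t)
    return tuple(out)


def compress_to_song_string(record: SingerRecord) -> tuple[ThemeToken, ...]:
    """A singer's song string: his theme order with phrase repetitions omitted."""
    if not record.phrases:
        raise TranscriptError(f"singer {record.singer_id} has no phrases")
    return compress_theme_sequence(record.theme_sequence())


def write_song_strings(catalog: Catalog, path: PathLike, included_only: bool = True) -> None:
    """One line per singer: singer_id then whitespace-separated theme tokens."""
    lines = []
    for s in catalog:
        if included_only and not s.included:
            continue
        tokens = " ".join(str(t) for t in compress_to_song_string(s))
        lines.append(f"{s.singer_id}\t{tokens}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_song_strings(path: PathLike) -> dict[str, tuple[ThemeToken, ...]]:
    out: dict[str, tuple[ThemeToken, ...]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        sid, _, rest = line.partition("\t")
        tokens = tuple(ThemeToken.parse(t) for t in rest.split())
        if not tokens:
            raise TranscriptError(f"{path}: line {lineno}: empty song string for {sid!r}")
        if sid in out:
            raise TranscriptError(f"{path}: line {lineno}: duplicate singer_id {sid!r}")
        out[sid] = tokens
    return out
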