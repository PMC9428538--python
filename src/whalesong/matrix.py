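"""Labelled similarity and dissimilarity matrices with CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = ["SimilarityMatrix", "DissimilarityMatrix"]

PathLike = Union[str, Path]


def _check_square(labels: Sequence[str], values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    return values


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise similarities in [0, 1], unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        v = _check_square(self.labels, self.values)
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be 1")
        self.values = np.clip(v, 0.0, 1.0)

    def to_dissimilarity(self) -> "DissimilarityMatrix":
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return DissimilarityMatrix(self.labels, d)

    def to_csv(self, path: PathLike) -> None:
        _write_csv(self.labels, self.values, path)

    @classmethod
    def from_csv(cls, path: PathLike) -> "SimilarityMatrix":
        return cls(*_read_csv(path))


@dataclass
class DissimilarityMatrix:
    """Symmetric matrix of pairwise dissimilarities, zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        v = _check_square(self.labels, self.values)
        if v.size and v.min() < -1e-12:
            raise ValueError("dissimilarities must be non-negative")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity diagonal must be 0")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, None)

    def condensed(self) -> np.ndarray:
        """Strict lower-triangle entries, row-major (each unordered pair once)."""
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.values[i, j]

    def reorder(self, labels: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DissimilarityMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_csv(self, path: PathLike) -> None:
        _write_csv(self.labels, self.values, path)

    @classmethod
    def from_csv(cls, path: PathLike) -> "DissimilarityMatrix":
        return cls(*_read_csv(path))


def _write_csv(labels: Sequence[str], values: np.ndarray, path: PathLike) -> None:
    lines = ["," + ",".join(labels)]
    for lab, row in zip(labels, values):
        lines.append(lab + "," + ",".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_csv(path: PathLike) -> tuple[tuple[str, ...], np.ndarray]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    labels = tuple(lines[0].split(",")[1:])
    rows = []
    for line in lines[1 : len(labels) + 1]:
        rows.append([float(x) for x in line.split(",")[1:]])
    values = np.array(rows, dtype=float)
    # symmetrize away the 6-decimal rounding
    values = (values + values.T) / 2.0
    return labels, values
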