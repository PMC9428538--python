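"""Cluster support via multiscale bootstrap: BP and AU p-values per split.

The ordinary bootstrap probability (BP) of a cluster — the fraction of
resampled trees containing exactly the same leafset — is biased as a
p-value. Multiscale bootstrap resampling removes most of that bias:
replicates are drawn at several sample-size scales ``r`` (resampling
``round(r * m)`` of the ``m`` feature rows with replacement), and the
per-scale counts are summarized by fitting

    z(r) = Phi^-1(1 - BP_r) = v * sqrt(r) + c / sqrt(r)

by least squares weighted with the binomial variance of each BP_r. ``v``
is the signed distance of the data from the cluster's boundary and ``c``
its curvature; the approximately unbiased p-value is

    AU = 1 - Phi(v - c)

Following the convention of the clustering-with-p-values lineage this
package emulates, a square dissimilarity matrix may itself serve as the
item-by-feature matrix: each row (one item's dissimilarity profile) is a
feature, and replicate item-item distances are Euclidean distances between
resampled column profiles. The reference tree is always built from the
primary dissimilarities directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .cluster import ClusterTree, upgma
from .matrix import DissimilarityMatrix

__all__ = ["BootstrapConfig", "EdgeSupport", "AuFit", "fit_au", "bootstrap_support",
           "support_table", "DEFAULT_SCALES"]

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4

AU_SIGNIFICANT = 0.95  # split stable: AU above 95%
BP_SIGNIFICANT = 0.70  # branching stable: BP above 70%


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling plan: replicates per scale, the scale grid, and the seed."""

    n_boot: int = 1000
    scales: tuple[float, ...] = DEFAULT_SCALES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        scales = tuple(float(r) for r in self.scales)
        if any(r <= 0 for r in scales):
            raise ValueError("scales must be positive")
        if list(scales) != sorted(set(scales)):
            raise ValueError("scales must be strictly increasing")
        if not any(abs(r - 1.0) < 1e-9 for r in scales):
            raise ValueError("scales must include r = 1")
        object.__setattr__(self, "scales", scales)


@dataclass
class AuFit:
    au: float
    v: float
    c: float
    fit_quality: float  # chi-square tail probability of the weighted fit
    degenerate: bool = False


@dataclass
class EdgeSupport:
    """Support for one split (identified by its exact leafset)."""

    leafset: frozenset[str]
    bp_by_scale: dict[float, float]
    au: float
    bp: float
    v: float
    c: float
    fit_quality: float
    degenerate: bool = False


def fit_au(bp_by_scale: Mapping[float, float], n_boot: int) -> AuFit:
    """Fit the multiscale curve and return the AU p-value.

    Requires at least two scales: a single scale cannot separate signed
    distance from curvature, so AU is undefined there and this function
    refuses rather than degrade to BP.
    """
    scales = sorted(bp_by_scale)
    if len(scales) < 2:
        raise ValueError("AU requires bootstrap counts at two or more scales")
    raw = np.array([bp_by_scale[r] for r in scales], dtype=float)
    if np.all(raw <= 0.0):
        return AuFit(au=0.0, v=np.inf, c=0.0, fit_quality=float("nan"), degenerate=True)
    if np.all(raw >= 1.0):
        return AuFit(au=1.0, v=-np.inf, c=0.0, fit_quality=float("nan"), degenerate=True)
    lo = 1.0 / (n_boot + 1)
    bp = np.clip(raw, lo, 1.0 - lo)
    z = stats.norm.isf(bp)  # Phi^-1(1 - bp)
    r = np.asarray(scales, dtype=float)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    var_bp = bp * (1.0 - bp) / n_boot
    w = stats.norm.pdf(z) ** 2 / var_bp  # delta-method weight for z
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    v, c = float(beta[0]), float(beta[1])
    resid = z - X @ beta
    chisq = float(np.sum(w * resid**2))
    dof = len(scales) - 2
    quality = float(stats.chi2.sf(chisq, dof)) if dof > 0 else float("nan")
    au = float(stats.norm.sf(v - c))  # 1 - Phi(v - c)
    return AuFit(au=au, v=v, c=c, fit_quality=quality)


def _euclidean_profile_distances(x: np.ndarray, labels: Sequence[str]) -> DissimilarityMatrix:
    d = squareform(pdist(x.T, metric="euclidean"))
    return DissimilarityMatrix(tuple(labels), d)


def bootstrap_support(
    features: Union[np.ndarray, DissimilarityMatrix],
    cfg: BootstrapConfig,
    labels: Optional[Sequence[str]] = None,
    reference_d: Optional[DissimilarityMatrix] = None,
) -> ClusterTree:
    """UPGMA reference tree with AU/BP support on every non-root split.

    ``features`` is an item-by-feature matrix (items = columns) or a
    :class:`DissimilarityMatrix`, in which case the matrix doubles as both
    the primary dissimilarities (reference tree) and the row-resampled
    feature matrix. Items are internally ordered by label so the result is
    invariant to input order; resampling is deterministic given the seed.
    """
    if isinstance(features, DissimilarityMatrix):
        if reference_d is None:
            reference_d = features
        labels = features.labels
        order = sorted(range(len(labels)), key=lambda i: labels[i])
        x = features.values[np.ix_(order, order)]
        labels = tuple(labels[i] for i in order)
    else:
        x = np.asarray(features, dtype=float)
        if labels is None:
            labels = tuple(f"item{i}" for i in range(x.shape[1]))
        order = sorted(range(len(labels)), key=lambda i: labels[i])
        x = x[:, order]
        labels = tuple(labels[i] for i in order)
    m, n = x.shape
    if n < 3:
        raise ValueError("need at least 3 items for cluster support")
    if m < 2 or len({tuple(row) for row in x}) < 2:
        raise ValueError("need at least 2 distinct feature rows to resample")
    if reference_d is None:
        reference_d = _euclidean_profile_distances(x, labels)
    else:
        reference_d = reference_d.reorder(labels)

    ref_tree = upgma(reference_d)
    ref_splits = ref_tree.splits(include_root=False)
    if len(cfg.scales) < 2:
        raise ValueError("AU requires at least two resampling scales")

    rng = np.random.default_rng(cfg.seed)
    counts: dict[frozenset[str], dict[float, int]] = {
        s.leafset: {r: 0 for r in cfg.scales} for s in ref_splits
    }
    for r in cfg.scales:
        m_r = max(2, round(r * m))
        for _ in range(cfg.n_boot):
            idx = rng.integers(0, m, size=m_r)
            rep_d = _euclidean_profile_distances(x[idx], labels)
            rep_leafsets = upgma(rep_d).leafsets()
            for leafset in counts:
                if leafset in rep_leafsets:
                    counts[leafset][r] += 1

    r1 = min(cfg.scales, key=lambda r: abs(r - 1.0))
    for node in ref_splits:
        bp_by_scale = {r: counts[node.leafset][r] / cfg.n_boot for r in cfg.scales}
        fit = fit_au(bp_by_scale, cfg.n_boot)
        node.support = EdgeSupport(
            leafset=node.leafset,
            bp_by_scale=bp_by_scale,
            au=min(1.0, max(0.0, fit.au)),
            bp=bp_by_scale[r1],
            v=fit.v,
            c=fit.c,
            fit_quality=fit.fit_quality,
            degenerate=fit.degenerate,
        )
    return ref_tree


def support_table(tree: ClusterTree, cfg: BootstrapConfig) -> pd.DataFrame:
    """Tabulate per-split support: leafset, au, bp, v, c, n_boot, seed."""
    rows = []
    for node in tree.splits(include_root=False):
        s = node.support
        if s is None:
            continue
        rows.append({
            "leafset": ",".join(sorted(s.leafset)),
            "au": s.au,
            "bp": s.bp,
            "v": s.v,
            "c": s.c,
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
        })
    rows.sort(key=lambda r: r["leafset"])
    return pd.DataFrame(rows, columns=["leafset", "au", "bp", "v", "c", "n_boot", "seed"])
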