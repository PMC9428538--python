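"""Validation of qualitative theme labels and per-group set-median exemplars.

Transcribers assign phrases to themes by eye and ear ("similar sounds in
similar positions"). To check that these labels are consistent across
locations and years, all phrase strings are clustered by 1 - LSI with
UPGMA; a faithful tree (high CCC) in which each theme's phrases fall
together supports the labelling. The dendrogram eyeball check is
operationalized here as a *majority-subtree purity* per theme: the
fraction of a theme's phrases contained in the best subtree in which that
theme is the plurality label.

Once labels are validated, each (theme, location, year) group is summarized
by its set-median unit string — the actually-sung phrase most similar to
all others in the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .cluster import ClusterTree, ccc, upgma
from .edit import pairwise_lsi, set_median
from .types import Catalog

__all__ = ["ThemeValidation", "validate_theme_assignment", "compute_set_medians",
           "write_set_medians"]

logger = logging.getLogger(__name__)

CCC_WARN_THRESHOLD = 0.8  # conventional "good clustering" cut-off


@dataclass
class ThemeValidation:
    tree: ClusterTree
    ccc: float
    purity: dict[str, float]  # theme token text -> majority-subtree purity

    @property
    def min_purity(self) -> float:
        return min(self.purity.values())


def _majority_subtree_purity(tree: ClusterTree, labels_by_phrase: dict[str, str]) -> dict[str, float]:
    themes = sorted(set(labels_by_phrase.values()))
    nodes = list(tree.root.walk())  # includes leaves and root
    counts = []
    for node in nodes:
        c: dict[str, int] = {}
        for leaf in node.leafset:
            t = labels_by_phrase[leaf]
            c[t] = c.get(t, 0) + 1
        counts.append(c)
    purity = {}
    for t in themes:
        total = sum(1 for v in labels_by_phrase.values() if v == t)
        best = 0
        best_size = None
        for node, c in zip(nodes, counts):
            inside = c.get(t, 0)
            if inside == 0 or inside < max(c.values()):
                continue  # theme must be the plurality label of the subtree
            size = len(node.leafset)
            if inside > best or (inside == best and (best_size is None or size < best_size)):
                best, best_size = inside, size
        purity[t] = best / total
    return purity


def validate_theme_assignment(
    catalog: Catalog, warn_threshold: float = CCC_WARN_THRESHOLD
) -> ThemeValidation:
    """Cluster all phrase strings by 1 - LSI (UPGMA) and score the labelling.

    Returns the tree, its CCC against the input dissimilarities (defined as
    1 when only a single pair exists), and per-theme majority-subtree
    purity. Raises if all phrases are identical (zero-variance clustering).
    """
    phrases = catalog.all_phrases(included_only=True)
    if len(phrases) < 2:
        raise ValueError("need at least 2 phrases to validate theme assignment")
    items = [(pid, p.units) for pid, p in phrases]
    if len({units for _, units in items}) == 1:
        raise ValueError("all phrases identical: clustering is degenerate")
    sim = pairwise_lsi(items)
    d = sim.to_dissimilarity()
    tree = upgma(d)
    if len(phrases) == 2:
        coefficient = 1.0  # a single distance pair is reproduced exactly
    else:
        coefficient = ccc(d, tree)
    if coefficient <= warn_threshold:
        logger.warning("phrase-level CCC %.3f is below the %.2f threshold",
                       coefficient, warn_threshold)
    labels_by_phrase = {pid: str(p.theme) for pid, p in phrases}
    purity = _majority_subtree_purity(tree, labels_by_phrase)
    return ThemeValidation(tree, coefficient, purity)


def compute_set_medians(catalog: Catalog) -> pd.DataFrame:
    """Set-median unit string per (theme, location, year) group.

    One row per observed group, columns: theme, location, year, n_phrases,
    median_units (space-separated). Groups partition the included phrases.
    """
    groups: dict[tuple[str, str, int], list[tuple[str, ...]]] = {}
    for s in catalog.included_singers():
        for p in s.phrases:
            groups.setdefault((str(p.theme), s.location, s.year), []).append(p.units)
    rows = []
    for (theme, location, year), units_list in sorted(groups.items()):
        _, median = set_median(units_list)
        rows.append({
            "theme": theme,
            "location": location,
            "year": year,
            "n_phrases": len(units_list),
            "median_units": " ".join(median),
        })
    return pd.DataFrame(rows, columns=["theme", "location", "year", "n_phrases", "median_units"])


def write_set_medians(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t", index=False)
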