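"""End-to-end orchestration: transcripts in, machine-readable report out.

Stages: parse -> inclusion filter -> phrase-level theme validation (tree,
CCC, purity) -> set medians -> song-string compression -> LSI and DSI
matrices -> UPGMA trees with CCC -> multiscale-bootstrap AU/BP support ->
JSON report. Every stage logs its row counts; any stage error aborts with
the stage name. Reports are byte-identical across reruns with the same
inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from . import io as tio
from .bootstrap import BootstrapConfig, DEFAULT_SCALES, bootstrap_support, support_table
from .cluster import ccc, cut_tree, to_newick, upgma
from .songs import song_dsi_matrix, song_lsi_matrix
from .themes import compute_set_medians, validate_theme_assignment, write_set_medians
from .types import Catalog

__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis"]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All stage parameters in one place (YAML-loadable)."""

    min_minutes: float = 10.0
    n_boot: int = 1000
    scales: tuple[float, ...] = DEFAULT_SCALES
    seed: int = 0
    run_bootstrap: bool = True
    membership_ks: tuple[int, ...] = (2, 3, 4)
    ccc_warn_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        for key in ("scales", "membership_ks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r}: {e}") from e
        return wrapper
    return deco


def run_full_analysis(
    transcripts: Union[PathLike, Catalog],
    out_dir: PathLike,
    config: Optional[PipelineConfig] = None,
    metadata: Optional[PathLike] = None,
) -> dict:
    """Run the whole similarity analysis and write all artifacts to ``out_dir``.

    ``transcripts`` may be a transcript TSV path or an in-memory Catalog.
    Returns the report dict (also written to ``report.json``).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "parameters": asdict(cfg), "stages": {}}

    @_stage("parse")
    def parse() -> Catalog:
        if isinstance(transcripts, Catalog):
            return transcripts
        return tio.parse_transcripts(transcripts, metadata)

    catalog = parse()
    report["stages"]["parse"] = {
        "n_singers": len(catalog),
        "n_phrases": sum(len(s.phrases) for s in catalog),
    }

    @_stage("inclusion_filter")
    def filter_(c: Catalog) -> Catalog:
        return tio.apply_inclusion_filter(c, cfg.min_minutes)

    catalog = filter_(catalog)
    included = catalog.included_singers()
    report["stages"]["inclusion_filter"] = {
        "min_minutes": cfg.min_minutes,
        "n_included": len(included),
        "excluded": sorted(s.singer_id for s in catalog if not s.included),
    }

    @_stage("theme_validation")
    def validate(c: Catalog):
        v = validate_theme_assignment(c, cfg.ccc_warn_threshold)
        path = out / "phrase_tree.nwk"
        path.write_text(to_newick(v.tree, with_support=False) + "\n", encoding="utf-8")
        return v, path

    validation, phrase_tree_path = validate(catalog)
    report["phrase_level"] = {
        "ccc": round(validation.ccc, 6),
        "purity": {k: round(v, 6) for k, v in sorted(validation.purity.items())},
        "min_purity": round(validation.min_purity, 6),
        "tree": phrase_tree_path.name,
    }

    @_stage("set_medians")
    def medians(c: Catalog):
        table = compute_set_medians(c)
        path = out / "set_medians.tsv"
        write_set_medians(table, path)
        return table, path

    median_table, median_path = medians(catalog)
    report["stages"]["set_medians"] = {"n_groups": len(median_table), "path": median_path.name}

    @_stage("song_strings")
    def songs(c: Catalog):
        path = out / "song_strings.txt"
        tio.write_song_strings(c, path)
        return path

    report["stages"]["song_strings"] = {"path": songs(catalog).name}

    report["song_level"] = {}
    for index_name, build in (("lsi", song_lsi_matrix), ("dsi", song_dsi_matrix)):

        @_stage(f"similarity_{index_name}")
        def similarity(c: Catalog, _build=build, _name=index_name):
            sim = _build(c)
            path = out / f"{_name}_matrix.csv"
            sim.to_csv(path)
            return sim, path

        sim, matrix_path = similarity(catalog)
        d = sim.to_dissimilarity()

        @_stage(f"cluster_{index_name}")
        def cluster(_d=d, _name=index_name):
            tree = upgma(_d)
            return tree, ccc(_d, tree)

        tree, coefficient = cluster()

        entry = {
            "ccc": round(coefficient, 6),
            "n_singers": len(sim.labels),
            "matrix": matrix_path.name,
        }

        if cfg.run_bootstrap:

            @_stage(f"bootstrap_{index_name}")
            def boot(_d=d, _name=index_name):
                bcfg = BootstrapConfig(n_boot=cfg.n_boot, scales=cfg.scales, seed=cfg.seed)
                supported = bootstrap_support(_d, bcfg)
                table = support_table(supported, bcfg)
                tpath = out / f"{_name}_support.tsv"
                table.to_csv(tpath, sep="\t", index=False, float_format="%.6f")
                return supported, tpath

            tree, support_path = boot()
            entry["support"] = support_path.name
            # recompute CCC on the (re-ordered) supported tree's input
            entry["ccc"] = round(ccc(d, tree), 6)

        tree_path = out / f"{index_name}_tree.nwk"
        tree_path.write_text(to_newick(tree) + "\n", encoding="utf-8")
        entry["tree"] = tree_path.name

        @_stage(f"memberships_{index_name}")
        def memberships(_tree=tree):
            result = {}
            for k in cfg.membership_ks:
                if 1 <= k <= len(_tree.labels):
                    result[str(k)] = cut_tree(_tree, k)
            return result

        entry["memberships"] = memberships()
        report["song_level"][index_name] = entry
        logger.info("%s: CCC=%.4f over %d singers", index_name.upper(),
                    entry["ccc"], entry["n_singers"])

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                           encoding="utf-8")
    return report
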