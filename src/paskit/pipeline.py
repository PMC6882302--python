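"""End-to-end orchestration: counts + design + pathway DB -> report bundle.

The pipeline chains the stages in analysis order — normalize, CNR/BTIF/PAS,
per-contrast significance, Venn partition of significant-ISP sets, time
profiles, PCA, clustering, miRNA presence patterns and single-sample
enrichment — writing each artifact as TSV/CSV/JSON into an output
directory together with a run manifest (parameters, SHA-256 input
checksums, artifact list).  Every stage is a plain library call, so any
subset can be re-run on the previous stage's files; there is no hidden
state, and identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, enrichment, mirna, pas, stats
from .errors import ParameterError, PaskitError
from .expression import (
    normalize,
    read_counts,
    read_design,
    reference_samples,
    validate_design,
)
from .pathway_db import parse_pathway_db

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(PaskitError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    counts: str
    design: str
    pathway_db: str
    signatures: str | None = None  # GMT file
    mirna_counts: str | None = None
    mirna_targets: str | None = None
    normalization: str = "cpm"
    pseudocount: float = 1.0
    alpha: float = 0.05
    fold_low: float = 0.66
    fold_high: float = 1.5
    min_pas: float = 0.1
    min_reads: int = 10
    sd_floor: float = 0.1
    cluster_metric: str = "pearson"
    venn_procedures: tuple[str, ...] | None = None
    venn_timepoint: float = 4.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "venn_procedures" in raw and raw["venn_procedures"] is not None:
            raw["venn_procedures"] = tuple(raw["venn_procedures"])
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {"counts": self.counts, "design": self.design,
                 "pathway_db": self.pathway_db}
        for name in ("signatures", "mirna_counts", "mirna_targets"):
            value = getattr(self, name)
            if value is not None:
                paths[name] = value
        return paths

    def validate(self) -> None:
        for name, value in self.input_paths().items():
            if not Path(value).is_file():
                raise PipelineError("inputs", f"{name} path {value!r} not found")
        if not 0 < self.alpha < 1:
            raise PipelineError("inputs", f"alpha {self.alpha} outside (0, 1)")
        if self.min_pas < 0 or self.min_reads < 0 or self.pseudocount < 0:
            raise PipelineError("inputs", "min_pas, min_reads, pseudocount must be >= 0")


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _contrast_cells(design: pd.DataFrame) -> list[tuple[str, float, list[str]]]:
    cases = design[~design["is_reference"].astype(bool)]
    cells: dict[tuple[str, float], list[str]] = {}
    for sample, row in cases.iterrows():
        cells.setdefault((row["procedure"], float(row["timepoint_h"])), []).append(sample)
    return [(proc, tp, cells[(proc, tp)]) for proc, tp in sorted(cells)]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {name: _sha256(path) for name, path in config.input_paths().items()},
        "artifacts": [],
        "status": "incomplete",
    }

    def _finish_artifact(name: str) -> None:
        manifest["artifacts"].append(name)

    def _write_manifest() -> None:
        with open(out / "manifest.json", "w", encoding="utf-8") as handle:
            json.dump(manifest, handle, indent=2, ensure_ascii=False)

    stage = "load"
    try:
        matrix = read_counts(config.counts)
        design = read_design(config.design)
        validate_design(design, matrix)
        db = parse_pathway_db(config.pathway_db)
        refs = reference_samples(design)

        stage = "pas"
        result = pas.score_pathways(
            matrix,
            design,
            db,
            normalization=config.normalization,
            pseudocount=config.pseudocount,
            alpha=config.alpha,
            fold_low=config.fold_low,
            fold_high=config.fold_high,
            sd_floor=config.sd_floor,
        )
        pas.write_pas(result.pas, out / "pas_matrix.tsv", result.params)
        _finish_artifact("pas_matrix.tsv")
        _finish_artifact("pas_matrix.yaml")

        stage = "stats"
        tables = []
        for proc, tp, samples in _contrast_cells(design):
            table = stats.significance_table(
                result.pas,
                samples,
                refs,
                alpha=config.alpha,
                min_pas=config.min_pas,
                sd_floor=config.sd_floor,
            )
            table.insert(0, "procedure", proc)
            table.insert(1, "timepoint_h", tp)
            tables.append(table)
        significance = pd.concat(tables)
        significance.to_csv(out / "significance.tsv", sep="\t", na_rep="NA",
                            index_label="pathway")
        _finish_artifact("significance.tsv")

        stage = "compare"
        procedures = config.venn_procedures
        if procedures is None:
            non_ref = [p for p, _, _ in _contrast_cells(design)]
            seen: list[str] = []
            for p in non_ref:
                if p not in seen:
                    seen.append(p)
            procedures = tuple(seen[:4])
        venn_sets = {}
        for proc in procedures:
            block = significance[
                (significance["procedure"] == proc)
                & (significance["timepoint_h"] == config.venn_timepoint)
            ]
            venn_sets[proc] = set(stats.select_significant(block, config.alpha, 0.0))
        if len(venn_sets) >= 2:
            partition = compare.venn_partition(venn_sets)
            (out / "venn.json").write_text(partition.to_json(), encoding="utf-8")
            _finish_artifact("venn.json")

        profiles = compare.time_profiles(result.pas, design)
        profiles.to_csv(out / "time_profiles.tsv", sep="\t", na_rep="NA")
        _finish_artifact("time_profiles.tsv")

        pca = compare.pca_transform(result.pas, n_components=2)
        coords = pca.coordinates.copy()
        coords.loc["variance_explained"] = pca.variance_explained
        coords.to_csv(out / "pca_coordinates.csv", index_label="sample")
        _finish_artifact("pca_coordinates.csv")

        clustering = compare.hierarchical_cluster(result.pas, metric=config.cluster_metric)
        cluster_payload = {
            "metric": config.cluster_metric,
            "linkage": "average",
            "leaf_order": clustering.leaf_order,
            "merge_tree": np.asarray(clustering.linkage).tolist(),
        }
        (out / "cluster.json").write_text(
            json.dumps(cluster_payload, indent=2), encoding="utf-8"
        )
        _finish_artifact("cluster.json")

        if config.mirna_counts is not None:
            stage = "mirna"
            mirna_expr = read_counts(config.mirna_counts)
            patterns = mirna.presence_patterns(mirna_expr, design, config.min_reads)
            flat = patterns.copy()
            flat.columns = [f"{p}@{tp:g}h" for p, tp in patterns.columns]
            flat.astype(int).to_csv(out / "mirna_patterns.tsv", sep="\t",
                                    index_label="mirna_id")
            _finish_artifact("mirna_patterns.tsv")
            if config.mirna_targets is not None:
                targets = mirna.read_target_table(config.mirna_targets)
                kept = mirna.filter_true_targets(targets, matrix, config.min_reads)
                mirna.write_target_table(kept, out / "mirna_true_targets.tsv")
                _finish_artifact("mirna_true_targets.tsv")

        if config.signatures is not None:
            stage = "enrich"
            signatures = enrichment.read_gmt(config.signatures)
            norm = normalize(matrix, config.normalization)
            scores = enrichment.enrichment_matrix(norm, signatures)
            scores.to_csv(out / "enrichment.tsv", sep="\t", na_rep="NA")
            _finish_artifact("enrichment.tsv")
    except PipelineError:
        _write_manifest()
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
        _write_manifest()
        raise PipelineError(stage, str(exc)) from exc

    manifest["status"] = "complete"
    _write_manifest()
    logger.info("pipeline complete: %d artifacts in %s", len(manifest["artifacts"]), out)
    return manifest
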