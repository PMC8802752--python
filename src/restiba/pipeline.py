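"""End-to-end orchestration: simulate -> preprocess -> metrics -> group -> correlate.

A :class:`RunConfig` bundles the cohort specification (or an input directory
produced by ``restiba simulate``), the preprocessing/metric/inference
parameters and one root seed.  :func:`run_full_pipeline` executes the stages
in the canonical order, enforcing the data-state contracts (ALFF/fALFF consume
the unfiltered series, PerAF/ReHo/DC the filtered one), and emits stat maps,
cluster tables, correlation tables and a JSON manifest with file hashes and
the subject inclusion/exclusion log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity_metrics import MetricConfig, compute_all_metrics, compute_alff
from .behavior_stats import cluster_score_correlations
from .core import MetricMap
from .group_inference import (build_design_matrix, estimate_smoothness,
                              glm_two_sample_t, grf_cluster_inference,
                              match_filter_cohort)
from .synthetic_cohort import (CohortSpec, EffectRegion, SiteSpec, SubjectSim,
                               behavioral_score_table, generate_cohort,
                               save_nifti_deterministic, write_cohort)
from .temporal_preprocess import (PreprocConfig, mean_framewise_displacement,
                                  motion_qc, preprocess_subject)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_full_pipeline", "load_run_config"]


class PipelineStageError(RuntimeError):
    """A stage-level failure; carries the name of the offending stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    outdir: str = "restiba_out"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    voxel_p: float = 0.05
    cluster_p: float = 0.05
    connectivity: int = 26
    score_associations: dict = field(default_factory=dict)
    score_noise_sd: float = 0.0
    write_images: bool = True
    # debug switch used to exercise the fail-fast contract checks
    force_filtered_alff: bool = False


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclass fields)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_raw = raw.pop("cohort", {})
    sites = [SiteSpec(**s) for s in cohort_raw.pop("sites", [])] or None
    effects = [EffectRegion(**{**e, "center": tuple(e["center"])})
               for e in cohort_raw.pop("effects", [])]
    if "grid_shape" in cohort_raw:
        cohort_raw["grid_shape"] = tuple(cohort_raw["grid_shape"])
    cohort = CohortSpec(**cohort_raw, effects=effects,
                        **({"sites": sites} if sites else {}))
    preproc = PreprocConfig(**raw.pop("preproc", {}))
    metrics = MetricConfig(**raw.pop("metrics", {}))
    return RunConfig(cohort=cohort, preproc=preproc, metrics=metrics, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False
    return _Ctx()


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a synthetic cohort; returns the manifest.

    The manifest records the config snapshot, the exclusion log (reasons drawn
    from {motion, site-coverage, user}), per-stage outputs with SHA-256 hashes
    and, per metric, the surviving-cluster table.  On a stage failure a
    partial manifest is written before the error propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "restiba", "version": __version__},
        "config": _config_snapshot(config),
        "stages": [],
        "files": {},
        "exclusions": [],
    }

    def _record(path: Path) -> None:
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    def _finish(stage: str) -> None:
        manifest["stages"].append(stage)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        with _stage("simulate"):
            subjects, table = generate_cohort(config.cohort)
            if config.write_images:
                for p in write_cohort(subjects, table, outdir / "cohort"):
                    _record(p)
        _finish("simulate")

        with _stage("qc"):
            table = table.copy()
            table["mean_fd"] = [
                mean_framewise_displacement(s.motion, config.preproc.head_radius_mm)
                for s in subjects]
            table["motion_include"] = [
                motion_qc(s.motion, config.preproc.motion_limit_mm,
                          config.preproc.motion_limit_deg) for s in subjects]
            kept, log = match_filter_cohort(table)
            manifest["exclusions"] = log.to_dict("records")
            manifest["inclusion_counts"] = {
                "enrolled": {g: int((table["group"] == g).sum())
                             for g in table["group"].unique()},
                "included": {g: int((kept["group"] == g).sum())
                             for g in kept["group"].unique()},
            }
            by_id = {s.subject_id: s for s in subjects}
            included: list[SubjectSim] = [by_id[i] for i in kept["subject_id"]]
        _finish("qc")

        with _stage("preprocess"):
            unfiltered_all, filtered_all = [], []
            for s in included:
                unf, filt, _ = preprocess_subject(
                    s.bold, s.motion, s.wm_mask, s.csf_mask, config.preproc)
                unfiltered_all.append(unf)
                filtered_all.append(filt)
        _finish("preprocess")

        with _stage("metrics"):
            per_subject_maps: list[dict[str, MetricMap]] = []
            for s, unf, filt in zip(included, unfiltered_all, filtered_all):
                if config.force_filtered_alff:
                    compute_alff(filt)  # contract violation: raises
                per_subject_maps.append(
                    compute_all_metrics(unf, filt, config.metrics))
        _finish("metrics")

        with _stage("group"):
            design = build_design_matrix(kept)
            cluster_tables = {}
            cluster_masks = {}
            for key in per_subject_maps[0]:
                maps = [m[key] for m in per_subject_maps]
                stat = glm_two_sample_t(maps, design)
                smooth = estimate_smoothness(stat.residuals, stat.mask,
                                             maps[0].voxel_size_mm)
                ct = grf_cluster_inference(stat, smooth, config.voxel_p,
                                           config.cluster_p,
                                           connectivity=config.connectivity)
                cluster_tables[key] = ct
                cluster_masks[key] = ct.label_map
                if config.write_images:
                    p = outdir / f"tmap_{key}.nii.gz"
                    save_nifti_deterministic(stat.t, stat.affine, p)
                    _record(p)
                tsv = outdir / f"clusters_{key}.tsv"
                ct.to_tsv(tsv)
                _record(tsv)
            manifest["clusters"] = {
                key: ct.table.to_dict("records") for key, ct in cluster_tables.items()}
        _finish("group")

        with _stage("correlate"):
            if config.score_associations:
                scores = behavioral_score_table(
                    included, config.score_associations,
                    config.score_noise_sd, config.cohort.seed)
                value_cols = {}
                for key, ct in cluster_tables.items():
                    for cid in ct.table["cluster_id"]:
                        cmask = ct.cluster_mask(int(cid))
                        col = f"{key}_c{cid}"
                        value_cols[col] = [
                            float(m[key].data[cmask].mean()) for m in per_subject_maps]
                if value_cols:
                    site_dummies = pd.get_dummies(
                        kept["site"], drop_first=True, dtype=float)
                    corr = cluster_score_correlations(
                        pd.DataFrame(value_cols),
                        scores.drop(columns="subject_id"),
                        site_dummies if site_dummies.shape[1] else None)
                    tsv = outdir / "correlations.tsv"
                    corr.to_csv(tsv, sep="\t", index=False)
                    _record(tsv)
                    manifest["correlations"] = corr.to_dict("records")
        _finish("correlate")
    except PipelineStageError as err:
        manifest["failed_stage"] = err.stage
        manifest["error"] = str(err.original)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    return manifest


def _config_snapshot(config: RunConfig) -> dict:
    snap = asdict(config)
    return json.loads(json.dumps(snap, default=str))
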