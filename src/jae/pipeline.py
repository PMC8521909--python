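"""End-to-end orchestration: simulate -> segment -> extract -> evaluate ->
importance -> heatmap -> longitudinal, each stage reading the previous
stage's files under one run directory, with a manifest of hashes and seeds
so a run is auditable and byte-reproducible."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .features import FeatureMatrix, build_feature_matrix, standardize_apply, standardize_fit
from .importance import accuracy_heatmap, rank_features
from .io import read_cohort, write_cohort
from .longitudinal import paired_one_tailed_ttest, score_pairs
from .model import loso_evaluate
from .preprocessing import bandpass, clamp_band, segment_cycles
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "StageError",
    "run_all",
    "stage_simulate",
    "stage_segment",
    "stage_extract",
    "stage_evaluate",
    "stage_importance",
    "stage_heatmap",
    "stage_longitudinal",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_simulate(config: PipelineConfig, out_dir: Path) -> Path:
    sessions = generate_cohort(config.cohort_spec())
    return write_cohort(sessions, out_dir / "cohort")


def stage_segment(config: PipelineConfig, manifest: Path, out_dir: Path) -> Path:
    """Per-channel cycle table (subject, visit, channel, cycle, start, end,
    qc correlation) from filtered audio + motion minima."""
    sessions = read_cohort(manifest)
    rows = []
    for sess in sessions:
        for rec in sess.recordings:
            lo, hi = clamp_band(rec.fs, *config.band)
            filtered = bandpass(rec, lo, hi)
            res = segment_cycles(filtered, sess.motion,
                                 lowpass_cutoff=config.lowpass_cutoff,
                                 expected_period=config.cycle_period)
            for ci, seg in enumerate(res):
                rows.append((sess.subject_id, sess.visit, rec.channel, ci,
                             seg.start, seg.end, res.qc_correlation))
    path = out_dir / "segments.csv"
    pd.DataFrame(rows, columns=["subject_id", "visit", "channel", "cycle",
                                "start", "end", "qc_correlation"]
                 ).to_csv(path, index=False)
    return path


def stage_extract(config: PipelineConfig, manifest: Path, out_dir: Path) -> Path:
    sessions = read_cohort(manifest)
    X = build_feature_matrix(
        sessions, band=config.band, lowpass_cutoff=config.lowpass_cutoff,
        frame_len=config.frame_len, cycle_period=config.cycle_period)
    path = out_dir / "features.csv"
    X.to_csv(path)
    return path


def stage_evaluate(config: PipelineConfig, features_path: Path, out_dir: Path) -> Path:
    X = FeatureMatrix.from_csv(features_path)
    result, reports = loso_evaluate(X, ridge=config.ridge,
                                    threshold=config.threshold)
    report = {
        "schema_version": 1,
        "config": config.to_dict(),
        "cycle_metrics": reports["cycle"].to_dict(),
        "subject_metrics_mean_rule": reports["subject_mean"].to_dict(),
        "subject_metrics_majority_rule": reports["subject_majority"].to_dict(),
        "subject_scores": {s: round(v, 10) for s, v in result.subject_scores.items()},
        "subject_truth": result.subject_truth,
    }
    path = out_dir / "report.json"
    _write_json(path, report)
    cyc = reports["cycle"]
    if cyc.roc_fpr is not None:
        pd.DataFrame({"fpr": cyc.roc_fpr, "tpr": cyc.roc_tpr}).to_csv(
            out_dir / "roc.csv", index=False)
    return path


def stage_importance(config: PipelineConfig, features_path: Path, out_dir: Path) -> Path:
    X = FeatureMatrix.from_csv(features_path).baseline()
    stats = standardize_fit(X)
    ranking = rank_features(standardize_apply(stats, X), ridge=config.ridge)
    path = out_dir / "ranking.csv"
    pd.DataFrame({"feature": ranking.features,
                  "abs_coefficient": ranking.magnitudes}).to_csv(path, index=False)
    return path


def stage_heatmap(config: PipelineConfig, features_path: Path,
                  ranking_path: Path, out_dir: Path) -> Path:
    X = FeatureMatrix.from_csv(features_path)
    ranking_df = pd.read_csv(ranking_path)
    from .importance import ImportanceRanking
    ranking = ImportanceRanking(features=list(ranking_df["feature"]),
                                magnitudes=ranking_df["abs_coefficient"].to_numpy())
    k = min(config.max_features, len(ranking.features))
    hm = accuracy_heatmap(X, ranking, max_features=k,
                          perm_cap=config.perm_cap, seed=config.seed,
                          ridge=config.ridge, threshold=config.threshold)
    path = out_dir / "heatmap.csv"
    pd.DataFrame(hm.accuracy,
                 index=[f"top{k}" for k in hm.feature_counts],
                 columns=[f"m{m}" for m in hm.cycle_counts]).to_csv(path)
    return path


def stage_longitudinal(config: PipelineConfig, features_path: Path,
                       out_dir: Path) -> Path | None:
    X = FeatureMatrix.from_csv(features_path)
    if not (X.meta["visit"] == "followup").any():
        logger.info("no follow-up sessions; longitudinal stage skipped")
        return None
    pairs = score_pairs(X, ridge=config.ridge, threshold=config.threshold)
    tt = paired_one_tailed_ttest(pairs.deltas)
    payload = {
        "schema_version": 1,
        "pairs": pairs.table.to_dict(orient="records"),
        "t_statistic": tt.t_statistic,
        "dof": tt.dof,
        "p_value": tt.p_value,
        "mean_delta": tt.mean_delta,
        "sd_delta": tt.sd_delta,
    }
    path = out_dir / "paired.json"
    _write_json(path, payload)
    return path


_STAGES = ("simulate", "segment", "extract", "evaluate", "importance",
           "heatmap", "longitudinal")


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage under ``out_dir``; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def run(stage: str, fn, *args):
        logger.info("stage %s", stage)
        try:
            result = fn(config, *args)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(stage, exc) from exc
        if result is not None:
            artifacts[stage] = str(Path(result).relative_to(out_dir))
        return result

    manifest = run("simulate", stage_simulate, out_dir)
    run("segment", stage_segment, manifest, out_dir)
    features = run("extract", stage_extract, manifest, out_dir)
    run("evaluate", stage_evaluate, features, out_dir)
    ranking = run("importance", stage_importance, features, out_dir)
    run("heatmap", stage_heatmap, features, ranking, out_dir)
    run("longitudinal", stage_longitudinal, features, out_dir)

    hashes = {name: _sha256(out_dir / rel) for name, rel in artifacts.items()
              if (out_dir / rel).is_file()}
    _write_json(out_dir / "manifest.json", {
        "package_version": __version__,
        "stages": list(_STAGES),
        "config": config.to_dict(),
        "seed": config.seed,
        "artifacts": artifacts,
        "sha256": hashes,
    })
    return out_dir
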