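"""End-to-end orchestration: feature extraction, model fitting, benchmarks.

Three entry points mirror the analysis stages:

* :func:`run_study1` — read (or simulate) landmark tracks, normalize them,
  compute the eight candidate measures, their correlation matrix and the
  block-based predictor selection.
* :func:`run_study2` — summarize ratings per clip and group and fit the
  within-group, between-group, single-predictor and valence-specificity
  models, with leverage diagnostics and outlier re-fits.
* :func:`run_benchmark` — parameter-recovery simulation: generate synthetic
  studies from known coefficients and measure CI coverage.

Every run writes a manifest with the configuration hash and seed so outputs
are reproducible and auditable.
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

from . import io as fio
from .kinematics import feature_table
from .models import (
    DEFAULT_PREDICTORS,
    fit_between_group,
    fit_single_predictor,
    fit_within_group,
    flag_outliers,
    refit_excluding,
    specificity_models,
    summarize_ratings,
)
from .procrustes import NormalizationConfig, align_study
from .selection import correlation_blocks, pearson_matrix, select_predictors
from .simulate import PanelConfig, StudyConfig, generate_ratings, make_study

log = logging.getLogger("facekin")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run, loadable from YAML."""

    tracks_dir: str | None = None
    ratings_file: str | None = None
    metadata_file: str | None = None
    output_dir: str = "facekin_out"
    seed: int = 0
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    accel_denominator: int = 2
    block_threshold: float = 0.5
    selection_policy: str = "mean"
    outlier_predictor: str = "dist_neutral_mean"
    outlier_threshold: float = 4.0
    ci_level: float = 0.95
    synthetic: StudyConfig = field(default_factory=StudyConfig)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "normalization" in data and isinstance(data["normalization"], dict):
            data["normalization"] = NormalizationConfig(**data["normalization"])
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            data["synthetic"] = StudyConfig(**data["synthetic"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _manifest(config: PipelineConfig, stage: str, extra: dict) -> dict:
    return {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        **extra,
    }


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def load_tracks(config: PipelineConfig):
    """Read all landmark CSVs in ``tracks_dir``, attaching clip metadata."""
    if config.tracks_dir is None:
        raise FileNotFoundError("no tracks_dir configured")
    tracks_dir = Path(config.tracks_dir)
    if not tracks_dir.is_dir():
        raise FileNotFoundError(f"tracks directory {tracks_dir} not found")
    meta = None
    if config.metadata_file:
        meta = fio.read_clip_metadata(config.metadata_file).set_index("clip_id")
    tracks = []
    for path in sorted(tracks_dir.glob("*.csv")):
        clip_id = path.stem
        actor, emotion = "", ""
        if meta is not None and clip_id in meta.index:
            actor = meta.loc[clip_id, "actor_id"]
            emotion = meta.loc[clip_id, "emotion_category"]
        tracks.append(
            fio.read_openface_csv(
                path, clip_id=clip_id, actor_id=actor, emotion=emotion
            )
        )
    if not tracks:
        raise FileNotFoundError(f"no landmark CSVs found in {tracks_dir}")
    return tracks


def run_study1(config: PipelineConfig) -> dict:
    """Normalize tracks, extract features, correlate and select predictors."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks = load_tracks(config)
    log.info("study1: %d tracks", len(tracks))
    aligned, gpa_result = align_study(tracks, config.normalization)
    features = feature_table(aligned, config.accel_denominator)
    fio.write_feature_table(features, out / "features.csv")
    corr = pearson_matrix(features)
    corr.to_csv(out / "correlation_matrix.csv")
    blocks = correlation_blocks(corr, config.block_threshold)
    predictors = select_predictors(blocks, config.selection_policy)
    report = _manifest(
        config,
        "study1",
        {
            "n_clips": len(tracks),
            "n_landmarks": tracks[0].n_landmarks,
            "gpa_iterations": gpa_result.n_iterations,
            "gpa_converged": gpa_result.converged,
            "gpa_residual": gpa_result.residual,
            "blocks": [list(b) for b in blocks],
            "selected_predictors": list(predictors),
        },
    )
    _write_json(report, out / "study1_report.json")
    return {
        "features": features,
        "correlation": corr,
        "blocks": blocks,
        "predictors": predictors,
        "report": report,
    }


def run_study2(
    config: PipelineConfig, features: pd.DataFrame | None = None
) -> dict:
    """Fit the full set of rating models and diagnostics."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if features is None:
        features = fio.read_feature_table(out / "features.csv")
    if config.ratings_file is None:
        raise FileNotFoundError("no ratings_file configured")
    ratings = fio.read_ratings(config.ratings_file)
    groups = [g for g in ("NT", "ASD", "HAT") if g in set(ratings["group"])]
    if "NT" not in groups:
        raise ValueError("ratings contain no NT group")
    predictors = DEFAULT_PREDICTORS
    summaries = {g: summarize_ratings(ratings, g) for g in groups}

    fits: dict = {}
    for g in groups:
        fits[f"arousal_{g}"] = fit_within_group(
            features, summaries[g], g, predictors, ci_level=config.ci_level
        )
        for p in predictors:
            fits[f"arousal_{g}_{p}"] = fit_single_predictor(
                features, summaries[g], g, p, ci_level=config.ci_level
            )
    for g in groups:
        if g == "NT":
            continue
        fits[f"arousal_NT-{g}"] = fit_between_group(
            features, summaries["NT"], summaries[g], predictors,
            ci_level=config.ci_level, label=f"arousal NT-{g}",
        )
    fits.update(
        specificity_models(
            features,
            {g: summaries[g] for g in groups[:2]},
            predictors,
            config.ci_level,
        )
    )

    # leverage diagnostics and outlier re-fits on the distance predictor
    analysis_clips = fits["arousal_NT"].design.index
    outliers = flag_outliers(
        features.loc[analysis_clips],
        config.outlier_predictor,
        config.outlier_threshold,
        fit=fits["arousal_NT"],
    )
    log.info(
        "flagged %d outlier clip(s) on %s: %s",
        len(outliers.flagged), outliers.predictor, outliers.flagged,
    )
    refits = {}
    if outliers.flagged:
        for g in groups:
            refits[f"arousal_{g}_refit"] = refit_excluding(
                features,
                summaries[g]["mean_arousal"],
                outliers,
                predictors,
                ci_level=config.ci_level,
                label=f"arousal {g} (outliers excluded)",
            )

    tables = {
        name: fit.to_frame().reset_index(names="term").to_dict("records")
        for name, fit in {**fits, **refits}.items()
    }
    report = _manifest(
        config,
        "study2",
        {
            "groups": groups,
            "models": {
                name: fit.summary_dict() for name, fit in {**fits, **refits}.items()
            },
            "outliers": {
                "predictor": outliers.predictor,
                "threshold": outliers.threshold,
                "flagged": list(outliers.flagged),
                "loo_z": {
                    str(k): float(v)
                    for k, v in outliers.loo_z.loc[outliers.flagged].items()
                },
            },
        },
    )
    _write_json(report, out / "study2_report.json")
    coef_rows = []
    for name, recs in tables.items():
        for rec in recs:
            coef_rows.append({"model": name, **rec})
    pd.DataFrame(coef_rows).to_csv(out / "model_coefficients.csv", index=False)
    return {"fits": fits, "refits": refits, "outliers": outliers, "report": report}


def run_simulate(config: PipelineConfig) -> dict:
    """Generate a synthetic study and write it in the pipeline's file formats."""
    out = Path(config.output_dir)
    tracks_dir = out / "tracks"
    tracks_dir.mkdir(parents=True, exist_ok=True)
    study = make_study(config.synthetic, seed=config.seed)
    for t in study.tracks:
        fio.write_openface_csv(t, tracks_dir / f"{t.clip_id}.csv")
    study.ratings.to_csv(out / "ratings.csv", index=False)
    meta = study.true_params.reset_index()[["clip_id", "actor_id", "emotion"]]
    meta = meta.rename(columns={"emotion": "emotion_category"})
    meta.to_csv(out / "clip_metadata.csv", index=False)
    study.true_params.to_csv(out / "true_params.csv")
    study.true_features.to_csv(out / "true_features.csv")
    _write_json(
        _manifest(
            config,
            "simulate",
            {
                "n_clips": len(study.tracks),
                "n_ratings": len(study.ratings),
                "realized_feature_correlation": study.realized_correlation,
            },
        ),
        out / "simulate_report.json",
    )
    return {"study": study, "tracks_dir": tracks_dir}


def run_benchmark(
    config: PipelineConfig, replicates: int = 100
) -> dict:
    """Parameter-recovery simulation over rating replicates.

    The clip set (and hence the measured features) is generated once; each
    replicate draws fresh clip effects, panels and rater noise, refits the
    within-group and difference models, and records whether the 95% CIs cover
    the generating coefficients.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    cfg = config.synthetic
    study = make_study(cfg, seed=config.seed)
    features = study.features
    rng = np.random.default_rng(config.seed + 1)
    truth = {
        "const": cfg.nt_beta0,
        "dist_neutral_mean": cfg.beta_distance,
        "speed_mean": cfg.beta_speed,
    }
    cover = {k: 0 for k in truth}
    cover_diff_intercept = 0
    est_records = []
    for _ in range(replicates):
        clip_eff = pd.Series(
            rng.normal(0, cfg.clip_effect_sd, len(features)),
            index=features.index,
        )
        panels = {
            "NT": PanelConfig(
                "NT", cfg.nt_raters, cfg.nt_clips_per_rater, cfg.nt_beta0,
                cfg.beta_distance, cfg.beta_speed, cfg.rater_noise_sd,
            ),
            "ASD": PanelConfig(
                "ASD", cfg.asd_raters, cfg.asd_clips_per_rater,
                cfg.nt_beta0 - cfg.asd_offset, cfg.beta_distance,
                cfg.beta_speed, cfg.rater_noise_sd,
            ),
        }
        ratings = pd.concat(
            [
                generate_ratings(
                    features, p, seed=int(rng.integers(2**31)),
                    clip_effects=clip_eff,
                )
                for p in panels.values()
            ],
            ignore_index=True,
        )
        summ_nt = summarize_ratings(ratings, "NT")
        summ_asd = summarize_ratings(ratings, "ASD")
        fit = fit_within_group(features, summ_nt, "NT")
        for term, true_val in truth.items():
            lo = fit.conf_int.loc[term, "low"]
            hi = fit.conf_int.loc[term, "high"]
            cover[term] += int(lo <= true_val <= hi)
        diff = fit_between_group(features, summ_nt, summ_asd)
        lo = diff.conf_int.loc["const", "low"]
        hi = diff.conf_int.loc["const", "high"]
        cover_diff_intercept += int(lo <= cfg.asd_offset <= hi)
        est_records.append(
            {term: float(fit.params[term]) for term in truth}
            | {"diff_intercept": float(diff.params["const"])}
        )
    est = pd.DataFrame(est_records)
    summary = {
        "replicates": replicates,
        "truth": truth,
        "coverage": {k: cover[k] / replicates for k in truth},
        "coverage_difference_intercept": cover_diff_intercept / replicates,
        "mean_estimates": est.mean().to_dict(),
        "sd_estimates": est.std(ddof=1).to_dict(),
    }
    out = Path(config.output_dir)
    _write_json(
        _manifest(config, "benchmark", summary), out / "benchmark_report.json"
    )
    return summary
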