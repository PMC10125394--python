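"""End-to-end study orchestration: generate -> preprocess -> features ->
split/train/select -> validate -> report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import DEFAULT_BANDS, StudyConfig
from .features import extract_features
from .plsr import (
    EvalReport,
    coefficient_spectrum,
    evaluate,
    feature_matrix_from_records,
    fit_plsr,
    predict,
    select_components,
    split_holdout,
)
from .preprocess import PreprocessConfig, preprocess_tissue
from .synth import simulate_study

log = logging.getLogger("fixir")

__all__ = ["RunConfig", "RunReport", "run_study", "report_summary"]


@dataclass
class RunConfig:
    study: StudyConfig = field(default_factory=StudyConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    holdout_frac: float = 0.25
    folds: int = 2
    max_components: int = 15
    seed: int = 0
    output_dir: str = "fixir_run"
    group_replicates: bool = False
    make_plots: bool = True

    def config_hash(self) -> str:
        payload = {
            "fixation_times": self.study.fixation_times,
            "tissues_per_time": self.study.tissues_per_time,
            "replicates_per_tissue": self.study.replicates_per_tissue,
            "regions_per_slide": self.study.regions_per_slide,
            "noise_sd": self.study.noise_sd,
            "baseline_scale": self.study.baseline_scale,
            "atmospheric_scale": self.study.atmospheric_scale,
            "study_seed": self.study.seed,
            "baseline_points": self.preprocess.baseline_points,
            "baseline_iterations": self.preprocess.baseline_iterations,
            "holdout_frac": self.holdout_frac,
            "folds": self.folds,
            "max_components": self.max_components,
            "seed": self.seed,
            "group_replicates": self.group_replicates,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a TOML or JSON config file."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        study_kw = raw.get("study", {})
        if "fixation_times" in study_kw:
            study_kw["fixation_times"] = tuple(study_kw["fixation_times"])
        pre_kw = raw.get("preprocess", {})
        model_kw = raw.get("model", {})
        return cls(
            study=StudyConfig(**study_kw),
            preprocess=PreprocessConfig(**pre_kw),
            holdout_frac=model_kw.get("holdout_frac", 0.25),
            folds=model_kw.get("folds", 2),
            max_components=model_kw.get("max_components", 15),
            seed=raw.get("seed", 0),
            output_dir=raw.get("output_dir", "fixir_run"),
            group_replicates=model_kw.get("group_replicates", False),
            make_plots=raw.get("make_plots", True),
        )


@dataclass
class RunReport:
    mae_validation: float
    mae_training: float
    n_train: int
    n_validation: int
    selected_components: int
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _write_predictions(path: Path, fm, preds: np.ndarray, split: str, rows=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "row_id": fm.row_ids,
            "split": split,
            "fixation_time_h": fm.y,
            "predicted_h": np.round(preds, 6),
        }
    )
    return df


def run_study(config: RunConfig) -> RunReport:
    """Run every stage in order and write all artifacts under
    ``config.output_dir``; idempotent for identical config + seed."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %-12s t=%.1fs", name, time.time() - t0)

    try:
        stage("simulate")
        records = simulate_study(config.study)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("preprocess")
        fm = feature_matrix_from_records(records, config.preprocess)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        stage("features")
        feats = []
        for rec, row in zip(records, fm.X):
            from .core import Spectrum

            bf = extract_features(Spectrum(config.study.grid, row))
            feats.append(
                {
                    "tissue_id": rec.tissue_id,
                    "replicate_id": rec.replicate_id,
                    "fixation_time_h": rec.fixation_time,
                    "amide1_peak_cm1": round(bf.amide1_peak_location, 6),
                    "amide1_fwhm_cm1": round(bf.amide1_fwhm, 6),
                    "amideA_mag": round(bf.amideA_peak_magnitude, 6),
                }
            )
        features_df = pd.DataFrame(feats)
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    try:
        stage("split")
        train, val = split_holdout(
            fm, config.holdout_frac, config.seed, config.group_replicates
        )
        stage("select")
        k, diagnostics = select_components(
            train, config.max_components, config.folds, config.seed
        )
        stage("fit")
        model = fit_plsr(train, k)
        model.provenance = {"seed": config.seed, "config_hash": config.config_hash()}
        pred_train = predict(model, train.X)
        pred_val = predict(model, val.X)
        rep_train = evaluate(pred_train, train.y)
        rep_val = evaluate(pred_val, val.y)
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc

    try:
        stage("report")
        model_path = out / "model.json"
        model.to_json(model_path)
        features_path = out / "features.csv"
        features_df.to_csv(features_path, index=False)
        preds = pd.concat(
            [
                _write_predictions(out, train, pred_train, "train"),
                _write_predictions(out, val, pred_val, "validation"),
            ]
        )
        preds_path = out / "predictions.csv"
        preds.to_csv(preds_path, index=False)
        coef_path = out / "coefficients.csv"
        coefficient_spectrum(model).to_csv(coef_path, index=False)
        diagnostics.to_csv(out / "cv_diagnostics.csv", index=False)

        artifacts = {
            "model": str(model_path),
            "features": str(features_path),
            "predictions": str(preds_path),
            "coefficients": str(coef_path),
        }
        if config.make_plots:
            artifacts.update(_make_plots(out, model, rep_train, rep_val))

        report = RunReport(
            mae_validation=rep_val.mae,
            mae_training=rep_train.mae,
            n_train=train.n,
            n_validation=val.n,
            selected_components=k,
            artifacts=artifacts,
        )
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_records": len(records),
            "selected_components": k,
            "runtime_s": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (out / "report.json").write_text(report.to_json())
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc

    stage("done")
    return report


def _make_plots(out: Path, model, rep_train: EvalReport, rep_val: EvalReport) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coef_png = out / "coefficients.png"
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(model.wavenumbers, model.coefficients, lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("PLSR coefficient")
    fig.tight_layout()
    fig.savefig(coef_png, dpi=120)
    plt.close(fig)

    cdf_png = out / "error_cdf.png"
    fig, ax = plt.subplots(figsize=(4, 3))
    for rep, label in ((rep_train, "train"), (rep_val, "validation")):
        x = rep.cdf
        yq = np.arange(1, len(x) + 1) / len(x)
        ax.step(x, yq, where="post", label=label)
    ax.set_xlabel("absolute error (h)")
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(cdf_png, dpi=120)
    plt.close(fig)
    return {"coefficient_plot": str(coef_png), "cdf_plot": str(cdf_png)}


def report_summary(report: RunReport) -> tuple[str, dict]:
    """Human-readable summary plus a JSON-ready mirror of the report."""
    for key, path in report.artifacts.items():
        if not path:
            raise ValueError(f"artifact path for {key!r} is empty")
    lines = [
        f"MAE (validation): {report.mae_validation:.3f} h",
        f"MAE (training):   {report.mae_training:.3f} h",
        f"samples: {report.n_train} train / {report.n_validation} validation",
        f"components: {report.selected_components}",
        "artifacts:",
    ]
    lines += [f"  {k}: {v}" for k, v in sorted(report.artifacts.items())]
    return "\n".join(lines), json.loads(report.to_json())
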