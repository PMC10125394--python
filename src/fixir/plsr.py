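"""Fixation-time prediction by partial least-squares regression.

Implements PLS1 with the classical NIPALS deflation scheme, a stratified
holdout split, twofold cross-validated component selection with a
parsimony rule, prediction, MAE/CDF evaluation, and export of the
regression-coefficient spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Spectrum, TissueRecord, WavenumberGrid
from .preprocess import PreprocessConfig, preprocess_tissue

__all__ = [
    "FeatureMatrix",
    "PLSRModel",
    "EvalReport",
    "feature_matrix_from_records",
    "split_holdout",
    "fit_plsr",
    "select_components",
    "predict",
    "evaluate",
    "coefficient_spectrum",
]


@dataclass
class FeatureMatrix:
    """Samples x predictors plus the fixation-time target."""

    X: np.ndarray
    y: np.ndarray
    row_ids: list[str]
    wavenumbers: Optional[np.ndarray] = None
    groups: Optional[list[str]] = None  # e.g. tissue ids, for grouped splits

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y row counts differ")
        if len(self.row_ids) != self.X.shape[0]:
            raise ValueError("row_ids length mismatch")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("feature matrix contains non-finite values")
        if np.any(self.y < 0):
            raise ValueError("fixation times must be non-negative")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def take(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx, int)
        return FeatureMatrix(
            self.X[idx],
            self.y[idx],
            [self.row_ids[i] for i in idx],
            self.wavenumbers,
            [self.groups[i] for i in idx] if self.groups is not None else None,
        )


def feature_matrix_from_records(
    records: Sequence[TissueRecord],
    config: PreprocessConfig | None = None,
) -> FeatureMatrix:
    """Preprocess every record and stack the representative spectra as
    predictor rows (full-spectrum predictors)."""
    config = config or PreprocessConfig()
    if not records:
        raise ValueError("no records")
    rows, y, ids, groups = [], [], [], []
    for rec in records:
        spec = preprocess_tissue(rec, config)
        rows.append(spec.values)
        y.append(rec.fixation_time)
        ids.append(f"{rec.tissue_id}/{rec.replicate_id}")
        groups.append(rec.tissue_id)
    return FeatureMatrix(
        np.vstack(rows), np.array(y), ids,
        wavenumbers=records[0].grid.values, groups=groups,
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _stratified_pick(
    strata: np.ndarray, total_pick: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick ``total_pick`` indices stratified over ``strata`` values.

    Per-stratum quotas start at floor(share) and the remaining picks go to
    the strata with the largest fractional remainders (ties broken by a
    seeded shuffle), so the pooled count matches ``total_pick`` exactly.
    """
    n = len(strata)
    labels, counts = np.unique(strata, return_counts=True)
    shares = counts * (total_pick / n)
    quotas = np.floor(shares).astype(int)
    remainder = total_pick - quotas.sum()
    order = rng.permutation(len(labels))
    order = order[np.argsort(-shares[order] + quotas[order], kind="stable")]
    for j in order[:remainder]:
        quotas[j] += 1
    picked = []
    for label, q in zip(labels, quotas):
        members = np.nonzero(strata == label)[0]
        picked.extend(rng.choice(members, size=q, replace=False))
    return np.sort(np.asarray(picked, int))


def split_holdout(
    matrix: FeatureMatrix,
    holdout_frac: float = 0.25,
    seed: int = 0,
    group_replicates: bool = False,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified (by fixation time) holdout split.

    The pooled validation size is floor(holdout_frac * n) with per-stratum
    quotas allocated by largest remainder; with ``group_replicates`` the
    unit of splitting is the tissue (replicate slides stay together) and the
    pooled size is floor(frac * n_tissues) tissues.
    """
    if not 0 < holdout_frac < 1:
        raise ValueError("holdout_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if group_replicates:
        if matrix.groups is None:
            raise ValueError("matrix has no group labels")
        groups = np.asarray(matrix.groups)
        uniq, first = np.unique(groups, return_index=True)
        g_strata = matrix.y[first]
        if np.min(np.unique(g_strata, return_counts=True)[1]) < 2:
            raise ValueError("every fixation-time stratum needs >= 2 tissues")
        total = int(np.floor(holdout_frac * len(uniq)))
        val_groups = set(uniq[_stratified_pick(g_strata, total, rng)])
        val_idx = np.nonzero(np.isin(groups, list(val_groups)))[0]
    else:
        if np.min(np.unique(matrix.y, return_counts=True)[1]) < 2:
            raise ValueError("every fixation-time stratum needs >= 2 rows")
        total = int(np.floor(holdout_frac * matrix.n))
        val_idx = _stratified_pick(matrix.y, total, rng)
    train_idx = np.setdiff1d(np.arange(matrix.n), val_idx)
    return matrix.take(train_idx), matrix.take(val_idx)


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (k, p) unit-norm weight vectors
    x_loadings: np.ndarray    # (k, p)
    y_loadings: np.ndarray    # (k,)
    coefficients: np.ndarray  # (p,)
    n_components: int
    variance_explained_x: np.ndarray = field(default_factory=lambda: np.array([]))
    variance_explained_y: np.ndarray = field(default_factory=lambda: np.array([]))
    wavenumbers: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "fixir-plsr",
            "version": 1,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "n_components": self.n_components,
            "variance_explained_x": self.variance_explained_x.tolist(),
            "variance_explained_y": self.variance_explained_y.tolist(),
            "wavenumbers": None if self.wavenumbers is None else self.wavenumbers.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "fixir-plsr":
            raise ValueError("not a fixir PLSR model file")
        return cls(
            x_mean=np.array(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            weights=np.array(d["weights"]),
            x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            coefficients=np.array(d["coefficients"]),
            n_components=int(d["n_components"]),
            variance_explained_x=np.array(d["variance_explained_x"]),
            variance_explained_y=np.array(d["variance_explained_y"]),
            wavenumbers=None if d["wavenumbers"] is None else np.array(d["wavenumbers"]),
            provenance=d.get("provenance", {}),
        )


def fit_plsr(train: FeatureMatrix, n_components: int) -> PLSRModel:
    """NIPALS PLS1 fit.

    Per component: w proportional to X'y (unit norm), scores s = Xw,
    x-loading p = X's/(s's), y-loading q = y's/(s's), then deflate X and y.
    Coefficients are assembled as B = W (P'W)^-1 q so that prediction is
    y_mean + (x - x_mean)' B.
    """
    X0 = train.X - train.X.mean(axis=0)
    y0 = train.y - train.y.mean()
    n, p = X0.shape
    if np.allclose(y0, 0):
        raise ValueError("training target is constant; nothing to regress")
    kmax = min(n - 1, p)
    if not 1 <= n_components <= kmax:
        raise ValueError(f"n_components must be in [1, {kmax}], got {n_components}")

    X, y = X0.copy(), y0.copy()
    ssx_total = float(np.sum(X0**2))
    ssy_total = float(np.sum(y0**2))
    W, P, Q, vex, vey = [], [], [], [], []
    for _ in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break  # remaining covariance exhausted; cap the component count
        w /= norm
        s = X @ w
        ss = float(s @ s)
        if ss < 1e-12:
            break
        p_load = X.T @ s / ss
        q_load = float(y @ s / ss)
        X = X - np.outer(s, p_load)
        y = y - q_load * s
        W.append(w)
        P.append(p_load)
        Q.append(q_load)
        vex.append(ss * float(p_load @ p_load) / ssx_total if ssx_total else 0.0)
        vey.append(q_load**2 * ss / ssy_total if ssy_total else 0.0)

    Wm, Pm, Qv = np.array(W), np.array(P), np.array(Q)
    k = len(W)
    coef = Wm.T @ np.linalg.solve(Pm @ Wm.T, Qv)
    return PLSRModel(
        x_mean=train.X.mean(axis=0),
        y_mean=float(train.y.mean()),
        weights=Wm,
        x_loadings=Pm,
        y_loadings=Qv,
        coefficients=coef,
        n_components=k,
        variance_explained_x=np.array(vex),
        variance_explained_y=np.array(vey),
        wavenumbers=train.wavenumbers,
    )


def predict(model: PLSRModel, rows: np.ndarray) -> np.ndarray:
    """y_hat = y_mean + (x - x_mean)' B, no clipping (negative predictions
    are diagnostic signal)."""
    rows = np.atleast_2d(np.asarray(rows, float))
    if rows.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"predictor dimension {rows.shape[1]} does not match model "
            f"({model.coefficients.shape[0]})"
        )
    return model.y_mean + (rows - model.x_mean) @ model.coefficients


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deal samples round-robin into folds in target order (random within
    ties), so each fold sees a balanced slice of the y distribution for
    discrete strata and continuous targets alike."""
    order = np.lexsort((rng.random(len(y)), y))
    assignment = np.empty(len(y), int)
    assignment[order] = np.arange(len(y)) % folds
    return [np.nonzero(assignment == f)[0] for f in range(folds)]


def select_components(
    train: FeatureMatrix,
    max_components: int = 15,
    folds: int = 2,
    seed: int = 0,
    tolerance: float = 0.02,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated component selection with a one-sided parsimony rule.

    Computes the fold-CV mean squared prediction error for k = 1..max and
    returns the smallest k whose CV-MSE is within ``tolerance`` of the
    global minimum, alongside a diagnostics table (CV-MSE and per-component
    variance explained).  The tight default keeps the selection on the CV
    plateau; looser values trade a little accuracy for fewer components.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    rng = np.random.default_rng(seed)
    fold_idx = _stratified_folds(train.y, folds, rng)
    kmax = max_components
    for f in fold_idx:
        n_tr = train.n - len(f)
        kmax = min(kmax, n_tr - 1, train.X.shape[1])
    errs = [[] for _ in range(kmax)]
    for f in fold_idx:
        tr_idx = np.setdiff1d(np.arange(train.n), f)
        tr, te = train.take(tr_idx), train.take(f)
        model = fit_plsr(tr, kmax)
        # score the held-out fold at every truncation of the component series
        Xc = te.X - model.x_mean
        for k in range(1, kmax + 1):
            Wk, Pk, Qk = model.weights[:k], model.x_loadings[:k], model.y_loadings[:k]
            coef_k = Wk.T @ np.linalg.solve(Pk @ Wk.T, Qk)
            pred = model.y_mean + Xc @ coef_k
            errs[k - 1].extend((pred - te.y) ** 2)
    cv_mse = np.array([np.mean(e) for e in errs])
    best = float(cv_mse.min())
    selected = int(np.nonzero(cv_mse <= (1.0 + tolerance) * best)[0][0]) + 1
    full = fit_plsr(train, kmax)
    diag = pd.DataFrame(
        {
            "n_components": np.arange(1, kmax + 1),
            "cv_mse": cv_mse,
            "variance_explained_x": np.resize(full.variance_explained_x, kmax),
            "variance_explained_y": np.resize(full.variance_explained_y, kmax),
        }
    )
    return selected, diag


@dataclass
class EvalReport:
    predictions: np.ndarray
    truth: np.ndarray
    absolute_errors: np.ndarray
    mae: float
    cdf: np.ndarray  # sorted absolute errors (the error quantile curve)

    def by_time(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"truth": self.truth, "prediction": self.predictions,
             "abs_error": self.absolute_errors}
        )
        return df.groupby("truth").agg(["mean", "std", "count"])


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> EvalReport:
    predictions = np.asarray(predictions, float)
    truth = np.asarray(truth, float)
    if predictions.size == 0:
        raise ValueError("cannot evaluate empty predictions")
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth lengths differ")
    abs_err = np.abs(predictions - truth)
    return EvalReport(
        predictions=predictions,
        truth=truth,
        absolute_errors=abs_err,
        mae=float(abs_err.mean()),
        cdf=np.sort(abs_err),
    )


def coefficient_spectrum(model: PLSRModel) -> pd.DataFrame:
    """(wavenumber, coefficient) table; positive coefficients mark
    wavenumbers whose absorbance increases the predicted fixation time."""
    if model.wavenumbers is None:
        wn = np.arange(model.coefficients.shape[0], dtype=float)
    else:
        wn = model.wavenumbers
    return pd.DataFrame({"wavenumber_cm1": wn, "coefficient": model.coefficients})
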