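"""NIPALS partial least squares regression for adulteration quantification.

Single-response NIPALS: for each latent factor the weight vector is the
(normalised) covariance direction X'y of the current residuals, followed by
deflation of both blocks.  With one response column no inner iteration is
needed, so the fit is fully deterministic.  Predictions use the folded-back
regression vector B = W (P'W)^-1 q in original variable space, which agrees
with sequential-deflation prediction to machine precision.

Figures of merit follow the usual multivariate-calibration conventions:
RMSEC/RMSECV are plain root-mean-square errors over calibration and
leave-one-out predictions, slope/offset come from ordinary least squares of
predicted on actual, and R^2 is the squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PreprocessConfig, preprocess_set
from .spectra import SpectrumSet
from .synth import BlendDesign

__all__ = [
    "PLSRModel",
    "CalibrationMetrics",
    "plsr_fit",
    "plsr_predict",
    "loo_cv",
    "figures_of_merit",
    "run_calibration_suite",
]


@dataclass(frozen=True)
class PLSRModel:
    n_factors: int
    x_mean: np.ndarray           # (p,)
    y_mean: float
    weights: np.ndarray          # W, (p, a)
    x_loadings: np.ndarray       # P, (p, a)
    y_loadings: np.ndarray       # q, (a,)
    regression_vector: np.ndarray  # B, (p,)


@dataclass(frozen=True)
class CalibrationMetrics:
    slope: float
    offset: float
    r2: float
    rmsec: float
    rmsecv: float
    n_factors: int
    cv_slope: float = float("nan")
    cv_offset: float = float("nan")
    cv_r2: float = float("nan")


def plsr_fit(X, y, a: int) -> PLSRModel:
    """Fit ``a`` NIPALS factors to centred X (n x p) and y (n,)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one y value per row")
    n, p = X.shape
    if not 1 <= a <= min(n - 1, p):
        raise ValueError(f"number of factors a={a} must lie in [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress on")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    scale = float(np.linalg.norm(X - x_mean)) or 1.0
    W = np.zeros((p, a))
    P = np.zeros((p, a))
    q = np.zeros(a)
    for j in range(a):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale:
            raise ValueError(
                f"X/y residuals exhausted after {j} factors; requested a={a} exceeds the data rank"
            )
        w /= nw
        t = E @ w
        tt = float(t @ t)
        pj = E.T @ t / tt
        qj = float(f @ t) / tt
        E = E - np.outer(t, pj)
        f = f - qj * t
        W[:, j], P[:, j], q[j] = w, pj, qj
    B = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(n_factors=a, x_mean=x_mean, y_mean=y_mean,
                     weights=W, x_loadings=P, y_loadings=q, regression_vector=B)


def plsr_predict(model: PLSRModel, X) -> np.ndarray:
    """yhat = (X - x_mean) B + y_mean; no clipping of out-of-range values."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.size == 0:
        raise ValueError("empty prediction matrix")
    if X.shape[1] != model.x_mean.size:
        raise ValueError(f"feature dimension {X.shape[1]} does not match model ({model.x_mean.size})")
    return (X - model.x_mean) @ model.regression_vector + model.y_mean


def loo_cv(X, y, a: int) -> np.ndarray:
    """Out-of-fold predictions: one refit per held-out sample at fixed a."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = plsr_fit(X[keep], y[keep], a)
        out[i] = plsr_predict(model, X[i])[0]
    return out


def figures_of_merit(y_true, y_pred_cal, y_pred_cv, n_factors: int = 0) -> CalibrationMetrics:
    """Slope/offset/R^2 of predicted-vs-actual plus RMSEC and RMSECV."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    yc = np.asarray(y_pred_cal, dtype=np.float64).ravel()
    yv = np.asarray(y_pred_cv, dtype=np.float64).ravel()
    if y.size != yc.size or y.size != yv.size:
        raise ValueError("y_true, y_pred_cal and y_pred_cv must have equal lengths")
    if np.ptp(y) == 0:
        raise ValueError("y_true has zero variance")

    def _line(pred):
        slope, offset = np.polyfit(y, pred, 1)
        r = np.corrcoef(y, pred)[0, 1]
        return float(slope), float(offset), float(r * r)

    slope, offset, r2 = _line(yc)
    cv_slope, cv_offset, cv_r2 = _line(yv)
    return CalibrationMetrics(
        slope=slope, offset=offset, r2=r2,
        rmsec=float(np.sqrt(np.mean((yc - y) ** 2))),
        rmsecv=float(np.sqrt(np.mean((yv - y) ** 2))),
        n_factors=n_factors,
        cv_slope=cv_slope, cv_offset=cv_offset, cv_r2=cv_r2,
    )


def run_calibration_suite(sset: SpectrumSet, design: BlendDesign, a: int = 4,
                          cfg: PreprocessConfig | None = None) -> pd.DataFrame:
    """One PLSR model per (rapeseed brand x camellia brand) ladder.

    Each ladder consists of the pure base oil (0 % v/v) plus the design's
    blend levels for that brand pair; spectra are preprocessed with ``cfg``
    (default: smoothing + first derivative, cropped to 1800-650 cm^-1)
    before fitting ``a`` factors and running leave-one-out validation.
    """
    if cfg is None:
        cfg = PreprocessConfig(derivative_order=1)
    prepped = preprocess_set(sset, cfg)
    rows = []
    for rso_brand in design.rso_brands:
        for cao_brand in design.cao_brands:
            def in_ladder(m, rb=rso_brand, cb=cao_brand):
                if m.blend_fraction_v == 0:
                    return m.oil_type == "CAO" and m.base_brand == cb
                return (m.oil_type == "BLEND" and m.base_brand == cb
                        and m.adulterant_brand == rb)

            ladder = prepped.subset(in_ladder)
            expected = len(design.levels) + 1
            got_levels = sorted({s.meta.blend_fraction_v for s in ladder})
            if len(got_levels) != expected:
                raise ValueError(
                    f"incomplete ladder for ({rso_brand}, {cao_brand}): found levels {got_levels},"
                    f" expected 0 plus {sorted(design.levels)}"
                )
            X = ladder.to_matrix()
            y = np.array([s.meta.blend_fraction_v for s in ladder], dtype=np.float64)
            model = plsr_fit(X, y, a)
            y_cal = plsr_predict(model, X)
            y_cv = loo_cv(X, y, a)
            m = figures_of_merit(y, y_cal, y_cv, n_factors=a)
            rows.append({
                "rso_brand": rso_brand, "cao_brand": cao_brand, "n_factors": a,
                "slope": m.slope, "offset": m.offset, "rmsec": m.rmsec, "r2": m.r2,
                "cv_slope": m.cv_slope, "cv_offset": m.cv_offset,
                "rmsecv": m.rmsecv, "cv_r2": m.cv_r2,
                "out_of_range": bool(((y_cal < 0) | (y_cal > 100) | (y_cv < 0) | (y_cv > 100)).any()),
            })
    return pd.DataFrame(rows)
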