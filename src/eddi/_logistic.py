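"""Minimal unpenalized single-feature logistic regression.

The pairwise screen performs on the order of 10^5–10^6 logistic fits
(one per pair x boundary iteration x CV fold), each with one predictor
and a few hundred observations. A damped Newton–Raphson solver on the
two-parameter model is exact for this case and orders of magnitude
faster than a general-purpose estimator. Only predicted probabilities
feed the Brier score, so perfect separation is handled by capping the
linear predictor: coefficients stop growing once probabilities
saturate, which leaves the Brier value unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

ETA_CAP = 30.0  # |linear predictor| cap; expit(30) == 1 to double precision


def fit_logistic_1d(
    x: np.ndarray,
    y: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Fit P(y=1|x) = expit(b0 + b1*x) by Newton-Raphson; returns (b0, b1).

    Degenerate inputs (constant x, or single-class y) collapse to the
    intercept-only fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0 or np.ptp(x) == 0.0:
        b0 = ETA_CAP if ybar >= 1.0 else (-ETA_CAP if ybar <= 0.0 else np.log(ybar / (1 - ybar)))
        return float(b0), 0.0

    b0 = float(np.log(ybar / (1.0 - ybar)))
    b1 = 0.0
    for _ in range(max_iter):
        eta = np.clip(b0 + b1 * x, -ETA_CAP, ETA_CAP)
        p = expit(eta)
        w = np.maximum(p * (1.0 - p), 1e-12)
        r = y - p
        g0, g1 = r.sum(), (r * x).sum()
        h00 = w.sum()
        h01 = (w * x).sum()
        h11 = (w * x * x).sum()
        det = h00 * h11 - h01 * h01
        if det <= 1e-300:
            break
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        # damp oversized steps (perfect or quasi-separation)
        scale = max(abs(d0), abs(d1))
        if scale > 10.0:
            d0, d1 = d0 * 10.0 / scale, d1 * 10.0 / scale
        b0 += d0
        b1 += d1
        if max(abs(d0), abs(d1)) < tol:
            break
    return float(b0), float(b1)


def predict_proba_1d(b0: float, b1: float, x: np.ndarray) -> np.ndarray:
    """Predicted P(y=1|x) with the capped linear predictor."""
    return expit(np.clip(b0 + b1 * np.asarray(x, dtype=float), -ETA_CAP, ETA_CAP))


def fit_logistic_folds(
    x: np.ndarray,
    y: np.ndarray,
    train_mask: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one 1-D logistic model per row of ``train_mask``, vectorized.

    Semantically one :func:`fit_logistic_1d` per row (same Newton
    update, damping and caps), but all rows advance together as array
    operations; each row is one (training subset, label vector)
    problem. ``y`` may be a single label vector or one row per
    problem. Rows whose training cells are single-class or constant-x
    collapse to the intercept-only fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    M = train_mask.astype(float)
    if y.ndim == 1:
        y = np.broadcast_to(y, M.shape)
    n_train = M.sum(axis=1)
    ybar = (M * y).sum(axis=1) / n_train
    xmin = np.where(train_mask, x, np.inf).min(axis=1)
    xmax = np.where(train_mask, x, -np.inf).max(axis=1)
    degenerate = (ybar <= 0.0) | (ybar >= 1.0) | (xmax - xmin == 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        b0 = np.where(
            ybar <= 0.0,
            -ETA_CAP,
            np.where(ybar >= 1.0, ETA_CAP, np.log(ybar / (1.0 - ybar))),
        )
    b1 = np.zeros_like(b0)
    active = np.flatnonzero(~degenerate)
    xs = x[None, :]
    for _ in range(max_iter):
        if active.size == 0:
            break
        eta = np.clip(b0[active, None] + b1[active, None] * xs, -ETA_CAP, ETA_CAP)
        p = expit(eta)
        Ma = M[active]
        w = np.maximum(p * (1.0 - p), 1e-12) * Ma
        r = (y[active] - p) * Ma
        g0, g1 = r.sum(axis=1), (r * x).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * x).sum(axis=1)
        h11 = (w * x * x).sum(axis=1)
        det = h00 * h11 - h01 * h01
        ok = det > 1e-300
        safe_det = np.where(ok, det, 1.0)
        d0 = np.where(ok, (h11 * g0 - h01 * g1) / safe_det, 0.0)
        d1 = np.where(ok, (h00 * g1 - h01 * g0) / safe_det, 0.0)
        scale = np.maximum(np.abs(d0), np.abs(d1))
        damp = np.where(scale > 10.0, 10.0 / np.maximum(scale, 1e-300), 1.0)
        b0[active] += d0 * damp
        b1[active] += d1 * damp
        # a row is done when its step shrank below tol or (under perfect
        # separation) its training residuals have saturated to zero
        grad_flat = (np.abs(g0) < 1e-9 * n_train[active]) & (
            np.abs(g1) < 1e-9 * n_train[active] * (1.0 + np.abs(x).max())
        )
        keep = ok & (scale * damp >= tol) & ~grad_flat
        active = active[keep]
    return b0, b1
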