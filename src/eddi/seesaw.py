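"""Stage 4 — relaxed-lasso regression within dependent cells (SEESAW).

Some predictors do not merely separate dependent from non-dependent
lines: their expression scales *linearly* with the dependency score
inside the dependent set. To find them, the dependency scores of the
dependent cells are regressed on the z-scored expression of the
screened predictors with a relaxed lasso: along the lasso path
lambda_1 > lambda_2 > ..., the relaxed coefficients blend the
penalized fit with the unpenalized (OLS) refit on the same active set,

    beta(gamma, lambda) = gamma * beta_lasso(lambda)
                          + (1 - gamma) * beta_OLS(active(lambda)),

so gamma = 1 is the plain lasso and gamma = 0 the debiased refit. The
pair (gamma, lambda) is chosen by leave-one-out cross-validation
(exact refitting — dependent sets are small, so n full refits are
cheap). Predictors active at the optimum earn the SEESAW label: a
negative coefficient means expression rises as the score falls, i.e.
rises with *stronger* dependency (SEE); a positive coefficient is the
mirror SAW direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lasso_path
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "zscore_features",
    "RelaxedLassoCV",
    "SeesawModel",
    "fit_relaxed_lasso",
    "seesaw_labels",
]

DEFAULT_GAMMA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def zscore_features(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise z-score (sample sd, ddof=1); zero-variance columns dropped.

    Returns the transformed frame plus the means and sds of the
    retained columns. Raises if nothing is left.
    """
    if features.shape[0] < 2:
        raise ValueError("need at least 2 rows to z-score")
    means = features.mean(axis=0)
    sds = features.std(axis=0, ddof=1)
    # relative tolerance: a column constant up to rounding has sd ~ eps*|mean|
    keep = sds > 1e-12 * np.maximum(1.0, means.abs())
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    if (~keep).any():
        warnings.warn(
            f"dropping zero-variance columns: {list(features.columns[~keep])[:5]}"
        )
    z = (features.loc[:, keep] - means[keep]) / sds[keep]
    return z, means[keep], sds[keep]


def _ols_on_active(Xc: np.ndarray, yc: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Least-squares refit restricted to the active columns (centred data)."""
    beta = np.zeros(Xc.shape[1])
    if active.size:
        beta[active], *_ = np.linalg.lstsq(Xc[:, active], yc, rcond=None)
    return beta


class RelaxedLassoCV(BaseEstimator, RegressorMixin):
    """Relaxed lasso with (gamma, lambda) chosen by leave-one-out CV.

    Parameters
    ----------
    gamma_grid : sequence of float in [0, 1]
        Relaxation weights; 1 = plain lasso, 0 = OLS refit on the
        active set.
    n_lambdas : int
        Length of the log-spaced penalty path, from the smallest
        all-zero penalty down by a factor ``lambda_min_ratio``.
    lambda_min_ratio : float
        Ratio of the smallest to the largest penalty on the path.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_, intercept_ : selected relaxed coefficients and intercept.
    lambda_, gamma_ : selected hyper-parameters.
    active_ : indices of predictors with nonzero coefficients.
    loocv_rmse_, r_squared_ : leave-one-out RMSE and R^2 (1 - PRESS/TSS).
    train_r_squared_ : in-sample R^2 of the selected model.
    """

    def __init__(
        self,
        gamma_grid=DEFAULT_GAMMA_GRID,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-3,
    ):
        self.gamma_grid = gamma_grid
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio

    def _path(self, X, y, alphas=None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny-alpha convergence chatter
            alphas_out, coefs, _ = lasso_path(
                X,
                y,
                alphas=alphas,
                n_alphas=self.n_lambdas,
                eps=self.lambda_min_ratio,
                tol=1e-10,
            )
        return alphas_out, coefs

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 observations")
        gammas = np.asarray(self.gamma_grid, dtype=float)

        x_mean, y_mean = X.mean(axis=0), y.mean()
        Xc, yc = X - x_mean, y - y_mean
        alphas, coefs = self._path(Xc, yc)
        n_lam = alphas.size

        # exact leave-one-out: refit the path (at the full-data lambda
        # grid) n times and score every (lambda, gamma) cell
        press = np.zeros((n_lam, gammas.size))
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            Xi, yi = X[keep], y[keep]
            xm, ym = Xi.mean(axis=0), yi.mean()
            _, coefs_i = self._path(Xi - xm, yi - ym, alphas=alphas)
            for j in range(n_lam):
                b_lasso = coefs_i[:, j]
                active = np.flatnonzero(b_lasso)
                b_ols = _ols_on_active(Xi - xm, yi - ym, active)
                for g, gamma in enumerate(gammas):
                    beta = gamma * b_lasso + (1.0 - gamma) * b_ols
                    pred = ym + (X[i] - xm) @ beta
                    press[j, g] += (y[i] - pred) ** 2

        # scan lambdas largest-first so ties resolve to the sparser model
        j_best, g_best = np.unravel_index(np.argmin(press), press.shape)
        self.lambda_ = float(alphas[j_best])
        self.gamma_ = float(gammas[g_best])

        b_lasso = coefs[:, j_best]
        active = np.flatnonzero(b_lasso)
        b_ols = _ols_on_active(Xc, yc, active)
        beta = self.gamma_ * b_lasso + (1.0 - self.gamma_) * b_ols
        self.coef_ = beta
        self.intercept_ = float(y_mean - x_mean @ beta)
        self.active_ = np.flatnonzero(beta)
        tss = float(((y - y_mean) ** 2).sum())
        self.loocv_rmse_ = float(np.sqrt(press[j_best, g_best] / n))
        self.r_squared_ = float(1.0 - press[j_best, g_best] / tss) if tss > 0 else np.nan
        resid = y - self.predict(X)
        self.train_r_squared_ = (
            float(1.0 - (resid**2).sum() / tss) if tss > 0 else np.nan
        )
        self.alphas_ = alphas
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def relaxed_coefficients(self, lambda_index: int, gamma: float, X, y):
        """Relaxed coefficients at one path point (diagnostic helper)."""
        check_is_fitted(self, "alphas_")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        _, coefs = self._path(Xc, yc, alphas=self.alphas_)
        b_lasso = coefs[:, lambda_index]
        b_ols = _ols_on_active(Xc, yc, np.flatnonzero(b_lasso))
        return gamma * b_lasso + (1.0 - gamma) * b_ols


@dataclass(frozen=True)
class SeesawModel:
    """Selected relaxed-lasso model for one dependency."""

    dependency_id: str
    lambda_: float
    gamma: float
    coefficients: pd.Series = field(repr=False)  # z-scored feature scale
    intercept: float = 0.0
    loocv_rmse: float = np.nan
    r_squared: float = np.nan  # LOOCV R^2, the primary metric
    train_r_squared: float = np.nan

    @property
    def active_set(self) -> list[str]:
        return list(self.coefficients.index[self.coefficients != 0.0])


def fit_relaxed_lasso(
    features: pd.DataFrame,
    response: np.ndarray,
    gamma_grid=DEFAULT_GAMMA_GRID,
    dependency_id: str = "",
    n_lambdas: int = 100,
) -> SeesawModel:
    """Z-score the dependent-cell features and fit :class:`RelaxedLassoCV`.

    ``features`` holds the screened predictors over dependent cells
    only; ``response`` their dependency scores.
    """
    z, _, _ = zscore_features(features)
    est = RelaxedLassoCV(gamma_grid=gamma_grid, n_lambdas=n_lambdas)
    est.fit(z.to_numpy(), np.asarray(response, dtype=float))
    return SeesawModel(
        dependency_id=dependency_id,
        lambda_=est.lambda_,
        gamma=est.gamma_,
        coefficients=pd.Series(est.coef_, index=z.columns, name="coefficient"),
        intercept=est.intercept_,
        loocv_rmse=est.loocv_rmse_,
        r_squared=est.r_squared_,
        train_r_squared=est.train_r_squared_,
    )


def seesaw_labels(model: SeesawModel) -> list[tuple[str, str]]:
    """Direction labels for the active set.

    Scores get *more negative* with stronger dependency, so a negative
    coefficient (expression up => score down) is the SEE direction
    (expression rises with stronger dependency) and a positive one SAW.
    """
    out = []
    for predictor, coef in model.coefficients.items():
        if coef != 0.0:
            out.append((predictor, "SEE" if coef < 0 else "SAW"))
    return out
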