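"""Variance-components heritability and per-SNP variance contributions.

:class:`PolygenicModel` fits the polygenic mixed model

    y = X beta + g + eps,   cov(g) = 2 * Phi * sigma2_g,   eps ~ N(0, sigma2_e I)

by restricted maximum likelihood, profiled over the heritability ratio
h2 = sigma2_g / (sigma2_g + sigma2_e). After projecting onto the
eigenbasis of 2*Phi the covariance is diagonal for every h2, so the
restricted likelihood is a cheap one-dimensional function of h2 which is
maximized by a grid scan plus bounded refinement. The total variance is
profiled in closed form. This is the classic eigen-rotation approach to
animal-model REML; boundary estimates (h2 of 0 or 1) are flagged, not
errors.

:func:`snp_b2` is the companion single-SNP estimator: the squared slope of
standardized residuals (response adjusted for covariates) on standardized
dosage — algebraically the squared Pearson correlation — approximating the
additive variance fraction attributable to one SNP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

_H2_EPS = 1e-9


def profiled_reml(yt, Xt, lam, grid_points: int = 26, xtol: float = 1e-8) -> dict:
    """One-ratio REML on eigen-rotated data.

    Fits cov(y) = sigma2_p * (h * diag(lam) + (1-h) * I) for rotated response
    ``yt`` and design ``Xt``, profiling the total variance in closed form and
    maximizing the restricted likelihood over the ratio h in [0, 1] by a grid
    scan plus bounded refinement. Shared by the kinship polygenic model and
    the family random-intercept mixed model (where lam are the eigenvalues of
    the family incidence Gram matrix Z Z').
    """
    yt = np.asarray(yt, float)
    Xt = np.asarray(Xt, float)
    lam = np.asarray(lam, float)
    n, p = Xt.shape

    def neg_restricted_ll(h: float) -> float:
        w = np.maximum(h * lam + (1.0 - h), 1e-12)
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        sigma2 = float(np.sum(r * r / w)) / (n - p)
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        return 0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(w)) + logdet_xwx + (n - p))

    grid = np.linspace(0.0, 1.0 - _H2_EPS, grid_points)
    vals = np.array([neg_restricted_ll(h) for h in grid])
    k = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": xtol},
    )
    h2 = float(res.x) if res.fun <= vals[k] else float(grid[k])
    h2 = min(max(h2, 0.0), 1.0)

    w = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma2_p = float(np.sum(r * r / w)) / (n - p)
    return {
        "h2": h2,
        "sigma2_p": sigma2_p,
        "beta": beta,
        "beta_se": np.sqrt(np.diag(sigma2_p * np.linalg.inv(XtWX))),
        "loglik": -neg_restricted_ll(min(h2, 1.0 - _H2_EPS)),
        "converged": bool(getattr(res, "success", True)),
    }


class PolygenicModel(BaseEstimator):
    """REML estimator of narrow-sense heritability under a kinship covariance.

    Parameters
    ----------
    grid_points : int, default 26
        Coarse grid over h2 in [0, 1) scanned before bounded refinement
        (guards against local optima of the profiled restricted likelihood).
    xtol : float, default 1e-8
        Absolute tolerance on h2 in the refinement step.

    Fitted attributes: ``h2_``, ``sigma2_g_``, ``sigma2_e_``,
    ``loglik_reml_``, ``beta_``, ``beta_se_``, ``converged_``, ``boundary_``.
    """

    def __init__(self, grid_points: int = 26, xtol: float = 1e-8):
        self.grid_points = grid_points
        self.xtol = xtol

    def fit(self, y, X, kinship):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        A = 2.0 * (kinship.to_numpy(float) if hasattr(kinship, "to_numpy") else np.asarray(kinship, float))
        n, p = X.shape
        if n < p + 2:
            raise ValueError("too few observations for the polygenic model")
        lam, U = np.linalg.eigh(A)
        if lam.min() < -1e-8 * max(1.0, lam.max()):
            raise ValueError("kinship matrix is not positive semi-definite")
        lam = np.clip(lam, 0.0, None)
        fit = profiled_reml(U.T @ y, U.T @ X, lam, self.grid_points, self.xtol)

        self.h2_ = fit["h2"]
        self.sigma2_g_ = fit["h2"] * fit["sigma2_p"]
        self.sigma2_e_ = (1.0 - fit["h2"]) * fit["sigma2_p"]
        self.loglik_reml_ = fit["loglik"]
        self.beta_ = fit["beta"]
        self.beta_se_ = fit["beta_se"]
        self.converged_ = fit["converged"]
        self.boundary_ = fit["h2"] <= 1e-6 or fit["h2"] >= 1 - 1e-6
        return self

    @staticmethod
    def restricted_loglik(h2: float, y, X, kinship) -> float:
        """Restricted log-likelihood (up to an additive constant) at a given
        h2; exposed for grid-search cross-checks."""
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        A = 2.0 * (kinship.to_numpy(float) if hasattr(kinship, "to_numpy") else np.asarray(kinship, float))
        lam, U = np.linalg.eigh(A)
        lam = np.clip(lam, 0.0, None)
        yt, Xt = U.T @ y, U.T @ X
        n, p = X.shape
        w = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        sigma2 = float(np.sum(r * r / w)) / (n - p)
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        return -0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(w)) + logdet_xwx + (n - p))


def polygenic_h2(response, covariates, kinship) -> PolygenicModel:
    """REML heritability of ``response`` adjusted for ``covariates``.

    ``covariates`` may be a DataFrame/array without an intercept column; one
    is added. Returns the fitted :class:`PolygenicModel`.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = np.column_stack([np.ones(len(X)), X])
    return PolygenicModel().fit(np.asarray(response, float), X, kinship)


def snp_b2(response, covariates, dosage) -> float:
    """Squared standardized regression coefficient of one SNP.

    Residualizes the response on the covariates (plus intercept), z-scores
    residuals and dosage (n-1 denominator), and returns the squared slope —
    identically the squared Pearson correlation. Monomorphic SNPs give NaN
    (not applicable).
    """
    y = np.asarray(response, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if np.ptp(d) == 0:
        return float("nan")
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = np.column_stack([np.ones(len(y)), X])
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    rz = (resid - resid.mean()) / resid.std(ddof=1)
    dz = (d - d.mean()) / d.std(ddof=1)
    slope = float(np.sum(rz * dz) / (len(y) - 1))
    return slope**2


def summarize_estimates(values: pd.DataFrame) -> pd.DataFrame:
    """Mean/median/SD per column across replicates (heritability-table style)."""
    return pd.DataFrame(
        {"mean": values.mean(), "median": values.median(), "sd": values.std(ddof=1)}
    )
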