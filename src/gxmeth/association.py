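"""Per-pair interaction tests in family data.

Two inferential routes are provided for each SNP-CpG pair and model:

* :class:`FamilyOLS` (Method I style): least squares with the family id
  entered as a categorical term, absorbing family means; the interaction
  p-value is the two-sided t-test on the interaction coefficient with
  residual degrees of freedom. A family-clustered sandwich covariance is
  available as a non-default variant (:func:`sandwich_se`).
* :class:`FamilyMixedLM` (Method II style): a linear mixed model with a
  random intercept per family estimated by REML; the interaction p-value is
  the Wald test on the interaction coefficient. A kinship-covariance variant
  (random effect with covariance 2*Phi*sigma2_g) is available through
  ``covariance="kinship"``.

Monomorphic SNPs and constant methylation columns make the interaction test
undefined; such fits are returned flagged ``applicable=False`` rather than
with a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm

from .exceptions import SingularDesignError
from .trait_models import DesignMatrix


@dataclass
class FitResult:
    """Outcome of one interaction-model fit."""

    method: str  # "GLM" or "MIXED"
    model_id: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    interaction_column: str
    df_resid: float | None
    converged: bool
    applicable: bool = True
    reason: str | None = None
    vc: dict = field(default_factory=dict)  # mixed only: variance components

    @property
    def p_interaction(self) -> float:
        if not (self.applicable and self.converged):
            return np.nan
        return float(self.pvalues[self.interaction_column])

    @property
    def beta_interaction(self) -> float:
        if not self.applicable:
            return np.nan
        return float(self.params[self.interaction_column])


def _degenerate_columns(X: pd.DataFrame) -> list[str]:
    return [c for c in X.columns if c != "intercept" and np.ptp(X[c].to_numpy(float)) == 0]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of columns implicated in the collinearity
        bad = []
        for j, name in enumerate(names):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise SingularDesignError(bad or names)


def _not_applicable(method: str, design: DesignMatrix, reason: str) -> FitResult:
    empty = pd.Series(dtype=float)
    return FitResult(
        method=method,
        model_id=design.model_id,
        params=empty,
        bse=empty,
        pvalues=empty,
        interaction_column=design.interaction_column,
        df_resid=None,
        converged=False,
        applicable=False,
        reason=reason,
    )


class FamilyOLS(BaseEstimator):
    """Least-squares interaction fit with family entered as a fixed categorical term.

    Parameters
    ----------
    absorb_family : bool, default True
        Add one indicator column per family (first family as reference).
    cov_type : {"nonrobust", "cluster"}, default "nonrobust"
        "cluster" replaces model-based standard errors with family-clustered
        sandwich estimates (non-default; known to misbehave for rare alleles).
    """

    def __init__(self, absorb_family: bool = True, cov_type: str = "nonrobust"):
        self.absorb_family = absorb_family
        self.cov_type = cov_type

    def fit(self, design: DesignMatrix, response: pd.Series | None = None, groups=None):
        y = design.response if response is None else response
        degenerate = _degenerate_columns(design.X)
        if degenerate:
            self.result_ = _not_applicable("GLM", design, f"constant columns: {degenerate}")
            return self

        X = design.X.copy()
        names = list(X.columns)
        if self.absorb_family:
            if groups is None:
                raise ValueError("groups (family ids) required when absorb_family=True")
            groups = np.asarray(groups)
            dummies = pd.get_dummies(pd.Series(groups, index=X.index), prefix="fam", drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
        if self.cov_type == "cluster":
            if groups is None or len(np.unique(groups)) < 2:
                raise ValueError("cluster-robust covariance requires at least two families")

        arr = X.to_numpy(float)
        _check_full_rank(arr[:, : len(names)], names)
        model = sm.OLS(np.asarray(y, float), arr)
        if self.cov_type == "cluster":
            res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
        else:
            res = model.fit()
        params = pd.Series(res.params[: len(names)], index=names)
        bse = pd.Series(res.bse[: len(names)], index=names)
        df = float(res.df_resid)
        tvals = params / bse
        pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), df), index=names)
        self.results_ = res
        self.result_ = FitResult(
            method="GLM",
            model_id=design.model_id,
            params=params,
            bse=bse,
            pvalues=pvals,
            interaction_column=design.interaction_column,
            df_resid=df,
            converged=True,
        )
        return self


_rotation_cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


def _family_rotation(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the family incidence Gram matrix A = Z Z'.

    A is block-diagonal with ones-blocks: each family of size m contributes
    one eigenvalue m (eigenvector 1/sqrt(m)) and m-1 zero eigenvalues with a
    Helmert orthonormal complement. Cached per distinct grouping.
    """
    key = np.asarray(groups).astype("U").tobytes()
    if key not in _rotation_cache:
        from scipy.linalg import helmert

        groups = np.asarray(groups)
        n = len(groups)
        U = np.zeros((n, n))
        lam = np.zeros(n)
        col = 0
        for g in pd.unique(groups):
            idx = np.flatnonzero(groups == g)
            m = len(idx)
            U[idx, col] = 1.0 / np.sqrt(m)
            lam[col] = m
            col += 1
            if m > 1:
                U[np.ix_(idx, np.arange(col, col + m - 1))] = helmert(m).T
                col += m - 1
        _rotation_cache[key] = (lam, U)
    return _rotation_cache[key]


class FamilyMixedLM(BaseEstimator):
    """Family random-intercept linear mixed model, estimated by REML.

    With ``covariance="family"`` the random effect is an i.i.d. intercept per
    family: cov(y) = sigma2_family * Z Z' + sigma2_e * I for the family
    incidence matrix Z. Because Z Z' has a closed-form eigenbasis the
    restricted likelihood profiles to a one-dimensional function of the
    variance ratio, maximized by the same machinery as the kinship polygenic
    model (grid scan + bounded refinement; see ``heritability.profiled_reml``).
    With ``covariance="kinship"`` the random effect instead has covariance
    ``2 * Phi * sigma2_g`` for a supplied kinship matrix Phi. Inference on
    coefficients uses the Wald z statistic by default; ``use_t=True``
    switches to a t reference with residual degrees of freedom.
    """

    def __init__(self, covariance: str = "family", use_t: bool = False):
        self.covariance = covariance
        self.use_t = use_t

    def fit(self, design: DesignMatrix, response: pd.Series | None = None, groups=None, kinship=None):
        y = np.asarray(design.response if response is None else response, float)
        degenerate = _degenerate_columns(design.X)
        if degenerate:
            self.result_ = _not_applicable("MIXED", design, f"constant columns: {degenerate}")
            return self
        names = list(design.X.columns)
        X = design.X.to_numpy(float)
        _check_full_rank(X, names)

        if self.covariance == "kinship":
            if kinship is None:
                raise ValueError("kinship matrix required for covariance='kinship'")
            return self._fit_kinship(design, y, X, names, kinship)

        if groups is None:
            raise ValueError("groups (family ids) required for the family random intercept")
        groups = np.asarray(groups)
        if len(np.unique(groups)) < 2:
            raise ValueError("mixed model requires at least two families")

        from .heritability import profiled_reml

        lam, U = _family_rotation(groups)
        fit = profiled_reml(U.T @ y, U.T @ X, lam)
        converged = fit["converged"]
        params = pd.Series(fit["beta"], index=names)
        bse = pd.Series(fit["beta_se"], index=names)
        if converged:
            z = params / bse
            if self.use_t:
                df = len(y) - len(names)
                pvals = pd.Series(2 * stats.t.sf(np.abs(z), df), index=names)
            else:
                pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
        else:
            pvals = pd.Series(np.nan, index=names)
        self.result_ = FitResult(
            method="MIXED",
            model_id=design.model_id,
            params=params,
            bse=bse,
            pvalues=pvals,
            interaction_column=design.interaction_column,
            df_resid=float(len(y) - len(names)),
            converged=converged,
            vc={
                "family": fit["h2"] * fit["sigma2_p"],
                "residual": (1.0 - fit["h2"]) * fit["sigma2_p"],
            },
        )
        return self

    def _fit_kinship(self, design, y, X, names, kinship):
        from .heritability import PolygenicModel

        pm = PolygenicModel().fit(y, X, kinship)
        params = pd.Series(pm.beta_, index=names)
        bse = pd.Series(pm.beta_se_, index=names)
        z = params / bse
        pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
        self.result_ = FitResult(
            method="MIXED",
            model_id=design.model_id,
            params=params,
            bse=bse,
            pvalues=pvals,
            interaction_column=design.interaction_column,
            df_resid=float(len(y) - len(names)),
            converged=pm.converged_,
            vc={"genetic": pm.sigma2_g_, "residual": pm.sigma2_e_},
        )
        return self


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_glm(design: DesignMatrix, response=None, families=None) -> FitResult:
    """Method I: least squares with a categorical family term."""
    return FamilyOLS(absorb_family=families is not None).fit(design, response, groups=families).result_


def fit_mixed(design: DesignMatrix, response=None, families=None, kinship=None) -> FitResult:
    """Method II: REML mixed model with a family random intercept
    (or a kinship-structured random effect when ``kinship`` is given)."""
    cov = "kinship" if kinship is not None else "family"
    return FamilyMixedLM(covariance=cov).fit(design, response, groups=families, kinship=kinship).result_


def sandwich_se(design: DesignMatrix, response=None, families=None) -> FitResult:
    """Non-default variant: family-clustered sandwich standard errors.

    Refits the least-squares model and replaces model-based standard errors
    with cluster-robust ones, recomputing the interaction p-value. Known to
    inflate Type-I error for rare alleles; kept for diagnostic comparison.
    """
    est = FamilyOLS(absorb_family=False, cov_type="cluster").fit(design, response, groups=families)
    res = est.result_
    if res.applicable:
        res.reason = "cluster-robust (sandwich) covariance; non-default"
    return res


# ---------------------------------------------------------------------------
# Batch runner
# ---------------------------------------------------------------------------


def run_pair_tests(
    traits,
    covariates: pd.DataFrame,
    genotypes,
    methylation,
    pairs,
    models=("1a",),
    methods=("glm", "mixed"),
    families=None,
) -> pd.DataFrame:
    """Fit a grid of (pair x model x method) interaction tests.

    ``pairs`` is an iterable of ``(snp_id, cpg_id, category)``. Returns a
    tidy table with one row per test: category, snp, cpg, model, method,
    beta3, se, p, converged, applicable.
    """
    from .trait_models import build_design

    rows = []
    for snp_id, cpg_id, category in pairs:
        snp = genotypes.dosages[snp_id]
        for model_id in models:
            if model_id in ("1a", "1b"):
                cpg_vals = methylation.beta_visit4[cpg_id]
            else:
                cpg_vals = traits.delta_cpg[cpg_id]
            design = build_design(model_id, snp, cpg_vals, traits, covariates)
            for method in methods:
                fit = (
                    fit_glm(design, families=families)
                    if method == "glm"
                    else fit_mixed(design, families=families)
                )
                se = (
                    float(fit.bse[fit.interaction_column])
                    if fit.applicable and fit.converged
                    else np.nan
                )
                rows.append(
                    {
                        "category": category,
                        "snp": snp_id,
                        "cpg": cpg_id,
                        "model": model_id,
                        "method": method,
                        "beta3": fit.beta_interaction,
                        "se": se,
                        "p": fit.p_interaction,
                        "converged": fit.converged,
                        "applicable": fit.applicable,
                    }
                )
    return pd.DataFrame(rows)
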