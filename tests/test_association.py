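"""Interaction-test inference: least squares with family term, REML mixed model,
sandwich variant, and their degenerate/oracle behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gxmeth as gx
from gxmeth.association import FamilyMixedLM, fit_glm, fit_mixed, sandwich_se
from gxmeth.exceptions import SingularDesignError
from gxmeth.heritability import PolygenicModel
from gxmeth.trait_models import DerivedTraits, build_design


def _iid_design(n, seed, beta3=0.0, maf=0.3, model_id="1a", family_size=None, family_sigma=0.0):
    """Small synthetic dataset wrapped into a DesignMatrix (+ family labels)."""
    rng = np.random.default_rng(seed)
    idx = pd.RangeIndex(n)
    snp = rng.binomial(2, maf, n).astype(float)
    cpg = rng.beta(6, 4, n)
    age = rng.uniform(20, 70, n)
    sex = rng.integers(1, 3, n)
    pre = rng.normal(4.7, 0.5, n)
    if family_size:
        fams = np.repeat(np.arange(int(np.ceil(n / family_size))), family_size)[:n]
    else:
        fams = np.arange(n) // 2  # couples: smallest valid clustering
    fam_eff = family_sigma * rng.standard_normal(fams.max() + 1)
    y = beta3 * snp * (1 - cpg) + fam_eff[fams] + rng.standard_normal(n)
    traits = DerivedTraits(
        pre=pd.Series(pre, index=idx),
        post=pd.Series(y, index=idx),
        delta_tg=pd.Series(y - pre, index=idx),
        delta_cpg=pd.DataFrame(index=idx),
    )
    covs = pd.DataFrame({"age": age, "sex": sex}, index=idx)
    return build_design(model_id, snp, cpg, traits, covs), fams.astype(str)


def test_noiseless_interaction_gives_vanishing_pvalue():
    design, fams = _iid_design(200, seed=1)
    design.response = design.X["snp_x_one_minus_cpg"].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = fit_glm(design, families=fams)
    assert fit.p_interaction < 1e-12


def test_null_glm_pvalues_are_uniform():
    ps = []
    for s in range(600):
        design, fams = _iid_design(120, seed=10_000 + s)
        ps.append(fit_glm(design, families=fams).p_interaction)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_least_squares_recovers_interaction_coefficient():
    design, fams = _iid_design(5000, seed=3, beta3=0.5)
    fit = fit_glm(design, families=fams)
    b, se = fit.beta_interaction, fit.bse[fit.interaction_column]
    assert abs(b - 0.5) < 3 * se


def test_mixed_matches_ols_when_family_variance_is_zero():
    # seed chosen to land the REML family variance on its zero boundary
    for seed in range(5):
        design, fams = _iid_design(240, seed=200 + seed, family_size=4)
        mixed = fit_mixed(design, families=fams)
        if mixed.vc["family"] < 1e-10:
            break
    else:
        pytest.fail("no boundary dataset found in 5 seeds")
    ols = fit_glm(design)  # plain least squares, no family term
    np.testing.assert_allclose(mixed.params, ols.params, rtol=1e-6)


def test_mixed_reml_matches_grid_search_on_toy_families():
    design, fams = _iid_design(10, seed=7, model_id="2b", family_size=5, family_sigma=1.0)
    est = FamilyMixedLM().fit(design, groups=fams)
    res = est.result_
    h_hat = res.vc["family"] / (res.vc["family"] + res.vc["residual"])
    # oracle: dense grid over the restricted likelihood of the equivalent
    # one-ratio model (A = ZZ' supplied as "kinship" A/2)
    Z = pd.get_dummies(fams).to_numpy(float)
    A_half = (Z @ Z.T) / 2.0
    grid = np.arange(0, 1.0, 0.01)
    ll = [
        PolygenicModel.restricted_loglik(h, np.asarray(design.response), design.X.to_numpy(), A_half)
        for h in grid
    ]
    assert abs(h_hat - grid[int(np.argmax(ll))]) <= 0.01
    assert PolygenicModel.restricted_loglik(
        min(h_hat, 1 - 1e-9), np.asarray(design.response), design.X.to_numpy(), A_half
    ) >= max(ll) - 1e-8


def test_mixed_cross_checks_against_statsmodels(study, traits, covariates, replicate, families):
    import statsmodels.api as sm

    design = build_design(
        "1a",
        replicate.genotypes.dosages["snpC1"],
        replicate.methylation.beta_visit4["cgC1"],
        traits,
        covariates,
    )
    ours = fit_mixed(design, families=families)
    ref = sm.MixedLM(
        np.asarray(design.response), design.X.to_numpy(), groups=families
    ).fit(reml=True)
    np.testing.assert_allclose(ours.params, ref.fe_params, rtol=1e-4)
    np.testing.assert_allclose(ours.bse, ref.bse_fe, rtol=1e-3)
    assert ours.vc["family"] == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3)
    assert ours.vc["residual"] == pytest.approx(float(ref.scale), rel=1e-3)


def test_mixed_nominal_but_naive_ols_inflated_under_family_clustering():
    """Family-level regressors + family variance: ignoring the clustering
    inflates the interaction Type-I error; the mixed model stays nominal."""
    rng = np.random.default_rng(42)
    n_fam, fam_size = 50, 4
    n = n_fam * fam_size
    idx = pd.RangeIndex(n)
    naive_p, mixed_p = [], []
    for _ in range(300):
        fams = np.repeat(np.arange(n_fam), fam_size)
        snp = rng.binomial(2, 0.3, n_fam)[fams].astype(float)
        cpg = rng.beta(6, 4, n_fam)[fams]
        y = rng.standard_normal(n_fam)[fams] + rng.standard_normal(n)
        traits = DerivedTraits(
            pre=pd.Series(rng.normal(0, 0.5, n), index=idx),
            post=pd.Series(y, index=idx),
            delta_tg=pd.Series(y, index=idx),
            delta_cpg=pd.DataFrame(index=idx),
        )
        covs = pd.DataFrame({"age": rng.uniform(20, 70, n), "sex": rng.integers(1, 3, n)}, index=idx)
        design = build_design("1a", snp, cpg, traits, covs)
        naive_p.append(fit_glm(design).p_interaction)
        mixed_p.append(fit_mixed(design, families=fams.astype(str)).p_interaction)
    naive_t1 = np.mean(np.asarray(naive_p) < 0.05)
    mixed_t1 = np.mean(np.asarray(mixed_p) < 0.05)
    se = np.sqrt(0.05 * 0.95 / 300)
    assert abs(mixed_t1 - 0.05) < 3 * se
    assert naive_t1 > mixed_t1 + 3 * se


def test_reported_pvalues_reconstruct_from_wald_statistics(traits, covariates, replicate, families):
    design = build_design(
        "1a",
        replicate.genotypes.dosages["snpC2"],
        replicate.methylation.beta_visit4["cgC2"],
        traits,
        covariates,
    )
    glm = fit_glm(design, families=families)
    t = glm.params / glm.bse
    np.testing.assert_allclose(glm.pvalues, 2 * stats.t.sf(np.abs(t), glm.df_resid), rtol=1e-12)
    mixed = fit_mixed(design, families=families)
    z = mixed.params / mixed.bse
    np.testing.assert_allclose(mixed.pvalues, 2 * stats.norm.sf(np.abs(z)), rtol=1e-12)


def test_sandwich_close_to_model_se_for_balanced_homoskedastic_data():
    design, fams = _iid_design(4000, seed=5, family_size=2)
    model = fit_glm(design)
    robust = sandwich_se(design, families=fams)
    ratio = robust.bse[robust.interaction_column] / model.bse[model.interaction_column]
    assert 0.9 < ratio < 1.1


def test_sandwich_requires_multiple_families():
    design, _ = _iid_design(50, seed=6)
    with pytest.raises(ValueError, match="famil"):
        sandwich_se(design, families=np.zeros(50, dtype=int))


def test_monomorphic_snp_flagged_not_applicable(traits, covariates, replicate, families):
    snp = pd.Series(0.0, index=traits.post.index)
    design = build_design("1a", snp, replicate.methylation.beta_visit4["cgC1"], traits, covariates)
    for fit in (fit_glm(design, families=families), fit_mixed(design, families=families)):
        assert not fit.applicable
        assert np.isnan(fit.p_interaction)
        assert "constant" in fit.reason


def test_rank_deficient_design_names_collinear_columns(traits, covariates, replicate, families):
    design = build_design(
        "1a",
        replicate.genotypes.dosages["snpC1"],
        replicate.methylation.beta_visit4["cgC1"],
        traits,
        covariates,
    )
    design.X["age2"] = design.X["age"]  # force exact collinearity
    with pytest.raises(SingularDesignError) as err:
        fit_glm(design, families=families)
    assert {"age", "age2"} <= set(err.value.columns)
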