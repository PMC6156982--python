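"""Generator invariants: pedigree structure, kinship, Mendelian transmission,
methylation marginals and the phenotype variance budget."""

import numpy as np
import pandas as pd
import pytest

import gxmeth as gx
from gxmeth.exceptions import PedigreeError
from gxmeth.synthetic_data import FOUNDER, simulate_phenotypes

from conftest import founder_pedigree, make_effects, single_pair_maps


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


def test_default_pedigree_is_680_nuclear_individuals(study):
    ped = study.pedigree
    assert len(ped) == 680
    for fam, block in ped.groupby("family"):
        founders = block[block["father"] == FOUNDER]
        children = block[block["father"] != FOUNDER]
        assert len(founders) == 2 and set(founders["sex"]) == {1, 2}
        assert len(children) >= 1
        assert set(children["father"]) | set(children["mother"]) == set(founders["individual"])


def test_trio_pedigree_child_has_both_founders_as_parents():
    ped = gx.build_pedigrees(3, {3: 1.0}, seed=4)
    assert len(ped) == 3
    child = ped[ped["father"] != FOUNDER].iloc[0]
    founders = set(ped.loc[ped["father"] == FOUNDER, "individual"])
    assert {child["father"], child["mother"]} == founders


@pytest.mark.parametrize("n", [3, 7, 23, 680])
def test_pedigree_total_is_exact_and_deterministic(n):
    a = gx.build_pedigrees(n, seed=9)
    b = gx.build_pedigrees(n, seed=9)
    assert len(a) == n
    pd.testing.assert_frame_equal(a, b)


def test_pedigree_rejects_too_few_individuals():
    with pytest.raises(ValueError):
        gx.build_pedigrees(2)


def test_cyclic_pedigree_raises():
    rows = [
        ("f", "X", "Y", "Z", 1, 40.0),
        ("f", "Y", "X", "Z", 2, 40.0),
        ("f", "Z", "0", "0", 2, 70.0),
    ]
    ped = pd.DataFrame(rows, columns=["family", "individual", "father", "mother", "sex", "age"])
    with pytest.raises(PedigreeError):
        gx.kinship_matrix(ped)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def test_kinship_reference_relationships(toy_pedigree):
    K = gx.kinship_matrix(toy_pedigree)
    assert K.loc["A", "A"] == 0.5  # non-inbred self
    assert K.loc["A", "C"] == 0.25  # parent-offspring
    assert K.loc["C", "D"] == 0.25  # full siblings
    assert K.loc["A", "B"] == 0.0  # founders
    assert K.loc["A", "E"] == 0.0
    assert K.loc["A", "F"] == 0.125  # grandparent-grandchild
    assert K.loc["D", "F"] == 0.125  # avuncular
    assert K.loc["F", "G"] == 0.25
    np.testing.assert_allclose(K.to_numpy(), K.to_numpy().T)
    assert np.linalg.eigvalsh(2 * K.to_numpy()).min() > -1e-9  # 2*Phi PSD


def _gene_dropping_kinship(pedigree: pd.DataFrame, n_drops: int, seed: int) -> pd.DataFrame:
    """Monte-Carlo identity-by-descent oracle: drop unique founder alleles and
    estimate Phi(i,j) as the probability two randomly sampled alleles are IBD."""
    rng = np.random.default_rng(seed)
    ids = list(pedigree["individual"])
    par = {r["individual"]: (r["father"], r["mother"]) for _, r in pedigree.iterrows()}
    alleles = {}
    next_allele = 0
    order = ids  # conftest toy pedigree is already parent-first
    for ind in order:
        f, m = par[ind]
        if f == FOUNDER:
            a1 = np.full(n_drops, next_allele)
            a2 = np.full(n_drops, next_allele + 1)
            next_allele += 2
        else:
            pick1 = rng.integers(0, 2, n_drops)
            pick2 = rng.integers(0, 2, n_drops)
            a1 = np.where(pick1 == 0, alleles[f][0], alleles[f][1])
            a2 = np.where(pick2 == 0, alleles[m][0], alleles[m][1])
        alleles[ind] = (a1, a2)
    K = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            ai, bi = alleles[a], alleles[b]
            ibd = sum((ai[x] == bi[y]).mean() for x in range(2) for y in range(2)) / 4
            K[i, j] = ibd
    return pd.DataFrame(K, index=ids, columns=ids)


def test_kinship_matches_gene_dropping_monte_carlo(toy_pedigree):
    n_drops = 100_000
    K = gx.kinship_matrix(toy_pedigree)
    K_mc = _gene_dropping_kinship(toy_pedigree, n_drops, seed=77)
    phat = K_mc.to_numpy()
    se = np.sqrt(np.maximum(phat * (1 - phat), 1e-6) / n_drops)
    assert np.all(np.abs(K.to_numpy() - phat) <= 3 * se + 1e-12)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def test_offspring_dosages_mendelian_consistent(study, replicate):
    dos = replicate.genotypes.dosages
    ped = study.pedigree
    children = ped[ped["father"] != FOUNDER]
    for _, row in children.iterrows():
        c = dos.loc[row["individual"]].to_numpy()
        f = dos.loc[row["father"]].to_numpy()
        m = dos.loc[row["mother"]].to_numpy()
        lo = (f == 2).astype(int) + (m == 2).astype(int)
        hi = 2 - (f == 0).astype(int) - (m == 0).astype(int)
        assert np.all(c >= lo) and np.all(c <= hi)


def test_homozygous_parents_transmit_deterministically():
    ped = gx.build_pedigrees(4, {4: 1.0}, seed=0)
    snp_map = pd.DataFrame(
        {"chromosome": [1], "position": [10], "maf": [0.5], "role": ["null"]},
        index=pd.Index(["s"], name="snp"),
    )
    for _ in range(20):
        g = gx.simulate_genotypes(ped, snp_map, seed=np.random.randint(2**31))
        d = g.dosages["s"]
        parents = d.iloc[:2]
        if (parents == 0).all():
            assert (d.iloc[2:] == 0).all()
        if (parents == 2).all():
            assert (d.iloc[2:] == 2).all()


def test_founder_dosage_mean_matches_hardy_weinberg():
    n = 10_000
    ped = founder_pedigree(n)
    snp_map = pd.DataFrame(
        {"chromosome": [1], "position": [10], "maf": [0.3], "role": ["null"]},
        index=pd.Index(["s"], name="snp"),
    )
    g = gx.simulate_genotypes(ped, snp_map, seed=3)
    se = np.sqrt(2 * 0.3 * 0.7 / n)
    assert abs(g.dosages["s"].mean() - 0.6) < 3 * se


def test_invalid_maf_rejected(study):
    bad = study.snp_map.copy()
    bad.loc[bad.index[0], "maf"] = 0.7
    with pytest.raises(ValueError, match="MAF"):
        gx.simulate_genotypes(study.pedigree, bad, seed=0)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def test_methylation_visits_identical_when_rho_one_and_no_treatment(study):
    m = gx.simulate_methylation(study.pedigree, study.cpg_map, treatment_effect=0.0, seed=5, rho=1.0)
    pd.testing.assert_frame_equal(m.beta_visit2, m.beta_visit4)


def test_methylation_values_bounded(replicate):
    for mat in (replicate.methylation.beta_visit2, replicate.methylation.beta_visit4):
        v = mat.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0


def test_methylation_marginal_mean():
    n = 10_000
    ped = founder_pedigree(n)
    _, cpg_map = single_pair_maps(mean=0.6, concentration=10.0)
    cpg_map = cpg_map.assign(role="null")  # no treatment shift
    m = gx.simulate_methylation(ped, cpg_map, seed=8)
    sd = np.sqrt(0.6 * 0.4 / 11.0)
    assert abs(m.beta_visit2["c1"].mean() - 0.6) < 3 * sd / np.sqrt(n)


def test_methylation_invalid_mean_rejected(study):
    bad = study.cpg_map.copy()
    bad.loc[bad.index[0], "mean"] = 1.2
    with pytest.raises(ValueError, match="mean"):
        gx.simulate_methylation(study.pedigree, bad, seed=0)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _tiny_world(n, maf=0.3, seed=0, **effect_kwargs):
    ped = founder_pedigree(n)
    snp_map, cpg_map = single_pair_maps(maf=maf)
    kin = gx.kinship_matrix(ped)
    eff = make_effects(**effect_kwargs)
    geno = gx.simulate_genotypes(ped, snp_map, seed=seed)
    meth = gx.simulate_methylation(ped, cpg_map, treatment_effect=eff.treatment_effect, seed=seed)
    pheno = simulate_phenotypes(ped, geno, meth, eff, kin, seed=seed)
    return ped, geno, meth, pheno, eff


def test_null_effects_residual_variance_recovered():
    n = 2000
    *_, pheno, eff = _tiny_world(n, sigma2_e=0.09)
    post = (np.log(pheno["TG3"]) + np.log(pheno["TG4"])) / 2
    se_var = 0.09 * np.sqrt(2.0 / (n - 1))
    assert abs(post.var(ddof=1) - 0.09) < 3 * se_var


def test_interaction_only_variance_contribution():
    n = 6000
    ped, geno, meth, pheno, eff = _tiny_world(n, seed=2, beta3=np.array([0.4]), sigma2_e=0.05)
    post = (np.log(pheno["TG3"]) + np.log(pheno["TG4"])) / 2
    interaction = geno.dosages["s1"].to_numpy() * (1 - meth.beta_visit4["c1"].to_numpy())
    expected = 0.4**2 * interaction.var(ddof=1) + 0.05
    assert post.var(ddof=1) == pytest.approx(expected, rel=0.1)


def test_positive_tg_and_trait_identities(replicate):
    assert (replicate.phenotypes[["TG1", "TG2", "TG3", "TG4"]] > 0).all().all()


def test_sibling_correlation_exceeds_unrelated(study):
    rng = np.random.default_rng(0)
    sib_x, sib_y, unrel_x, unrel_y = [], [], [], []
    for seed in (21, 22, 23):
        rep = gx.generate_replicate(study, seed)
        tr = gx.derive_traits(rep.phenotypes, rep.methylation)
        post = tr.post
        ped = study.pedigree
        children = ped[ped["father"] != FOUNDER]
        for _, block in children.groupby("family"):
            kids = block["individual"].tolist()
            for a, b in zip(kids, kids[1:]):
                sib_x.append(post[a])
                sib_y.append(post[b])
        ids = ped["individual"].to_numpy()
        fams = ped["family"].to_numpy()
        for _ in range(len(sib_x)):
            i, j = rng.integers(0, len(ids), 2)
            if fams[i] != fams[j]:
                unrel_x.append(post[ids[i]])
                unrel_y.append(post[ids[j]])
    r_sib = np.corrcoef(sib_x, sib_y)[0, 1]
    r_unrel = np.corrcoef(unrel_x, unrel_y)[0, 1]
    assert r_sib > r_unrel + 0.05
    assert r_sib > 0.1


def test_replicate_fully_deterministic(study):
    a = gx.generate_replicate(study, 99)
    b = gx.generate_replicate(study, 99)
    pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
    pd.testing.assert_frame_equal(a.methylation.beta_visit4, b.methylation.beta_visit4)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)


def test_calibrated_phenotypic_variance_is_unit(study, traits, covariates):
    X = np.column_stack(
        [
            np.ones(len(covariates)),
            covariates["age"],
            covariates["age"] ** 2,
            (covariates["sex"] == 1).astype(float),
        ]
    )
    y = traits.post.to_numpy()
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    assert resid.var(ddof=1) == pytest.approx(1.0, rel=0.12)


def test_calibration_rejects_overfull_variance_budget(study):
    with pytest.raises(ValueError):
        gx.calibrate_effects(study.snp_map, study.cpg_map, target_h2=0.10)
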