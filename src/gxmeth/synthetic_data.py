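"""Generation of GAW20-style family replicates.

Each replicate emulates the structure of the GAW20 simulated data: a fixed
set of nuclear families (680 individuals by default), SNP dosages dropped
through the pedigree from Hardy-Weinberg founders, methylation beta-values at
two visits, and log-triglyceride phenotypes at four visits generated from

    Post = b0 + sum_causal [b1*SNP + b2*(1-CpG) + b3*SNP*(1-CpG)]
         + sum_background b*SNP + b_age*age + b_age2*age^2 + b_sex*sex
         + gamma*Pre + g + eps

where ``Post`` is the mean of log(TG3) and log(TG4), ``Pre`` the mean of
log(TG1) and log(TG2), ``g`` is a polygenic effect with covariance
``2*Phi*sigma2_poly`` (Phi the kinship matrix) and ``eps`` is i.i.d. noise.
Five SNP/CpG pairs carry interaction effects and 100 "background" SNPs carry
tiny main effects, all on chromosomes 1-20; chromosomes 21 and 22 carry
markers with no simulated effects and serve as an empirical null.

Effect sizes are calibrated (``calibrate_effects``) so that, on the scale of
unit phenotypic variance after covariates, each causal SNP's marginal
standardized contribution matches a configured b^2 target and the total
additive genetic fraction equals ``target_h2`` (default 0.43).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import PedigreeError

FOUNDER = "0"  # sentinel parent id, linkage-file convention

# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

#: default distribution over nuclear-family sizes (2 founders + 1..4 children)
DEFAULT_FAMILY_SIZES = {3: 0.25, 4: 0.35, 5: 0.25, 6: 0.15}


def build_pedigrees(
    n_individuals: int = 680,
    family_size_distribution: dict[int, float] | None = None,
    seed: int = 0,
    parent_age_range: tuple[float, float] = (45.0, 70.0),
    child_age_range: tuple[float, float] = (18.0, 40.0),
) -> pd.DataFrame:
    """Build a sample of nuclear families totalling exactly ``n_individuals``.

    Family sizes are drawn from ``family_size_distribution`` (total members,
    two founders plus children); the last family is truncated, or leftover
    individuals are attached as extra children, so the total is exact.

    Returns a DataFrame with columns ``family, individual, father, mother,
    sex, age`` (sex coded 1=male, 2=female; founders have father/mother "0").
    """
    if n_individuals < 3:
        raise ValueError(f"n_individuals must be >= 3, got {n_individuals}")
    dist = dict(family_size_distribution or DEFAULT_FAMILY_SIZES)
    sizes = np.array(sorted(dist), dtype=int)
    if (sizes < 3).any():
        raise ValueError("nuclear family size must be >= 3 (two founders + a child)")
    probs = np.array([dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    fam_sizes: list[int] = []
    while sum(fam_sizes) < n_individuals:
        fam_sizes.append(int(rng.choice(sizes, p=probs)))
    excess = sum(fam_sizes) - n_individuals
    if excess:
        fam_sizes[-1] -= excess
        if fam_sizes[-1] < 3:  # too few left for a trio: fold into previous family
            fam_sizes[-2] += fam_sizes.pop()

    rows = []
    for f, size in enumerate(fam_sizes):
        fam = f"fam{f + 1:04d}"
        father = f"{fam}_01"
        mother = f"{fam}_02"
        rows.append((fam, father, FOUNDER, FOUNDER, 1, rng.uniform(*parent_age_range)))
        rows.append((fam, mother, FOUNDER, FOUNDER, 2, rng.uniform(*parent_age_range)))
        for c in range(size - 2):
            rows.append(
                (
                    fam,
                    f"{fam}_{c + 3:02d}",
                    father,
                    mother,
                    int(rng.integers(1, 3)),
                    rng.uniform(*child_age_range),
                )
            )
    ped = pd.DataFrame(rows, columns=["family", "individual", "father", "mother", "sex", "age"])
    ped["age"] = ped["age"].round(1)
    return ped


def validate_pedigree(pedigree: pd.DataFrame) -> None:
    """Check structural invariants: parents present, within-family, acyclic."""
    ids = set(pedigree["individual"])
    if len(ids) != len(pedigree):
        raise PedigreeError("duplicate individual ids")
    fam_of = dict(zip(pedigree["individual"], pedigree["family"]))
    for _, row in pedigree.iterrows():
        for parent in (row["father"], row["mother"]):
            if parent != FOUNDER:
                if parent not in ids:
                    raise PedigreeError(f"parent {parent} of {row['individual']} not in pedigree")
                if fam_of[parent] != row["family"]:
                    raise PedigreeError(f"parent {parent} is in a different family")
    _topological_order(pedigree)  # raises on cycles


def _topological_order(pedigree: pd.DataFrame) -> list[str]:
    """Individuals ordered so that parents precede children; raises on cycles."""
    parents = {
        row["individual"]: [p for p in (row["father"], row["mother"]) if p != FOUNDER]
        for _, row in pedigree.iterrows()
    }
    order: list[str] = []
    placed: set[str] = set()
    pending = list(pedigree["individual"])
    while pending:
        progress = False
        rest = []
        for ind in pending:
            if all(p in placed for p in parents[ind]):
                order.append(ind)
                placed.add(ind)
                progress = True
            else:
                rest.append(ind)
        if not progress:
            raise PedigreeError(f"cyclic or unresolvable pedigree involving {rest}")
        pending = rest
    return order


def _kinship_block(block: pd.DataFrame) -> pd.DataFrame:
    order = _topological_order(block)
    idx = {ind: k for k, ind in enumerate(order)}
    par = {row["individual"]: (row["father"], row["mother"]) for _, row in block.iterrows()}
    n = len(order)
    K = np.zeros((n, n))
    for i, ind in enumerate(order):
        f, m = par[ind]
        if f == FOUNDER and m == FOUNDER:
            K[i, i] = 0.5
        else:
            fi, mi = idx[f], idx[m]
            K[i, i] = 0.5 + 0.5 * K[fi, mi]
            K[i, :i] = K[:i, i] = 0.5 * (K[fi, :i] + K[mi, :i])
    return pd.DataFrame(K, index=order, columns=order)


def kinship_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Recursive kinship coefficients Phi for a (possibly inbred) pedigree.

    Founders are assumed unrelated and non-inbred: Phi(i,i) = 0.5 + Phi(f,m)/2
    and Phi(i,j) = (Phi(f,j) + Phi(m,j)) / 2 for j a non-descendant of i.
    Families share no ancestry, so the matrix is assembled family-block by
    family-block.
    """
    validate_pedigree(pedigree)
    ids = list(pedigree["individual"])
    n = len(ids)
    pos = {ind: k for k, ind in enumerate(ids)}
    K = np.zeros((n, n))
    for _, block in pedigree.groupby("family", sort=False):
        kb = _kinship_block(block)
        rows = np.array([pos[i] for i in kb.index])
        K[np.ix_(rows, rows)] = kb.to_numpy()
    return pd.DataFrame(K, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Marker maps
# ---------------------------------------------------------------------------

CAUSAL_MAFS = (0.30, 0.15, 0.25, 0.10, 0.20)
B2_TARGETS = (0.0210, 0.0008, 0.0070, 0.0004, 0.0090)


def default_marker_maps(
    seed: int = 0,
    n_background: int = 100,
    n_null_snps: tuple[int, int] = (60, 70),
    n_null_cpgs: tuple[int, int] = (70, 85),
    null_maf_range: tuple[float, float] = (0.02, 0.5),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct the fixed SNP and CpG maps used by every replicate.

    Five causal SNP/CpG pairs sit on chromosomes 1-5 and ``n_background``
    background SNPs (each with an effect-free companion CpG) are spread over
    chromosomes 1-20; chromosomes 21 and 22 carry only effect-free markers
    used for the empirical null.

    Returns ``(snp_map, cpg_map)``: snp_map indexed by SNP id with columns
    ``chromosome, position, maf, role``; cpg_map indexed by CpG id with
    columns ``chromosome, position, role, paired_snp, mean, concentration``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3A9]))
    snps, cpgs = [], []
    # causal pairs
    for i, (maf, chrom) in enumerate(zip(CAUSAL_MAFS, range(1, 6)), start=1):
        pos = int(rng.integers(1_000_000, 80_000_000))
        snps.append((f"snpC{i}", chrom, pos, maf, "main_causal"))
        cpgs.append((f"cgC{i}", chrom, pos + 5_000, "main_causal", f"snpC{i}"))
    # background SNPs, each with an effect-free companion CpG so an
    # interaction test can be formed for them
    for j in range(1, n_background + 1):
        chrom = int(rng.integers(1, 21))
        pos = int(rng.integers(1_000_000, 80_000_000))
        maf = float(rng.uniform(0.05, 0.5))
        snps.append((f"snpB{j:03d}", chrom, pos, maf, "background"))
        cpgs.append((f"cgB{j:03d}", chrom, pos + 5_000, "background", f"snpB{j:03d}"))
    # null chromosomes 21/22: unpaired marker clouds
    def distinct_positions(k: int) -> np.ndarray:
        pos = np.unique(rng.integers(1_000_000, 45_000_000, size=2 * k))
        return np.sort(rng.choice(pos, size=k, replace=False))

    for chrom, n_s, n_c in zip((21, 22), n_null_snps, n_null_cpgs):
        s_pos = distinct_positions(n_s)
        c_pos = distinct_positions(n_c)
        for k, pos in enumerate(s_pos, start=1):
            maf = float(rng.uniform(*null_maf_range))
            snps.append((f"snpN{chrom}_{k:03d}", chrom, int(pos), maf, "null"))
        for k, pos in enumerate(c_pos, start=1):
            cpgs.append((f"cgN{chrom}_{k:03d}", chrom, int(pos), "null", None))

    snp_map = pd.DataFrame(
        snps, columns=["snp", "chromosome", "position", "maf", "role"]
    ).set_index("snp")
    cpg_map = pd.DataFrame(
        cpgs, columns=["cpg", "chromosome", "position", "role", "paired_snp"]
    ).set_index("cpg")
    cpg_map["mean"] = 0.6
    cpg_map["concentration"] = 10.0
    return snp_map, cpg_map


# ---------------------------------------------------------------------------
# Effect configuration
# ---------------------------------------------------------------------------


@dataclass
class EffectConfig:
    """All generating-model coefficients, on the log-triglyceride scale.

    ``beta1/beta2/beta3`` are aligned with the ``main_causal`` SNPs of the
    marker map (sorted by id); ``beta_background`` with the ``background``
    SNPs. The phenotypic variance of ``Post`` conditional on age/sex is
    ``total_var`` by construction of :func:`calibrate_effects`.
    """

    beta0: float = 4.6
    beta1: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta2: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta3: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_background: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_age: float = 0.01
    beta_age2: float = -0.0001
    beta_sex: float = 0.15
    gamma_pre: float = 1.4
    mu_pre: float = 4.7
    sigma_pre: float = 0.5
    sigma2_poly: float = 0.0
    sigma2_e: float = 1.0
    target_h2: float = 0.43
    sigma_visit: float = 0.1
    treatment_effect: float = -0.05
    meth_rho: float = 0.9
    cpg_visit: str = "visit4"  # which visit's beta-value enters the generating model
    total_var: float = 1.0

    def __post_init__(self):
        if self.sigma2_poly < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if not (0 <= self.target_h2 < 1):
            raise ValueError("target_h2 must be in [0, 1)")


def calibrate_effects(
    snp_map: pd.DataFrame,
    cpg_map: pd.DataFrame,
    b2_targets: tuple[float, ...] = B2_TARGETS,
    background_var: float = 0.001,
    target_h2: float = 0.43,
    corr_pre_post: float = 0.7,
    interaction_share: float = 0.5,
    beta2: float = 0.3,
    treatment_effect: float = -0.05,
    sigma_pre: float = 0.5,
    total_var: float = 1.0,
    **overrides,
) -> EffectConfig:
    """Derive generating coefficients from per-locus variance targets.

    For causal locus *i* with founder MAF *p*, dosage variance
    ``s2 = 2p(1-p)`` and mean visit-4 expression regressor
    ``mbar = 1 - (cpg_mean + treatment_effect)``, the marginal standardized
    slope is set to ``m' = sqrt(b2_i * total_var / s2)`` and split between the
    SNP main effect and the interaction: ``beta1 = (1-w) m'``,
    ``beta3 = w m' / mbar`` with ``w = interaction_share``. The polygenic
    variance fills the gap to ``target_h2`` and the residual variance fills
    the gap to ``total_var``.
    """
    causal = snp_map[snp_map["role"] == "main_causal"].sort_index()
    background = snp_map[snp_map["role"] == "background"].sort_index()
    if len(causal) != len(b2_targets):
        raise ValueError(f"{len(b2_targets)} b2 targets for {len(causal)} causal SNPs")

    causal_cpgs = cpg_map[cpg_map["role"] == "main_causal"].sort_values("paired_snp")
    mu = causal_cpgs["mean"].to_numpy()
    conc = causal_cpgs["concentration"].to_numpy()
    mu4 = np.clip(mu + treatment_effect, 1e-3, 1 - 1e-3)
    var_m = mu4 * (1 - mu4) / (1 + conc)  # Beta marginal variance at visit 4
    mbar = 1.0 - mu4

    p = causal["maf"].to_numpy()
    s2 = 2 * p * (1 - p)
    mu_s = 2 * p
    mprime = np.sqrt(np.asarray(b2_targets) * total_var / s2)
    b3 = interaction_share * mprime / mbar
    b1 = (1 - interaction_share) * mprime
    b2_vec = np.full(len(causal), beta2)

    # exact second-moment accounting (SNP independent of CpG):
    #   Var(b1*S + b3*S*M + b2*M) = s2*m'^2 + b3^2*var_m*(s2 + mu_s^2)
    #                               + b2^2*var_m + 2*b2*b3*mu_s*var_m
    var_pair = (
        s2 * mprime**2
        + b3**2 * var_m * (s2 + mu_s**2)
        + b2_vec**2 * var_m
        + 2 * b2_vec * b3 * mu_s * var_m
    )

    p_bg = background["maf"].to_numpy()
    s2_bg = 2 * p_bg * (1 - p_bg)
    sign = np.where(np.arange(len(background)) % 2 == 0, 1.0, -1.0)
    beta_bg = sign * np.sqrt(background_var * total_var / s2_bg)
    var_bg = background_var * total_var * len(background)

    genic = float(np.sum(b2_targets)) * total_var + var_bg
    sigma2_poly = target_h2 * total_var - genic
    if sigma2_poly < 0:
        raise ValueError("b2 targets plus background variance exceed target_h2")
    var_pre = (corr_pre_post**2) * total_var
    gamma = np.sqrt(var_pre) / sigma_pre
    sigma2_e = total_var - var_pair.sum() - var_bg - var_pre - sigma2_poly
    if sigma2_e <= 0:
        raise ValueError("variance budget exhausted: residual variance would be <= 0")

    return EffectConfig(
        beta1=b1,
        beta2=b2_vec,
        beta3=b3,
        beta_background=beta_bg,
        gamma_pre=float(gamma),
        sigma_pre=sigma_pre,
        sigma2_poly=float(sigma2_poly),
        sigma2_e=float(sigma2_e),
        target_h2=target_h2,
        treatment_effect=treatment_effect,
        total_var=total_var,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeSet:
    dosages: pd.DataFrame  # individuals x SNPs, entries in {0,1,2}
    snp_map: pd.DataFrame


def simulate_genotypes(pedigree: pd.DataFrame, snp_map: pd.DataFrame, seed: int = 0) -> GenotypeSet:
    """Drop genotypes through the pedigree.

    Founders are drawn under Hardy-Weinberg equilibrium at each SNP's MAF;
    each offspring receives from each parent one allele that is the minor
    allele with probability ``dosage/2`` (exact single-locus Mendelian
    transmission for unlinked markers).
    """
    mafs = snp_map["maf"].to_numpy(float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        bad = snp_map.index[(mafs <= 0) | (mafs > 0.5)].tolist()
        raise ValueError(f"MAF must lie in (0, 0.5]; offending SNPs: {bad}")
    order = _topological_order(pedigree)
    par = {row["individual"]: (row["father"], row["mother"]) for _, row in pedigree.iterrows()}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E0]))
    n_snp = len(snp_map)
    dos: dict[str, np.ndarray] = {}
    for ind in order:
        f, m = par[ind]
        if f == FOUNDER:
            dos[ind] = rng.binomial(2, mafs)
        else:
            dos[ind] = rng.binomial(1, dos[f] / 2.0) + rng.binomial(1, dos[m] / 2.0)
    mat = pd.DataFrame(
        np.vstack([dos[i] for i in pedigree["individual"]]).astype(np.int8),
        index=pedigree["individual"].to_numpy(),
        columns=snp_map.index,
    )
    return GenotypeSet(dosages=mat, snp_map=snp_map)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


@dataclass
class MethylationSet:
    beta_visit2: pd.DataFrame  # individuals x CpGs, values in [0, 1]
    beta_visit4: pd.DataFrame
    cpg_map: pd.DataFrame


def simulate_methylation(
    pedigree: pd.DataFrame,
    cpg_map: pd.DataFrame,
    treatment_effect: float = -0.05,
    seed: int = 0,
    rho: float = 0.9,
) -> MethylationSet:
    """Simulate beta-values with Beta marginals and a Gaussian copula between visits.

    Visit-2 values follow ``Beta(mean * conc, (1-mean) * conc)`` per CpG; the
    visit-4 latent normal correlates ``rho`` with visit 2, and causal CpGs'
    visit-4 marginal mean is shifted by ``treatment_effect`` (the treatment
    acting on methylation at effect sites). All values lie in [0, 1] exactly.
    """
    means = cpg_map["mean"].to_numpy(float)
    conc = cpg_map["concentration"].to_numpy(float)
    if np.any(means <= 0) or np.any(means >= 1):
        raise ValueError("per-CpG mean must lie in (0, 1)")
    if np.any(conc <= 0):
        raise ValueError("per-CpG concentration must be > 0")
    if not 0 <= rho <= 1:
        raise ValueError("visit correlation rho must lie in [0, 1]")

    shifted = cpg_map["role"].to_numpy() == "main_causal"
    means4 = np.where(shifted, np.clip(means + treatment_effect, 1e-3, 1 - 1e-3), means)

    n = len(pedigree)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCB6]))
    z2 = rng.standard_normal((n, len(cpg_map)))
    z4 = rho * z2 + np.sqrt(1 - rho**2) * rng.standard_normal((n, len(cpg_map)))
    a2, b2 = means * conc, (1 - means) * conc
    a4, b4 = means4 * conc, (1 - means4) * conc
    beta2 = stats.beta.ppf(stats.norm.cdf(z2), a2, b2)
    beta4 = stats.beta.ppf(stats.norm.cdf(z4), a4, b4)
    ids = pedigree["individual"].to_numpy()
    return MethylationSet(
        beta_visit2=pd.DataFrame(beta2, index=ids, columns=cpg_map.index),
        beta_visit4=pd.DataFrame(beta4, index=ids, columns=cpg_map.index),
        cpg_map=cpg_map,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _sample_polygenic(kinship: pd.DataFrame, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw g ~ MVN(0, 2*Phi*sigma2) by Cholesky of the (jittered) kinship."""
    if sigma2 == 0:
        return np.zeros(len(kinship))
    A = 2.0 * kinship.to_numpy(float) * sigma2
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
    return L @ rng.standard_normal(len(A))


def simulate_phenotypes(
    pedigree: pd.DataFrame,
    genotypes: GenotypeSet,
    methylation: MethylationSet,
    effects: EffectConfig,
    kinship: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate TG1..TG4 (positive scale) from the interaction generating model.

    ``Pre`` (mean of log TG1/TG2) is drawn as an individual-level baseline;
    ``Post`` follows the generating model above; per-visit noise ``u`` splits
    each mean into its two visits as ``exp(mean +/- u)`` so that the visit
    averages reproduce Pre and Post exactly.
    """
    ids = pedigree["individual"].to_numpy()
    if not (
        np.array_equal(genotypes.dosages.index.to_numpy(), ids)
        and np.array_equal(methylation.beta_visit2.index.to_numpy(), ids)
        and np.array_equal(np.asarray(kinship.index), ids)
    ):
        raise PedigreeError("genotypes, methylation and kinship must be indexed like the pedigree")

    snp_map = genotypes.snp_map
    causal = snp_map[snp_map["role"] == "main_causal"].sort_index()
    background = snp_map[snp_map["role"] == "background"].sort_index()
    cpg_map = methylation.cpg_map
    causal_cpgs = cpg_map[cpg_map["role"] == "main_causal"].sort_values("paired_snp")
    beta_mat = methylation.beta_visit4 if effects.cpg_visit == "visit4" else methylation.beta_visit2

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF0E]))
    n = len(ids)
    age = pedigree["age"].to_numpy(float)
    sex01 = (pedigree["sex"].to_numpy() == 1).astype(float)  # 1 = male

    pre = effects.mu_pre + effects.sigma_pre * rng.standard_normal(n)
    g = _sample_polygenic(kinship, effects.sigma2_poly, rng)
    eps = np.sqrt(effects.sigma2_e) * rng.standard_normal(n)

    post = (
        effects.beta0
        + effects.beta_age * age
        + effects.beta_age2 * age**2
        + effects.beta_sex * sex01
        + effects.gamma_pre * (pre - effects.mu_pre)
        + g
        + eps
    )
    S_c = genotypes.dosages[causal.index].to_numpy(float)
    M_c = 1.0 - beta_mat[causal_cpgs.index].to_numpy(float)
    post += S_c @ effects.beta1 + M_c @ effects.beta2 + (S_c * M_c) @ effects.beta3
    if len(background):
        post += genotypes.dosages[background.index].to_numpy(float) @ effects.beta_background

    u1 = effects.sigma_visit * rng.standard_normal(n)
    u2 = effects.sigma_visit * rng.standard_normal(n)
    pheno = pd.DataFrame(
        {
            "TG1": np.exp(pre + u1),
            "TG2": np.exp(pre - u1),
            "TG3": np.exp(post + u2),
            "TG4": np.exp(post - u2),
            "age": age,
            "sex": pedigree["sex"].to_numpy(),
        },
        index=ids,
    )
    pheno.index.name = "individual"
    return pheno


# ---------------------------------------------------------------------------
# Study bundle and replicate generation
# ---------------------------------------------------------------------------


@dataclass
class Study:
    """Fixed-across-replicates part of a simulation: families and marker maps."""

    pedigree: pd.DataFrame
    kinship: pd.DataFrame
    snp_map: pd.DataFrame
    cpg_map: pd.DataFrame
    effects: EffectConfig


@dataclass
class Replicate:
    genotypes: GenotypeSet
    methylation: MethylationSet
    phenotypes: pd.DataFrame
    seed: int


def default_study(seed: int = 0, n_individuals: int = 680, **effect_overrides) -> Study:
    """The default GAW20-style study: 680 individuals, 5 causal pairs,
    100 background SNPs, null markers on chromosomes 21/22, calibrated effects."""
    ped = build_pedigrees(n_individuals=n_individuals, seed=seed)
    kin = kinship_matrix(ped)
    snp_map, cpg_map = default_marker_maps(seed=seed)
    effects = calibrate_effects(snp_map, cpg_map, **effect_overrides)
    return Study(pedigree=ped, kinship=kin, snp_map=snp_map, cpg_map=cpg_map, effects=effects)


def generate_replicate(study: Study, seed: int) -> Replicate:
    """Generate one replicate: genotypes, methylation and phenotypes are
    redrawn; pedigree and marker maps are fixed study-wide."""
    geno = simulate_genotypes(study.pedigree, study.snp_map, seed=seed)
    meth = simulate_methylation(
        study.pedigree,
        study.cpg_map,
        treatment_effect=study.effects.treatment_effect,
        seed=seed,
        rho=study.effects.meth_rho,
    )
    pheno = simulate_phenotypes(study.pedigree, geno, meth, study.effects, study.kinship, seed=seed)
    return Replicate(genotypes=geno, methylation=meth, phenotypes=pheno, seed=seed)
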