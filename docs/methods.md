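# Methods

## The analysis problem

`gxmeth` studies whether SNP-by-methylation interaction effects on
triglyceride (TG) levels can be detected in family data, and with what
Type-I error and power. It emulates the structure of the GAW20 simulated
family study: ~680 individuals in nuclear families, TG measured at four
visits (two before and two after a methylation-modifying treatment),
methylation beta-values at visits 2 and 4, five causative SNP/CpG pairs plus
100 tiny-effect "background" SNPs on chromosomes 1–20, and effect-free
chromosomes 21/22 providing an empirical null. Because the original
replicate data and its exact generating coefficients are not public, the
package contains its own generator calibrated to the quantities that *are*
recoverable (heritability, per-SNP variance shares, null calibration), and
analysis machinery that is meaningful for any data with this layout.

## Generating model

With `Pre` = mean(log TG1, log TG2) and `Post` = mean(log TG3, log TG4),
phenotypes are drawn from

    Post = b0 + sum_causal [ b1·SNP + b2·(1−CpG) + b3·SNP·(1−CpG) ]
         + sum_background b·SNP
         + b_age·age + b_age2·age² + b_sex·sex + gamma·Pre + g + eps,

    g ~ MVN(0, 2·Phi·sigma2_poly),    eps ~ N(0, sigma2_e) i.i.d.,

where Phi is the pedigree kinship matrix and CpG is the visit-4 beta-value
(the visit entering the generating model is configurable; visit 4 is the
default because the interaction acts on the post-treatment trait).
Methylation enters as `1 − CpG` throughout: lower methylation means higher
expression, so the expression-scale regressor is the unmethylated fraction.
TG visits are reconstructed as `exp(mean ± u)` with per-visit noise `u`
(SD `sigma_visit = 0.1` on the log scale), so the visit averages reproduce
Pre and Post exactly and all TG values are positive.

Genotypes are dropped through the pedigree: founders are Hardy–Weinberg at
the configured MAF and each offspring allele is the minor allele with
probability `dosage/2` per parent (exact single-locus Mendelian
transmission; loci are unlinked, no LD). Methylation beta-values have Beta
marginals (default mean 0.6, concentration 10) joined across visits by a
Gaussian copula with latent correlation `rho = 0.9`; causal CpGs receive a
visit-4 treatment shift of −0.05 on the mean. Ages are uniform (parents
45–70, children 18–40 years); sex is balanced at random.

### Calibration of effect sizes

The generator's coefficients are derived, not hand-set, by
`calibrate_effects`, on the scale of **unit phenotypic variance of Post
conditional on age/sex**:

* Each causal locus *i* is given a marginal standardized variance share
  `b2_i` of (0.0210, 0.0008, 0.0070, 0.0004, 0.0090) — the recoverable
  per-locus contributions. With dosage variance `s2 = 2p(1−p)` and mean
  expression regressor `mbar = E[1−CpG4]`, the marginal slope
  `m' = sqrt(b2_i / s2)` is split half-and-half between main effect and
  interaction: `b1 = m'/2`, `b3 = m'/(2·mbar)` (the split is configurable
  via `interaction_share`).
* Causal founder MAFs default to (0.30, 0.15, 0.25, 0.10, 0.20); background
  MAFs are uniform on (0.05, 0.5) and each background SNP contributes 0.1%
  of variance; null-chromosome MAFs are uniform on (0.02, 0.5) so that a
  small fraction of null SNPs fails the MAC > 50 filter.
* The polygenic variance fills the gap so the total additive fraction is
  `target_h2 = 0.43`: `sigma2_poly = 0.43 − sum(b2) − 0.1 ≈ 0.292`.
* `Post` includes `gamma·(Pre − mu_pre)` with `gamma·sigma_pre = 0.7`, so
  corr(Pre, Post) ≈ 0.7 and Pre dominates tree-based importance rankings.
* The residual variance absorbs whatever remains after exact second-moment
  accounting of every term (≈ 0.064), which pins total variance at 1;
  a configuration whose effects exceed the budget is rejected.

Because methylation and Pre are simulated as individual-level (non-familial)
variables, the covariance between relatives is exactly `2·Phi` times the
additive variance, and the REML heritability target of 0.43 follows by
construction rather than by tuning against any estimate.

## Estimators

**Family-absorbing least squares (GLM route).** Ordinary least squares with
one indicator column per family; the interaction p-value is the two-sided t
test with residual degrees of freedom. A family-clustered sandwich
covariance is available as an explicitly non-default variant; with rare
alleles (MAC < 20) its Type-I error is inflated relative to model-based
standard errors, a property the tests check directionally.

**Family random-intercept mixed model (REML).** cov(y) = `sigma2_f·ZZ' +
sigma2_e·I` with Z the family incidence matrix. Since ZZ' has a closed-form
eigenbasis (one eigenvalue per family equal to its size, Helmert complement
for the rest), the restricted likelihood profiles to a one-dimensional
function of the variance ratio, maximized by a 26-point grid scan plus
bounded refinement to 1e-8 — the same core as the polygenic model below.
Wald z inference is the default (a t reference is available via `use_t`;
with ~170 families the difference is negligible). The family intercept is an
approximation to the true kinship covariance (it gives spouses and siblings
the same correlation); its tail calibration at alpha = 0.05 is nominal on
the empirical null, but a large-sample KS test can detect mild mid-range
non-uniformity there. A kinship-structured variant
(`FamilyMixedLM(covariance="kinship")`) is provided for comparison.

**Polygenic REML heritability.** y = Xb + g + eps with cov(g) =
`2·Phi·sigma2_g`, profiled over h² ∈ [0, 1] after eigen-rotation of 2·Phi
(the classic animal-model/EMMA reduction); the total variance is profiled in
closed form. Covariates are age, age², sex — Pre is deliberately excluded so
the estimand is the heritability of Post itself. Boundary estimates are
flagged, not errors. The optimizer is cross-checked in the tests against a
dense grid search of the restricted likelihood and, for the family-intercept
special case, against an independent mixed-model implementation.

**Single-SNP b².** Residualize the response on covariates, z-score residuals
and dosage (n−1 denominator), square the slope — algebraically the squared
Pearson correlation. As an estimator of a small variance share it carries an
upward finite-sample bias of order (1−b²)/n (≈ 0.0014 at n = 680), visible
as a slight excess of the replicate mean over the generating share.

**Empirical null pairs.** On each effect-free chromosome, SNPs are walked in
ascending position and paired with the nearest unused CpG at a strictly
higher position; SNPs with no downstream CpG remain unpaired, so there are
fewer pairs than SNPs. This is one deterministic formalization of
"adjacent CpG with a higher base-pair position"; the filter retains pairs
with SNP minor allele count strictly greater than 50 (computed over all
simulated individuals). The default maps carry 130 null SNPs and 155 null
CpGs on chromosomes 21/22, yielding ~124 pairs per study.

**Trees and forests.** Variance-reduction CART via scikit-learn. The
regression tree enforces a minimum leaf size of 10; the combined-replicates
fit uses a seeded 40/30/30 training/validation/test split by row. Importance
is the per-feature summed impurity reduction, max-normalized; held-out
importances route the partition's samples through the fitted tree and credit
each split with the held-out SSE reduction obtained from the *training*
means (overfit splits earn negative credit, clipped to zero after
normalization). The forest uses bootstrap aggregation with P/3 features per
split; its default predictor set on generator output is Pre, age, sex, the
five causal SNPs, their five CpGs and the 100 background SNPs (113
predictors). Ranks are dense 1..P by descending score, ties broken by
predictor name. The headline forest size of 10,000 trees is available
through configuration; tests and the bundled summaries use 200–500 trees,
which is ample for the rank statistics examined.

## Numerical and degenerate-input choices

* Natural logarithms throughout; base only rescales coefficients.
* Sex is 0/1 (female/male) in design matrices, 1/2 (male/female) in
  pedigree files (linkage convention).
* Monomorphic SNPs or constant methylation columns make the interaction
  untestable: the fit is returned flagged not-applicable, never p = 1, and
  such tests are excluded from power denominators and counted separately.
* Rank-deficient designs raise an error naming the collinear columns.
* Significance uses strict inequality (`p < alpha`), as does the MAC filter
  (`MAC > 50`); proportions are reported to 2 decimals by default.
* One global seed expands into per-component substreams
  (`numpy.random.SeedSequence`); every output is byte-reproducible from the
  run manifest.

## Problem sizes used by the bundled checks

The test-suite and `scripts/acceptance.py` choices are: 20 replicates of
~124 null pairs (≈ 2,480 tests per method) for Type-I calibration, 50
replicates for the heritability mean, 200 replicates for the b² mean, 5
replicates of a 200-tree forest for the Pre-rank check, and 2,000
simulations for uniformity and clustering-inflation properties. These sizes
put the Monte-Carlo standard errors well below the effects being checked.

## What the generator does and does not emulate

It reproduces: nuclear-family relatedness and its phenotypic signature,
Mendelian dosage transmission, bounded two-visit methylation with a
treatment shift at causal sites, a genuine SNP-by-methylation interaction
architecture, tiny polygenic background effects, and effect-free
chromosomes for empirical nulls. It does not model: linkage disequilibrium
or linkage between loci, heritable or familially clustered methylation,
heritability of the pretreatment level, missing data, X chromosomes,
inbreeding, or multi-generation households. Consequently, passing tests
demonstrate the correctness and calibration of the estimators under this
architecture — not the power values attainable on the original data, whose
interaction effect sizes are not public and are out of scope here.
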