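# gxmeth

Family-based simulation and testing of **SNP-by-methylation interaction
effects** on triglycerides.

Epigenetic marks modulate how genetic variants affect a trait: at a
causative locus, the effect of a SNP on post-treatment triglycerides (TG)
can depend on how methylated a nearby CpG site is. Detecting such G×M
interactions in family studies raises three intertwined questions — does the
interaction test keep its nominal Type-I error once relatedness is accounted
for, how much power is there at realistic effect sizes, and how do
tree-based importance rankings compare with parametric tests? `gxmeth` is a
workbench for those questions, emulating the design of the GAW20 simulated
family study (680 individuals in nuclear families, TG at four visits
bracketing a methylation-modifying treatment, methylation β-values at visits
2 and 4, five causative SNP/CpG pairs plus 100 tiny "background" SNPs on
chromosomes 1–20, and effect-free chromosomes 21/22 for an empirical null).

With Pre = mean(log TG1, log TG2), Post = mean(log TG3, log TG4), the
central model (model 1a, also the generating model) is

    Post = β₀ + β₁·SNP + β₂·(1−CpG) + β₃·SNP·(1−CpG) + β_C + ε

with covariates β_C over age, age², sex and Pre; the null hypothesis of
interest is β₃ = 0. Variants 1b (interaction only), 2a/2b (change scores:
δTG = Post − Pre regressed on δCpG = CpG₄ − CpG₂ and SNP·δCpG) are included.
Methylation enters as (1 − CpG) because less methylation means more
expression.

The package provides:

* `synthetic_data` — pedigree construction, recursive kinship Φ, Mendelian
  gene dropping, Beta-copula methylation, and phenotypes from the generating
  model with polygenic covariance 2Φσ²_poly; effect sizes are calibrated so
  each causal locus contributes a fixed standardized variance share and the
  narrow-sense heritability of Post is 0.43.
* `trait_models` — derived traits and the four design-matrix layouts.
* `association` — per-pair interaction tests: least squares with a family
  term (`FamilyOLS`), a family random-intercept REML mixed model
  (`FamilyMixedLM`, Wald inference), and a cluster-robust sandwich variant.
* `null_harness` — empirical-null SNP–CpG pairs on effect-free chromosomes
  (nearest downstream CpG, one use per CpG) and the MAC > 50 filter.
* `evaluation` — power / Type-I tables across replicates at a nominal α.
* `heritability` — eigen-rotation profiled REML for h² under a kinship
  covariance, and single-SNP b² (squared standardized regression slope).
* `tree_models` — CART regression tree (minimum leaf 10) and random forest
  with impurity-based, max-normalized importances and per-replicate ranks.
* `workbench` — YAML config, manifest, checkpointed pipeline and a
  `gxmeth` command-line interface (`simulate`, `fit`, `evaluate`,
  `heritability`, `trees`, `all`).

## Worked example

```python
import numpy as np
import gxmeth as gx

study = gx.default_study(seed=1)            # families, kinship, maps, effects
rep = gx.generate_replicate(study, seed=42) # genotypes, methylation, TG1..TG4
traits = gx.derive_traits(rep.phenotypes, rep.methylation)

# interaction test at the strongest causal pair, model 1a, mixed model
design = gx.build_design("1a", rep.genotypes.dosages["snpC1"],
                         rep.methylation.beta_visit4["cgC1"], traits,
                         rep.phenotypes[["age", "sex"]])
fit = gx.fit_mixed(design, families=study.pedigree["family"].to_numpy())
print(f"beta3 = {fit.beta_interaction:.3f} "
      f"(SE {fit.bse[fit.interaction_column]:.3f}), p = {fit.p_interaction:.4g}")
print(f"variance components: family {fit.vc['family']:.3f}, "
      f"residual {fit.vc['residual']:.3f}")

# heritability of Post and the per-SNP variance share
covs = np.column_stack([rep.phenotypes["age"], rep.phenotypes["age"]**2,
                        (rep.phenotypes["sex"] == 1).astype(float)])
pm = gx.polygenic_h2(traits.post, covs, study.kinship)
print(f"polygenic h2 of Post: {pm.h2_:.3f}")
print(f"b2 at snpC1: {gx.snp_b2(traits.post, covs, rep.genotypes.dosages['snpC1']):.4f}")
```

prints

```
beta3 = 0.309 (SE 0.233), p = 0.1836
variance components: family 0.172, residual 0.277
polygenic h2 of Post: 0.321
b2 at snpC1: 0.0170
```

On this single replicate the interaction at the strongest locus is not
significant — with n = 680 and a standardized variance share of ~2%,
single-replicate power is limited — and the one-replicate h² (0.32) and b²
(0.017) scatter around their generating values (0.43 and 0.021); averaging
over replicates recovers both (see below). The mixed model attributes about
38% of the residual trait variance to between-family differences, the
random-intercept proxy for the polygenic background.

A full pipeline run (tables of Type-I/power per model × method, a
heritability summary, forest rank summaries, a manifest that reproduces
everything) is one command:

```bash
gxmeth all --seed 7 --replicates 10 --out runs/demo
```

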