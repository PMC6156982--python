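"""Run configuration, end-to-end orchestration and the command-line interface.

``run_pipeline`` drives replicate generation -> per-pair interaction fits ->
power/Type-I, heritability and tree-importance tables, with per-replicate
checkpoints and a machine-readable manifest (config + seed + versions) that
suffices to reproduce every table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .association import run_pair_tests
from .evaluation import summarize_replicates
from .exceptions import ConfigError
from .heritability import polygenic_h2, snp_b2, summarize_estimates
from .null_harness import minor_allele_count, pair_null_markers
from .synthetic_data import Study, default_study, generate_replicate
from .trait_models import derive_traits
from .tree_models import fit_random_forest, fit_regression_tree, forest_features, summarize_forest_ranks

logger = logging.getLogger(__name__)

VALID_MODELS = ("1a", "1b", "2a", "2b")
VALID_METHODS = ("glm", "mixed", "tree", "forest")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the study design
    (680 individuals, 200 replicates, alpha 0.05, MAC > 50)."""

    n_replicates: int = 200
    n_individuals: int = 680
    seed: int = 0
    models: tuple[str, ...] = ("1a", "1b", "2a", "2b")
    methods: tuple[str, ...] = ("glm", "mixed")
    alpha: float = 0.05
    mac_threshold: int = 50
    include_background: bool = True
    include_null: bool = True
    n_trees: int = 500
    tree_min_leaf: int = 10
    out_dir: str = "gxmeth_out"
    effect_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_replicates < 1 or self.n_individuals < 3:
            raise ConfigError("n_replicates must be >= 1 and n_individuals >= 3")
        bad = set(self.models) - set(VALID_MODELS)
        if bad:
            raise ConfigError(f"unknown models: {sorted(bad)}")
        bad = set(self.methods) - set(VALID_METHODS)
        if bad:
            raise ConfigError(f"unknown methods: {sorted(bad)}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.mac_threshold < 0:
            raise ConfigError("mac_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ConfigError(f"cannot parse config {path}{line}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "methods"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        d["methods"] = list(self.methods)
        return d


def replicate_seeds(config: RunConfig) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E9]))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=config.n_replicates)]


def _linear_grid(config: RunConfig):
    """(model, method) combinations: the GLM route is defined for the
    Post-response models 1a/1b only; the mixed route covers all four."""
    grid = []
    for method in config.methods:
        if method not in ("glm", "mixed"):
            continue
        for model in config.models:
            if method == "glm" and model not in ("1a", "1b"):
                continue
            grid.append((model, method))
    return grid


def build_pairs(study: Study):
    """Causal, background and null (nearest-downstream CpG) test pairs."""
    snp_map, cpg_map = study.snp_map, study.cpg_map
    pairs = []
    for role, label in (("main_causal", "causal"), ("background", "background")):
        sub = cpg_map[cpg_map["role"] == role]
        for cpg_id, row in sub.iterrows():
            cat = f"causal:{row['paired_snp']}*{cpg_id}" if role == "main_causal" else "background"
            pairs.append((row["paired_snp"], cpg_id, cat))
    null_pairs = pair_null_markers(snp_map, cpg_map, null_chromosomes=(21, 22))
    for _, row in null_pairs.iterrows():
        pairs.append((row["snp"], row["cpg"], "null"))
    return pairs, null_pairs


def run_replicate(study: Study, pairs, config: RunConfig, seed: int) -> pd.DataFrame:
    """Generate one replicate and run the linear-model test grid on it."""
    rep = generate_replicate(study, seed)
    traits = derive_traits(rep.phenotypes, rep.methylation)
    covariates = rep.phenotypes[["age", "sex"]]
    grid = _linear_grid(config)
    models = sorted({m for m, _ in grid})
    methods = sorted({me for _, me in grid})
    results = run_pair_tests(
        traits,
        covariates,
        rep.genotypes,
        rep.methylation,
        [p for p in pairs if config.include_background or p[2] != "background"],
        models=models,
        methods=methods,
        families=study.pedigree["family"].to_numpy(),
    )
    results = results[[ (m, me) in grid for m, me in zip(results["model"], results["method"]) ]]
    macs = {s: minor_allele_count(rep.genotypes.dosages[s]) for s in results.loc[results["category"] == "null", "snp"].unique()}
    results = results.copy()
    results["mac"] = results["snp"].map(macs)
    results.insert(0, "replicate_seed", seed)
    return results


def _with_mac_category(results: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Duplicate MAC-passing null rows under a filtered category label."""
    nulls = results[(results["category"] == "null") & (results["mac"] > threshold)].copy()
    nulls["category"] = f"null_mac>{threshold}"
    return pd.concat([results, nulls], ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Full pipeline: replicates -> fits -> Table-style outputs on disk.

    Writes ``results.tsv`` (all per-test rows), ``power_table.tsv``,
    ``heritability_table.tsv``, ``forest_ranks.tsv``/``tree_importance.tsv``
    (when requested) and ``manifest.json`` into ``config.out_dir``.
    Per-replicate checkpoints under ``replicates/`` allow resuming.
    """
    out = io.ensure_dir(config.out_dir)
    ckpt_dir = io.ensure_dir(out / "replicates")
    study = default_study(
        seed=config.seed, n_individuals=config.n_individuals, **config.effect_overrides
    )
    io.write_pedigree(study.pedigree, out / "pedigree.ped")
    io.write_snp_map(study.snp_map, out / "snp_map.tsv")
    io.write_cpg_map(study.cpg_map, out / "cpg_map.tsv")
    pairs, null_pairs = build_pairs(study)
    if not config.include_null:
        pairs = [p for p in pairs if p[2] != "null"]

    seeds = replicate_seeds(config)
    all_results = []
    h2_rows = []
    forest_tables = []
    causal_snps = study.snp_map[study.snp_map["role"] == "main_causal"].sort_index().index
    cov_cols = ["age", "age2", "sex"]

    for r, seed in enumerate(seeds):
        ckpt = ckpt_dir / f"rep_{r:04d}.tsv"
        if ckpt.exists():
            all_results.append(io.read_table(ckpt))
            logger.info("replicate %d: loaded checkpoint", r)
        else:
            res = run_replicate(study, pairs, config, seed)
            io.write_table(res, ckpt)
            all_results.append(res)
            logger.info("replicate %d: %d tests", r, len(res))

        rep = generate_replicate(study, seed)
        traits = derive_traits(rep.phenotypes, rep.methylation)
        covs = pd.DataFrame(
            {
                "age": rep.phenotypes["age"],
                "age2": rep.phenotypes["age"] ** 2,
                "sex": (rep.phenotypes["sex"] == 1).astype(float),
            }
        )
        pm = polygenic_h2(traits.post, covs[cov_cols], study.kinship)
        row = {"replicate": r, "h2": pm.h2_, "converged": pm.converged_}
        for s in causal_snps:
            row[f"b2_{s}"] = snp_b2(traits.post, covs[cov_cols], rep.genotypes.dosages[s])
        h2_rows.append(row)

        if "forest" in config.methods:
            feats, resp = forest_features(study, rep, traits)
            fr = fit_random_forest(feats, resp, n_trees=config.n_trees, seed=seed % (2**31))
            forest_tables.append(fr.table)

    results = pd.concat(all_results, ignore_index=True)
    io.write_table(results, out / "results.tsv")

    labelled = _with_mac_category(results, config.mac_threshold)
    power = summarize_replicates(labelled, alpha=config.alpha)
    power["alpha_label"] = f"p<{config.alpha:g}"
    io.write_table(power, out / "power_table.tsv")

    h2_table = pd.DataFrame(h2_rows)
    h2_summary = summarize_estimates(h2_table.drop(columns=["replicate", "converged"]))
    h2_summary.index.name = "quantity"
    h2_summary.reset_index().to_csv(out / "heritability_table.tsv", sep="\t", index=False, float_format="%.6g")

    outputs = {"power": power, "heritability": h2_summary, "results": results}

    if forest_tables:
        ranks = summarize_forest_ranks(forest_tables) if len(forest_tables) > 1 else forest_tables[0]
        ranks.reset_index().to_csv(out / "forest_ranks.tsv", sep="\t", index=False, float_format="%.6g")
        outputs["forest_ranks"] = ranks
    if "tree" in config.methods:
        frames, resps = [], []
        for seed in seeds:
            rep = generate_replicate(study, seed)
            traits = derive_traits(rep.phenotypes, rep.methylation)
            f, y = forest_features(study, rep, traits)
            frames.append(f)
            resps.append(y)
        tree_res = fit_regression_tree(
            pd.concat(frames, ignore_index=True),
            pd.concat(resps, ignore_index=True),
            min_leaf=config.tree_min_leaf,
            partition=(0.4, 0.3, 0.3),
            seed=config.seed,
        )
        io.write_table(tree_res.table, out / "tree_importance.tsv")
        outputs["tree_importance"] = tree_res.table

    manifest = {
        "package": "gxmeth",
        "version": __version__,
        "config": config.to_dict(),
        "replicate_seeds": seeds,
        "n_pairs": {"total": len(pairs), "null": int(len(null_pairs))},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    outputs["manifest"] = manifest
    return outputs


def run_from_manifest(manifest_path) -> dict:
    """Reproduce a run from its manifest alone."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg = dict(manifest["config"])
    cfg["models"] = tuple(cfg["models"])
    cfg["methods"] = tuple(cfg["methods"])
    return run_pipeline(RunConfig(**cfg))


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _load_config(config_path, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    fields = {k: v for k, v in overrides.items() if v is not None}
    if fields:
        cfg = dataclasses.replace(cfg, **fields)
    return cfg


def _run(stage_fn, config_path, **overrides):
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    try:
        cfg = _load_config(config_path, **overrides)
    except ConfigError as exc:
        click.echo(f"config error: {exc}", err=True)
        sys.exit(2)
    try:
        stage_fn(cfg)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        click.echo(f"runtime failure: {exc}", err=True)
        sys.exit(3)
    sys.exit(0)


@click.group()
def cli():
    """Family-based SNP-by-methylation interaction simulation and testing."""


_config_opt = click.option("--config", "config_path", type=click.Path(exists=True), default=None)
_out_opt = click.option("--out", "out_dir", type=click.Path(), default=None)
_seed_opt = click.option("--seed", type=int, default=None)
_reps_opt = click.option("--replicates", "n_replicates", type=int, default=None)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@_reps_opt
def simulate(config_path, out_dir, seed, n_replicates):
    """Write pedigree, marker maps and per-replicate data tables."""

    def stage(cfg: RunConfig):
        out = io.ensure_dir(cfg.out_dir)
        study = default_study(seed=cfg.seed, n_individuals=cfg.n_individuals, **cfg.effect_overrides)
        io.write_pedigree(study.pedigree, out / "pedigree.ped")
        io.write_snp_map(study.snp_map, out / "snp_map.tsv")
        io.write_cpg_map(study.cpg_map, out / "cpg_map.tsv")
        for r, s in enumerate(replicate_seeds(cfg)):
            rep = generate_replicate(study, s)
            io.write_matrix(rep.genotypes.dosages, out / f"dosages_rep{r:04d}.tsv")
            io.write_matrix(rep.methylation.beta_visit2, out / f"meth_v2_rep{r:04d}.tsv")
            io.write_matrix(rep.methylation.beta_visit4, out / f"meth_v4_rep{r:04d}.tsv")
            io.write_phenotypes(rep.phenotypes, out / f"phenotypes_rep{r:04d}.tsv")

    _run(stage, config_path, out_dir=out_dir, seed=seed, n_replicates=n_replicates)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@_reps_opt
@click.option("--models", default=None, help="comma-separated subset of 1a,1b,2a,2b")
@click.option("--methods", default=None, help="comma-separated subset of glm,mixed,tree,forest")
def fit(config_path, out_dir, seed, n_replicates, models, methods):
    """Run the model x method grid and write per-test results."""
    _run(
        run_pipeline,
        config_path,
        out_dir=out_dir,
        seed=seed,
        n_replicates=n_replicates,
        models=tuple(models.split(",")) if models else None,
        methods=tuple(methods.split(",")) if methods else None,
    )


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@_reps_opt
@click.option("--alpha", type=float, default=None)
@click.option("--mac", "mac_threshold", type=int, default=None)
def evaluate(config_path, out_dir, seed, n_replicates, alpha, mac_threshold):
    """Aggregate an existing results table into a power/Type-I table."""

    def stage(cfg: RunConfig):
        out = Path(cfg.out_dir)
        results = io.read_table(out / "results.tsv")
        labelled = _with_mac_category(results, cfg.mac_threshold)
        power = summarize_replicates(labelled, alpha=cfg.alpha)
        power["alpha_label"] = f"p<{cfg.alpha:g}"
        io.write_table(power, out / "power_table.tsv")

    _run(stage, config_path, out_dir=out_dir, seed=seed, n_replicates=n_replicates,
         alpha=alpha, mac_threshold=mac_threshold)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@_reps_opt
def heritability(config_path, out_dir, seed, n_replicates):
    """Polygenic h2 and per-SNP b2 summary across replicates."""

    def stage(cfg: RunConfig):
        cfg2 = dataclasses.replace(cfg, methods=("glm",), models=("1a",),
                                   include_background=False, include_null=False)
        run_pipeline(cfg2)

    _run(stage, config_path, out_dir=out_dir, seed=seed, n_replicates=n_replicates)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@_reps_opt
@click.option("--trees", "n_trees", type=int, default=None)
def trees(config_path, out_dir, seed, n_replicates, n_trees):
    """Regression-tree and random-forest importance tables."""

    def stage(cfg: RunConfig):
        cfg2 = dataclasses.replace(cfg, methods=("tree", "forest"),
                                   include_background=False, include_null=False)
        run_pipeline(cfg2)

    _run(stage, config_path, out_dir=out_dir, seed=seed, n_replicates=n_replicates,
         n_trees=n_trees)


@cli.command(name="all")
@_config_opt
@_out_opt
@_seed_opt
@_reps_opt
def run_all(config_path, out_dir, seed, n_replicates):
    """Full pipeline: simulate, fit, evaluate, heritability and trees."""

    def stage(cfg: RunConfig):
        cfg2 = dataclasses.replace(cfg, methods=tuple(set(cfg.methods) | {"forest"}))
        run_pipeline(cfg2)

    _run(stage, config_path, out_dir=out_dir, seed=seed, n_replicates=n_replicates)
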