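"""Derived traits and design matrices for the four interaction models.

Responses and regressors (natural logs throughout):

* ``Pre``  = mean(log TG1, log TG2), ``Post`` = mean(log TG3, log TG4)
* ``deltaTG`` = Post - Pre; ``deltaCpG`` = beta(visit 4) - beta(visit 2)
* model 1a: Post ~ SNP + (1-CpG) + SNP*(1-CpG) + age + age^2 + sex + Pre
* model 1b: Post ~ SNP*(1-CpG) + age + age^2 + sex + Pre
* model 2a: deltaTG ~ SNP + deltaCpG + SNP*deltaCpG + age + age^2 + sex
* model 2b: deltaTG ~ SNP*deltaCpG + age + age^2 + sex

Methylation enters models 1a/1b as (1 - beta-value): lower methylation means
higher expression, so the expression-scale regressor is the unmethylated
fraction. Sex is coded 0/1 (female/male); age is in years, uncentred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import MethylationSet

MODEL_IDS = ("1a", "1b", "2a", "2b")

#: design columns per model, in order (intercept first)
MODEL_COLUMNS = {
    "1a": ["intercept", "snp", "one_minus_cpg", "snp_x_one_minus_cpg", "age", "age2", "sex", "pre"],
    "1b": ["intercept", "snp_x_one_minus_cpg", "age", "age2", "sex", "pre"],
    "2a": ["intercept", "snp", "delta_cpg", "snp_x_delta_cpg", "age", "age2", "sex"],
    "2b": ["intercept", "snp_x_delta_cpg", "age", "age2", "sex"],
}

INTERACTION_COLUMN = {
    "1a": "snp_x_one_minus_cpg",
    "1b": "snp_x_one_minus_cpg",
    "2a": "snp_x_delta_cpg",
    "2b": "snp_x_delta_cpg",
}


@dataclass
class DerivedTraits:
    pre: pd.Series
    post: pd.Series
    delta_tg: pd.Series
    delta_cpg: pd.DataFrame  # individuals x CpGs


@dataclass
class DesignMatrix:
    X: pd.DataFrame
    response: pd.Series
    model_id: str
    response_label: str
    interaction_column: str


def derive_traits(phenotypes: pd.DataFrame, methylation: MethylationSet) -> DerivedTraits:
    """Compute Pre, Post, deltaTG and per-CpG deltaCpG from raw tables."""
    tg = phenotypes[["TG1", "TG2", "TG3", "TG4"]]
    bad = tg.index[(tg <= 0).any(axis=1)]
    if len(bad):
        raise ValueError(f"non-positive TG values for individuals {list(bad[:5])}")
    log_tg = np.log(tg)
    pre = (log_tg["TG1"] + log_tg["TG2"]) / 2.0
    post = (log_tg["TG3"] + log_tg["TG4"]) / 2.0
    return DerivedTraits(
        pre=pre.rename("pre"),
        post=post.rename("post"),
        delta_tg=(post - pre).rename("delta_tg"),
        delta_cpg=methylation.beta_visit4 - methylation.beta_visit2,
    )


def build_design(
    model_id: str,
    snp_dosage: pd.Series | np.ndarray,
    cpg_values: pd.Series | np.ndarray,
    traits: DerivedTraits,
    covariates: pd.DataFrame,
) -> DesignMatrix:
    """Assemble the named design matrix and response for one SNP-CpG pair.

    ``cpg_values`` is the raw beta-value for models 1a/1b (it is converted to
    1 - beta internally) and the visit-4 minus visit-2 difference for models
    2a/2b. ``covariates`` must provide ``age`` and ``sex`` columns; sex may
    be given as 1/2 (male/female) or already as 0/1 (male=1).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")

    index = traits.post.index
    snp = np.asarray(snp_dosage, dtype=float)
    cpg = np.asarray(cpg_values, dtype=float)
    age = covariates["age"].to_numpy(float)
    sex_raw = covariates["sex"].to_numpy()
    sex = (sex_raw == 1).astype(float) if set(np.unique(sex_raw)) <= {1, 2} else sex_raw.astype(float)

    meth = 1.0 - cpg if model_id in ("1a", "1b") else cpg
    cols = {
        "intercept": np.ones(len(index)),
        "snp": snp,
        ("one_minus_cpg" if model_id in ("1a", "1b") else "delta_cpg"): meth,
        INTERACTION_COLUMN[model_id]: snp * meth,
        "age": age,
        "age2": age**2,
        "sex": sex,
        "pre": traits.pre.to_numpy(),
    }
    names = MODEL_COLUMNS[model_id]
    X = pd.DataFrame({c: cols[c] for c in names}, index=index)
    response = traits.post if model_id in ("1a", "1b") else traits.delta_tg
    return DesignMatrix(
        X=X,
        response=response,
        model_id=model_id,
        response_label="post" if model_id in ("1a", "1b") else "delta_tg",
        interaction_column=INTERACTION_COLUMN[model_id],
    )
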