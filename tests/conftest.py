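import numpy as np
import pandas as pd
import pytest

import gxmeth as gx


@pytest.fixture(scope="session")
def study():
    """Default 680-individual study: families, kinship, maps, calibrated effects."""
    return gx.default_study(seed=11)


@pytest.fixture(scope="session")
def replicate(study):
    return gx.generate_replicate(study, 123)


@pytest.fixture(scope="session")
def traits(replicate):
    return gx.derive_traits(replicate.phenotypes, replicate.methylation)


@pytest.fixture(scope="session")
def covariates(replicate):
    return replicate.phenotypes[["age", "sex"]]


@pytest.fixture(scope="session")
def families(study):
    return study.pedigree["family"].to_numpy()


def founder_pedigree(n: int) -> pd.DataFrame:
    """n unrelated founders arranged as couples (for moment checks)."""
    rows = []
    for i in range(n // 2):
        fam = f"f{i:05d}"
        rows.append((fam, f"{fam}a", "0", "0", 1, 50.0))
        rows.append((fam, f"{fam}b", "0", "0", 2, 50.0))
    return pd.DataFrame(rows, columns=["family", "individual", "father", "mother", "sex", "age"])


@pytest.fixture(scope="session")
def toy_pedigree():
    """Three generations, eight members, one family.

    A,B founders -> children C,D; E founder marries C -> children F,G,H.
    """
    rows = [
        ("t1", "A", "0", "0", 1, 60.0),
        ("t1", "B", "0", "0", 2, 58.0),
        ("t1", "C", "A", "B", 1, 35.0),
        ("t1", "D", "A", "B", 2, 33.0),
        ("t1", "E", "0", "0", 2, 34.0),
        ("t1", "F", "C", "E", 1, 10.0),
        ("t1", "G", "C", "E", 2, 8.0),
        ("t1", "H", "C", "E", 1, 6.0),
    ]
    return pd.DataFrame(rows, columns=["family", "individual", "father", "mother", "sex", "age"])


def single_pair_maps(maf=0.3, mean=0.6, concentration=10.0):
    snp_map = pd.DataFrame(
        {"chromosome": [1], "position": [100], "maf": [maf], "role": ["main_causal"]},
        index=pd.Index(["s1"], name="snp"),
    )
    cpg_map = pd.DataFrame(
        {
            "chromosome": [1],
            "position": [200],
            "role": ["main_causal"],
            "paired_snp": ["s1"],
            "mean": [mean],
            "concentration": [concentration],
        },
        index=pd.Index(["c1"], name="cpg"),
    )
    return snp_map, cpg_map


def make_effects(n_causal=1, n_background=0, **kwargs):
    """EffectConfig with all effects zero unless overridden."""
    base = dict(
        beta1=np.zeros(n_causal),
        beta2=np.zeros(n_causal),
        beta3=np.zeros(n_causal),
        beta_background=np.zeros(n_background),
        beta_age=0.0,
        beta_age2=0.0,
        beta_sex=0.0,
        gamma_pre=0.0,
        sigma2_poly=0.0,
        sigma2_e=0.05,
    )
    base.update(kwargs)
    return gx.EffectConfig(**base)
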