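"""Plain-text readers/writers for pedigrees, marker maps, matrices and tables.

Pedigrees use a LINKAGE/PLINK pre-makeped style layout (whitespace-delimited:
family, individual, father, mother, sex 1/2) extended with an age column and
a header line. Matrices (dosages, beta-values) are tab-delimited with a
header row of marker ids and one row per individual. Every writer's output
round-trips through its reader with value equality.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

PED_COLUMNS = ["family", "individual", "father", "mother", "sex", "age"]


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree[PED_COLUMNS].to_csv(path, sep=" ", index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep=r"\s+", dtype={"family": str, "individual": str, "father": str, "mother": str})
    ped["sex"] = ped["sex"].astype(int)
    ped["age"] = ped["age"].astype(float)
    return ped[PED_COLUMNS]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="individual", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual")


def write_snp_map(snp_map: pd.DataFrame, path) -> None:
    snp_map.to_csv(path, sep="\t", index_label="snp", float_format="%.10g")


def read_snp_map(path) -> pd.DataFrame:
    # keep_default_na: the role label "null" is data, not a missing value
    return pd.read_csv(path, sep="\t", index_col="snp", keep_default_na=False, na_values=[""])


def write_cpg_map(cpg_map: pd.DataFrame, path) -> None:
    cpg_map.to_csv(path, sep="\t", index_label="cpg", float_format="%.10g")


def read_cpg_map(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", index_col="cpg", keep_default_na=False, na_values=[""])
    out["paired_snp"] = out["paired_snp"].where(out["paired_snp"].notna(), None)
    return out


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="individual", float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual")


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
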