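"""Empirical-null SNP-CpG pairs on effect-free chromosomes.

Null pairs are built by walking each effect-free chromosome's SNPs in
ascending base-pair position and pairing each SNP with the nearest CpG at a
strictly higher position, each CpG used at most once (SNPs with no available
downstream CpG remain unpaired). Pairs are optionally filtered on the SNP's
minor allele count, MAC = min(sum(dosage), 2n - sum(dosage)), with a strict
``MAC > threshold`` rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pair_null_markers(
    snp_map: pd.DataFrame,
    cpg_map: pd.DataFrame,
    null_chromosomes=(21, 22),
    max_distance: int | None = None,
) -> pd.DataFrame:
    """Nearest-downstream-CpG pairing on the given chromosomes.

    Returns a DataFrame with columns ``chromosome, snp, snp_pos, cpg,
    cpg_pos`` (one row per pair); empty maps give an empty frame.
    """
    rows = []
    for chrom in null_chromosomes:
        snps = snp_map[snp_map["chromosome"] == chrom].sort_values("position")
        cpgs = cpg_map[cpg_map["chromosome"] == chrom].sort_values("position")
        cpg_pos = cpgs["position"].to_numpy()
        cpg_ids = cpgs.index.to_numpy()
        j = 0  # next unused CpG; assignments are monotone in position
        for snp_id, s_pos in zip(snps.index, snps["position"]):
            while j < len(cpg_pos) and cpg_pos[j] <= s_pos:
                j += 1
            if j >= len(cpg_pos):
                break
            if max_distance is not None and cpg_pos[j] - s_pos > max_distance:
                continue
            rows.append((chrom, snp_id, int(s_pos), cpg_ids[j], int(cpg_pos[j])))
            j += 1
    return pd.DataFrame(rows, columns=["chromosome", "snp", "snp_pos", "cpg", "cpg_pos"])


def minor_allele_count(dosages) -> int:
    """MAC = min(sum d, 2n - sum d) for a dosage vector with entries in {0,1,2}."""
    d = np.asarray(dosages)
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError("dosages must take values in {0, 1, 2}")
    total = int(d.sum())
    return min(total, 2 * len(d) - total)


def apply_mac_filter(pairs: pd.DataFrame, genotypes, threshold: int = 50) -> pd.DataFrame:
    """Retain pairs whose SNP has MAC strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    dosages = genotypes.dosages if hasattr(genotypes, "dosages") else genotypes
    macs = pairs["snp"].map(lambda s: minor_allele_count(dosages[s]))
    out = pairs.loc[macs > threshold].copy()
    out["mac"] = macs[macs > threshold]
    return out
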