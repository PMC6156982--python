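"""Power and Type-I error aggregation across simulation replicates.

Power at level alpha is the fraction of tests with p strictly below alpha.
The replicate summary mirrors the shape of a power table: one row per
(category x model x method) with the number of applicable tests and the
proportion significant; tests flagged not-applicable (monomorphic SNP,
constant CpG) are excluded from the denominator and counted separately.
No multiple-testing correction is applied: calibration is at nominal alpha.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def estimate_power(pvalues, alpha: float = 0.05) -> float:
    """Fraction of p-values strictly below alpha."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no applicable p-values: power is undefined")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.mean(p < alpha))


def summarize_replicates(
    results: pd.DataFrame, alpha: float = 0.05, decimals: int | None = 2
) -> pd.DataFrame:
    """Aggregate a batch-test table into a power/Type-I table.

    ``results`` needs columns ``category, model, method, p, applicable``
    (the output of ``association.run_pair_tests``, concatenated over
    replicates). Returns one row per (category, model, method) with
    ``n_tests`` (applicable and converged), ``n_na`` and ``proportion``.
    """
    rows = []
    for (category, model, method), grp in results.groupby(
        ["category", "model", "method"], sort=True
    ):
        ok = grp[grp["applicable"] & grp["p"].notna()]
        n_na = len(grp) - len(ok)
        if len(ok) == 0:
            logger.warning("category %s (%s/%s): no applicable tests; omitted", category, model, method)
            continue
        prop = estimate_power(ok["p"], alpha)
        if decimals is not None:
            prop = round(prop, decimals)
        rows.append(
            {
                "category": category,
                "model": model,
                "method": method,
                "n_tests": len(ok),
                "n_na": n_na,
                "proportion": prop,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)
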