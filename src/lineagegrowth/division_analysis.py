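"""Division asymmetry, mother-to-daughter growth-rate changes, and lambda_bar memory.

Asymmetry is measured against half the mother's division mass: a daughter
born with exactly Mdiv/2 scores 0%.  The mother-to-daughter change in the
averaged growth rate is reported as an absolute percent change with the
mother as baseline.  Generation-scale memory of lambda_bar is quantified by
the plug-in autocorrelation at integer generation lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .acf import AcfResult, autocorrelation
from .lineage_io import Lineage, LineageSet

__all__ = [
    "DivisionRecord",
    "division_records",
    "asymmetry_growth_regression",
    "generation_acf",
    "mean_generation_acf",
]


@dataclass
class DivisionRecord:
    """One mother -> retained-daughter division."""

    lineage_id: str
    mother_index: int
    daughter_index: int
    asymmetry_pct: float        # 100 |Mb_daughter - Mdiv_mother/2| / (Mdiv_mother/2)
    lambda_change_pct: float    # 100 |lb_daughter - lb_mother| / lb_mother
    asymmetry_signed_pct: float
    lambda_change_signed_pct: float


def division_records(lineage: Lineage) -> list[DivisionRecord]:
    """One record per adjacent pair of full cycles."""
    full = lineage.full_records
    out = []
    for mom, dau in zip(full, full[1:]):
        if dau.index_in_lineage != mom.index_in_lineage + 1:
            continue
        half = mom.division_mass / 2.0
        asym = 100.0 * (dau.birth_mass - half) / half
        dlam = 100.0 * (dau.lambda_bar - mom.lambda_bar) / mom.lambda_bar
        out.append(DivisionRecord(
            lineage_id=lineage.lineage_id,
            mother_index=mom.index_in_lineage,
            daughter_index=dau.index_in_lineage,
            asymmetry_pct=abs(asym), lambda_change_pct=abs(dlam),
            asymmetry_signed_pct=asym, lambda_change_signed_pct=dlam))
    if not out:
        warnings.warn(f"lineage {lineage.lineage_id!r}: no mother-daughter pairs")
    return out


def asymmetry_growth_regression(records: list[DivisionRecord],
                                signed: bool = False) -> dict:
    """Regression of the lambda_bar change on division asymmetry across pairs.

    Returns the Pearson correlation with its (ANOVA-equivalent) p-value plus
    the OLS slope.  ``signed`` uses signed deviations instead of magnitudes.
    """
    if len(records) < 3:
        raise ValueError("need >=3 division records")
    if signed:
        x = np.array([r.asymmetry_signed_pct for r in records])
        y = np.array([r.lambda_change_signed_pct for r in records])
    else:
        x = np.array([r.asymmetry_pct for r in records])
        y = np.array([r.lambda_change_pct for r in records])
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("degenerate variance in regression inputs")
    res = stats.linregress(x, y)
    return {"pearson_r": float(res.rvalue), "p": float(res.pvalue),
            "slope": float(res.slope), "n": len(records)}


def generation_acf(lineage: Lineage, max_lag: int = 6) -> AcfResult:
    """Autocorrelation of the lambda_bar sequence at integer generation lags."""
    lb = lineage.lambda_bars()
    if lb.size <= 1:
        raise ValueError("need >1 full cycles")
    return autocorrelation(lb, max_lag, xcal=1.0)


def mean_generation_acf(lineages: LineageSet, max_lag: int = 6,
                        n_longest: int = 10) -> pd.DataFrame:
    """Cross-lineage mean +/- SEM of the generation ACF for the longest lineages.

    Also reports a one-sample t test of the per-lineage coefficients against
    zero at each lag.
    """
    ranked = sorted(lineages, key=lambda ln: ln.n_full, reverse=True)[:n_longest]
    acfs = []
    for ln in ranked:
        try:
            acfs.append(generation_acf(ln, max_lag).coefficients)
        except ValueError:
            warnings.warn(f"lineage {ln.lineage_id!r} too short for ACF; skipped")
    if len(acfs) < 2:
        raise ValueError("need >=2 lineages with usable ACFs")
    width = max(a.size for a in acfs)
    mat = np.full((len(acfs), width), np.nan)
    for i, a in enumerate(acfs):
        mat[i, : a.size] = a
    rows = []
    for k in range(width):
        col = mat[:, k]
        col = col[np.isfinite(col)]
        t, p = (np.nan, np.nan) if k == 0 or col.size < 2 else stats.ttest_1samp(col, 0.0)
        rows.append({"lag": k, "mean": float(col.mean()),
                     "sem": float(col.std(ddof=1) / np.sqrt(col.size)) if col.size > 1 else np.nan,
                     "n": int(col.size), "p_vs_0": float(p) if np.isfinite(p) else np.nan})
    return pd.DataFrame(rows)
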