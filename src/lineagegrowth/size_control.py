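"""Cell-size homeostasis estimators for ancestral lineages.

The autoregressive framework relates a cell's birth mass M0 to the next
generation through a division-scale final mass Mf:

    Mf = 2 (1 - a) M0 + 2 a E[M0] + xi_M,

with a = 0 (timer), 0.5 (adder), 1 (sizer).  Only the retained daughter is
observed here, so Mf is taken as twice the daughter's birth mass (the
division-scale mass including partitioning noise).  The covariance-based
twin of a is alpha = -cov(x, lambda_bar * tau) / var(x) with x = ln M0, and
the growth-rate share of size control is alpha_lambda = -beta_{x,lambda} E[tau]
with beta_{x,lambda} = cov(x, lambda_bar)/var(x): alpha_lambda near zero means
homeostasis acts through the generation time, not through growth-rate
modulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lineage_io import Lineage

__all__ = [
    "SizeControlStats",
    "fit_autoregressive_a",
    "alpha_covariance",
    "beta_x_lambda",
    "alpha_lambda",
    "birth_size_correlations",
    "size_control_stats",
    "pooled_weighted_summary",
]


def _mother_daughter_birth_masses(lineage: Lineage) -> tuple[np.ndarray, np.ndarray]:
    full = lineage.full_records
    pairs = [(m.birth_mass, d.birth_mass) for m, d in zip(full, full[1:])
             if d.index_in_lineage == m.index_in_lineage + 1]
    if len(pairs) < 3:
        raise ValueError("need >=3 consecutive mother-daughter pairs of full cycles")
    arr = np.asarray(pairs)
    return arr[:, 0], arr[:, 1]


def fit_autoregressive_a(lineage: Lineage) -> float:
    """Size-control strength a from the autoregressive mass map.

    Regresses Mf = 2 x (retained daughter's birth mass) on the mother's birth
    mass M0 and returns a = 1 - slope/2.  Slope 0 -> sizer (a=1), slope 1 ->
    adder (a=0.5), slope 2 -> timer (a=0).
    """
    m0, daughter = _mother_daughter_birth_masses(lineage)
    if np.var(m0) == 0:
        raise ValueError("var(M0) = 0; slope undefined")
    slope = stats.linregress(m0, 2.0 * daughter).slope
    return float(1.0 - slope / 2.0)


def alpha_covariance(lineage: Lineage) -> float:
    """alpha = -cov(x, lambda_bar * tau) / var(x), x = ln birth mass.

    Small-noise equivalent of the autoregressive a, computed per cycle from
    lambda_bar * tau = ln(M_div / M_birth).
    """
    full = lineage.full_records
    if len(full) < 3:
        raise ValueError("need >=3 full cycles")
    x = np.log([r.birth_mass for r in full])
    y = np.array([r.lambda_bar * r.tau for r in full])
    vx = np.var(x, ddof=1)
    if vx == 0:
        raise ValueError("var(ln M0) = 0")
    return float(-np.cov(x, y, ddof=1)[0, 1] / vx)


def beta_x_lambda(lineage: Lineage) -> float:
    """Regression coefficient beta = cov(x, lambda_bar)/var(x), 1/h per log-mass."""
    full = lineage.full_records
    if len(full) < 3:
        raise ValueError("need >=3 full cycles")
    x = np.log([r.birth_mass for r in full])
    lb = np.array([r.lambda_bar for r in full])
    vx = np.var(x, ddof=1)
    if vx == 0:
        raise ValueError("var(ln M0) = 0")
    return float(np.cov(x, lb, ddof=1)[0, 1] / vx)


def alpha_lambda(lineage: Lineage) -> float:
    """Growth-rate share of size control: alpha_lambda = -beta_{x,lambda} E[tau]."""
    full = lineage.full_records
    taus = np.array([r.tau for r in full])
    return float(-beta_x_lambda(lineage) * taus.mean())


def birth_size_correlations(lineage: Lineage) -> pd.DataFrame:
    """OLS of tau, lambda_bar and added mass on birth mass (slope, R^2, p)."""
    full = lineage.full_records
    if len(full) < 3:
        raise ValueError("need >=3 full cycles")
    m0 = np.array([r.birth_mass for r in full])
    targets = {
        "tau": np.array([r.tau for r in full]),
        "lambda_bar": np.array([r.lambda_bar for r in full]),
        "added_mass": np.array([r.added_mass for r in full]),
    }
    rows = []
    for name, y in targets.items():
        res = stats.linregress(m0, y)
        rows.append({"response": name, "slope": res.slope, "r2": res.rvalue ** 2,
                     "p": res.pvalue, "n": len(full)})
    return pd.DataFrame(rows)


@dataclass
class SizeControlStats:
    lineage_id: str
    n_cells: int
    a_autoregressive: float
    alpha: float
    beta_x_lambda: float
    alpha_lambda: float
    slope_birth_tau: float
    r2_birth_tau: float
    slope_birth_lambda: float
    r2_birth_lambda: float
    added_mass_slope: float
    added_mass_p: float
    flag_outside_range: bool     # a or alpha outside the plausible [0, 2] window

    def __post_init__(self) -> None:
        # alpha_lambda = -beta * E[tau] holds by construction; keep the flag honest
        pass


def size_control_stats(lineage: Lineage) -> SizeControlStats:
    """All per-lineage size-control statistics in one record."""
    corr = birth_size_correlations(lineage).set_index("response")
    a = fit_autoregressive_a(lineage)
    al = alpha_covariance(lineage)
    return SizeControlStats(
        lineage_id=lineage.lineage_id,
        n_cells=lineage.n_full,
        a_autoregressive=a,
        alpha=al,
        beta_x_lambda=beta_x_lambda(lineage),
        alpha_lambda=alpha_lambda(lineage),
        slope_birth_tau=float(corr.loc["tau", "slope"]),
        r2_birth_tau=float(corr.loc["tau", "r2"]),
        slope_birth_lambda=float(corr.loc["lambda_bar", "slope"]),
        r2_birth_lambda=float(corr.loc["lambda_bar", "r2"]),
        added_mass_slope=float(corr.loc["added_mass", "slope"]),
        added_mass_p=float(corr.loc["added_mass", "p"]),
        flag_outside_range=bool(not (0.0 <= a <= 2.0) or not (0.0 <= al <= 2.0)),
    )


def pooled_weighted_summary(stats_list: list[SizeControlStats], min_cells: int = 8,
                            weighting: str = "n_cells") -> pd.DataFrame:
    """Lineage-length-weighted pooled mean +/- SE per statistic.

    Lineages with fewer than ``min_cells`` full cycles are excluded.  The SE is
    the weighted SD over lineages divided by sqrt(N lineages); the p-value is a
    one-sample t test of the per-lineage values against 0.
    """
    kept = [s for s in stats_list if s.n_cells >= min_cells]
    if len(kept) < 2:
        raise ValueError("fewer than 2 lineages pass min_cells")
    if weighting == "n_cells":
        w = np.array([s.n_cells for s in kept], dtype=float)
    elif weighting == "equal":
        w = np.ones(len(kept))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    fields = ["a_autoregressive", "alpha", "beta_x_lambda", "alpha_lambda",
              "slope_birth_tau", "r2_birth_tau", "slope_birth_lambda",
              "r2_birth_lambda", "added_mass_slope"]
    rows = []
    n = len(kept)
    for f in fields:
        x = np.array([getattr(s, f) for s in kept])
        mean = float(np.sum(w * x))
        wsd = float(np.sqrt(np.sum(w * (x - mean) ** 2) * n / (n - 1)))
        t, p = stats.ttest_1samp(x, 0.0)
        rows.append({"statistic": f, "mean": mean, "se": wsd / np.sqrt(n),
                     "n_lineages": n, "t_vs_0": float(t), "p_vs_0": float(p)})
    return pd.DataFrame(rows)
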