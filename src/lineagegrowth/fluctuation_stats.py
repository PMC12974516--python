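"""Statistics of the isolated growth-rate fluctuations lambda_flucs.

Covers the autocorrelation/relaxation-time analysis, the age-resolved
fluctuation magnitude, regressions of fluctuation magnitude on cell-cycle
covariates, the within/between-cell mean-squared-displacement (MSD) suite,
and the scaling of var(lambda_bar_t) with cell age used to discriminate
continuous from division-localized growth noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .acf import AcfResult, autocorrelation
from .lineage_io import Lineage

__all__ = [
    "FlucSeries",
    "MsdResult",
    "MagnitudeByAge",
    "VarScalingResult",
    "flucseries_from_decomposition",
    "acf_timeseries",
    "relaxation_time",
    "magnitude_by_age",
    "magnitude_regressions",
    "msd_suite",
    "per_cell_integral",
    "var_time_averaged_growth",
    "var_time_averaged_growth_raw",
    "loglog_slope",
]


@dataclass
class FlucSeries:
    """Posterior-mean (or latent) lambda_flucs samples with cell bookkeeping.

    ``cell_index`` holds 0-based cell labels per point; ``cell_t0`` and
    ``cell_tau`` give each cell's birth time and full generation time on the
    same time axis (the series itself may stop short of division where the
    mitotic window was excised).
    """

    lineage_id: str
    times: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None
    cell_index: np.ndarray
    cell_t0: np.ndarray
    cell_tau: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.cell_t0)

    def relative_age(self) -> np.ndarray:
        cid = self.cell_index.astype(int)
        return (self.times - self.cell_t0[cid]) / self.cell_tau[cid]


def flucseries_from_decomposition(decomp) -> FlucSeries:
    """Build a :class:`FlucSeries` from a fitted GP decomposition."""
    ins = decomp.inputs
    return FlucSeries(lineage_id=ins.lineage_id, times=ins.t,
                      values=decomp.lambda_flucs, sd=decomp.lambda_flucs_sd,
                      cell_index=ins.cell_index, cell_t0=ins.cell_birth_times,
                      cell_tau=ins.cell_taus)


def acf_timeseries(series: FlucSeries, max_lag: float = 8.0) -> AcfResult:
    """ACF of lambda_flucs at integer sample lags, reported against k * xcal.

    xcal = median(delta t).  Gaps (e.g. excised mitoses) larger than 3 xcal are
    tolerated under the lag-in-steps convention; a warning notes how many.
    """
    if series.times.size < 100:
        raise ValueError("need >=100 points for a stable ACF")
    dts = np.diff(series.times)
    xcal = float(np.median(dts))
    n_gaps = int(np.sum(dts > 3 * xcal))
    if n_gaps:
        warnings.warn(f"{n_gaps} gaps exceed 3*xcal; lags counted in steps")
    return autocorrelation(series.values, int(round(max_lag / xcal)), xcal=xcal)


def relaxation_time(acf: AcfResult, fit_window: float | None = None,
                    threshold: float = 0.2, min_lag: float = 0.0) -> float:
    """Relaxation time 1/gamma from the initial exponential decay of the ACF.

    Least-squares fit of ln ACF versus lag over the initial contiguous run of
    lags where ACF > ``threshold`` (optionally limited to ``fit_window``
    hours).  The lag-0 point (ln ACF = 0) anchors the fit unless ``min_lag``
    excludes the shortest lags — useful when the series carries a short-lag
    artifact (e.g. the noise-driven wiggle of a posterior mean), which would
    otherwise steepen the apparent decay.
    """
    c = acf.coefficients
    if c.size < 2 or c[1] <= 0:
        raise ValueError("ACF must be positive at lag 1 to fit a decay")
    k = 1
    while k < c.size and c[k] > threshold and (
            fit_window is None or acf.lag_times[k] <= fit_window):
        k += 1
    if k < 2:
        k = 2  # at least lags {0, 1}
    keep = acf.lag_times[:k] >= min_lag
    if keep.sum() < 2:
        keep = np.ones(k, dtype=bool)
    tt = acf.lag_times[:k][keep]
    slope = np.polyfit(tt, np.log(c[:k][keep]), 1)[0]
    if slope >= 0:
        raise ValueError("ACF does not decay over the fit window")
    return float(-1.0 / slope)


@dataclass
class MagnitudeByAge:
    bin_edges: np.ndarray
    sd_per_bin: np.ndarray          # pooled SD of lambda_flucs in each age bin
    n_per_bin: np.ndarray
    anova_f: float
    anova_p: float                  # one-way ANOVA over per-cell SDs across bins


def magnitude_by_age(series: FlucSeries, n_bins: int = 5,
                     min_points: int = 3) -> MagnitudeByAge:
    """Fluctuation magnitude (SD) by relative-age bin, with one-way ANOVA.

    The ANOVA compares per-cell SDs of lambda_flucs across age bins, so cells
    are the replication unit.  Bins holding fewer than two per-cell SDs are
    merged into their left neighbour with a warning.
    """
    u = series.relative_age()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    edges[-1] = max(edges[-1], u.max() + 1e-9)
    which = np.clip(np.digitize(u, edges) - 1, 0, n_bins - 1)
    groups: list[list[float]] = [[] for _ in range(n_bins)]
    for cid in np.unique(series.cell_index):
        sel = series.cell_index == cid
        for b in range(n_bins):
            v = series.values[sel & (which == b)]
            if v.size >= min_points:
                groups[b].append(float(v.std(ddof=1)))
    merged: list[list[float]] = []
    for b, g in enumerate(groups):
        if len(g) < 2 and merged:
            warnings.warn(f"age bin {b} underpopulated; merged with neighbour")
            merged[-1].extend(g)
        else:
            merged.append(list(g))
    if len(merged) < 3:
        raise ValueError("fewer than 3 populated age bins")
    f, p = stats.f_oneway(*merged)
    sd_bin = np.array([series.values[which == b].std(ddof=1) if np.sum(which == b) > 1
                       else np.nan for b in range(n_bins)])
    return MagnitudeByAge(bin_edges=edges,
                          sd_per_bin=sd_bin,
                          n_per_bin=np.bincount(which, minlength=n_bins),
                          anova_f=float(f), anova_p=float(p))


def magnitude_regressions(series: FlucSeries, lineage: Lineage) -> pd.DataFrame:
    """Per-cell fluctuation SD regressed on birth mass, division mass, added mass, tau."""
    full = lineage.full_records
    if len(full) < 5:
        raise ValueError("need >=5 full cycles")
    sds, rows = [], []
    for cid in range(len(full)):
        v = series.values[series.cell_index == cid]
        sds.append(v.std(ddof=1) if v.size > 2 else np.nan)
    sds = np.asarray(sds)
    ok = np.isfinite(sds)
    covs = {
        "birth_mass": np.array([r.birth_mass for r in full]),
        "division_mass": np.array([r.division_mass for r in full]),
        "added_mass": np.array([r.added_mass for r in full]),
        "tau": np.array([r.tau for r in full]),
    }
    for name, x in covs.items():
        if np.var(x[ok]) == 0:
            rows.append({"covariate": name, "slope": 0.0, "r2": 0.0,
                         "p": np.nan, "n": int(ok.sum())})
            continue
        res = stats.linregress(x[ok], sds[ok])
        rows.append({"covariate": name, "slope": res.slope, "r2": res.rvalue ** 2,
                     "p": res.pvalue, "n": int(ok.sum())})
    return pd.DataFrame(rows)


@dataclass
class MsdResult:
    lags: np.ndarray            # hours (k * xcal)
    msd: np.ndarray             # pooled MSD over all pairs
    msd_within: np.ndarray      # pairs confined to single cells
    msd_between: np.ndarray     # pairs spanning exactly one consecutive-cell boundary
    n: np.ndarray
    n_within: np.ndarray
    n_between: np.ndarray
    k_cells: int
    avg_window: float
    ratio: float                # <MSD_between> / (<MSD_between> + <MSD_within>)


def msd_suite(series: FlucSeries, max_lag: float = 4.0,
              avg_window: float = 4.0) -> MsdResult:
    """Mean-squared displacement of lambda_flucs, split within/between cells.

    Lags are counted in sample steps and mapped to hours by xcal =
    median(delta t).  Within-cell terms average per cell before averaging over
    cells; between-cell terms use consecutive-cell pairs only (each cell has at
    most one successor in a sequential lineage).  The ratio averages lags in
    (0, ``avg_window``] hours.
    """
    v = series.values
    cid = series.cell_index.astype(int)
    xcal = float(np.median(np.diff(series.times)))
    kmax = int(round(max_lag / xcal))
    if kmax < 1:
        raise ValueError("max_lag shorter than one sampling step")
    n_cells = int(np.unique(cid).size)
    lags = np.arange(1, kmax + 1) * xcal
    msd = np.full(kmax, np.nan)
    msd_w = np.full(kmax, np.nan)
    msd_b = np.full(kmax, np.nan)
    n_all = np.zeros(kmax, dtype=int)
    n_w = np.zeros(kmax, dtype=int)
    n_b = np.zeros(kmax, dtype=int)
    for k in range(1, kmax + 1):
        d2 = (v[k:] - v[:-k]) ** 2
        c1, c2 = cid[:-k], cid[k:]
        if d2.size == 0:
            break
        msd[k - 1] = d2.mean()
        n_all[k - 1] = d2.size
        same = c1 == c2
        if np.any(same):
            sums = np.bincount(c1[same], weights=d2[same])
            cnts = np.bincount(c1[same])
            percell = sums[cnts > 0] / cnts[cnts > 0]
            msd_w[k - 1] = percell.mean()
            n_w[k - 1] = int(same.sum())
        nxt = c2 == c1 + 1
        if np.any(nxt):
            sums = np.bincount(c1[nxt], weights=d2[nxt])
            cnts = np.bincount(c1[nxt])
            perpair = sums[cnts > 0] / cnts[cnts > 0]
            msd_b[k - 1] = perpair.mean()
            n_b[k - 1] = int(nxt.sum())
    in_win = lags <= avg_window
    wv = msd_w[in_win & np.isfinite(msd_w)]
    bv = msd_b[in_win & np.isfinite(msd_b)]
    if bv.size == 0:
        raise ValueError("no valid between-cell pairs within the averaging window")
    ratio = float(bv.mean() / (bv.mean() + wv.mean()))
    return MsdResult(lags=lags, msd=msd, msd_within=msd_w, msd_between=msd_b,
                     n=n_all, n_within=n_w, n_between=n_b, k_cells=n_cells,
                     avg_window=avg_window, ratio=ratio)


def per_cell_integral(series: FlucSeries, ages: np.ndarray) -> np.ndarray:
    """A_t = int lambda_flucs ds from each cell's first sample, at given ages.

    Trapezoidal integration; cells not spanning max(ages) are dropped.
    Returns (n_cells_used, n_ages).
    """
    ages = np.asarray(ages, dtype=float)
    rows = []
    for c in np.unique(series.cell_index):
        sel = series.cell_index == c
        t = series.times[sel]
        x = series.values[sel]
        if t.size < 4:
            continue
        tr = t - t[0]
        if tr[-1] < ages[-1]:
            continue
        A = np.concatenate([[0.0], np.cumsum(0.5 * (x[1:] + x[:-1]) * np.diff(tr))])
        rows.append(np.interp(ages, tr, A))
    return np.asarray(rows)


@dataclass
class VarScalingResult:
    ages: np.ndarray
    variance: np.ndarray        # var(lambda_bar_t) across cells, (1/h)^2
    n_cells: np.ndarray
    ref_inv_t: np.ndarray       # t^-1 reference anchored at the median age
    ref_inv_t2: np.ndarray      # t^-2 reference, same anchor


def _with_references(ages: np.ndarray, var: np.ndarray, n: np.ndarray) -> VarScalingResult:
    mid = len(ages) // 2
    anchor_t, anchor_v = ages[mid], var[mid]
    return VarScalingResult(ages=ages, variance=var, n_cells=n,
                            ref_inv_t=anchor_v * anchor_t / ages,
                            ref_inv_t2=anchor_v * (anchor_t / ages) ** 2)


def var_time_averaged_growth(series: FlucSeries, ages: np.ndarray,
                             min_cells: int = 5) -> VarScalingResult:
    """var across cells of the time-averaged fluctuation A_t / t at each age t.

    Cells are aligned at birth (their first retained sample); ages beyond the
    shortest contributing cell are dropped with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    var, ncell, kept = [], [], []
    for t in ages:
        A = per_cell_integral(series, np.array([t]))
        if A.shape[0] < min_cells:
            warnings.warn(f"age {t:.2f} h: only {A.shape[0]} cells; dropped")
            continue
        var.append((A[:, 0] / t).var(ddof=1))
        ncell.append(A.shape[0])
        kept.append(t)
    if not kept:
        raise ValueError("no ages with enough contributing cells")
    return _with_references(np.asarray(kept), np.asarray(var), np.asarray(ncell))


def var_time_averaged_growth_raw(lineage: Lineage, ages: np.ndarray,
                                 min_cells: int = 5) -> VarScalingResult:
    """Same scaling computed from the raw log-mass trace.

    lambda_bar_t = ln(M(t_birth + t) / M(t_birth)) / t per full cycle; the
    age-trend contribution is identical across cells and cancels in the
    across-cell variance.
    """
    ages = np.asarray(ages, dtype=float)
    cells = []
    for rec in lineage.full_records:
        sl = rec.trace_slice
        t = lineage.trace.times[sl] - rec.birth_time
        lm = np.log(lineage.trace.masses[sl])
        cells.append((t, lm - lm[0]))
    var, ncell, kept = [], [], []
    for t in ages:
        vals = [np.interp(t, ct, clm) / t for ct, clm in cells if ct[-1] >= t]
        if len(vals) < min_cells:
            warnings.warn(f"age {t:.2f} h: only {len(vals)} cells; dropped")
            continue
        var.append(np.var(vals, ddof=1))
        ncell.append(len(vals))
        kept.append(t)
    if not kept:
        raise ValueError("no ages with enough contributing cells")
    return _with_references(np.asarray(kept), np.asarray(var), np.asarray(ncell))


def loglog_slope(result: VarScalingResult,
                 fit_range: tuple[float, float] | None = None) -> float:
    """OLS slope of ln var(lambda_bar_t) versus ln t (optionally over a t range)."""
    t, v = result.ages, result.variance
    if fit_range is not None:
        m = (t >= fit_range[0]) & (t <= fit_range[1])
        t, v = t[m], v[m]
    if t.size < 3:
        raise ValueError("need >=3 ages in the fit range")
    return float(np.polyfit(np.log(t), np.log(v), 1)[0])
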