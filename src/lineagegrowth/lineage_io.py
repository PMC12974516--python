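"""Reading, validation and segmentation of single-cell buoyant-mass lineage traces.

A *lineage* is one ancestral chain of cells measured in a suspended microchannel
resonator (SMR): a single cell is trapped, its buoyant mass is recorded roughly
once per minute, and at each division one daughter is retained at random.  This
module turns raw (time, mass) tables into per-cell-cycle records and the
stitched log-mass signal that downstream decomposition operates on.

Units are fixed internally to hours and picograms; readers convert on ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MassTrace",
    "CellCycleRecord",
    "Lineage",
    "LineageSet",
    "StitchedSignal",
    "Dialect",
    "VariabilitySummary",
    "read_lineages",
    "segment_cycles",
    "average_growth_rate",
    "stitched_log_mass",
    "variability_summary",
]


@dataclass
class MassTrace:
    """Timestamped buoyant-mass series for one lineage.

    times are hours (strictly increasing), masses picograms (positive).
    ``cell_index`` optionally carries explicit per-point cell labels
    (monotone non-decreasing integers), used as division markers when present.
    """

    lineage_id: str
    times: np.ndarray
    masses: np.ndarray
    cell_index: np.ndarray | None = None
    setup_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.masses.shape:
            raise ValueError("times and masses must be 1-D arrays of equal length")
        if self.times.size >= 2:
            bad = np.nonzero(np.diff(self.times) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"lineage {self.lineage_id!r}: non-monotone time at row {bad[0] + 1}"
                )
        if np.any(~np.isfinite(self.times)) or np.any(~np.isfinite(self.masses)):
            raise ValueError(f"lineage {self.lineage_id!r}: non-finite entries")
        if np.any(self.masses <= 0):
            row = int(np.nonzero(self.masses <= 0)[0][0])
            raise ValueError(f"lineage {self.lineage_id!r}: non-positive mass at row {row}")
        if self.cell_index is not None:
            self.cell_index = np.asarray(self.cell_index)
            if self.cell_index.shape != self.times.shape:
                raise ValueError("cell_index must align with times")

    def __len__(self) -> int:
        return self.times.size

    @property
    def median_dt(self) -> float:
        """Median sampling interval in hours."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(np.diff(self.times)))


@dataclass
class CellCycleRecord:
    """One observed cell cycle: birth/division times and masses, tau, lambda_bar."""

    index_in_lineage: int
    birth_time: float
    division_time: float
    birth_mass: float
    division_mass: float
    trace_slice: slice
    is_partial: bool = False

    @property
    def tau(self) -> float:
        """Generation time in hours (birth to last pre-division sample)."""
        return self.division_time - self.birth_time

    @property
    def lambda_bar(self) -> float:
        """Cycle-averaged growth rate ln(M_div / M_birth) / tau, 1/h."""
        return float(np.log(self.division_mass / self.birth_mass) / self.tau)

    @property
    def added_mass(self) -> float:
        return self.division_mass - self.birth_mass


@dataclass
class Lineage:
    """Ordered cell-cycle records of one ancestral lineage plus the source trace.

    Record ``i + 1`` is the retained daughter of record ``i``.
    """

    lineage_id: str
    records: list[CellCycleRecord]
    trace: MassTrace

    def __post_init__(self) -> None:
        births = [r.birth_time for r in self.records]
        if any(b2 <= b1 for b1, b2 in zip(births, births[1:])):
            raise ValueError("records must be ordered by birth_time")

    @property
    def full_records(self) -> list[CellCycleRecord]:
        return [r for r in self.records if not r.is_partial]

    @property
    def n_full(self) -> int:
        return len(self.full_records)

    def lambda_bars(self) -> np.ndarray:
        return np.array([r.lambda_bar for r in self.full_records])


@dataclass
class LineageSet:
    lineages: list[Lineage]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [ln.lineage_id for ln in self.lineages]
        if len(set(ids)) != len(ids):
            raise ValueError("lineage_ids must be unique")

    def __iter__(self):
        return iter(self.lineages)

    def __len__(self) -> int:
        return len(self.lineages)

    def __getitem__(self, key: int | str) -> Lineage:
        if isinstance(key, str):
            for ln in self.lineages:
                if ln.lineage_id == key:
                    return ln
            raise KeyError(key)
        return self.lineages[key]


@dataclass
class StitchedSignal:
    """Continuous log-mass signal f-hat pooled across the full cycles of a lineage."""

    lineage_id: str
    times: np.ndarray           # h, origin at first retained birth
    values: np.ndarray          # f-hat, dimensionless log-mass
    cell_index: np.ndarray      # 0..n_full-1 per point
    cell_birth_times: np.ndarray
    cell_taus: np.ndarray       # full cycle durations (pre-excision)


@dataclass
class Dialect:
    """Column/unit mapping for tabular trace files."""

    lineage_col: str = "lineage_id"
    time_col: str = "time_h"
    mass_col: str = "mass_pg"
    cell_col: str | None = "cell_index"
    time_unit: str = "h"        # "h", "min" or "s"
    mass_unit: str = "pg"

    _TIME_FACTORS = {"h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0}

    def to_hours(self, t: np.ndarray) -> np.ndarray:
        try:
            return np.asarray(t, dtype=float) * self._TIME_FACTORS[self.time_unit]
        except KeyError:
            raise ValueError(f"unknown time unit {self.time_unit!r}") from None


def _frame_to_lineages(df: pd.DataFrame, dialect: Dialect) -> list[MassTrace]:
    missing = [c for c in (dialect.lineage_col, dialect.time_col, dialect.mass_col)
               if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    traces = []
    for lid, grp in df.groupby(dialect.lineage_col, sort=False):
        cells = None
        if dialect.cell_col and dialect.cell_col in grp.columns and grp[dialect.cell_col].notna().all():
            cells = grp[dialect.cell_col].to_numpy(dtype=int)
        traces.append(MassTrace(
            lineage_id=str(lid),
            times=dialect.to_hours(grp[dialect.time_col].to_numpy()),
            masses=grp[dialect.mass_col].to_numpy(dtype=float),
            cell_index=cells,
        ))
    return traces


def read_lineages(path: str | Path, dialect: Dialect | None = None) -> LineageSet:
    """Read a CSV/TSV/XLSX table of mass traces into a :class:`LineageSet`.

    CSV/TSV files need the columns named in ``dialect``.  XLSX workbooks are
    accepted in two layouts: a single-sheet long table with a lineage column,
    or one sheet per lineage (sheet name becomes the lineage id) with time and
    mass columns.  The detected mapping is stored in the set's provenance.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    prov: dict = {"path": str(path), "dialect": dialect.__dict__.copy()}
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        first = next(iter(sheets.values()))
        if dialect.lineage_col in first.columns:
            prov["layout"] = "long-table"
            df = pd.concat(sheets.values(), ignore_index=True)
            traces = _frame_to_lineages(df, dialect)
        else:
            prov["layout"] = "sheet-per-lineage"
            traces = []
            for name, sdf in sheets.items():
                if dialect.time_col not in sdf.columns or dialect.mass_col not in sdf.columns:
                    raise ValueError(f"sheet {name!r}: missing required column(s) "
                                     f"{[dialect.time_col, dialect.mass_col]}")
                cells = None
                if dialect.cell_col and dialect.cell_col in sdf.columns:
                    cells = sdf[dialect.cell_col].to_numpy(dtype=int)
                traces.append(MassTrace(
                    lineage_id=str(name),
                    times=dialect.to_hours(sdf[dialect.time_col].to_numpy()),
                    masses=sdf[dialect.mass_col].to_numpy(dtype=float),
                    cell_index=cells,
                ))
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        prov["layout"] = "long-table"
        traces = _frame_to_lineages(df, dialect)
    lineages = [Lineage(t.lineage_id, [], t) for t in traces]
    return LineageSet(lineages=lineages, provenance=prov)


def _boundaries_from_markers(cells: np.ndarray) -> np.ndarray:
    return np.nonzero(np.diff(cells) != 0)[0]


def _boundaries_from_drops(masses: np.ndarray, drop_threshold: float) -> np.ndarray:
    # division called where mass falls by more than drop_threshold between samples
    return np.nonzero(masses[1:] < (1.0 - drop_threshold) * masses[:-1])[0]


def segment_cycles(trace: MassTrace, drop_threshold: float = 0.25,
                   prefer_markers: bool = True) -> Lineage:
    """Segment a trace into cell cycles at divisions.

    Divisions are taken from explicit ``cell_index`` markers when present and
    ``prefer_markers`` is set, otherwise called where the mass falls by more
    than ``drop_threshold`` (fraction) between consecutive samples.  The first
    and last segments are flagged partial: the first cell's birth and the last
    cell's division are not observed.
    """
    if not (0.0 < drop_threshold < 1.0):
        raise ValueError("drop_threshold must lie in (0, 1)")
    if prefer_markers and trace.cell_index is not None:
        bounds = _boundaries_from_markers(trace.cell_index)
    else:
        bounds = _boundaries_from_drops(trace.masses, drop_threshold)
    if bounds.size == 0:
        warnings.warn(f"lineage {trace.lineage_id!r}: no divisions detected; "
                      "returning a single partial record")
        rec = CellCycleRecord(0, trace.times[0], trace.times[-1], trace.masses[0],
                              trace.masses[-1], slice(0, len(trace)), is_partial=True)
        return Lineage(trace.lineage_id, [rec], trace)

    starts = np.concatenate([[0], bounds + 1])
    stops = np.concatenate([bounds, [len(trace) - 1]])  # inclusive index of last point
    records = []
    for k, (i0, i1) in enumerate(zip(starts, stops)):
        partial = (k == 0) or (k == len(starts) - 1)
        if i1 <= i0:
            continue  # degenerate one-point segment at the trace edge
        if k == 0 and k < len(starts) - 1:
            # the leading segment's birth is unobserved unless the trace caught
            # the cell essentially at birth: accept it as full only when it
            # spans (at least) a near-complete doubling
            span = np.log(trace.masses[i1] / trace.masses[i0]) / np.log(2.0)
            partial = span < 0.9
        records.append(CellCycleRecord(
            index_in_lineage=k,
            birth_time=float(trace.times[i0]),
            division_time=float(trace.times[i1]),
            birth_mass=float(trace.masses[i0]),
            division_mass=float(trace.masses[i1]),
            trace_slice=slice(int(i0), int(i1) + 1),
            is_partial=partial,
        ))
    return Lineage(trace.lineage_id, records, trace)


def average_growth_rate(record: CellCycleRecord) -> float:
    """Cycle-averaged growth rate ln(M_div / M_birth) / tau for a full cycle."""
    if record.is_partial:
        raise ValueError("average growth rate is undefined for a partial cycle")
    return record.lambda_bar


def stitched_log_mass(lineage: Lineage, mitosis_window: float = 0.5) -> StitchedSignal:
    """Paste per-cell log masses into one continuous signal.

    f-hat(t) = ln(M_i(t) / M_i_birth) + sum_{j<i} ln(M_j_div / M_j_birth),
    evaluated on the pooled sample grid of the full cycles, with the last
    ``mitosis_window`` hours of each cycle excised (mitotic mass dynamics are
    not modelled).  The signal is continuous across divisions by construction.
    Time origin is the first retained cell's birth.
    """
    full = lineage.full_records
    if not full:
        raise ValueError(f"lineage {lineage.lineage_id!r} has no full cycles")
    t0 = full[0].birth_time
    times, values, cells = [], [], []
    offset = 0.0
    for ci, rec in enumerate(full):
        sl = rec.trace_slice
        t = lineage.trace.times[sl]
        m = lineage.trace.masses[sl]
        keep = t <= rec.division_time - mitosis_window
        if not np.any(keep):
            raise ValueError(
                f"cycle {rec.index_in_lineage} empty after mitosis excision "
                f"(window {mitosis_window} h, tau {rec.tau:.2f} h)")
        times.append(t[keep] - t0)
        values.append(np.log(m[keep] / rec.birth_mass) + offset)
        cells.append(np.full(int(keep.sum()), ci))
        offset += np.log(rec.division_mass / rec.birth_mass)
    return StitchedSignal(
        lineage_id=lineage.lineage_id,
        times=np.concatenate(times),
        values=np.concatenate(values),
        cell_index=np.concatenate(cells),
        cell_birth_times=np.array([r.birth_time - t0 for r in full]),
        cell_taus=np.array([r.tau for r in full]),
    )


@dataclass
class VariabilitySummary:
    per_lineage: pd.DataFrame       # lineage_id, n_cells, mean_lambda_bar, cv
    within_cv: float                # mean within-lineage CV of lambda_bar
    between_cv: float               # CV across lineage-mean lambda_bar
    within_variance: float          # cell-count-weighted mean within-lineage variance
    between_variance: float
    total_variance: float
    within_share: float             # within_variance / total_variance

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"within-lineage CV {100 * self.within_cv:.1f}%, "
                f"between-lineage CV {100 * self.between_cv:.1f}%, "
                f"within share of variance {self.within_share:.2f}")


def variability_summary(lineages: LineageSet | Iterable[Lineage]) -> VariabilitySummary:
    """Within- versus between-lineage variability of the averaged growth rate.

    The variance decomposition uses population (ddof=0) variances with
    cell-count weights so that within + between = total holds exactly
    (law of total variance).
    """
    rows, groups = [], []
    for ln in lineages:
        lb = ln.lambda_bars()
        if lb.size < 2:
            warnings.warn(f"lineage {ln.lineage_id!r} has <2 full cycles; excluded")
            continue
        rows.append({"lineage_id": ln.lineage_id, "n_cells": lb.size,
                     "mean_lambda_bar": lb.mean(),
                     "cv": lb.std(ddof=1) / lb.mean()})
        groups.append(lb)
    if len(groups) < 2:
        raise ValueError("need at least 2 lineages with >=2 full cycles each")
    per = pd.DataFrame(rows)
    pooled = np.concatenate(groups)
    n = np.array([g.size for g in groups], dtype=float)
    w = n / n.sum()
    means = np.array([g.mean() for g in groups])
    grand = pooled.mean()
    within_var = float(np.sum(w * np.array([g.var(ddof=0) for g in groups])))
    between_var = float(np.sum(w * (means - grand) ** 2))
    total_var = float(pooled.var(ddof=0))
    return VariabilitySummary(
        per_lineage=per,
        within_cv=float(per["cv"].mean()),
        between_cv=float(means.std(ddof=1) / means.mean()),
        within_variance=within_var,
        between_variance=between_var,
        total_variance=total_var,
        within_share=within_var / total_var if total_var > 0 else float("nan"),
    )
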