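"""Trace ingestion, cycle segmentation and the stitched log-mass signal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lineagegrowth as lg
from lineagegrowth.lineage_io import CellCycleRecord, Lineage, MassTrace


def make_lineage(birth_masses, div_masses, taus, lineage_id="X"):
    """Assemble full cycle records directly from per-cycle quantities."""
    t = 0.0
    recs = []
    for i, (mb, md, tau) in enumerate(zip(birth_masses, div_masses, taus)):
        recs.append(CellCycleRecord(i, t, t + tau, mb, md, slice(i, i + 1)))
        t += tau
    trace = MassTrace(lineage_id, np.array([r.birth_time for r in recs]),
                      np.array([r.birth_mass for r in recs]))
    return Lineage(lineage_id, recs, trace)


class TestReadLineages:
    def test_three_row_csv_identity(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame({"lineage_id": "A", "time_h": [0, 1 / 60, 2 / 60],
                      "mass_pg": [30.0, 30.03, 30.06]}).to_csv(p, index=False)
        lset = lg.read_lineages(p)
        assert len(lset) == 1
        tr = lset["A"].trace
        assert len(tr) == 3
        np.testing.assert_allclose(tr.masses, [30.0, 30.03, 30.06])

    def test_minute_unit_conversion(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame({"lid": "A", "t": [0, 30, 60], "m": [30, 31, 32]}
                     ).to_csv(p, index=False)
        d = lg.Dialect(lineage_col="lid", time_col="t", mass_col="m",
                       time_unit="min")
        tr = lg.read_lineages(p, d)["A"].trace
        np.testing.assert_allclose(tr.times, [0.0, 0.5, 1.0])

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"lineage_id": ["A"], "mass_pg": [30.0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing required column"):
            lg.read_lineages(p)

    def test_non_monotone_time_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"lineage_id": "A", "time_h": [0.0, 0.2, 0.1],
                      "mass_pg": [30, 31, 32]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="row 2"):
            lg.read_lineages(p)


class TestSegmentCycles:
    def test_noiseless_doubling_single_cycle(self):
        t = np.arange(0, 20, 0.1)
        m = 30.0 * np.exp(np.log(2) / 10.0 * t)
        m[t >= 10.0] = m[t >= 10.0] / 2.0
        ln = lg.segment_cycles(MassTrace("A", t, m), prefer_markers=False)
        full = ln.full_records
        assert len(full) == 1
        assert full[0].birth_mass == pytest.approx(30.0, rel=1e-6)
        assert full[0].division_mass == pytest.approx(60.0, rel=0.01)

    def test_monotone_trace_single_partial_with_warning(self):
        t = np.linspace(0, 5, 50)
        m = 30 * np.exp(0.07 * t)
        with pytest.warns(UserWarning, match="no divisions"):
            ln = lg.segment_cycles(MassTrace("A", t, m), prefer_markers=False)
        assert len(ln.records) == 1 and ln.records[0].is_partial

    def test_detects_true_divisions_within_one_dt(self):
        dt = 1.0 / 60.0
        sim = lg.simulate_lineage(lg.OUParams(0.2, 1e-5), n_cells=8, dt=dt, seed=2)
        ln = lg.segment_cycles(sim.trace, prefer_markers=False)
        detected = np.array([r.birth_time for r in ln.records[1:]])
        true_div = sim.truth.all_division_times
        matched = sum(np.min(np.abs(true_div - d)) <= dt + 1e-9 for d in detected)
        assert matched >= 0.95 * len(detected)
        # birth/division masses within measurement + one-step growth tolerance
        for rec, mb in zip(ln.full_records, sim.truth.birth_masses):
            assert rec.birth_mass == pytest.approx(mb, rel=5e-3)

    def test_markers_preferred_over_drops(self):
        sim = lg.simulate_lineage(lg.OUParams(0.2, 1e-5), n_cells=5, dt=1 / 30,
                                  seed=5)
        by_marker = lg.segment_cycles(sim.trace, prefer_markers=True)
        by_drop = lg.segment_cycles(sim.trace, prefer_markers=False)
        assert by_marker.n_full == by_drop.n_full == 5

    def test_bad_threshold_rejected(self):
        tr = MassTrace("A", np.arange(3.0), np.array([30.0, 31, 32]))
        with pytest.raises(ValueError):
            lg.segment_cycles(tr, drop_threshold=1.5)


class TestAverageGrowthRate:
    def test_doubling_quarter(self):
        rec = CellCycleRecord(0, 0.0, 10.0, 25.0, 50.0, slice(0, 2))
        assert lg.average_growth_rate(rec) == pytest.approx(np.log(2) / 10.0)

    def test_no_growth_is_zero(self):
        rec = CellCycleRecord(0, 0.0, 10.0, 25.0, 25.0, slice(0, 2))
        assert lg.average_growth_rate(rec) == 0.0

    def test_partial_refused(self):
        rec = CellCycleRecord(0, 0.0, 10.0, 25.0, 50.0, slice(0, 2), is_partial=True)
        with pytest.raises(ValueError):
            lg.average_growth_rate(rec)

    def test_constant_rate_synthetic(self):
        sim = lg.simulate_lineage(
            lg.OUParams(0.2, 0.0), lambda0=0.07, asymmetry_sd=0.0,
            added_mass_noise_sd=0.0, measurement_cv=0.0, n_cells=3,
            dt=1 / 600, seed=0)
        for lb in sim.truth.lambda_bars:
            assert lb == pytest.approx(0.07, abs=1e-10)


class TestStitchedLogMass:
    def test_single_noiseless_exponential(self):
        t = np.arange(0, 10, 0.05)
        m = 30 * np.exp(0.07 * t)
        m2 = np.concatenate([m, [m[-1] / 2]])
        t2 = np.concatenate([t, [10.0]])
        ln = lg.segment_cycles(MassTrace("A", t2, m2), prefer_markers=False)
        sig = lg.stitched_log_mass(ln, mitosis_window=0.0)
        np.testing.assert_allclose(sig.values, 0.07 * sig.times, atol=1e-12)

    def test_value_at_second_birth_is_log2(self):
        dt = 0.05
        t1 = np.arange(0, 10 + dt / 2, dt)
        lam = np.log(2) / 10.0
        m1 = 30 * np.exp(lam * t1)
        t2 = np.arange(10 + dt, 20 + dt / 2, dt)
        m2 = 30 * np.exp(lam * (t2 - 10 - dt))
        t3 = np.array([20 + dt])
        m3 = np.array([30.0])
        trace = MassTrace("A", np.concatenate([t1, t2, t3]),
                          np.concatenate([m1, m2, m3]))
        ln = lg.segment_cycles(trace, prefer_markers=False)
        sig = lg.stitched_log_mass(ln, mitosis_window=0.0)
        second_birth = sig.times[sig.cell_index == 1][0]
        val = sig.values[sig.cell_index == 1][0]
        assert val == pytest.approx(np.log(2), rel=1e-9)
        assert second_birth > 10.0

    def test_continuous_across_divisions(self):
        sim = lg.simulate_lineage(lg.OUParams(0.2, 1e-5), lambda0=0.068,
                                  n_cells=5, dt=1 / 30, measurement_cv=0.0, seed=7)
        ln = lg.segment_cycles(sim.trace)
        sig = lg.stitched_log_mass(ln, mitosis_window=0.0)
        jumps = np.abs(np.diff(sig.values))
        boundary = np.diff(sig.cell_index) != 0
        assert jumps[boundary].max() <= 2.0 * jumps[~boundary].max()

    def test_nondecreasing_for_growing_noiseless_input(self):
        sim = lg.simulate_lineage(lg.OUParams(0.2, 0.0), lambda0=0.07,
                                  asymmetry_sd=0.0, added_mass_noise_sd=0.0,
                                  measurement_cv=0.0, n_cells=4, dt=1 / 30, seed=0)
        sig = lg.stitched_log_mass(lg.segment_cycles(sim.trace), mitosis_window=0.5)
        assert np.all(np.diff(sig.values) >= -1e-12)

    def test_empty_after_excision_errors(self):
        ln = make_lineage([30.0], [60.0], [0.3])
        # trace_slice points into the 1-point dummy trace; excision removes it
        with pytest.raises(ValueError, match="excision"):
            lg.stitched_log_mass(ln, mitosis_window=1.0)


class TestVariabilitySummary:
    def test_identical_rates_zero_cv(self):
        lns = [make_lineage([30] * 4, [60] * 4, [10] * 4, lineage_id=f"L{i}")
               for i in range(3)]
        s = lg.variability_summary(lns)
        assert s.within_cv == 0.0 and s.between_cv == 0.0

    def test_two_lineage_between_only(self):
        l1 = make_lineage([30] * 3, list(30 * np.exp(np.array([0.06] * 3) * 10)),
                          [10] * 3, "A")
        l2 = make_lineage([30] * 3, list(30 * np.exp(np.array([0.08] * 3) * 10)),
                          [10] * 3, "B")
        s = lg.variability_summary([l1, l2])
        assert s.within_cv == pytest.approx(0.0, abs=1e-12)
        expected = np.std([0.06, 0.08], ddof=1) / np.mean([0.06, 0.08])
        assert s.between_cv == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_variance_decomposition_exact(self, seed):
        rng = np.random.default_rng(seed)
        lns = []
        for i in range(rng.integers(2, 5)):
            n = int(rng.integers(2, 7))
            lam = rng.uniform(0.05, 0.09, n)
            taus = rng.uniform(8, 12, n)
            mb = rng.uniform(25, 35, n)
            lns.append(make_lineage(mb, mb * np.exp(lam * taus), taus, f"L{i}"))
        s = lg.variability_summary(lns)
        assert s.within_variance + s.between_variance == pytest.approx(
            s.total_variance, rel=1e-9)

    def test_short_lineage_excluded_with_warning(self):
        l1 = make_lineage([30, 31, 29], [60, 61, 58], [10, 10, 10], "A")
        l2 = make_lineage([30, 32, 31], [61, 60, 62], [10, 10, 10], "B")
        l3 = make_lineage([30], [60], [10], "C")
        with pytest.warns(UserWarning, match="excluded"):
            s = lg.variability_summary([l1, l2, l3])
        assert len(s.per_lineage) == 2


class TestMassTraceValidation:
    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError, match="non-positive mass"):
            MassTrace("A", np.array([0.0, 1.0]), np.array([30.0, -1.0]))

    def test_lambda_bar_matches_definition(self):
        rec = CellCycleRecord(0, 1.0, 11.5, 27.3, 55.1, slice(0, 2))
        assert rec.lambda_bar == pytest.approx(
            np.log(55.1 / 27.3) / 10.5, rel=1e-12)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "xlsx"])
    def test_write_read_equal(self, tmp_path, fmt):
        lset, _ = lg.generate_dataset(lg.SyntheticConfig(
            n_lineages=2, cells_per_lineage=3, dt=1 / 12, seed=5))
        p = tmp_path / f"d.{fmt}"
        lg.write_dataset(lset, p, format=fmt)
        back = lg.read_lineages(p)
        assert sorted(ln.lineage_id for ln in back) == sorted(
            ln.lineage_id for ln in lset)
        for ln in lset:
            tr0, tr1 = ln.trace, back[ln.lineage_id].trace
            np.testing.assert_allclose(tr1.times, tr0.times, atol=1e-9)
            np.testing.assert_allclose(tr1.masses, tr0.masses, rtol=1e-9)

    def test_empty_set_header_only(self, tmp_path):
        p = tmp_path / "e.csv"
        lg.write_dataset(lg.LineageSet(lineages=[]), p)
        df = pd.read_csv(p)
        assert list(df.columns) == ["lineage_id", "time_h", "mass_pg"]
        assert len(df) == 0
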