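"""ACF/relaxation, age-resolved magnitude, MSD suite and variance scaling."""

import numpy as np
import pytest

import lineagegrowth as lg
from lineagegrowth.acf import AcfResult
from lineagegrowth.fluctuation_stats import FlucSeries, per_cell_integral
from lineagegrowth.ou_model import _truth_flucseries

from test_lineage_io import make_lineage


def ou_series(gamma=0.2, svar=5e-5, total_h=200.0, dt=1.0 / 30.0, tau=10.0,
              seed=0, values=None):
    """A FlucSeries holding one OU path chopped into tau-hour 'cells'."""
    n = int(total_h / dt)
    t = np.arange(n) * dt
    v = (values if values is not None
         else lg.simulate_ou(lg.OUParams(gamma, svar * gamma), dt, n, seed=seed))
    cid = np.minimum((t // tau).astype(int), int(total_h / tau) - 1)
    t0 = np.arange(cid.max() + 1) * tau
    return FlucSeries("S", t, v, None, cid, t0, np.full(cid.max() + 1, tau))


class TestAcfTimeseries:
    def test_ou_closed_form_decay(self):
        s = ou_series(gamma=0.2, total_h=3000.0, seed=1)
        acf = lg.acf_timeseries(s, max_lag=6.0)
        for lag_h in (1.0, 2.0, 4.0):
            k = int(round(lag_h / acf.xcal))
            assert acf[k] == pytest.approx(np.exp(-0.2 * lag_h), abs=0.07)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(2)
        s = ou_series(total_h=300.0, values=rng.standard_normal(9000))
        acf = lg.acf_timeseries(s, max_lag=2.0)
        assert np.all(np.abs(acf.coefficients[1:]) < 0.05)

    def test_too_short_series_rejected(self):
        s = ou_series(total_h=200.0)
        short = FlucSeries("S", s.times[:50], s.values[:50], None,
                           s.cell_index[:50], s.cell_t0, s.cell_tau)
        with pytest.raises(ValueError, match="100"):
            lg.acf_timeseries(short)


class TestRelaxationTime:
    def test_exact_exponential_gives_five_hours(self):
        lags = np.arange(0, 40)
        xcal = 0.25
        coeffs = np.exp(-(lags * xcal) / 5.0)
        acf = AcfResult(lags, lags * xcal, coeffs, np.full_like(lags, 100),
                        0.0, 1.0, xcal)
        assert lg.relaxation_time(acf) == pytest.approx(5.0, rel=1e-9)

    def test_recovers_generator_timescale(self):
        """1/gamma within 20% across gamma in {0.1, 0.2, 0.5} at ~2600 h of data."""
        for gamma in (0.1, 0.2, 0.5):
            ests = []
            for seed in range(5):
                s = ou_series(gamma=gamma, total_h=2600.0, dt=1.0 / 12.0, seed=seed)
                ests.append(lg.relaxation_time(lg.acf_timeseries(s, max_lag=20.0)))
            assert np.median(ests) == pytest.approx(1.0 / gamma, rel=0.2)

    def test_nonpositive_initial_acf_errors(self):
        lags = np.arange(0, 5)
        acf = AcfResult(lags, lags * 1.0, np.array([1.0, -0.1, 0.0, 0.0, 0.0]),
                        np.full(5, 10), 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            lg.relaxation_time(acf)


class TestMagnitudeByAge:
    def test_null_type_one_error_near_nominal(self):
        rejections = []
        for seed in range(60):
            s = ou_series(total_h=120.0, seed=seed)
            out = lg.magnitude_by_age(s, n_bins=4)
            rejections.append(out.anova_p < 0.05)
        assert np.mean(rejections) < 0.15

    def test_detects_age_dependent_magnitude(self):
        rng = np.random.default_rng(5)
        s0 = ou_series(total_h=120.0, seed=5)
        u = s0.relative_age()
        inflated = s0.values * np.where(u > 0.5, 2.0, 1.0)
        s = ou_series(total_h=120.0, values=inflated)
        out = lg.magnitude_by_age(s, n_bins=4)
        assert out.anova_p < 0.01
        assert out.sd_per_bin[-1] > out.sd_per_bin[0]


class TestMagnitudeRegressions:
    def _lineage(self, n=12):
        rng = np.random.default_rng(6)
        mb = 30 * np.exp(rng.normal(0, 0.1, n))
        return make_lineage(mb, 2 * mb, np.full(n, 10.0))

    def test_constructed_dependence_detected(self):
        ln = self._lineage()
        rng = np.random.default_rng(7)
        t, v, cid = [], [], []
        for i, rec in enumerate(ln.full_records):
            tt = rec.birth_time + np.arange(0, 9.5, 1 / 30)
            t.append(tt)
            v.append(rng.standard_normal(tt.size) * (rec.birth_mass / 30.0) * 0.01)
            cid.append(np.full(tt.size, i))
        s = FlucSeries("S", np.concatenate(t), np.concatenate(v), None,
                       np.concatenate(cid),
                       np.array([r.birth_time for r in ln.full_records]),
                       np.array([r.tau for r in ln.full_records]))
        tab = lg.magnitude_regressions(s, ln).set_index("covariate")
        assert tab.loc["birth_mass", "r2"] > 0.8
        assert tab.loc["birth_mass", "p"] < 0.01

    def test_independent_generator_null_slopes(self):
        ln = self._lineage()
        rng = np.random.default_rng(8)
        t, v, cid = [], [], []
        for i, rec in enumerate(ln.full_records):
            tt = rec.birth_time + np.arange(0, 9.5, 1 / 30)
            t.append(tt)
            v.append(rng.standard_normal(tt.size) * 0.01)
            cid.append(np.full(tt.size, i))
        s = FlucSeries("S", np.concatenate(t), np.concatenate(v), None,
                       np.concatenate(cid),
                       np.array([r.birth_time for r in ln.full_records]),
                       np.array([r.tau for r in ln.full_records]))
        tab = lg.magnitude_regressions(s, ln)
        assert (tab["p"].dropna() > 0.01).all()


class TestMsdSuite:
    def test_constant_series_msd_zero(self):
        s = ou_series(total_h=60.0, values=np.full(1800, 0.37))
        with np.errstate(invalid="ignore"):
            res = lg.msd_suite(s, max_lag=2.0)
        assert np.nanmax(res.msd) == 0.0
        assert np.nanmax(res.msd_within) == 0.0
        assert np.isnan(res.ratio)  # 0/0: undefined for a constant signal

    def test_ou_msd_matches_closed_form(self):
        gamma, svar = 0.3, 1.0
        s = ou_series(gamma=gamma, svar=svar, total_h=4000.0, dt=0.1,
                      tau=2000.0, seed=9)
        res = lg.msd_suite(s, max_lag=4.0, avg_window=4.0)
        expected = 2.0 * svar * (1.0 - np.exp(-gamma * res.lags))
        np.testing.assert_allclose(res.msd, expected, rtol=0.1)

    def test_continuous_ou_ratio_near_half(self):
        ratios = [lg.msd_suite(ou_series(total_h=200.0, seed=s), 4.0).ratio
                  for s in range(8)]
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.06)

    def test_division_kick_ratio_near_one(self):
        sim = lg.simulate_lineage(lg.OUParams(0.2, 1e-12), lg.DivisionNoise(0.01),
                                  lambda0=0.068, fixed_tau=10.0, dt=1 / 30,
                                  n_cells=12, measurement_cv=0.0, seed=3)
        ser = _truth_flucseries(sim, 0.5)
        # add a small measurement-like floor so MSD_within is finite
        rng = np.random.default_rng(0)
        ser = FlucSeries(ser.lineage_id, ser.times,
                         ser.values + rng.normal(0, 2e-4, ser.values.size),
                         None, ser.cell_index, ser.cell_t0, ser.cell_tau)
        assert lg.msd_suite(ser, 4.0).ratio > 0.8

    def test_ratio_invariant_to_shift_and_scale(self):
        s = ou_series(total_h=150.0, seed=11)
        r0 = lg.msd_suite(s, 4.0).ratio
        shifted = FlucSeries(s.lineage_id, s.times, 3.0 * s.values + 0.123, None,
                             s.cell_index, s.cell_t0, s.cell_tau)
        assert lg.msd_suite(shifted, 4.0).ratio == pytest.approx(r0, rel=1e-12)


class TestVarScaling:
    def test_ou_slope_near_minus_one(self):
        chunks = []
        for seed in range(6):
            sim = lg.simulate_lineage(lg.OUParams(1.0, 5e-5), lambda0=0.068,
                                      fixed_tau=30.0, dt=1 / 30, n_cells=8,
                                      measurement_cv=0.0, seed=seed)
            chunks.append(_truth_flucseries(sim, 0.5))
        ages = np.geomspace(8.0, 28.0, 8)
        vs = [lg.var_time_averaged_growth(c, ages).variance for c in chunks]
        mean_var = np.mean(vs, axis=0)
        slope = np.polyfit(np.log(ages), np.log(mean_var), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)

    def test_division_kick_slope_near_minus_two(self):
        chunks = []
        for seed in range(6):
            sim = lg.simulate_lineage(lg.OUParams(1.0, 1e-14), lg.DivisionNoise(0.02),
                                      lambda0=0.068, fixed_tau=30.0, dt=1 / 30,
                                      n_cells=8, measurement_cv=0.0, seed=seed)
            chunks.append(_truth_flucseries(sim, 0.5))
        ages = np.geomspace(8.0, 28.0, 8)
        mean_var = np.mean([lg.var_time_averaged_growth(c, ages).variance
                            for c in chunks], axis=0)
        slope = np.polyfit(np.log(ages), np.log(mean_var), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.25)

    def test_exact_ou_variance_not_just_asymptote(self):
        """var(lambda_bar_t) matches exact var(A_t)/t^2 from the closed form."""
        params = lg.OUParams(0.2, 1e-5)
        vs = []
        ages = np.array([1.0, 3.0, 6.0, 9.0])
        for seed in range(10):
            s = ou_series(gamma=0.2, svar=5e-5, total_h=400.0, seed=100 + seed)
            vs.append(lg.var_time_averaged_growth(s, ages).variance)
        expected = lg.var_integrated_ou(params, ages) / ages ** 2
        np.testing.assert_allclose(np.mean(vs, axis=0), expected, rtol=0.15)

    def test_deterministic_input_zero_variance(self):
        s = ou_series(total_h=100.0, values=np.zeros(3000))
        res = lg.var_time_averaged_growth(s, np.array([2.0, 4.0, 6.0]))
        assert np.allclose(res.variance, 0.0)

    def test_raw_trace_variant_close_to_flucs_variant(self, gp_case):
        sim, lineage, inputs, _ = gp_case
        ages = np.array([2.0, 4.0, 6.0])
        raw = lg.var_time_averaged_growth_raw(lineage, ages, min_cells=4)
        ser = _truth_flucseries(sim, 0.0)
        fl = lg.var_time_averaged_growth(ser, ages, min_cells=4)
        # raw includes measurement noise; same order of magnitude and shape
        assert raw.variance == pytest.approx(fl.variance, rel=1.0)

    def test_ages_beyond_cells_dropped_with_warning(self):
        s = ou_series(total_h=60.0, tau=10.0, seed=12)
        with pytest.warns(UserWarning, match="dropped"):
            res = lg.var_time_averaged_growth(s, np.array([2.0, 25.0]))
        assert res.ages.tolist() == [2.0]


def test_per_cell_integral_trapezoid():
    t = np.arange(0, 10, 0.5)
    s = FlucSeries("S", t, np.full_like(t, 0.01), None,
                   np.zeros(t.size, dtype=int), np.array([0.0]), np.array([10.0]))
    A = per_cell_integral(s, np.array([4.0, 8.0]))
    np.testing.assert_allclose(A, [[0.04, 0.08]], rtol=1e-12)
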