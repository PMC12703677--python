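"""Calibration, binding, stopped-flow and depletion analyses."""

import numpy as np
import pytest

import cbmscreen as cs
from cbmscreen.errors import ConvergenceError, ValidationError


class TestCalibration:
    def test_exact_line_recovered_and_inverted(self):
        curve = cs.fit_linear_calibration([0, 2, 4, 8], [5, 25, 45, 85])
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(5.0)
        assert cs.apply_calibration(curve, 45.0) == pytest.approx(4.0)

    def test_negative_concentration_clipped_with_warning(self):
        curve = cs.fit_linear_calibration([0, 2, 4, 8], [5, 25, 45, 85])
        with pytest.warns(UserWarning, match="clipped"):
            assert cs.apply_calibration(curve, 2.0) == 0.0

    def test_extrapolation_flagged(self):
        curve = cs.fit_linear_calibration([0, 2, 4, 8], [5, 25, 45, 85])
        with pytest.warns(UserWarning, match="extrapolat"):
            cs.apply_calibration(curve, 120.0)

    def test_quenching_probe_negative_slope_inverts_too(self):
        curve = cs.fit_linear_calibration([0, 2, 4, 8], [80, 60, 40, 0])
        assert curve.slope == pytest.approx(-10.0)
        assert cs.apply_calibration(curve, 60.0) == pytest.approx(2.0)

    def test_singular_design_rejected(self):
        with pytest.raises(ValidationError, match="singular"):
            cs.fit_linear_calibration([3, 3, 3], [1, 2, 3])

    def test_noisy_standards_recover_slope_within_2_se(self):
        data = cs.gen_calibration(slope=10, intercept=5,
                                  concentrations=(0, 1, 2, 4, 6, 8),
                                  noise_sd=0.5, replicates=3, seed=4)
        t = data.table
        curve = cs.fit_linear_calibration(t["conc_uM"], t["response"])
        assert abs(curve.slope - 10) <= 2 * curve.slope_se

    def test_standards_round_trip_exactly_when_noiseless(self):
        conc = np.array([0.0, 1.0, 2.5, 4.0, 8.0])
        resp = -3.2 * conc + 40
        curve = cs.fit_linear_calibration(conc, resp)
        for c, r in zip(conc, resp):
            assert cs.apply_calibration(curve, r) == pytest.approx(c, abs=1e-10)


class TestBoundCopper:
    def test_one_to_one_stoichiometry(self):
        res = cs.compute_bound_copper(total_cu=8.0, free_cu=4.0,
                                      cbm_concentration=4.0)
        assert res.stoichiometry == pytest.approx(1.0)

    def test_no_binding(self):
        res = cs.compute_bound_copper(8.0, 8.0, 4.0)
        assert res.stoichiometry == 0.0

    def test_conservation(self):
        res = cs.compute_bound_copper(8.0, 2.5, 4.0)
        assert res.bound_cu + res.free_cu == pytest.approx(res.total_cu)

    def test_free_above_total_within_tolerance_clipped(self):
        with pytest.warns(UserWarning, match="clipped"):
            res = cs.compute_bound_copper(8.0, 8.3, 4.0)
        assert res.stoichiometry == 0.0

    def test_calibration_fault_rejected(self):
        with pytest.raises(ValidationError, match="calibration fault"):
            cs.compute_bound_copper(8.0, 10.0, 4.0)

    def test_end_to_end_stoichiometry_recovery(self):
        # standards and samples share the calibration; planted 0.9 Cu/CBM
        curve_data = cs.gen_calibration(slope=-12.0, intercept=100.0,
                                        noise_sd=0.3, seed=6)
        t = curve_data.table
        curve = cs.fit_linear_calibration(t["conc_uM"], t["response"])
        true_free = 8.0 - 0.9 * 4.0
        response = -12.0 * true_free + 100.0
        free = cs.apply_calibration(curve, response)
        res = cs.compute_bound_copper(8.0, free, 4.0)
        assert res.stoichiometry == pytest.approx(0.9, abs=0.1)


class TestOneSiteBinding:
    def test_noiseless_recovery_to_1e6(self):
        f = np.array([0.5, 1, 2, 4, 8, 16, 32])
        y = cs.one_site(f, 2.0, 10.0)
        fit = cs.fit_one_site_binding(f, y)
        assert fit.kd == pytest.approx(2.0, rel=1e-6)
        assert fit.bmax == pytest.approx(10.0, rel=1e-6)

    def test_half_saturation_identity(self):
        f = np.array([0.5, 1, 2, 4, 8, 16])
        fit = cs.fit_one_site_binding(f, cs.one_site(f, 2.0, 10.0))
        assert cs.one_site(np.array([fit.kd]), fit.kd, fit.bmax)[0] == \
            pytest.approx(fit.bmax / 2)

    def test_sccbm2_avicel_kd_recovered_within_15_percent(self):
        data = cs.gen_isotherm(kd=3.7, bmax=2.0, noise_sd=0.04,
                               replicates=3, seed=cs.DEFAULT_SEED)
        kds = [cs.fit_one_site_binding(g["free_uM"], g["bound_umol_g"]).kd
               for _, g in data.table.groupby("replicate")]
        mean_kd, _ = cs.replicate_summary(kds)
        assert mean_kd == pytest.approx(3.7, rel=0.15)

    def test_saturation_warning_when_kd_not_approached(self):
        f = np.array([0.01, 0.02, 0.04, 0.08])
        fit = cs.fit_one_site_binding(f, cs.one_site(f, 50.0, 10.0))
        assert fit.saturation_warning

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            cs.fit_one_site_binding([1, 2, 2], [0.5, 0.8, 0.8])

    def test_residual_no_worse_than_truth(self):
        data = cs.gen_isotherm(kd=3.7, bmax=2.0, noise_sd=0.06,
                               replicates=1, seed=12)
        f = data.table["free_uM"].to_numpy()
        y = data.table["bound_umol_g"].to_numpy()
        fit = cs.fit_one_site_binding(f, y)
        rss_truth = float(np.sum((cs.one_site(f, 3.7, 2.0) - y) ** 2))
        assert fit.rss <= rss_truth + 1e-12


class TestSingleExponential:
    def _trace(self, a, b, c, k, n=120, span=None):
        t = np.linspace(0, span or 6 / k, n)
        return t, cs.exponential_model(t, a, b, c, k)

    def test_noiseless_recovery(self):
        t, y = self._trace(0.0, 1.0, 1.0, 0.5)
        fit = cs.fit_single_exponential(t, y)
        assert fit.k_obs == pytest.approx(0.5, rel=1e-6)
        assert fit.b == pytest.approx(1.0, rel=1e-6)
        assert fit.c == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_recovery_with_drift_and_rise(self):
        t, y = self._trace(0.02, 2.0, -0.7, 1.3)
        fit = cs.fit_single_exponential(t, y)
        assert fit.k_obs == pytest.approx(1.3, rel=1e-6)
        assert fit.a == pytest.approx(0.02, rel=1e-5)

    def test_pure_drift_rejected_as_degenerate(self):
        t = np.linspace(0, 10, 50)
        y = 0.3 * t + 2.0
        with pytest.raises(ConvergenceError, match="degenerate"):
            cs.fit_single_exponential(t, y)

    def test_noisy_trace_k_within_5_percent(self):
        rng = np.random.default_rng(31)
        t, y = self._trace(0.0, 1.0, 0.5, 2.0, n=200)
        y = y + rng.normal(0, 0.005, t.size)  # 1% of amplitude
        fit = cs.fit_single_exponential(t, y)
        assert fit.k_obs == pytest.approx(2.0, rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError, match="20"):
            cs.fit_single_exponential([0, 1, 2], [1, 0.5, 0.2])


class TestSecondOrder:
    def test_exact_line_reproduced_to_machine_precision(self):
        conc = np.array([50, 100, 200, 400, 800, 1600]) * 1e-6
        kobs = 10700.0 * conc
        fit = cs.fit_second_order(conc, kobs)
        assert fit.k_app == pytest.approx(10700.0, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(2)
        x = np.array([25, 50, 100, 200, 400, 800]) * 1e-6
        y = 15000.0 * x + rng.normal(0, 0.05, x.size)
        fit = cs.fit_second_order(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        assert fit.k_app == pytest.approx(slope, rel=1e-12)

    def test_zero_slope_with_residual_se(self):
        x = np.array([1, 2, 3, 4]) * 1e-4
        fit = cs.fit_second_order(x, [0.5, 0.5, 0.5, 0.5])
        assert fit.k_app == pytest.approx(0.0, abs=1e-12)

    def test_through_origin_option(self):
        x = np.array([1, 2, 3, 4], dtype=float)
        y = 2.0 * x
        fit = cs.fit_second_order(x, y, through_origin=True)
        assert fit.k_app == pytest.approx(2.0) and fit.intercept == 0.0

    def test_fewer_than_four_concentrations_rejected(self):
        with pytest.raises(ValidationError, match="4"):
            cs.fit_second_order([1e-4, 2e-4, 3e-4], [1, 2, 3])


class TestLinearPhaseAndDepletion:
    def test_exact_linear_series(self):
        t = np.arange(0, 200, 10.0)
        res = cs.estimate_linear_phase_rate(t, 0.2 * t + 1.0)
        assert res.rate == pytest.approx(0.2)

    def test_windowed_slope_exceeds_whole_series_on_saturating_curve(self):
        t = np.arange(0, 600, 10.0)
        y = 10 * (1 - np.exp(-t / 150))
        early = cs.estimate_linear_phase_rate(t, y, window=(0, 120))
        import scipy.stats as ss
        whole = ss.linregress(t, y).slope
        assert early.rate > whole

    def test_auto_window_extends_over_linear_prefix(self):
        t = np.arange(0, 300, 5.0)
        y = np.where(t <= 150, 0.2 * t, 30.0)  # linear then flat
        res = cs.estimate_linear_phase_rate(t, y, auto=True)
        # the R² stop rule trails a little past the kink at t=150
        assert res.rate == pytest.approx(0.2, rel=0.15)
        assert 145 <= res.window[1] <= 220
        assert res.r_squared >= 0.98

    def test_too_few_points_in_window_rejected(self):
        with pytest.raises(ValidationError, match="3 points"):
            cs.estimate_linear_phase_rate([0, 50, 200], [0, 1, 2],
                                          window=(0, 60))

    def test_depletion_crossing_at_sample(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        c = np.array([100.0, 60.0, 20.0, 5.0, 1.0])
        s = cs.summarize_depletion(t, c, threshold_fraction=0.05)
        assert s.status == "depleted" and s.depletion_time == pytest.approx(3.0)

    def test_flat_control_never_depletes(self):
        t = np.arange(0, 19, 0.5)
        s = cs.summarize_depletion(t, np.full(t.size, 1000.0))
        assert s.status == "not_depleted" and s.depletion_time is None

    def test_single_noise_dip_does_not_count(self):
        t = np.arange(6.0)
        c = np.array([100, 80, 3.0, 60, 50, 40.0])
        s = cs.summarize_depletion(t, c, threshold_fraction=0.05)
        assert s.status == "not_depleted"

    def test_exponential_depletion_matches_closed_form(self):
        data = cs.gen_depletion(initial_uM=1000, rate_per_h=1.0, seed=2)
        tbl = data.table
        s = cs.summarize_depletion(tbl["time_h"], tbl["conc_uM"])
        assert s.depletion_time == pytest.approx(
            data.truth["crossing_time_h"], abs=0.05)  # sampling interval
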