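import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardioperf as cp
from cardioperf.core_io import ValidationError
from cardioperf.pd_metrics import FitError, _hill_curve


def pcs_from(times, pct, baseline=60.0):
    return cp.PercentChangeSeries(np.asarray(times, float), np.asarray(pct, float), baseline, (0.0, 1.0))


class TestPercentChange:
    def test_constant_series_all_zero(self):
        rec = cp.Recording(np.arange(10.0), np.full(10, 48.0))
        pcs = cp.percent_change(rec)
        np.testing.assert_allclose(pcs.pct_change, 0.0)
        assert pcs.baseline_value == 48.0

    def test_half_baseline_is_minus_fifty(self):
        rec = cp.Recording(np.array([0.0, 0.5, 2.0]), np.array([50.0, 50.0, 25.0]))
        pcs = cp.percent_change(rec)
        assert pcs.pct_change[-1] == pytest.approx(-50.0)

    def test_baseline_window_points_near_zero(self, plateau_recording):
        pcs = cp.percent_change(plateau_recording(-77.9))
        in_base = (pcs.times >= 0) & (pcs.times < 1)
        np.testing.assert_allclose(pcs.pct_change[in_base], 0.0, atol=1e-9)

    def test_zero_baseline_rejected(self):
        rec = cp.Recording(np.arange(5.0), np.array([0.0, 0.0, 10.0, 10.0, 10.0]))
        with pytest.raises(ValidationError, match="baseline"):
            cp.percent_change(rec)

    def test_empty_baseline_window_rejected(self):
        rec = cp.Recording(np.arange(5.0) + 2.0, np.full(5, 50.0))
        with pytest.raises(ValidationError, match="baseline window"):
            cp.percent_change(rec, (0.0, 1.0))

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        freqs = rng.uniform(20, 80, 20)
        times = np.arange(20.0)
        a = cp.percent_change(cp.Recording(times, freqs))
        b = cp.percent_change(cp.Recording(times, freqs * scale))
        np.testing.assert_allclose(a.pct_change, b.pct_change, atol=1e-9)

    def test_noiseless_plateau_matches_target(self, variant_a_protocol):
        params = cp.PDParams(potency={"x": cp.CompoundPD(-77.9, 1e-9, 1.0)}, k_on=5.0, k_off=1.0)
        rec = cp.simulate_frequency_series(variant_a_protocol, params, seed=0)
        pcs = cp.percent_change(rec)
        plateau = pcs.pct_change[(pcs.times >= 8) & (pcs.times < 13.5)]
        np.testing.assert_allclose(plateau, -77.9, atol=0.1)


class TestSlopeCoefficient:
    def test_unit_interval(self):
        s = cp.slope_coefficient(pcs_from([4.0, 5.0], [0.0, -10.0]))
        assert s.a_values[0] == pytest.approx(-10.0)
        assert s.times[0] == 5.0

    def test_flat_zero(self):
        s = cp.slope_coefficient(pcs_from([4.0, 5.0], [-10.0, -10.0]))
        assert s.a_values[0] == 0.0

    def test_half_minute_spacing(self):
        # 0 -> -15 over 4.0 -> 4.5 gives -30 %/min
        s = cp.slope_coefficient(pcs_from([4.0, 4.5], [0.0, -15.0]))
        assert s.a_values[0] == pytest.approx(-30.0)

    def test_length_contract(self):
        s = cp.slope_coefficient(pcs_from(np.arange(10.0), np.zeros(10)))
        assert s.a_values.size == 9

    def test_oracle_equivalence_random_nonuniform(self):
        # independent per-pair recomputation, machine precision
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            times = np.cumsum(rng.uniform(0.1, 2.0, n))
            pct = rng.normal(0, 40, n)
            s = cp.slope_coefficient(pcs_from(times, pct))
            for i in range(n - 1):
                expected = (pct[i + 1] - pct[i]) / (times[i + 1] - times[i])
                assert s.a_values[i] == expected


class TestEffectSummary:
    def test_plateau_e_max(self, plateau_recording, variant_a_protocol):
        pcs = cp.percent_change(plateau_recording(-77.9))
        s = cp.effect_summary(pcs, variant_a_protocol)
        assert s.e_max == pytest.approx(-77.9)
        assert s.e_at[13.0] == pytest.approx(-77.9)

    def test_all_zero_pct(self, variant_a_protocol):
        pcs = pcs_from(np.arange(0, 22.5, 0.5), np.zeros(45))
        s = cp.effect_summary(pcs, variant_a_protocol)
        assert s.e_max == 0.0
        assert s.t_max == 4.0  # exposure onset

    def test_e_at_13_on_plateau_from_min_7(self, plateau_recording, variant_a_protocol):
        rec = plateau_recording(-66.7, ramp=3.0)  # plateau reached at min 7
        s = cp.effect_summary(cp.percent_change(rec), variant_a_protocol)
        assert s.e_at[13.0] == pytest.approx(-66.7)

    def test_e_max_dominates_reported_minutes(self, plateau_recording, variant_a_protocol):
        s = cp.effect_summary(cp.percent_change(plateau_recording(-50.0)), variant_a_protocol)
        for v in s.e_at.values():
            assert abs(s.e_max) >= abs(v) - 1e-9

    def test_report_minute_outside_recording(self, plateau_recording, variant_a_protocol):
        pcs = cp.percent_change(plateau_recording(-50.0))
        with pytest.raises(ValidationError, match="outside"):
            cp.effect_summary(pcs, variant_a_protocol, report_minutes=[40.0])

    def test_arrest_flag(self, variant_a_protocol):
        t = np.arange(0, 22.5, 0.5)
        f = np.where((t >= 6) & (t < 13), 0.0, 60.0)
        s = cp.effect_summary(cp.percent_change(cp.Recording(t, f)), variant_a_protocol)
        assert s.arrested
        assert s.e_max == pytest.approx(-100.0)


class TestHalfTimes:
    def test_linear_ramp_t50(self, variant_a_protocol):
        # 0 -> -100 over minutes 4 -> 6: half effect at minute 5
        t = np.arange(0, 22.5, 0.5)
        y = np.interp(t, [0, 4, 6, 13.5, 15.5, 22], [0, 0, -100, -100, 0, 0])
        assert cp.t50(pcs_from(t, y), variant_a_protocol, "interp") == pytest.approx(1.0)

    def test_linear_recovery_rt50(self, variant_a_protocol):
        t = np.arange(0, 22.5, 0.5)
        y = np.interp(t, [0, 4, 6, 13.5, 15.5, 22], [0, 0, -100, -100, 0, 0])
        val, censored = cp.rt50(pcs_from(t, y), variant_a_protocol, "interp")
        assert not censored
        assert val == pytest.approx(1.0)

    def test_no_recovery_censored(self, variant_a_protocol):
        t = np.arange(0, 22.5, 0.5)
        y = np.where(t >= 5, -80.0, 0.0)
        val, censored = cp.rt50(pcs_from(t, y), variant_a_protocol, "interp")
        assert censored
        assert math.isnan(val)

    def test_step_to_plateau_within_one_bin(self, variant_a_protocol):
        t = np.arange(0, 22.5, 0.5)
        y = np.where((t >= 4.5) & (t < 13.5), -60.0, 0.0)
        assert cp.t50(pcs_from(t, y), variant_a_protocol, "interp") <= 0.5 + 1e-9

    def test_fit_t50_first_order(self, variant_a_protocol):
        k = 0.667
        params = cp.PDParams(potency={"x": cp.CompoundPD(-80.0, 1e-9, 1.0)}, k_on=k, k_off=k)
        rec = cp.simulate_frequency_series(variant_a_protocol, params, seed=0, dt=0.25)
        t50_fit = cp.t50(cp.percent_change(rec), variant_a_protocol, "fit")
        assert t50_fit == pytest.approx(1.04, abs=0.05)

    def test_fit_rt50_first_order(self, variant_a_protocol):
        params = cp.PDParams(potency={"x": cp.CompoundPD(-80.0, 1e-9, 1.0)}, k_on=2.0, k_off=0.26)
        rec = cp.simulate_frequency_series(variant_a_protocol, params, seed=0, dt=0.25)
        val, censored = cp.rt50(cp.percent_change(rec), variant_a_protocol, "fit")
        assert not censored
        assert val == pytest.approx(math.log(2) / 0.26, abs=0.1)

    def test_zero_effect_rejected(self, variant_a_protocol):
        t = np.arange(0, 22.5, 0.5)
        with pytest.raises(ValidationError, match="zero"):
            cp.t50(pcs_from(t, np.zeros_like(t)), variant_a_protocol)

    @pytest.mark.parametrize("method", ["interp", "fit"])
    @pytest.mark.parametrize("k", [0.1, 0.25, 0.5, 1.0, 2.0])
    def test_half_times_match_ln2_over_k(self, method, k):
        # long windows so the observed extreme is the true asymptote
        proto = cp.continuous_protocol({"x": 1.0}, window=(4.0, 84.0), total_duration=160.0)
        params = cp.PDParams(potency={"x": cp.CompoundPD(-80.0, 1e-9, 1.0)}, k_on=k, k_off=k)
        dt = 0.25
        rec = cp.simulate_frequency_series(proto, params, seed=0, dt=dt)
        pcs = cp.percent_change(rec)
        target = math.log(2) / k
        assert cp.t50(pcs, proto, method) == pytest.approx(target, abs=dt)
        val, censored = cp.rt50(pcs, proto, method)
        assert not censored
        assert val == pytest.approx(target, abs=dt)


class TestDoseResponse:
    DOSES = [9e-6, 1e-5, 2e-5, 3e-5, 5e-5]

    def test_exact_hill_recovery(self):
        eff = _hill_curve(np.asarray(self.DOSES), math.log10(1.685e-5), 2.0, 0.0, -100.0)
        fit = cp.fit_dose_response(self.DOSES, eff)
        assert fit.ic50 == pytest.approx(1.685e-5, rel=0.01)
        assert fit.hill_slope == pytest.approx(2.0, rel=0.01)
        assert fit.e_bottom == pytest.approx(-100.0, abs=0.5)

    def test_all_zero_effects_degenerate(self):
        fit = cp.fit_dose_response(self.DOSES, [0.0] * 5)
        assert fit.degenerate
        assert math.isnan(fit.ic50)

    def test_three_point_printed_endpoints(self):
        fit = cp.fit_dose_response([9e-6, 3e-5, 5e-5], [-15.9, -77.9, -100.0], e_bottom=-100.0)
        assert 1.6e-5 <= fit.ic50 <= 2.0e-5

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValidationError, match="3 distinct"):
            cp.fit_dose_response([1e-6, 1e-6, 2e-6], [-10, -11, -20])

    def test_monotone_fitted_curve(self):
        rng = np.random.default_rng(4)
        eff = _hill_curve(np.asarray(self.DOSES), math.log10(2e-5), 1.5, 0.0, -90.0) + rng.normal(0, 3, 5)
        fit = cp.fit_dose_response(self.DOSES, np.clip(eff, -100, 0))
        grid = np.logspace(-7, -3, 50)
        curve = _hill_curve(grid, math.log10(fit.ic50), fit.hill_slope, fit.e_top, fit.e_bottom)
        assert np.all(np.diff(curve) <= 1e-9)

    def test_determinism(self):
        eff = list(_hill_curve(np.asarray(self.DOSES), math.log10(2e-5), 1.3, 0.0, -85.0))
        f1 = cp.fit_dose_response(self.DOSES, eff)
        f2 = cp.fit_dose_response(self.DOSES, eff)
        assert f1.ic50 == f2.ic50 and f1.hill_slope == f2.hill_slope


class TestInverseDose:
    def _fit(self, h=1.0):
        eff = _hill_curve(np.asarray([1e-6, 1e-5, 1e-4]), math.log10(1e-5), h, 0.0, -100.0)
        return cp.fit_dose_response([1e-6, 1e-5, 1e-4], eff, e_bottom=-100.0)

    def test_half_span_returns_ic50(self):
        fit = self._fit()
        assert cp.inverse_dose(fit, -50.0) == pytest.approx(fit.ic50, rel=1e-6)

    def test_ec75_is_three_ic50_at_unit_hill(self):
        fit = self._fit(h=1.0)
        assert cp.ec(fit, 0.75) == pytest.approx(3.0 * fit.ic50, rel=0.01)

    def test_level_outside_range_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            cp.inverse_dose(self._fit(), 10.0)

    def test_verapamil_style_ec75_bracket(self):
        fit = cp.fit_dose_response([9e-6, 3e-5, 5e-5], [-15.9, -77.9, -100.0], e_bottom=-100.0)
        assert 2e-5 <= cp.ec(fit, 0.75) <= 4e-5


class TestParameterRecovery:
    def test_median_ic50_error_under_10pct(self):
        # 200 seeded 5-dose experiments, n = 15, effect noise at the scale
        # of the reported group SDs (~8%)
        doses = np.asarray([9e-6, 1e-5, 2e-5, 3e-5, 5e-5])
        true_ic50, true_h = 1.685e-5, 2.0
        truth = _hill_curve(doses, math.log10(true_ic50), true_h, 0.0, -100.0)
        rel_err_ic50, rel_err_h = [], []
        rng = np.random.default_rng(1234)
        for _ in range(200):
            per_prep = truth[None, :] + rng.normal(0, 8.0, size=(15, doses.size))
            means = np.clip(per_prep, -100, None).mean(axis=0)
            fit = cp.fit_dose_response(doses, means, e_bottom=-100.0)
            rel_err_ic50.append(abs(fit.ic50 - true_ic50) / true_ic50)
            rel_err_h.append(abs(fit.hill_slope - true_h) / true_h)
        assert float(np.median(rel_err_ic50)) < 0.10
        assert float(np.median(rel_err_h)) < 0.25
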