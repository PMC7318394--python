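import numpy as np
import pytest

from pisa import (
    ExposureCurve,
    ParametricArm,
    PowerFit,
    SyntheticTrialSpec,
    TimeGainCurve,
    analytic_mot,
    eval_power,
    fit_power,
    fit_timegain_quadratic,
    generate_trial,
    months_of_treatment,
    mot_per_year_gained,
    nnt_per_year_gained,
    round_up_to,
    threshold_crossing_time,
    time_gain,
    time_lost,
)
from pisa.errors import DomainError, InsufficientDataError, MonotonicityError
from pisa.pharmaco import IndexCurve


def month_grid(t_end, step=0.25):
    return np.arange(int(round(t_end / step)) + 1) * step


class TestMonthsOfTreatment:
    def test_no_events_full_exposure(self, grid_factory):
        curve = grid_factory(np.zeros(49))  # [0, 12] months
        assert months_of_treatment(curve).mot[-1] == pytest.approx(1200.0)

    def test_all_events_no_exposure(self, grid_factory):
        curve = grid_factory(np.full(49, 100.0))
        assert np.all(months_of_treatment(curve).mot == 0)

    def test_exponential_closed_form(self, exp_trial, exp_arms):
        mot = months_of_treatment(exp_trial.active)
        exact = analytic_mot(exp_arms[1], 60.0)
        assert mot.mot[-1] == pytest.approx(exact, rel=5e-6)


class TestIndexCurves:
    def test_mot_index_arithmetic(self):
        times = month_grid(24)
        exposure = ExposureCurve(times, 100.0 * times)  # mot(24) = 2400
        gain = TimeGainCurve(times, times)  # gain(24) = 24
        idx = mot_per_year_gained(exposure, gain)
        assert idx.values[-1] == pytest.approx(2400.0 / (24.0 / 12.0))

    def test_harmful_treatment_fully_masked(self):
        times = month_grid(24)
        exposure = ExposureCurve(times, 100.0 * times)
        gain = TimeGainCurve(times, -times)
        idx = mot_per_year_gained(exposure, gain)
        assert np.all(~np.isfinite(idx.values))
        assert idx.valid_from is None

    def test_valid_from_is_six_month_gain(self):
        times = month_grid(24)
        gain = TimeGainCurve(times, times)  # reaches 6 at t = 6
        idx = mot_per_year_gained(ExposureCurve(times, 100.0 * times), gain)
        assert idx.valid_from == 6.0

    def test_nnt_mot_pointwise_identity(self, exp_trial, exp_gain):
        exposure = months_of_treatment(exp_trial.active)
        mot_idx = mot_per_year_gained(exposure, exp_gain)
        nnt_idx = nnt_per_year_gained(exposure, exp_gain)
        ok = np.isfinite(mot_idx.values) & (mot_idx.times > 0)
        np.testing.assert_allclose(
            nnt_idx.values[ok] * mot_idx.times[ok], mot_idx.values[ok]
        )

    def test_nnt_hand_arithmetic(self):
        # average 95% of the cohort on treatment, 51.5 months gained at 24 m
        times = month_grid(24)
        exposure = ExposureCurve(times, 95.0 * times)
        gain = TimeGainCurve(times, np.full_like(times, 51.5))
        nnt = nnt_per_year_gained(exposure, gain)
        assert nnt.values[-1] == pytest.approx(95.0 / (51.5 / 12.0))
        assert round(nnt.values[-1], 1) == 22.1

    def test_nnt_undefined_at_zero(self):
        times = month_grid(6)
        nnt = nnt_per_year_gained(
            ExposureCurve(times, 100 * times), TimeGainCurve(times, times + 1)
        )
        assert not np.isfinite(nnt.values[0])

    def test_full_exposure_limit(self, grid_factory):
        """With no events, NNT/y+ equals 100*12/gain(t)."""
        curve = grid_factory(np.zeros(97))  # [0, 24]
        exposure = months_of_treatment(curve)
        times = exposure.times
        gain = TimeGainCurve(times, 0.05 * times**2 + 0.5 * times)
        nnt = nnt_per_year_gained(exposure, gain)
        ok = times > 0
        np.testing.assert_allclose(nnt.values[ok], 1200.0 / gain.values[ok])

    def test_provit_scale_synthetic_index(self):
        """Exponential arms calibrated to gain(24) ~ 50 per 100 give an
        MoT/y+ at 2 years on the scale seen in a high-event-rate statin
        trial (within 15% of 487)."""
        control = ParametricArm("exponential", {"hazard": 0.0105})
        active = ParametricArm("exponential", {"hazard": 0.008482211165628943})
        ds = generate_trial(
            SyntheticTrialSpec(control=control, active=active, duration_T=30.0,
                               t50_override=21.0)
        )
        gain = time_gain(time_lost(ds.control), time_lost(ds.active))
        idx = mot_per_year_gained(months_of_treatment(ds.active), gain)
        ok = np.isfinite(idx.values)
        at24 = np.interp(24.0, idx.times[ok], idx.values[ok])
        assert at24 == pytest.approx(487.0, rel=0.15)


def power_index(coef, expo, t_start=6.0, t_end=30.0, kind="MoT_per_year"):
    times = np.arange(int(round((t_end - t_start) / 0.25)) + 1) * 0.25 + t_start
    return IndexCurve(times, coef * times**expo, kind, valid_from=t_start)


class TestFitPower:
    def test_roundtrip_printed_parameters(self):
        fit = fit_power(power_index(2757.0, -0.554))
        assert fit.coef == pytest.approx(2757.0, rel=1e-10)
        assert fit.expo == pytest.approx(-0.554, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_index(self):
        fit = fit_power(power_index(123.0, 0.0))
        assert fit.expo == pytest.approx(0.0, abs=1e-12)
        assert fit.coef == pytest.approx(123.0)

    def test_shift_law_dividing_by_time(self):
        """a*t^b / t is exactly a*t^(b-1): the NNT fit inherits the MoT
        coefficient and shifts the exponent by exactly -1."""
        mot = power_index(2757.0, -0.554)
        nnt = IndexCurve(mot.times, mot.values / mot.times, "NNT_per_year", 6.0)
        fit = fit_power(nnt)
        assert round(fit.expo, 3) == -1.554
        assert fit.coef == pytest.approx(2757.0, rel=1e-6)

    def test_gain_threshold_never_reached(self):
        idx = IndexCurve(np.arange(10.0), np.ones(10), "MoT_per_year", None)
        with pytest.raises(DomainError, match="6-month"):
            fit_power(idx)

    def test_too_few_points(self):
        idx = IndexCurve(np.arange(5.0) + 1, np.ones(5), "MoT_per_year", 1.0)
        with pytest.raises(InsufficientDataError):
            fit_power(idx)

    def test_nonpositive_in_window(self):
        times = np.arange(20.0) + 1
        vals = np.ones(20)
        vals[10] = -1.0
        with pytest.raises(DomainError):
            fit_power(IndexCurve(times, vals, "MoT_per_year", 1.0))


class TestEvalPower:
    @pytest.mark.parametrize(
        "coef, expo, t, ndigits, expected",
        [
            (2757.0, -0.554, 24.0, 0, 474),
            (109635.0, -2.278, 72.0, 1, 6.4),
            (11459.0, -1.562, 24.0, 1, 80.0),
        ],
    )
    def test_table_values(self, coef, expo, t, ndigits, expected):
        fit = PowerFit(coef, expo, (6.0, 30.0), 1.0)
        assert round(eval_power(fit, t), ndigits) == expected

    def test_coef_is_value_at_one_month(self):
        fit = PowerFit(321.0, -1.1, (6.0, 30.0), 1.0)
        assert eval_power(fit, 1.0) == pytest.approx(321.0)

    def test_nonpositive_time_rejected(self):
        fit = PowerFit(1.0, -1.0, (6.0, 30.0), 1.0)
        with pytest.raises(DomainError):
            eval_power(fit, 0.0)


class TestThresholdCrossing:
    def test_unit_crossing(self):
        fit = PowerFit(1000.0, -0.7, (6.0, 30.0), 1.0)
        assert threshold_crossing_time(fit, 1000.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "coef, expo, level, expected",
        [
            (2757.0, -0.554, 1000.0, 6.3),
            (109635.0, -1.278, 1000.0, 39.5),
            (109635.0, -2.278, 50.0, 29.3),
        ],
    )
    def test_reported_crossings(self, coef, expo, level, expected):
        """'Reached after' times are the exact crossing rounded up to the
        displayed 0.1-month resolution."""
        fit = PowerFit(coef, expo, (6.0, 72.0), 1.0)
        t = threshold_crossing_time(fit, level)
        assert round_up_to(t, 0.1) == pytest.approx(expected)

    def test_increasing_index_rejected(self):
        with pytest.raises(MonotonicityError):
            threshold_crossing_time(PowerFit(10.0, 0.5, (1.0, 10.0), 1.0), 5.0)

    def test_mutual_inverse_with_eval(self):
        fit = PowerFit(2757.0, -0.554, (6.0, 30.0), 1.0)
        for t in (6.0, 12.5, 30.0):
            level = eval_power(fit, t)
            assert threshold_crossing_time(fit, level) == pytest.approx(t, rel=1e-12)

    def test_round_up_keeps_exact_multiples(self):
        assert round_up_to(6.3, 0.1) == 6.3
        assert round_up_to(6.21, 0.1) == 6.3
        assert round_up_to(16.0, 1.0) == 16.0


def test_mot_index_strictly_decreasing_on_superlinear_gain(exp_trial, exp_gain):
    """With super-linear gain (a2 > 0), MoT/y+ decreases over its defined range."""
    quad = fit_timegain_quadratic(exp_gain, exp_trial.t50)
    assert quad.a2 > 0
    exposure = months_of_treatment(exp_trial.active)
    idx = mot_per_year_gained(exposure, exp_gain)
    vals = idx.values[np.isfinite(idx.values)]
    assert np.all(np.diff(vals) < 0)
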