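"""Weibull survival mathematics, transition probabilities, and KM fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adjuvant_cea.survival import (
    CycleSpec,
    FitError,
    KMCurve,
    WeibullParams,
    cumulative_event_probability,
    fit_weibull_to_km,
    params_from_median,
    transition_probability,
    weibull_median,
    weibull_survival,
)

LN2 = math.log(2.0)


class TestWeibullSurvival:
    def test_median_of_exponential_curve_is_half(self):
        # chemotherapy median DFS 19.8 months: survival at the median is 0.5
        p = WeibullParams(scale=LN2 / 19.8, shape=1.0)
        assert weibull_survival(p, 19.8) == pytest.approx(0.5, rel=1e-12)

    def test_survival_is_one_at_time_zero(self):
        assert weibull_survival(WeibullParams(0.3, 2.7), 0.0) == 1.0

    def test_against_hazard_integral_oracle(self):
        # S(t) = exp(-integral of h(s) = scale*shape*s**(shape-1) from 0 to t)
        from scipy.integrate import quad

        p = WeibullParams(scale=0.01, shape=1.5)
        cumhaz, _ = quad(lambda s: p.scale * p.shape * s ** (p.shape - 1.0), 0.0, 10.0)
        assert weibull_survival(p, 10.0) == pytest.approx(math.exp(-cumhaz), rel=1e-9)

    def test_strictly_decreasing(self):
        p = WeibullParams(0.05, 0.8)
        t = np.linspace(0.1, 100, 50)
        assert np.all(np.diff(weibull_survival(p, t)) < 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(WeibullParams(0.1), -1.0)

    @pytest.mark.parametrize("scale,shape", [(0.0, 1.0), (-1.0, 1.0), (0.1, 0.0), (0.1, -2.0)])
    def test_nonpositive_parameters_rejected(self, scale, shape):
        with pytest.raises(ValueError):
            WeibullParams(scale, shape)


class TestCumulativeEventProbability:
    def test_zero_rate_means_no_events(self):
        assert cumulative_event_probability(0.0, 42.0) == 0.0

    def test_median_rate_gives_half(self):
        assert cumulative_event_probability(LN2 / 19.8, 19.8) == pytest.approx(0.5, rel=1e-12)

    def test_closed_form(self):
        assert cumulative_event_probability(0.1, 5.0) == pytest.approx(1 - math.exp(-0.5), rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cumulative_event_probability(-0.1, 1.0)
        with pytest.raises(ValueError):
            cumulative_event_probability(0.1, -1.0)


class TestTransitionProbability:
    def test_exponential_is_memoryless(self):
        p = WeibullParams(scale=0.035, shape=1.0)
        u = 0.69
        expected = 1.0 - math.exp(-0.035 * u)
        vals = [transition_probability(p, t, u) for t in np.arange(1, 120) * u]
        assert max(abs(v - expected) for v in vals) < 1e-12

    def test_vanishing_cycle_length_gives_zero(self):
        p = WeibullParams(0.02, 1.3)
        assert transition_probability(p, 12.0, 1e-10) == pytest.approx(0.0, abs=1e-10)

    def test_conditional_survival_oracle_single_case(self):
        p = WeibullParams(scale=0.01, shape=1.3)
        direct = transition_probability(p, 12.0, 0.69)
        oracle = 1.0 - weibull_survival(p, 12.0) / weibull_survival(p, 12.0 - 0.69)
        assert direct == pytest.approx(oracle, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        scale=st.floats(0.005, 0.1),
        shape=st.floats(0.5, 2.0),
        u=st.floats(0.3, 1.5),
        frac=st.floats(0.0, 1.0),
    )
    def test_conditional_survival_oracle_property(self, scale, shape, u, frac):
        """P(t, u) == 1 - S(t)/S(t-u) wherever the ratio is well-conditioned."""
        p = WeibullParams(scale, shape)
        tmax = (8.0 / scale) ** (1.0 / shape)  # cumulative hazard <= 8
        t = u + frac * max(min(120.0, tmax) - u, 0.0)
        direct = transition_probability(p, t, u)
        oracle = 1.0 - weibull_survival(p, t) / weibull_survival(p, t - u)
        assert direct == pytest.approx(oracle, rel=1e-12, abs=1e-15)

    def test_chaining_recovers_survival(self):
        # product over cycles of (1 - P_k) equals S(K*u)
        p = WeibullParams(scale=0.03, shape=1.4)
        u = 0.69
        K = 120
        prod = np.prod([1.0 - transition_probability(p, k * u, u) for k in range(1, K + 1)])
        assert prod == pytest.approx(weibull_survival(p, K * u), rel=1e-10)

    def test_cycle_end_before_cycle_length_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(WeibullParams(0.1), 0.5, 0.69)


class TestParamsFromMedian:
    def test_trial_median_calibration(self):
        # gefitinib median DFS 30.8 months, exponential
        p = params_from_median(30.8, shape=1.0)
        assert p.scale == pytest.approx(LN2 / 30.8, rel=1e-12)
        assert p.scale == pytest.approx(0.022506, rel=1e-4)

    def test_unit_median_quadratic_shape(self):
        assert params_from_median(1.0, shape=2.0).scale == pytest.approx(LN2, rel=1e-12)

    @pytest.mark.parametrize("median,shape", [(30.8, 1.0), (19.8, 1.0), (5.0, 2.2), (75.5, 0.7)])
    def test_defining_identity(self, median, shape):
        p = params_from_median(median, shape)
        assert weibull_survival(p, median) == pytest.approx(0.5, rel=1e-12)
        assert weibull_median(p) == pytest.approx(median, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            params_from_median(0.0)
        with pytest.raises(ValueError):
            params_from_median(10.0, shape=-1.0)


class TestKMCurve:
    def test_duplicate_times_keep_last_survival(self):
        c = KMCurve(times=[0, 6, 6, 12], survival=[1.0, 0.9, 0.8, 0.7])
        assert list(c.times) == [0, 6, 12]
        assert list(c.survival) == [1.0, 0.8, 0.7]

    def test_nonmonotone_survival_rejected(self):
        with pytest.raises(ValueError):
            KMCurve(times=[1, 2, 3], survival=[0.9, 0.95, 0.8])

    def test_csv_round_trip(self, tmp_path):
        c = KMCurve(times=[0, 6, 12], survival=[1.0, 0.8, 0.6], at_risk=[100, 80, 55])
        path = tmp_path / "km.csv"
        c.to_csv(path)
        back = KMCurve.from_csv(path)
        np.testing.assert_allclose(back.times, c.times)
        np.testing.assert_allclose(back.survival, c.survival)
        np.testing.assert_allclose(back.at_risk, c.at_risk)


class TestFitWeibull:
    def test_noise_free_curve_recovered_exactly(self):
        true = WeibullParams(scale=0.02, shape=1.2)
        t = np.array([6.0, 12.0, 18.0, 24.0, 36.0])
        fit = fit_weibull_to_km(KMCurve(times=t, survival=weibull_survival(true, t)))
        assert fit.scale == pytest.approx(true.scale, rel=1e-7)
        assert fit.shape == pytest.approx(true.shape, rel=1e-7)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.n_points == 5

    def test_points_at_survival_one_are_dropped(self):
        true = WeibullParams(scale=0.03, shape=0.9)
        t = np.array([0.0, 6.0, 12.0, 24.0, 48.0])
        s = np.append(1.0, weibull_survival(true, t[1:]))
        fit = fit_weibull_to_km(KMCurve(times=t, survival=s))
        assert fit.n_points == 4
        assert fit.shape == pytest.approx(0.9, rel=1e-7)

    def test_two_usable_points_is_an_error(self):
        with pytest.raises(FitError):
            fit_weibull_to_km(KMCurve(times=[0, 6, 12], survival=[1.0, 0.8, 0.6]))

    def test_at_risk_weighting_changes_fit_on_noisy_data(self):
        rng = np.random.default_rng(7)
        true = WeibullParams(scale=0.03, shape=1.0)
        t = np.linspace(2, 60, 20)
        s = np.clip(weibull_survival(true, t) * np.exp(rng.normal(0, 0.02, t.size)), 1e-3, 0.999)
        s = np.minimum.accumulate(s)
        unweighted = fit_weibull_to_km(KMCurve(times=t, survival=s))
        weighted = fit_weibull_to_km(
            KMCurve(times=t, survival=s, at_risk=np.linspace(200, 5, t.size))
        )
        assert weighted.scale != unweighted.scale  # weights actually used
        assert weighted.shape == pytest.approx(1.0, rel=0.15)


class TestCycleSpec:
    def test_trial_grid_has_174_cycles(self):
        spec = CycleSpec(cycle_length_days=21.0, horizon_years=10.0)
        assert spec.n_cycles == 174

    def test_cycle_length_in_months(self):
        assert CycleSpec().cycle_months == pytest.approx(21.0 / (365.25 / 12.0), rel=1e-12)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            CycleSpec(cycle_length_days=0.0)
        with pytest.raises(ValueError):
            CycleSpec(horizon_years=-1.0)
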