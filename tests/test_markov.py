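"""Markov cohort engine: transition structure, accrual arithmetic, discounting."""

import math

import numpy as np
import pytest

from adjuvant_cea.config import build_strategy
from adjuvant_cea.markov import (
    CycleState,
    DiscountSpec,
    PatientProfile,
    StrategySpec,
    accumulate,
    cycle_cost,
    cycle_utility,
    discount_factor,
    drug_schedule,
    run_cohort,
    transition_matrix,
)
from adjuvant_cea.survival import CycleSpec, WeibullParams, weibull_survival

CYCLES = CycleSpec()
U = CYCLES.cycle_months


def make_strategy(**kwargs) -> StrategySpec:
    defaults = dict(
        name="test",
        dfs_params=WeibullParams(scale=math.log(2) / 30.8),
        os_params=WeibullParams(scale=math.log(2) / 75.5),
        drug_costs=np.zeros(CYCLES.n_cycles + 1),
        treatment_cycles=0,
        ae_incidence_g34=0.0,
        dfs_utility=0.80,
    )
    defaults.update(kwargs)
    return StrategySpec(**defaults)


def rate_for_prob(p: float) -> WeibullParams:
    """Exponential params whose per-cycle event probability is exactly p."""
    return WeibullParams(scale=-math.log(1.0 - p) / U, shape=1.0)


class TestTransitionMatrix:
    def test_negligible_hazards_give_identity(self):
        s = make_strategy(dfs_params=WeibullParams(1e-15), os_params=WeibullParams(1e-15))
        np.testing.assert_allclose(transition_matrix(s, 10, CYCLES), np.eye(3), atol=1e-12)

    def test_event_death_decomposition(self):
        # DFS event prob 0.10, death prob 0.03 -> DFS row (0.90, 0.07, 0.03)
        s = make_strategy(dfs_params=rate_for_prob(0.10), os_params=rate_for_prob(0.03))
        m = transition_matrix(s, 5, CYCLES)
        np.testing.assert_allclose(m[0], [0.90, 0.07, 0.03], atol=1e-12)
        np.testing.assert_allclose(m[1], [0.0, 0.97, 0.03], atol=1e-12)
        np.testing.assert_allclose(m[2], [0.0, 0.0, 1.0], atol=0)

    def test_rows_stochastic_under_fixture_calibration(self, model):
        for s in model.strategies.values():
            for k in (1, 10, 100, 174):
                m = transition_matrix(s, k, CYCLES)
                np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(m >= 0)

    def test_matrix_rederivable_from_survival_fits(self, model):
        # conditional-probability oracle at cycle 10
        from adjuvant_cea.survival import transition_probability

        s = model.strategies["gefitinib"]
        m = transition_matrix(s, 10, CYCLES)
        d = transition_probability(s.os_params, 10 * U, U)
        e = transition_probability(s.dfs_params, 10 * U, U)
        np.testing.assert_allclose(m[0], [1 - e, e - d, d], atol=1e-14)

    def test_cycle_index_must_be_positive(self):
        with pytest.raises(ValueError):
            transition_matrix(make_strategy(), 0, CYCLES)


class TestRunCohort:
    def test_occupancy_conserved_and_death_monotone(self, model):
        for trace in model.run_traces().values():
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(trace.occupancy[:, 2]) >= -1e-15)
            assert np.all((trace.occupancy >= -1e-15) & (trace.occupancy <= 1 + 1e-15))

    def test_cohort_survival_tracks_os_curve(self, model):
        # 1 - p_death at every cycle boundary equals the fitted OS curve
        for name, trace in model.run_traces().items():
            os_params = model.strategies[name].os_params
            k = np.arange(trace.occupancy.shape[0])
            expected = weibull_survival(os_params, k * U)
            np.testing.assert_allclose(1.0 - trace.occupancy[:, 2], expected, atol=1e-10)

    def test_stationary_cohort_closed_form(self):
        # no transitions, utility 0.8, no discounting: QALY = 174*(21/365.25)*0.8
        s = make_strategy(
            dfs_params=WeibullParams(1e-18),
            os_params=WeibullParams(1e-18),
            followup_cost=55.60,
            supportive_cost=0.0,
            pd_entry_cost=0.0,
            ae_cost=0.0,
        )
        trace = run_cohort(s, CYCLES, DiscountSpec(0.0))
        assert trace.qaly.sum() == pytest.approx(174 * (21 / 365.25) * 0.8, rel=1e-9)
        assert trace.cost.sum() == pytest.approx(174 * 55.60, rel=1e-9)

    def test_cohort_started_in_death_accrues_nothing(self):
        trace = run_cohort(make_strategy(), CYCLES, start_state="death")
        assert trace.disc_cost.sum() == 0.0
        assert trace.disc_qaly.sum() == 0.0

    def test_modeled_dfs_median_matches_input_median(self, model):
        # invert the DFS occupancy column of the trace
        trace = model.run_traces()["gefitinib"]
        p_dfs = trace.occupancy[:, 0]
        k_cross = int(np.argmax(p_dfs <= 0.5))
        assert abs(k_cross * U - 30.8) <= U

    def test_undiscounted_totals_dominate_discounted(self, model):
        for trace in model.run_traces().values():
            assert trace.cost.sum() >= trace.disc_cost.sum()
            assert trace.qaly.sum() >= trace.disc_qaly.sum()

    def test_monotonicity_in_utility_and_cost(self, model):
        base = accumulate(run_cohort(model.strategies["gefitinib"], CYCLES))
        richer = model.strategies["gefitinib"].with_overrides(dfs_utility=0.9)
        pricier = model.strategies["gefitinib"].with_overrides(supportive_cost=500.0)
        assert accumulate(run_cohort(richer, CYCLES)).qaly > base.qaly
        assert accumulate(run_cohort(pricier, CYCLES)).cost > base.cost

    def test_halved_cycle_length_is_discretization_stable(self, fixture_config):
        # total QALY moves by < 1% when the cycle grid is twice as fine
        profile = fixture_config.patient.to_profile()
        results = {}
        for days in (21.0, 10.5):
            cyc = CycleSpec(cycle_length_days=days, horizon_years=10.0)
            spec, _ = build_strategy(fixture_config.intervention, cyc, profile)
            results[days] = accumulate(run_cohort(spec, cyc, DiscountSpec(0.03)))
        assert results[10.5].qaly == pytest.approx(results[21.0].qaly, rel=0.01)

    def test_trace_frame_layout(self, model):
        df = model.run_traces()["gefitinib"].to_frame()
        assert list(df.columns) == [
            "cycle", "p_dfs", "p_pd", "p_death", "new_pd", "disc_cost_usd", "disc_qaly",
        ]
        assert df.iloc[-1]["cycle"] == "total"
        assert len(df) == CYCLES.n_cycles + 2


class TestDrugSchedule:
    def test_chemotherapy_vial_arithmetic(self):
        # vinorelbine 43 mg -> 5 vials x2 days = 81.60; cisplatin 129 mg -> 5 vials = 14.00
        costs = drug_schedule(PatientProfile(), "chemotherapy", CYCLES)
        np.testing.assert_allclose(costs[1:5], 95.60)
        assert np.all(costs[5:] == 0.0)

    def test_gefitinib_daily_tablets(self):
        costs = drug_schedule(PatientProfile(), "gefitinib", CYCLES)
        np.testing.assert_allclose(costs[1:35], 21 * 23.33)
        # final partial cycle: 24 months = 730.5 days -> 16.5 treated days
        assert costs[35] == pytest.approx(16.5 * 23.33, rel=1e-12)
        assert np.all(costs[36:] == 0.0)

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError):
            drug_schedule(PatientProfile(), "osimertinib", CYCLES)


class TestCycleAccrual:
    def test_followup_only_after_treatment(self):
        s = make_strategy(followup_cost=55.60)
        state = CycleState(p_dfs=1.0, p_pd=0.0, p_death=0.0, new_pd=0.0)
        assert cycle_cost(s, state, 100) == pytest.approx(55.60)

    def test_supportive_care_for_prevalent_pd(self):
        s = make_strategy()
        state = CycleState(p_dfs=0.0, p_pd=1.0, p_death=0.0, new_pd=0.0)
        assert cycle_cost(s, state, 10) == pytest.approx(337.50)

    def test_gefitinib_first_cycle_cost(self, model):
        # 55.60 + 21*23.33 + 0.12*507.40 = 606.418 by hand
        s = model.strategies["gefitinib"]
        state = CycleState(1.0, 0.0, 0.0, 0.0)
        assert cycle_cost(s, state, 1) == pytest.approx(55.60 + 21 * 23.33 + 0.12 * 507.40, rel=1e-12)
        assert cycle_cost(s, state, 1) == pytest.approx(606.418, abs=1e-3)

    def test_pd_entry_charged_to_incident_fraction(self):
        s = make_strategy()
        with_inflow = cycle_cost(s, CycleState(0.5, 0.2, 0.3, 0.1), 50)
        without = cycle_cost(s, CycleState(0.5, 0.2, 0.3, 0.0), 50)
        assert with_inflow - without == pytest.approx(0.1 * 1877.25)

    def test_utility_of_death_is_zero(self):
        s = make_strategy()
        assert cycle_utility(s, CycleState(0.0, 0.0, 1.0, 0.0), 5, CYCLES) == 0.0

    def test_pd_utility_accrual(self):
        s = make_strategy()
        q = cycle_utility(s, CycleState(0.0, 1.0, 0.0, 0.0), 5, CYCLES)
        assert q == pytest.approx(0.70 * 21 / 365.25, rel=1e-12)

    def test_ae_disutility_applies_only_on_treatment(self, model):
        s = model.strategies["gefitinib"]
        state = CycleState(1.0, 0.0, 0.0, 0.0)
        on = cycle_utility(s, state, 1, CYCLES)
        off = cycle_utility(s, state, s.treatment_cycles + 1, CYCLES)
        assert on == pytest.approx((0.80 - 0.12 * 0.0731) * 21 / 365.25, rel=1e-12)
        assert off == pytest.approx(0.80 * 21 / 365.25, rel=1e-12)


class TestDiscounting:
    def test_no_time_no_discount(self):
        assert discount_factor(0, DiscountSpec(0.03)) == 1.0

    def test_zero_rate_never_discounts(self):
        assert discount_factor(174, DiscountSpec(0.0)) == 1.0

    def test_ten_year_factor_closed_form(self):
        f = discount_factor(174, DiscountSpec(0.03))
        assert f == pytest.approx(1.03 ** (-174 * 21 / 365.25), rel=1e-12)
        assert f == pytest.approx(0.744, abs=5e-4)

    def test_strictly_decreasing(self):
        d = DiscountSpec(0.03)
        factors = [discount_factor(k, d) for k in range(0, 50)]
        assert all(a > b for a, b in zip(factors, factors[1:]))
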