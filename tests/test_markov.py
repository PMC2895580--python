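"""Transition estimation, matrix transforms, cohort runs, valuation."""
import numpy as np
import pytest

from pucea import markov
from pucea.costing import build_cost_profiles
from pucea.markov import (
    CohortTrace,
    DiscountSpec,
    ModelError,
    ScenarioSpec,
    TransitionMatrix,
    UtilityProfile,
    accumulate,
    add_mortality,
    annual_to_monthly,
    estimate_annual_matrix_intervention,
    estimate_monthly_matrix_control,
    icer,
    present_value,
    run_cohort,
    scenario_matrix,
)
from pucea.states import HealthState, STATE_INDEX, STATE_ORDER
from pucea.synthetic_data import CohortParams, generate_registry

from conftest import constant_registry, make_registry

NO = HealthState.NO_PU.value
S1 = HealthState.SINGLE_1.value
S2 = HealthState.SINGLE_2.value


def no_healing():
    return {g: 0.0 for g in (1, 2, 3, 4)}


class TestControlMatrix:
    def test_zero_incidence_zero_healing_is_identity(self):
        registry = constant_registry(10, 88)
        tm = estimate_monthly_matrix_control(
            registry, no_healing(), {1: 1.0}
        )
        assert np.allclose(tm.probs, np.eye(10))

    def test_no_pu_row_off_diagonal_equals_observed_incidence(self):
        m1 = [NO] * 88
        m2 = [S1] * 13 + [NO] * 75
        registry = make_registry({1: m1, 2: m2}, n_patients=88)
        tm = estimate_monthly_matrix_control(
            registry, no_healing(), {1: 10 / 13, 2: 3 / 13}
        )
        i = STATE_INDEX[HealthState.NO_PU]
        off = tm.probs[i].sum() - tm.probs[i, i]
        assert off == pytest.approx(13 / 88)

    def test_grade2_healing_converted_to_monthly(self):
        registry = constant_registry(10, 88)
        tm = estimate_monthly_matrix_control(
            registry, {1: 0.0, 2: 0.67, 3: 0.0, 4: 0.0}, {1: 1.0}
        )
        i = STATE_INDEX[HealthState.SINGLE_2]
        # 1 - (1 - 0.67)^(30/90), evaluated independently
        assert tm.probs[i, STATE_INDEX[HealthState.NO_PU]] == pytest.approx(
            1 - 0.33 ** (1 / 3)
        )

    def test_empty_registry_rejected(self):
        registry = constant_registry(1, 4)
        registry.records = registry.records.iloc[0:0]
        with pytest.raises(ModelError):
            estimate_monthly_matrix_control(registry, no_healing(), {1: 1.0})


class TestAnnualMatrix:
    def test_identical_periods_give_identity(self):
        registry = constant_registry(10, 40)
        tm = estimate_annual_matrix_intervention(registry, registry)
        assert np.allclose(tm.probs, np.eye(10))
        assert tm.cycle_length_months == 12.0

    def test_everyone_heals_sends_pu_rows_to_no_pu(self):
        baseline = constant_registry(15, 40, pu_state=S2)
        final = constant_registry(0, 40)
        tm = estimate_annual_matrix_intervention(baseline, final)
        i = STATE_INDEX[HealthState.SINGLE_2]
        assert tm.probs[i, STATE_INDEX[HealthState.NO_PU]] == 1.0

    def test_unobserved_rows_fall_back_to_self_transition(self):
        baseline = constant_registry(5, 20, pu_state=S1)
        final = constant_registry(5, 20, pu_state=S1)
        tm = estimate_annual_matrix_intervention(baseline, final)
        assert HealthState.MULTI_3.value in tm.meta["fallback_rows"]

    def test_disjoint_patient_sets_rejected(self):
        baseline = constant_registry(2, 10)
        final = constant_registry(2, 10)
        final.records = final.records.assign(
            patient_id=final.records["patient_id"] + 100
        )
        with pytest.raises(ModelError, match="paired"):
            estimate_annual_matrix_intervention(baseline, final)


class TestAnnualToMonthly:
    def test_identity_stays_identity(self):
        annual = TransitionMatrix(np.eye(10), 12.0)
        monthly = annual_to_monthly(annual)
        assert np.allclose(monthly.probs, np.eye(10))
        assert monthly.cycle_length_months == 1.0

    def test_two_state_absorbing_closed_form(self):
        annual = TransitionMatrix(
            np.array([[0.9, 0.1], [0.0, 1.0]]), 12.0, labels=("well", "sick")
        )
        monthly = annual_to_monthly(annual)
        assert monthly.probs[0, 1] == pytest.approx(1 - 0.9 ** (1 / 12))
        assert monthly.meta["frobenius_error"] < 1e-6

    def test_rows_sum_to_one_exactly(self):
        rng = np.random.default_rng(8)
        P = rng.dirichlet(np.full(10, 5.0), size=10)
        P = 0.8 * np.eye(10) + 0.2 * P  # diagonally dominant, safe root
        P = P / P.sum(1, keepdims=True)
        monthly = annual_to_monthly(
            TransitionMatrix(P, 12.0, labels=tuple("abcdefghij"))
        )
        assert np.allclose(monthly.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_twelfth_power_recovers_annual_without_clipping(self):
        P = np.eye(10) * 0.9
        P[:, STATE_INDEX[HealthState.NO_PU]] += 0.1
        P[STATE_INDEX[HealthState.DEATH]] = 0.0
        P[STATE_INDEX[HealthState.DEATH], STATE_INDEX[HealthState.DEATH]] = 1.0
        P[STATE_INDEX[HealthState.NO_PU]] = 0.0
        P[STATE_INDEX[HealthState.NO_PU], STATE_INDEX[HealthState.NO_PU]] = 0.95
        P[STATE_INDEX[HealthState.NO_PU], STATE_INDEX[HealthState.SINGLE_1]] = 0.05
        monthly = annual_to_monthly(TransitionMatrix(P, 12.0))
        if monthly.meta["clipped_mass"] == 0.0:
            recovered = np.linalg.matrix_power(monthly.probs, 12)
            assert np.linalg.norm(recovered - P) < 1e-6


class TestMortality:
    def test_zero_mortality_only_adds_absorbing_row(self):
        base = TransitionMatrix(_alive_identity(), 1.0)
        out = add_mortality(base, 0.0)
        assert np.allclose(out.probs, base.probs)

    def test_thirty_percent_annual_converts_to_monthly(self):
        out = add_mortality(TransitionMatrix(_alive_identity(), 1.0), 0.30)
        d = out.meta["monthly_death_prob"]
        assert d == pytest.approx(1 - 0.7 ** (1 / 12))

    def test_certain_death_within_a_year(self):
        out = add_mortality(TransitionMatrix(_alive_identity(), 1.0), 1.0)
        init = np.zeros(10)
        init[0] = 1.0
        trace = run_cohort(init, [(out, 12)])
        assert trace.state_series(HealthState.DEATH)[12] == pytest.approx(1.0)

    def test_mortality_outside_unit_interval_rejected(self):
        with pytest.raises(ModelError):
            add_mortality(TransitionMatrix(_alive_identity(), 1.0), 1.5)

    def test_existing_death_mass_rejected(self):
        P = _alive_identity()
        P[0, 0] = 0.9
        P[0, STATE_INDEX[HealthState.DEATH]] = 0.1
        with pytest.raises(ModelError, match="death mass"):
            add_mortality(TransitionMatrix(P, 1.0), 0.1)


@pytest.fixture(scope="module")
def year1():
    registry = generate_registry(CohortParams(seed=17))
    params = CohortParams(seed=17)
    control = estimate_monthly_matrix_control(
        registry, params.healing_prob_90d_by_grade, params.grade_mix
    )
    annual = TransitionMatrix(
        np.linalg.matrix_power(control.probs, 12), 12.0
    )
    return control, annual


class TestScenarios:

    def test_total_keeps_year1_dynamics(self, year1):
        monthly, annual = year1
        out = scenario_matrix(ScenarioSpec("total"), monthly, annual)
        assert np.allclose(out.probs, monthly.probs)

    def test_partial_freezes_distribution_without_mortality(self, year1):
        monthly, annual = year1
        out = scenario_matrix(ScenarioSpec("partial"), monthly, annual)
        init = np.zeros(10)
        init[0], init[1] = 0.7, 0.3
        trace = run_cohort(init, [(out, 12)])
        assert np.allclose(trace.occupancy[-1], init)

    def test_reversal_returns_prevalence_toward_baseline(self):
        # well-conditioned annual dynamics: modest onset and healing
        A = np.eye(9)
        A[0, 0], A[0, 1], A[0, 2] = 0.90, 0.07, 0.03
        A[1, 0], A[1, 1] = 0.30, 0.70
        A[2, 0], A[2, 2] = 0.25, 0.75
        P = np.zeros((10, 10))
        P[:9, :9] = A
        P[9, 9] = 1.0
        annual = TransitionMatrix(P, 12.0)
        monthly = annual_to_monthly(annual)
        pi0 = np.zeros(10)
        pi0[0], pi0[1], pi0[2] = 0.614, 0.25, 0.136
        year1 = run_cohort(pi0, [(monthly, 12)])
        reversal = scenario_matrix(
            ScenarioSpec("none"), monthly, annual, pi0
        )
        year2 = run_cohort(year1.occupancy[-1], [(reversal, 12)])
        pu0 = year1.any_pu_series()[0]
        pu12 = year1.any_pu_series()[-1]
        pu_series = year2.any_pu_series()
        assert pu12 < pu0
        # monotone rise back toward the starting prevalence
        assert np.all(np.diff(pu_series) > -1e-9)
        assert pu_series[-1] == pytest.approx(pu0, abs=0.02)

    def test_singular_annual_matrix_uses_time_reversal(self):
        A = np.zeros((9, 9))
        A[:, 0] = 1.0  # everyone heals: rank 1, singular
        P = np.zeros((10, 10))
        P[:9, :9] = A
        P[9, 9] = 1.0
        annual = TransitionMatrix(P, 12.0)
        monthly = annual_to_monthly(annual)
        pi0 = np.zeros(10)
        pi0[0], pi0[1] = 0.6, 0.4
        out = scenario_matrix(ScenarioSpec("none"), monthly, annual, pi0)
        assert out.meta["method"].startswith("time_reversal")
        # one year of the reversal restores the baseline mix
        end = np.zeros(10)
        end[0] = 1.0  # post-year-1 distribution: everyone healed
        trace = run_cohort(end, [(out, 12)])
        assert trace.occupancy[-1][1] == pytest.approx(0.4, abs=1e-6)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ModelError):
            ScenarioSpec("forever")


class TestCohortRuns:
    def test_identity_matrix_keeps_trace_constant(self):
        tm = TransitionMatrix(np.eye(10), 1.0)
        init = np.full(10, 0.1)
        trace = run_cohort(init, [(tm, 5)])
        assert np.allclose(trace.occupancy, init)
        assert trace.n_cycles == 5

    def test_schedule_length_sets_trace_length(self):
        tm = TransitionMatrix(np.eye(10), 1.0)
        init = np.zeros(10)
        init[0] = 1.0
        trace = run_cohort(init, [(tm, 12), (tm, 12)])
        assert trace.occupancy.shape == (25, 10)

    def test_invalid_initial_distribution_rejected(self):
        tm = TransitionMatrix(np.eye(10), 1.0)
        with pytest.raises(ModelError):
            run_cohort(np.full(10, 0.2), [(tm, 1)])

    def test_death_occupancy_never_decreases(self):
        registry = generate_registry(CohortParams(seed=23))
        params = CohortParams(seed=23)
        control = estimate_monthly_matrix_control(
            registry, params.healing_prob_90d_by_grade, params.grade_mix
        )
        with_death = add_mortality(control, 0.3)
        init = np.zeros(10)
        init[0] = 1.0
        trace = run_cohort(init, [(control, 12), (with_death, 12)])
        dead = trace.state_series(HealthState.DEATH)
        assert np.all(np.diff(dead) >= 0)
        assert np.all(np.diff(dead[12:]) > 0)  # strict once mortality acts


class TestValuation:
    def test_two_years_of_full_health_is_two_qalys(self):
        occ = np.zeros((25, 10))
        occ[:, 0] = 1.0
        trace = CohortTrace(occ)
        utilities = UtilityProfile(
            weights={**UtilityProfile().weights, HealthState.NO_PU: 1.0}
        )
        costs = build_cost_profiles()[0]
        qalys, _ = accumulate(
            trace, utilities, costs, DiscountSpec(cost_rate=0.0, effect_rate=0.0)
        )
        assert qalys == pytest.approx(2.0, abs=1e-12)

    def test_present_value_of_100_after_one_year(self):
        assert present_value(100.0, 1.0, 0.04) == pytest.approx(96.15, abs=0.005)

    def test_qalys_decrease_with_mortality_and_discounting(self):
        init = np.zeros(10)
        init[0] = 1.0
        utilities = UtilityProfile()
        costs = build_cost_profiles()[0]
        qalys_by_mort = []
        for mort in (0.0, 0.3, 0.6):
            tm = add_mortality(TransitionMatrix(_alive_identity(), 1.0), mort)
            trace = run_cohort(init, [(tm, 24)])
            q, _ = accumulate(trace, utilities, costs, DiscountSpec())
            qalys_by_mort.append(q)
        assert qalys_by_mort == sorted(qalys_by_mort, reverse=True)

        tm = add_mortality(TransitionMatrix(_alive_identity(), 1.0), 0.3)
        trace = run_cohort(init, [(tm, 24)])
        qalys_by_rate = [
            accumulate(
                trace, utilities, costs, DiscountSpec(effect_rate=r)
            )[0]
            for r in (0.0, 0.015, 0.1)
        ]
        assert qalys_by_rate == sorted(qalys_by_rate, reverse=True)

    def test_overhead_lump_sum_added_undiscounted(self):
        occ = np.zeros((13, 10))
        occ[:, 0] = 1.0
        trace = CohortTrace(occ)
        _, qic = build_cost_profiles()
        _, with_overhead = accumulate(
            trace, UtilityProfile(), qic, DiscountSpec(), overhead_years=1.0
        )
        _, without = accumulate(
            trace, UtilityProfile(), qic, DiscountSpec(), overhead_years=0.0
        )
        assert with_overhead - without == pytest.approx(323.0 + 1550.0)

    def test_missing_utility_is_an_error(self):
        occ = np.zeros((2, 10))
        occ[:, 0] = 1.0
        trace = CohortTrace(occ)
        partial = UtilityProfile(weights={HealthState.NO_PU: 0.7, HealthState.DEATH: 0.0})
        with pytest.raises(ModelError, match="utility"):
            accumulate(trace, partial, build_cost_profiles()[0], DiscountSpec())


class TestICER:
    def test_published_increments_reproduce_ratio(self):
        value = icer(2208.0, 0.016820965)
        assert value == pytest.approx(131_253, rel=1e-3)

    def test_dominance_labels(self):
        assert icer(-1.0, 0.1) == "dominant"
        assert icer(100.0, -0.1) == "dominated"
        assert icer(100.0, 0.0) == "undefined"
        assert icer(-100.0, -0.1) == pytest.approx(1000.0)

    def test_identical_arms_give_zero_deltas(self, cost_profiles, utilities):
        init = np.zeros(10)
        init[0] = 1.0
        tm = add_mortality(TransitionMatrix(_alive_identity(), 1.0), 0.3)
        trace = run_cohort(init, [(tm, 24)])
        standard, _ = cost_profiles
        q1, c1 = accumulate(trace, utilities, standard, DiscountSpec())
        q2, c2 = accumulate(trace, utilities, standard, DiscountSpec())
        assert q1 - q2 == 0.0 and c1 - c2 == 0.0
        assert icer(c1 - c2, q1 - q2) == "undefined"


def _alive_identity() -> np.ndarray:
    return np.eye(len(STATE_ORDER))
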