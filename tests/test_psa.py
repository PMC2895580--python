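"""Lognormal input resampling and cost-effectiveness-plane summaries."""
import numpy as np
import pandas as pd
import pytest

from pucea.costing import build_cost_profiles
from pucea.markov import UtilityProfile
from pucea.psa import (
    PSAConfig,
    PSAError,
    PSAResult,
    acceptability,
    ce_plane_summary,
    iteration_rng,
    lognormal_multipliers,
    perturb_transition_rows,
    quadrant_shares,
    run_psa,
    sample_inputs,
)
from pucea.states import HealthState


@pytest.fixture(scope="module")
def base_inputs():
    std, qic = build_cost_profiles()
    return std, qic, UtilityProfile()


def linear_runner(slope_cost=1.0, slope_qaly=1.0):
    """Toy model: deltas read directly off the perturbed inputs."""

    def runner(costs_std, costs_qic, utilities, rng):
        dc = (
            costs_qic.state_monthly_cost[HealthState.NO_PU]
            - costs_std.state_monthly_cost[HealthState.NO_PU]
        ) * slope_cost + costs_qic.program_cost_per_patient_year
        dq = utilities.weights[HealthState.NO_PU] * slope_qaly - 0.5
        return {"total": (dc, dq)}

    return runner


class TestLognormalMultipliers:
    def test_zero_cv_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert np.all(lognormal_multipliers(0.0, 100, rng) == 1.0)

    def test_mean_one_at_cv_point_two(self):
        rng = np.random.default_rng(1)
        draws = lognormal_multipliers(0.2, 1_000_000, rng)
        # closed-form lognormal moments: E[X] = 1, SD[X] = cv
        assert abs(draws.mean() - 1.0) < 0.002
        assert abs(draws.std() - 0.2) < 0.002

    def test_deterministic_per_seed_iteration(self, base_inputs):
        std, qic, util = base_inputs
        config = PSAConfig(cv_costs=0.3, cv_effects=0.3, seed=5)
        a = sample_inputs(std, qic, util, config, iteration=7)
        b = sample_inputs(std, qic, util, config, iteration=7)
        assert a[0].state_monthly_cost == b[0].state_monthly_cost
        assert a[2].weights == b[2].weights

    def test_zero_cv_returns_inputs_unchanged(self, base_inputs):
        std, qic, util = base_inputs
        config = PSAConfig(cv_costs=0.0, cv_effects=0.0)
        p_std, p_qic, p_util = sample_inputs(std, qic, util, config, 0)
        assert p_std.state_monthly_cost == std.state_monthly_cost
        assert p_qic.program_cost_per_patient_year == 323.0
        assert p_util.weights == util.weights

    def test_utilities_capped_at_one(self):
        util = UtilityProfile(
            weights={**UtilityProfile().weights, HealthState.NO_PU: 0.99}
        )
        rng = np.random.default_rng(2)
        capped = util.perturbed(np.full(10, 5.0))
        assert capped.weights[HealthState.NO_PU] == 1.0
        assert capped.weights[HealthState.DEATH] == 0.0


class TestRunPSA:
    def test_zero_cv_reproduces_base_case_every_iteration(self, base_inputs):
        std, qic, util = base_inputs
        config = PSAConfig(n_iterations=20, cv_costs=0.0, cv_effects=0.0)
        result = run_psa(linear_runner(), std, qic, util, config)
        base = linear_runner()(std, qic, util, None)["total"]
        assert np.allclose(result.samples["delta_cost"], base[0])
        assert np.allclose(result.samples["delta_qaly"], base[1])

    def test_fixed_seed_is_bit_identical(self, base_inputs):
        std, qic, util = base_inputs
        config = PSAConfig(n_iterations=50, seed=3)
        a = run_psa(linear_runner(), std, qic, util, config)
        b = run_psa(linear_runner(), std, qic, util, config)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_point_cloud_collapses_as_cv_shrinks(self, base_inputs):
        std, qic, util = base_inputs
        base = linear_runner()(std, qic, util, None)["total"]
        spreads = []
        for cv in (0.3, 0.05, 0.0):
            config = PSAConfig(n_iterations=50, cv_costs=cv, cv_effects=cv)
            result = run_psa(linear_runner(), std, qic, util, config)
            spreads.append(
                np.abs(result.samples["delta_cost"] - base[0]).max()
            )
        assert spreads[0] > spreads[1] > spreads[2] == 0.0

    def test_failed_iterations_are_tallied(self, base_inputs):
        std, qic, util = base_inputs
        calls = {"n": 0}

        def flaky(costs_std, costs_qic, utilities, rng):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("numerical failure")
            return {"total": (1.0, 1.0)}

        config = PSAConfig(n_iterations=10)
        result = run_psa(flaky, std, qic, util, config)
        assert result.n_failed == 5
        assert len(result.samples) == 5

    def test_summary_is_exact_recount_of_pairs(self, base_inputs):
        std, qic, util = base_inputs
        config = PSAConfig(n_iterations=100, cv_costs=0.4, cv_effects=0.4)
        result = run_psa(linear_runner(), std, qic, util, config)
        summary = result.summary().iloc[0]
        dc = result.samples["delta_cost"].to_numpy()
        dq = result.samples["delta_qaly"].to_numpy()
        assert summary["p_cost_positive"] == sum(x > 0 for x in dc) / 100
        assert summary["p_qaly_positive"] == sum(x > 0 for x in dq) / 100
        assert summary["mean_delta_cost"] == pytest.approx(dc.mean())


class TestCEPlane:
    def test_brute_force_recount_of_toy_sample(self):
        rng = np.random.default_rng(6)
        dc = rng.normal(1000, 2000, 100)
        dq = rng.normal(0.01, 0.02, 100)
        shares = quadrant_shares(dc, dq)
        counted = {
            "more_effective_cheaper": 0,
            "more_effective_costlier": 0,
            "less_effective_cheaper": 0,
            "less_effective_costlier": 0,
        }
        for c, q in zip(dc, dq):
            if q > 0 and c < 0:
                counted["more_effective_cheaper"] += 1
            elif q > 0:
                counted["more_effective_costlier"] += 1
            elif c < 0:
                counted["less_effective_cheaper"] += 1
            else:
                counted["less_effective_costlier"] += 1
        assert shares == {k: v / 100 for k, v in counted.items()}
        accept = acceptability(dc, dq, 80_000.0)
        brute = sum(q > 0 and c / q < 80_000.0 for c, q in zip(dc, dq)) / 100
        assert accept == brute

    def test_quadrants_partition_even_with_axis_ties(self):
        dc = np.array([0.0, 1.0, -1.0, 0.0])
        dq = np.array([0.0, 0.0, 1.0, 1.0])
        shares = quadrant_shares(dc, dq)
        assert sum(shares.values()) == pytest.approx(1.0)
        # zero cost with positive gain counts as the costlier quadrant
        assert shares["more_effective_costlier"] == 0.25
        # zero gain counts as less effective
        assert shares["less_effective_costlier"] == 0.5

    def test_all_acceptable_cloud(self):
        dc = np.full(10, 100.0)
        dq = np.full(10, 0.1)  # ICER 1000 << threshold
        assert acceptability(dc, dq, 80_000.0) == 1.0

    def test_acceptability_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        dc = rng.normal(2000, 1500, 400)
        dq = rng.normal(0.01, 0.03, 400)
        grid = np.linspace(1.0, 200_000.0, 50)
        probs = [acceptability(dc, dq, t) for t in grid]
        assert np.all(np.diff(probs) >= 0)

    def test_infinite_threshold_tends_to_p_positive_gain(self):
        rng = np.random.default_rng(10)
        dc = rng.normal(2000, 500, 300)
        dq = rng.normal(0.02, 0.02, 300)
        assert acceptability(dc, dq, 1e12) == pytest.approx(
            (dq > 0).mean()
        )

    def test_ce_plane_summary_structure(self, base_inputs):
        std, qic, util = base_inputs
        config = PSAConfig(n_iterations=50, cv_costs=0.3, cv_effects=0.3)
        result = run_psa(linear_runner(), std, qic, util, config)
        summary = ce_plane_summary(result)
        assert set(summary) == {
            "scenario",
            "quadrants",
            "acceptability",
            "curve",
        }
        assert np.all(np.diff(summary["curve"]["probability"]) >= -1e-12)


class TestTransitionPerturbation:
    def test_rows_stay_stochastic_and_centred(self):
        rng = np.random.default_rng(11)
        P = np.array([[0.8, 0.2, 0.0], [0.1, 0.85, 0.05], [0.0, 0.0, 1.0]])
        draws = np.mean(
            [perturb_transition_rows(P, 500.0, rng) for _ in range(400)],
            axis=0,
        )
        sample = perturb_transition_rows(P, 500.0, rng)
        assert np.allclose(sample.sum(axis=1), 1.0)
        assert sample[0, 2] == 0.0  # structural zeros preserved
        assert np.allclose(draws, P, atol=0.01)


class TestConfigValidation:
    def test_invalid_settings_rejected(self):
        with pytest.raises(PSAError):
            PSAConfig(n_iterations=0).validate()
        with pytest.raises(PSAError):
            PSAConfig(cv_costs=-0.1).validate()
        with pytest.raises(PSAError):
            PSAConfig(wtp_threshold=0.0).validate()
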