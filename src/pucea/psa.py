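"""Probabilistic sensitivity analysis on the cost-effectiveness model.

Parameter uncertainty is propagated by Monte-Carlo resampling: every
per-state cost (both arms, plus the program/organizational overheads)
and every state utility is multiplied by an independent lognormal draw
with mean 1 and a configured coefficient of variation, the model is
re-valued, and the resulting cloud of (incremental cost, incremental
QALY) pairs per scenario is summarized on the cost-effectiveness plane:
quadrant shares, probability of a positive cost/QALY difference, and
the probability that the intervention is acceptable at a
willingness-to-pay threshold (default EUR 80,000/QALY, the Dutch
policy ceiling for severe conditions).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import CostProfile
from .markov import UtilityProfile
from .states import STATE_ORDER


class PSAError(ValueError):
    pass


@dataclass
class PSAConfig:
    """Settings of the Monte-Carlo sensitivity analysis."""

    n_iterations: int = 10_000
    cv_costs: float = 0.2
    cv_effects: float = 0.2
    wtp_threshold: float = 80_000.0
    seed: int = 0
    perturb_transitions: bool = False
    transition_concentration: float = 500.0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise PSAError("n_iterations must be >= 1")
        if self.cv_costs < 0 or self.cv_effects < 0:
            raise PSAError("coefficients of variation must be >= 0")
        if self.wtp_threshold <= 0:
            raise PSAError("willingness-to-pay threshold must be > 0")


def lognormal_multipliers(
    cv: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent lognormal draws with mean exactly 1 and the given CV.

    Uses sigma^2 = ln(1 + cv^2), mu = -sigma^2 / 2, so E[X] = 1 and
    SD[X] = cv. A zero CV returns ones (the degenerate distribution).
    """
    if cv < 0:
        raise PSAError("cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def iteration_rng(
    seed: int, iteration: int, stream: int = 0
) -> np.random.Generator:
    """Deterministic per-(seed, iteration) random stream.

    ``stream`` separates independent uses within one iteration (0 for
    the input multipliers, 1 for any extra draws by the model runner).
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(iteration, stream))
    )


def sample_inputs(
    base_costs_standard: CostProfile,
    base_costs_qic: CostProfile,
    base_utilities: UtilityProfile,
    config: PSAConfig,
    iteration: int,
) -> tuple[CostProfile, CostProfile, UtilityProfile]:
    """One perturbed parameter set, deterministic per (seed, iteration)."""
    rng = iteration_rng(config.seed, iteration)
    n_cost = len(STATE_ORDER) + 2  # states + program + organizational
    std = base_costs_standard.perturbed(
        lognormal_multipliers(config.cv_costs, n_cost, rng)
    )
    qic = base_costs_qic.perturbed(
        lognormal_multipliers(config.cv_costs, n_cost, rng)
    )
    utilities = base_utilities.perturbed(
        lognormal_multipliers(config.cv_effects, len(STATE_ORDER), rng)
    )
    return std, qic, utilities


@dataclass
class PSAResult:
    """Per-iteration incremental pairs and exact summaries thereof."""

    samples: pd.DataFrame  # iteration, scenario, delta_cost, delta_qaly
    n_failed: int = 0
    wtp_threshold: float = 80_000.0

    def pairs(self, scenario: str) -> pd.DataFrame:
        sub = self.samples[self.samples["scenario"] == scenario]
        if sub.empty:
            raise PSAError(f"no samples for scenario {scenario!r}")
        return sub

    @property
    def scenarios(self) -> list[str]:
        return list(dict.fromkeys(self.samples["scenario"]))

    def summary(self, threshold: float | None = None) -> pd.DataFrame:
        threshold = threshold or self.wtp_threshold
        rows = []
        for scenario in self.scenarios:
            sub = self.pairs(scenario)
            dc = sub["delta_cost"].to_numpy()
            dq = sub["delta_qaly"].to_numpy()
            rows.append(
                {
                    "scenario": scenario,
                    "mean_delta_cost": float(dc.mean()),
                    "mean_delta_qaly": float(dq.mean()),
                    "p_cost_positive": float((dc > 0).mean()),
                    "p_qaly_positive": float((dq > 0).mean()),
                    "p_acceptable": acceptability(dc, dq, threshold),
                }
            )
        return pd.DataFrame(rows)


def acceptability(
    delta_cost: np.ndarray, delta_qaly: np.ndarray, threshold: float
) -> float:
    """P(positive QALY gain and ICER below threshold)."""
    dc = np.asarray(delta_cost, dtype=float)
    dq = np.asarray(delta_qaly, dtype=float)
    ok = (dq > 0) & (dc < threshold * dq)
    return float(ok.mean())


def quadrant_shares(
    delta_cost: np.ndarray, delta_qaly: np.ndarray
) -> dict[str, float]:
    """Shares of the four cost-effectiveness-plane quadrants.

    Pairs exactly on an axis count toward the less favourable quadrant
    (zero QALY gain is treated as no gain; zero extra cost as extra
    cost), so the four shares always partition the sample.
    """
    dc = np.asarray(delta_cost, dtype=float)
    dq = np.asarray(delta_qaly, dtype=float)
    gain = dq > 0
    cheaper = dc < 0
    return {
        "more_effective_cheaper": float((gain & cheaper).mean()),
        "more_effective_costlier": float((gain & ~cheaper).mean()),
        "less_effective_cheaper": float((~gain & cheaper).mean()),
        "less_effective_costlier": float((~gain & ~cheaper).mean()),
    }


def ce_plane_summary(
    result: PSAResult,
    threshold: float | None = None,
    scenario: str | None = None,
    threshold_grid: np.ndarray | None = None,
) -> dict:
    """Quadrant shares, acceptability, and an acceptability curve.

    Without ``scenario`` the summary covers the first scenario in the
    result. The curve evaluates acceptability on ``threshold_grid``
    (default: 0 to 2x the configured threshold in 41 steps).
    """
    threshold = threshold or result.wtp_threshold
    scenario = scenario or result.scenarios[0]
    sub = result.pairs(scenario)
    dc = sub["delta_cost"].to_numpy()
    dq = sub["delta_qaly"].to_numpy()
    if threshold_grid is None:
        threshold_grid = np.linspace(1e-9, 2 * threshold, 41)
    curve = pd.DataFrame(
        {
            "threshold": threshold_grid,
            "probability": [acceptability(dc, dq, t) for t in threshold_grid],
        }
    )
    return {
        "scenario": scenario,
        "quadrants": quadrant_shares(dc, dq),
        "acceptability": acceptability(dc, dq, threshold),
        "curve": curve,
    }


def run_psa(
    model_runner,
    base_costs_standard: CostProfile,
    base_costs_qic: CostProfile,
    base_utilities: UtilityProfile,
    config: PSAConfig,
) -> PSAResult:
    """Monte-Carlo loop over perturbed inputs.

    ``model_runner(costs_standard, costs_qic, utilities, rng)`` must
    return a mapping scenario -> (delta_cost, delta_qaly) for one
    parameter draw (``rng`` is the iteration's stream, available to
    runners that also perturb transitions). Failed iterations are
    excluded and tallied in ``n_failed``. With both CVs at zero every
    iteration reproduces the deterministic base case exactly.
    """
    config.validate()
    rows = []
    n_failed = 0
    for it in range(config.n_iterations):
        std, qic, utilities = sample_inputs(
            base_costs_standard, base_costs_qic, base_utilities, config, it
        )
        rng = iteration_rng(config.seed, it, stream=1)  # extras only
        try:
            deltas = model_runner(std, qic, utilities, rng)
        except Exception:
            n_failed += 1
            continue
        for scenario, (dc, dq) in deltas.items():
            rows.append(
                {
                    "iteration": it,
                    "scenario": scenario,
                    "delta_cost": float(dc),
                    "delta_qaly": float(dq),
                }
            )
    if not rows:
        raise PSAError("every PSA iteration failed")
    return PSAResult(
        samples=pd.DataFrame(rows),
        n_failed=n_failed,
        wtp_threshold=config.wtp_threshold,
    )


def perturb_transition_rows(
    probs: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-resample each row around its point estimate.

    Optional extension for PSAs that also treat transition
    probabilities as uncertain: each row p is replaced by a draw from
    Dirichlet(concentration * p), which keeps the row stochastic and
    centred on p. Zero entries stay zero.
    """
    out = np.zeros_like(probs)
    for i, row in enumerate(probs):
        pos = row > 0
        if pos.sum() <= 1:
            out[i] = row
            continue
        out[i, pos] = rng.dirichlet(concentration * row[pos])
    return out
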