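"""Markov cohort model for pressure-ulcer cost-effectiveness.

The decision model follows a cohort of long-term-care patients through
ten health states (no PU, single/multiple PU of grade 1-4, death) in
monthly cycles. Two arms are compared over two years:

* a simulated control arm, whose monthly transition matrix is built
  from the incidence observed in the baseline measurement month and
  literature healing probabilities -- i.e. what would have happened
  without the improvement program; and
* an intervention arm, whose annual transition matrix is estimated
  from the paired baseline/final measurement months and converted to
  a monthly matrix via the principal 12th matrix root.

Mortality enters as an extra absorbing state with a uniform monthly
death probability derived from annual nursing-home mortality. The
second (extrapolation) year of the intervention arm follows one of
three sustainability scenarios: ``total`` keeps the first-year
dynamics, ``partial`` freezes the achieved state distribution among
survivors (identity dynamics plus mortality), and ``none`` reverses the
improvement by running the inverse of the first-year annual matrix.
Costs and QALYs accumulate per cycle with differential annual
discounting and no half-cycle correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import CostProfile
from .effectiveness import monthly_incidence, representative_states
from .states import (
    ALIVE_STATES,
    HealthState,
    STATE_INDEX,
    STATE_ORDER,
    state_for,
)
from .synthetic_data import PatientRegistry, rescale_probability

_N = len(STATE_ORDER)
_DEATH = STATE_INDEX[HealthState.DEATH]

SCENARIOS = ("none", "partial", "total")
SCENARIO_LABELS = {
    "none": "not sustained",
    "partial": "partially sustained",
    "total": "totally sustained",
}


class ModelError(ValueError):
    """Invalid model input."""


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix for a stated cycle length.

    ``probs[i, j]`` is the probability of moving from state i to state
    j within one cycle of ``cycle_length_months``. ``labels`` defaults
    to the ten model states; small matrices with custom labels are
    allowed for generic matrix utilities. ``meta`` records estimation
    diagnostics (clipped mass, root residuals, fallbacks).
    """

    probs: np.ndarray
    cycle_length_months: float = 1.0
    labels: tuple = STATE_ORDER
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        k = len(self.labels)
        if self.probs.shape != (k, k):
            raise ModelError(
                f"matrix shape {self.probs.shape} does not match {k} labels"
            )
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.probs < -tol) or np.any(self.probs > 1 + tol):
            raise ModelError("transition probabilities must lie in [0, 1]")
        rows = self.probs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > tol):
            raise ModelError(f"rows must sum to 1 (sums: {rows})")
        if HealthState.DEATH in self.labels:
            i = self.labels.index(HealthState.DEATH)
            unit = np.zeros(len(self.labels))
            unit[i] = 1.0
            if not np.allclose(self.probs[i], unit, atol=tol):
                raise ModelError("death row must be absorbing")

    @property
    def death_mass(self) -> float:
        if HealthState.DEATH not in self.labels:
            return 0.0
        i = self.labels.index(HealthState.DEATH)
        off = np.delete(np.arange(len(self.labels)), i)
        return float(self.probs[off, i].sum())

    def copy(self, **meta) -> "TransitionMatrix":
        return TransitionMatrix(
            self.probs.copy(),
            self.cycle_length_months,
            self.labels,
            {**self.meta, **meta},
        )

    def to_frame(self) -> pd.DataFrame:
        names = [getattr(s, "value", str(s)) for s in self.labels]
        return pd.DataFrame(self.probs, index=names, columns=names)


@dataclass(frozen=True)
class UtilityProfile:
    """Quality-of-life weight per state, on an annual full-health scale.

    Defaults: 0.703 for PU-free nursing-home patients, 0.68 for a single
    grade 1-2 ulcer, 0.5 for multiple grade 1-2 ulcers, 0.36 for any
    grade 3-4 ulcer, 0 for death.
    """

    weights: dict = field(
        default_factory=lambda: {
            HealthState.NO_PU: 0.703,
            HealthState.SINGLE_1: 0.68,
            HealthState.SINGLE_2: 0.68,
            HealthState.MULTI_1: 0.5,
            HealthState.MULTI_2: 0.5,
            HealthState.SINGLE_3: 0.36,
            HealthState.SINGLE_4: 0.36,
            HealthState.MULTI_3: 0.36,
            HealthState.MULTI_4: 0.36,
            HealthState.DEATH: 0.0,
        }
    )

    def validate(self) -> None:
        for s, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise ModelError(f"utility for {s} must lie in [0, 1], got {w}")
        if self.weights.get(HealthState.DEATH, 0.0) != 0.0:
            raise ModelError("death utility must be 0")

    def vector(self, states: tuple = STATE_ORDER) -> np.ndarray:
        try:
            return np.array([self.weights[s] for s in states])
        except KeyError as exc:
            raise ModelError(f"missing utility for state {exc.args[0]!r}") from None

    def perturbed(self, multipliers: np.ndarray) -> "UtilityProfile":
        """Scale alive-state weights, capping at 1; death stays 0."""
        new = {}
        for s, m in zip(STATE_ORDER, multipliers):
            if s is HealthState.DEATH:
                new[s] = 0.0
            else:
                new[s] = min(1.0, self.weights[s] * m)
        return UtilityProfile(weights=new)


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rates (Dutch guideline: 4% costs, 1.5% effects)."""

    cost_rate: float = 0.04
    effect_rate: float = 0.015

    def validate(self) -> None:
        if self.cost_rate < 0 or self.effect_rate < 0:
            raise ModelError("discount rates must be >= 0")


def present_value(amount: float, years: float, rate: float) -> float:
    """Discount ``amount`` accruing at ``years`` back to time 0."""
    return amount * (1.0 + rate) ** (-years)


@dataclass
class CohortTrace:
    """State occupancy per cycle: row 0 is the initial distribution."""

    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    cycle_length_months: float = 1.0
    labels: tuple = STATE_ORDER

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        rows = self.occupancy.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ModelError("each cycle's occupancy must sum to 1")
        if HealthState.DEATH in self.labels:
            dead = self.occupancy[:, self.labels.index(HealthState.DEATH)]
            if np.any(np.diff(dead) < -1e-12):
                raise ModelError("death occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_series(self, state: HealthState) -> np.ndarray:
        return self.occupancy[:, self.labels.index(state)]

    def any_pu_series(self) -> np.ndarray:
        idx = [i for i, s in enumerate(self.labels) if s.is_pu]
        return self.occupancy[:, idx].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        names = [getattr(s, "value", str(s)) for s in self.labels]
        df = pd.DataFrame(self.occupancy, columns=names)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


# ---------------------------------------------------------------------------
# Matrix estimation


def estimate_monthly_matrix_control(
    registry: PatientRegistry,
    healing_prob_90d_by_grade: dict[int, float],
    grade_mix: dict[int, float],
    denominator: int | None = None,
) -> TransitionMatrix:
    """Monthly control-arm matrix from one measurement month.

    The no-PU row sends the observed monthly incidence, split over
    grades by ``grade_mix``, to the single-PU states; each PU state
    heals to no-PU with its 90-day probability rescaled to 30 days; all
    remaining mass stays on the diagonal. Death mass is zero (mortality
    is added separately).
    """
    if registry.records.empty:
        raise ModelError("cannot estimate a matrix from an empty registry")
    incidence = monthly_incidence(registry, denominator)

    P = np.eye(_N)
    mix_total = sum(grade_mix.values())
    if mix_total <= 0:
        raise ModelError("grade_mix must have positive mass")
    i_no = STATE_INDEX[HealthState.NO_PU]
    for grade, w in grade_mix.items():
        P[i_no, STATE_INDEX[state_for(grade)]] = incidence * w / mix_total
    P[i_no, i_no] = 1.0 - incidence

    for state in STATE_ORDER:
        if not state.is_pu:
            continue
        p90 = healing_prob_90d_by_grade.get(state.grade, 0.0)
        p_month = rescale_probability(p90, 90.0, 30.0)
        i = STATE_INDEX[state]
        P[i, STATE_INDEX[HealthState.NO_PU]] = p_month
        P[i, i] = 1.0 - p_month

    return TransitionMatrix(
        P, 1.0, meta={"monthly_incidence": incidence, "source": "control"}
    )


def estimate_annual_matrix_intervention(
    baseline: PatientRegistry, final: PatientRegistry
) -> TransitionMatrix:
    """Annual intervention matrix from paired measurement months.

    Each patient contributes one (baseline representative state, final
    representative state) pair; representative = modal state over the
    month with ties to the worse state. Rows are the normalized
    cross-tabulation. Patients absent from the final month (deaths,
    drop-outs) are excluded -- mortality is modelled separately. Alive
    states never observed at baseline fall back to self-transition and
    are flagged in ``meta['fallback_rows']``.
    """
    base_rep = representative_states(baseline)
    final_rep = representative_states(final)
    common = base_rep.index.intersection(final_rep.index)
    if len(common) == 0:
        raise ModelError("no paired patients between baseline and final months")

    counts = np.zeros((_N, _N))
    for pid in common:
        i = STATE_INDEX[HealthState(base_rep.loc[pid])]
        j = STATE_INDEX[HealthState(final_rep.loc[pid])]
        counts[i, j] += 1

    P = np.zeros((_N, _N))
    fallback = []
    for i, state in enumerate(STATE_ORDER):
        if state is HealthState.DEATH:
            P[i, i] = 1.0
            continue
        row_total = counts[i].sum()
        if row_total == 0:
            P[i, i] = 1.0
            fallback.append(state.value)
        else:
            P[i] = counts[i] / row_total
    return TransitionMatrix(
        P,
        12.0,
        meta={
            "n_pairs": int(len(common)),
            "fallback_rows": fallback,
            "source": "intervention",
        },
    )


# ---------------------------------------------------------------------------
# Matrix transformations


class _RootError(RuntimeError):
    pass


def _principal_root(P: np.ndarray, n_steps: int, imag_tol: float = 1e-8) -> np.ndarray:
    """Principal n-th matrix root via eigendecomposition."""
    w, V = np.linalg.eig(P.astype(complex))
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:  # defective eigenstructure
        raise _RootError(str(exc)) from exc
    root = V @ np.diag(w ** (1.0 / n_steps)) @ Vinv
    if np.max(np.abs(root.imag)) > imag_tol:
        raise _RootError("root has non-negligible imaginary part")
    return root.real


def _clip_renormalize(P: np.ndarray) -> tuple[np.ndarray, float]:
    """Project onto row-stochastic matrices; returns clipped mass."""
    clipped_mass = float(-P[P < 0].sum())
    Q = np.clip(P, 0.0, None)
    sums = Q.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ModelError("cannot renormalize a row with no positive mass")
    return Q / sums, clipped_mass


def _elementwise_root(P: np.ndarray, n_steps: int) -> np.ndarray:
    """Per-element fallback: off-diagonals 1-(1-p)^(1/n), rows renormalized."""
    Q = 1.0 - (1.0 - np.clip(P, 0.0, 1.0)) ** (1.0 / n_steps)
    np.fill_diagonal(Q, 0.0)
    diag = 1.0 - Q.sum(axis=1)
    if np.any(diag < 0):  # heavy off-diagonal mass: renormalize instead
        np.fill_diagonal(Q, 0.0)
        row = Q.sum(axis=1, keepdims=True)
        scale = np.where(row > 1.0, 1.0 / row, 1.0)
        Q = Q * scale
        diag = 1.0 - Q.sum(axis=1)
    np.fill_diagonal(Q, diag)
    return Q


def annual_to_monthly(annual: TransitionMatrix, n_steps: int = 12) -> TransitionMatrix:
    """Convert an annual matrix to a monthly one (R with R^n ~= annual).

    Computed as the principal matrix root via eigendecomposition;
    negative entries are clipped and rows renormalized. If the root is
    complex or the eigenstructure defective beyond tolerance, falls
    back to the per-element constant-hazard conversion (flagged in
    ``meta['method']``). ``meta`` also records the clipped mass and the
    Frobenius distance of the n-step power from the input.
    """
    meta: dict = {}
    try:
        R = _principal_root(annual.probs, n_steps)
        meta["method"] = "principal_root"
    except _RootError as exc:
        R = _elementwise_root(annual.probs, n_steps)
        meta["method"] = "elementwise_fallback"
        meta["fallback_reason"] = str(exc)
    R, clipped = _clip_renormalize(R)
    meta["clipped_mass"] = clipped
    meta["frobenius_error"] = float(
        np.linalg.norm(np.linalg.matrix_power(R, n_steps) - annual.probs)
    )
    return TransitionMatrix(
        R, annual.cycle_length_months / n_steps, annual.labels, {**annual.meta, **meta}
    )


def add_mortality(
    matrix: TransitionMatrix, annual_mortality: float
) -> TransitionMatrix:
    """Overlay a uniform monthly death risk on every alive state.

    The cycle-length death probability d = 1-(1-annual)^(cycle/12)
    applies from every alive state; surviving transitions are rescaled
    by (1-d); the death row is absorbing. The input must carry no death
    mass of its own.
    """
    if not 0.0 <= annual_mortality <= 1.0:
        raise ModelError("annual mortality must lie in [0, 1]")
    if HealthState.DEATH not in matrix.labels:
        raise ModelError("matrix must include the death state")
    if matrix.death_mass > 1e-12:
        raise ModelError("matrix already carries death mass")
    d = 1.0 - (1.0 - annual_mortality) ** (matrix.cycle_length_months / 12.0)
    P = matrix.probs * (1.0 - d)
    P[:, _DEATH] += d
    P[_DEATH] = 0.0
    P[_DEATH, _DEATH] = 1.0
    return TransitionMatrix(
        P,
        matrix.cycle_length_months,
        matrix.labels,
        {**matrix.meta, "monthly_death_prob": d},
    )


def _alive_block(matrix: TransitionMatrix) -> np.ndarray:
    idx = [STATE_INDEX[s] for s in ALIVE_STATES]
    return matrix.probs[np.ix_(idx, idx)]


def _from_alive_block(block: np.ndarray, cycle: float, meta: dict) -> TransitionMatrix:
    P = np.zeros((_N, _N))
    idx = [STATE_INDEX[s] for s in ALIVE_STATES]
    P[np.ix_(idx, idx)] = block
    P[_DEATH, _DEATH] = 1.0
    return TransitionMatrix(P, cycle, STATE_ORDER, meta)


def _time_reversal(A: np.ndarray, initial_dist: np.ndarray) -> np.ndarray:
    """Bayes time-reversal of an annual chain w.r.t. a starting mix.

    With pi0 the pre-intervention distribution and pi1 = pi0 A the
    achieved one, B[j, i] = pi0[i] A[i, j] / pi1[j] is row-stochastic
    and satisfies pi1 B = pi0 exactly: one annual application of B
    undoes the year's improvement. Used as the reversal when the
    annual matrix has no usable stochastic inverse root.
    """
    pi0 = np.asarray(initial_dist, dtype=float)
    pi0 = pi0 / pi0.sum()
    pi1 = pi0 @ A
    B = np.zeros_like(A)
    for j in range(A.shape[0]):
        if pi1[j] > 0:
            B[j] = pi0 * A[:, j] / pi1[j]
        else:
            B[j, j] = 1.0  # state unreachable after year 1
    B, _ = _clip_renormalize(B)
    return B


@dataclass(frozen=True)
class ScenarioSpec:
    """Sustainability scenario for the extrapolation year."""

    name: str  # "total" | "partial" | "none"

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ModelError(
                f"scenario must be one of {SCENARIOS}, got {self.name!r}"
            )

    @property
    def label(self) -> str:
        return SCENARIO_LABELS[self.name]


def scenario_matrix(
    spec: ScenarioSpec,
    year1_monthly: TransitionMatrix,
    year1_annual: TransitionMatrix,
    initial_occupancy: np.ndarray | None = None,
) -> TransitionMatrix:
    """Year-2 monthly PU dynamics (before mortality) for a scenario.

    ``total``: the first-year monthly matrix unchanged. ``partial``:
    identity on the alive states -- the achieved distribution is frozen
    among survivors. ``none``: the improvement is reversed by running
    the inverse of the first-year annual matrix -- the monthly
    principal root of the matrix inverse, negative entries clipped and
    rows renormalized. That literal construction only survives when it
    is already stochastic: the inverse of a stochastic matrix with any
    real movement has negative off-diagonals, so clipping its root
    collapses the dynamics toward identity; and annual matrices
    estimated from small cohorts are frequently singular outright. In
    either case the reversal falls back to the Bayes time-reversal of
    the annual chain
    with respect to ``initial_occupancy`` (the pre-intervention mix
    over all ten states; uniform over alive states when omitted), which
    by construction walks the achieved distribution back to the
    pre-intervention one over the year. The fallback is flagged in
    ``meta``.
    """
    meta: dict = {"scenario": spec.name}
    if spec.name == "total":
        return year1_monthly.copy(**meta)
    if spec.name == "partial":
        return _from_alive_block(
            np.eye(len(ALIVE_STATES)), year1_monthly.cycle_length_months, meta
        )

    # "none": invert the annual matrix, then take the monthly root.
    A = _alive_block(year1_annual)
    R = None
    try:
        A_inv = np.linalg.inv(A)
        R = _principal_root(A_inv, 12)
        meta["method"] = "principal_root_of_inverse"
    except (np.linalg.LinAlgError, _RootError) as exc:
        meta["fallback_reason"] = str(exc)
    if R is not None:
        R, clipped = _clip_renormalize(R)
        # The inverse of a stochastic matrix has negative off-diagonal
        # entries whenever any state can actually move, so clipping its
        # root usually collapses the dynamics to near-identity. Accept
        # the literal inverse root only when essentially nothing had to
        # be clipped; otherwise treat it as failed.
        if clipped > 1e-9:
            meta["fallback_reason"] = f"root clipped mass {clipped:.3g}"
            R = None
        else:
            meta["clipped_mass"] = clipped
    if R is None:
        if initial_occupancy is None:
            pi0 = np.full(len(ALIVE_STATES), 1.0 / len(ALIVE_STATES))
        else:
            pi0 = np.asarray(initial_occupancy, dtype=float)[
                [STATE_INDEX[s] for s in ALIVE_STATES]
            ]
        B = _time_reversal(A, pi0)
        try:
            R = _principal_root(B, 12)
            meta["method"] = "time_reversal_root"
        except _RootError:
            R = _elementwise_root(B, 12)
            meta["method"] = "time_reversal_elementwise"
        R, clipped = _clip_renormalize(R)
        meta["clipped_mass"] = clipped
    return _from_alive_block(R, year1_monthly.cycle_length_months, meta)


# ---------------------------------------------------------------------------
# Cohort evolution and valuation


def run_cohort(
    initial: np.ndarray, schedule: list[tuple[TransitionMatrix, int]]
) -> CohortTrace:
    """Evolve an occupancy vector through a schedule of matrices.

    ``schedule`` is a list of (matrix, n_cycles) segments, e.g. twelve
    first-year cycles followed by twelve extrapolation cycles. Row 0 of
    the trace is the initial distribution.
    """
    initial = np.asarray(initial, dtype=float)
    if not schedule:
        raise ModelError("schedule must contain at least one segment")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ModelError("initial occupancy must sum to 1")
    labels = schedule[0][0].labels
    k = len(labels)
    if initial.shape != (k,):
        raise ModelError(f"initial occupancy must have length {k}")
    rows = [initial]
    occ = initial
    for matrix, n_cycles in schedule:
        if matrix.labels != labels:
            raise ModelError("all matrices in a schedule must share labels")
        for _ in range(n_cycles):
            occ = occ @ matrix.probs
            rows.append(occ)
    return CohortTrace(
        np.vstack(rows), schedule[0][0].cycle_length_months, labels
    )


def microsimulate(
    n_individuals: int,
    initial: np.ndarray,
    schedule: list[tuple[TransitionMatrix, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Individual-level Monte-Carlo counterpart of :func:`run_cohort`.

    Returns occupancy fractions with the same shape as the cohort
    trace; used as an independent oracle for the deterministic cohort
    arithmetic.
    """
    k = len(schedule[0][0].labels)
    counts = rng.multinomial(n_individuals, np.asarray(initial, dtype=float))
    out = [counts / n_individuals]
    for matrix, n_cycles in schedule:
        for _ in range(n_cycles):
            new = np.zeros(k, dtype=np.int64)
            for s in range(k):
                if counts[s] > 0:
                    new += rng.multinomial(counts[s], matrix.probs[s])
            counts = new
            out.append(counts / n_individuals)
    return np.vstack(out)


def accumulate(
    trace: CohortTrace,
    utilities: UtilityProfile,
    costs: CostProfile,
    discount: DiscountSpec,
    overhead_years: float = 0.0,
    overhead_timing: str = "time0",
) -> tuple[float, float]:
    """Discounted (QALYs, costs in EUR) over a cohort trace.

    Each cycle contributes occupancy x utility / 12 QALYs and occupancy
    x monthly state cost EUR, discounted at the end of the cycle with
    t = cycle / 12 years (no half-cycle correction). ``overhead_years``
    years of the profile's program + organizational per-patient-year
    costs are added: as an undiscounted time-0 lump sum by default, or
    spread over the first year's cycles with ``overhead_timing=
    "discounted_monthly"``.
    """
    utilities.validate()
    discount.validate()
    u = utilities.vector(trace.labels)
    c = costs.cost_vector(trace.labels)
    months_per_cycle = trace.cycle_length_months
    t_years = (
        np.arange(1, trace.n_cycles + 1) * months_per_cycle / 12.0
    )
    occ = trace.occupancy[1:]
    qalys = float(
        np.sum(occ @ u * (months_per_cycle / 12.0) * (1 + discount.effect_rate) ** (-t_years))
    )
    cost_total = float(np.sum(occ @ c * (1 + discount.cost_rate) ** (-t_years)))

    overhead = costs.overhead_per_patient_year * overhead_years
    if overhead:
        if overhead_timing == "time0":
            cost_total += overhead
        elif overhead_timing == "discounted_monthly":
            n_first_year = min(trace.n_cycles, int(round(12 / months_per_cycle)))
            share = overhead / n_first_year
            cost_total += float(
                np.sum(share * (1 + discount.cost_rate) ** (-t_years[:n_first_year]))
            )
        else:
            raise ModelError(f"unknown overhead_timing {overhead_timing!r}")
    return qalys, cost_total


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-effectiveness ratio or a dominance label.

    Returns EUR/QALY when the ratio is informative, ``"dominant"`` when
    the intervention is cheaper and more effective, ``"dominated"``
    when costlier and less effective, and ``"undefined"`` when the QALY
    difference is exactly zero.
    """
    if delta_qaly == 0:
        return "undefined"
    if delta_qaly > 0 and delta_cost < 0:
        return "dominant"
    if delta_qaly < 0 and delta_cost > 0:
        return "dominated"
    return delta_cost / delta_qaly
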