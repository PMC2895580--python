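"""Synthetic patient registries for pressure-ulcer surveillance months.

Long-term-care surveillance of pressure ulcers (PUs) is organized around
"measurement months": during one month every patient on a pilot
department is inspected at 12 measurement moments spaced two to three
days apart, and the observed PU state is registered. This module
generates such registries with a configurable statistical structure --
baseline state mix, monthly onset probability, 90-day healing
probabilities per grade, and annual mortality -- so that every
downstream stage (effectiveness measures, transition-matrix estimation,
cost-effectiveness modelling) can be exercised and validated without
access to confidential patient data.

Dynamics are intentionally simple: between consecutive moments a
PU-free patient may acquire a new single ulcer of a grade drawn from
``grade_mix``, an ulcerated patient may heal back to the no-PU state,
and any patient may die. Probabilities stated on a monthly, 90-day or
annual basis are rescaled to the inter-moment gap under a
constant-hazard assumption. Once a patient dies they stop contributing
records.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .states import (
    ALIVE_STATES,
    HealthState,
    STATE_INDEX,
    STATE_ORDER,
    state_for,
)


class ParameterError(ValueError):
    """A cohort parameter violates its constraints."""


#: Baseline PU prevalence by grade in the 88-patient study cohort
#: (21 + 10 + 1 + 2 = 34 prevalent cases, 54 PU-free).
STUDY_BASELINE_GRADE_COUNTS: dict[int, int] = {1: 21, 2: 10, 3: 1, 4: 2}

#: Published probability of a PU healing within 90 days, by grade.
#: Grade 1 is not reported in that source; superficial erythema resolves
#: quickly once pressure is relieved, so 0.90 is used as the default.
DEFAULT_HEALING_PROB_90D: dict[int, float] = {1: 0.90, 2: 0.67, 3: 0.44, 4: 0.32}

#: Grade distribution of incident ulcers. Incident cases in the study
#: month were observed only at grades 1 and 2 (10 and 3 of 13 cases).
DEFAULT_GRADE_MIX: dict[int, float] = {1: 10 / 13, 2: 3 / 13, 3: 0.0, 4: 0.0}

_DEATH_CODE = STATE_INDEX[HealthState.DEATH]
_NO_PU_CODE = STATE_INDEX[HealthState.NO_PU]


def baseline_counts_from_grades(
    grade_counts: dict[int, int],
    n_patients: int,
    multiple_pu_fraction: float = 0.15,
) -> dict[HealthState, int]:
    """Expand per-grade prevalence counts into per-state counts.

    Surveillance tables report prevalent cases per grade without saying
    whether the patient has one or several ulcers; the model's cost and
    utility tables do distinguish them. ``multiple_pu_fraction`` of each
    grade's prevalent cases (rounded) are assigned to the multiple-PU
    state of that grade, the rest to the single-PU state.
    """
    total_pu = sum(grade_counts.values())
    if total_pu > n_patients:
        raise ParameterError("more prevalent PU cases than patients")
    counts: dict[HealthState, int] = {s: 0 for s in STATE_ORDER}
    for grade, count in grade_counts.items():
        n_multi = int(round(count * multiple_pu_fraction))
        counts[state_for(grade, multiple=True)] = n_multi
        counts[state_for(grade, multiple=False)] = count - n_multi
    counts[HealthState.NO_PU] = n_patients - total_pu
    return counts


@dataclass
class CohortParams:
    """Parameters of one synthetic surveillance cohort.

    Defaults reproduce the structure of the 88-patient study cohort:
    12 moments spaced 2-3 days, baseline any-grade prevalence
    34/88 (38.6%), one-month incidence 13/88 (15%) concentrated on
    grades 1-2, literature 90-day healing probabilities, and an annual
    nursing-home mortality of 30% (average stay of 2-3 years).
    """

    n_patients: int = 88
    n_measurement_moments: int = 12
    moment_spacing_days: tuple[int, int] = (2, 3)
    baseline_state_counts: dict[HealthState, int] | None = None
    # Onset applies per PU-free (at-risk) patient. The cohort-level
    # one-month incidence of 13/88 arose among the 54 PU-free patients,
    # so the implied per-at-risk monthly probability is 13/54.
    monthly_onset_prob: float = 13 / 54
    grade_mix: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_GRADE_MIX))
    healing_prob_90d_by_grade: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_HEALING_PROB_90D)
    )
    multiple_pu_fraction: float = 0.15
    annual_mortality: float = 0.30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_state_counts is None:
            self.baseline_state_counts = baseline_counts_from_grades(
                STUDY_BASELINE_GRADE_COUNTS,
                self.n_patients,
                self.multiple_pu_fraction,
            )

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.n_measurement_moments < 1:
            raise ParameterError("n_measurement_moments must be >= 1")
        probs = {
            "monthly_onset_prob": self.monthly_onset_prob,
            "multiple_pu_fraction": self.multiple_pu_fraction,
            "annual_mortality": self.annual_mortality,
            **{
                f"healing_prob_90d_by_grade[{g}]": p
                for g, p in self.healing_prob_90d_by_grade.items()
            },
            **{f"grade_mix[{g}]": p for g, p in self.grade_mix.items()},
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        if abs(sum(self.grade_mix.values()) - 1.0) > 1e-9:
            raise ParameterError("grade_mix must sum to 1")
        counts = self.baseline_state_counts
        if any(c < 0 for c in counts.values()):
            raise ParameterError("baseline_state_counts must be non-negative")
        if counts.get(HealthState.DEATH, 0) != 0:
            raise ParameterError("baseline cohort cannot contain dead patients")
        if sum(counts.values()) != self.n_patients:
            raise ParameterError(
                "baseline_state_counts must sum to n_patients "
                f"({sum(counts.values())} != {self.n_patients})"
            )

    @property
    def baseline_prevalence(self) -> float:
        """Any-grade prevalence implied by the baseline state counts."""
        pu = sum(
            c for s, c in self.baseline_state_counts.items() if s.is_pu
        )
        return pu / self.n_patients


@dataclass
class InterventionEffect:
    """Multiplicative effect of a prevention program on PU dynamics.

    ``onset`` scales the monthly onset probability (values < 1 mean
    fewer new ulcers); ``healing`` scales per-period healing
    probabilities (values > 1 mean faster healing). Scaled probabilities
    are clipped to [0, 1].
    """

    onset: float = 1.0
    healing: float = 1.0

    def validate(self) -> None:
        if self.onset < 0 or self.healing < 0:
            raise ParameterError("effect multipliers must be >= 0")


@dataclass
class PatientRegistry:
    """Longitudinal per-patient PU observations over one measurement month.

    ``records`` holds one row per (patient, moment) with columns
    ``patient_id``, ``moment_index`` (1-based), ``day_offset`` (days
    since the first moment) and ``state`` (a :class:`HealthState`
    value). Patients who die stop contributing rows. ``n_patients`` is
    the cohort size used as the prevalence/incidence denominator and
    may exceed the number of observed patients (the study keeps the
    denominator at 88 even when patients drop out).
    """

    records: pd.DataFrame
    period_label: str = "baseline"
    n_patients: int | None = None

    COLUMNS = ("patient_id", "moment_index", "day_offset", "state")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"registry records missing columns: {missing}")
        dup = self.records.duplicated(subset=["patient_id", "moment_index"])
        if dup.any():
            raise ValueError("duplicate (patient_id, moment_index) records")
        if (self.records["state"] == HealthState.DEATH.value).any():
            raise ValueError("dead patients must stop contributing records")

    @property
    def denominator(self) -> int:
        if self.n_patients is not None:
            return self.n_patients
        return int(self.records["patient_id"].nunique())

    @property
    def moments(self) -> list[int]:
        return sorted(self.records["moment_index"].unique())

    def states_at(self, moment: int) -> pd.Series:
        sub = self.records[self.records["moment_index"] == moment]
        if sub.empty:
            raise ValueError(f"moment {moment} not present in registry")
        return sub.set_index("patient_id")["state"]

    def to_csv(self, path) -> None:
        """Write the registry as commented-header CSV (UTF-8)."""
        header = (
            "# pressure-ulcer patient registry\n"
            f"# period: {self.period_label}\n"
            f"# n_patients: {self.denominator}\n"
            f"# states: {','.join(s.value for s in STATE_ORDER)}\n"
        )
        df = self.records.copy()
        df.insert(1, "period", self.period_label)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PatientRegistry":
        n_patients = None
        period = "unknown"
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith("# n_patients:"):
                n_patients = int(line.split(":", 1)[1])
            elif line.startswith("# period:"):
                period = line.split(":", 1)[1].strip()
        df = pd.read_csv(io.StringIO(text), comment="#")
        if "period" in df.columns:
            labels = df["period"].unique()
            if len(labels) == 1:
                period = str(labels[0])
            df = df.drop(columns=["period"])
        bad = set(df["state"]) - {s.value for s in STATE_ORDER}
        if bad:
            raise ValueError(f"unknown states in registry file: {sorted(bad)}")
        return cls(records=df, period_label=period, n_patients=n_patients)


def rescale_probability(p: float, from_days: float, to_days: float) -> float:
    """Convert an event probability between time horizons.

    Assumes a constant hazard, i.e. ``1 - (1 - p) ** (to_days / from_days)``.
    A 90-day healing probability of 0.67 becomes a 30-day probability of
    about 0.309.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability must lie in [0, 1], got {p}")
    return 1.0 - (1.0 - p) ** (to_days / from_days)


def moment_day_offsets(params: CohortParams) -> np.ndarray:
    """Day offsets of the measurement moments (first moment at day 0).

    Spacing alternates between the two configured gaps (2, 3, 2, 3, ...)
    so that 12 moments span 27 days, i.e. roughly one month of
    every-two-to-three-day measurements.
    """
    a, b = params.moment_spacing_days
    gaps = [a if i % 2 == 0 else b for i in range(params.n_measurement_moments - 1)]
    return np.concatenate([[0], np.cumsum(gaps)]).astype(int)


def _initial_codes(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    codes = np.concatenate(
        [
            np.full(count, STATE_INDEX[state], dtype=np.int64)
            for state, count in params.baseline_state_counts.items()
            if count > 0
        ]
    )
    rng.shuffle(codes)
    return codes


def _grade_sampler(params: CohortParams):
    grades = np.array(sorted(params.grade_mix), dtype=np.int64)
    weights = np.array([params.grade_mix[g] for g in grades], dtype=float)
    weights = weights / weights.sum()
    cum = np.cumsum(weights)
    single_codes = np.array([STATE_INDEX[state_for(int(g))] for g in grades])

    def sample(u: np.ndarray) -> np.ndarray:
        return single_codes[np.searchsorted(cum, u, side="right").clip(0, len(cum) - 1)]

    return sample


def _healing_per_grade(params: CohortParams, days: float, multiplier: float) -> np.ndarray:
    """Per-state healing probability vector over ``days`` days (len 10)."""
    out = np.zeros(len(STATE_ORDER))
    for state in STATE_ORDER:
        g = state.grade
        if g is None:
            continue
        p90 = params.healing_prob_90d_by_grade.get(g, 0.0)
        out[STATE_INDEX[state]] = min(
            1.0, rescale_probability(p90, 90.0, days) * multiplier
        )
    return out


def _step(
    codes: np.ndarray,
    days: float,
    params: CohortParams,
    rng: np.random.Generator,
    onset_multiplier: float,
    healing_multiplier: float,
    grade_sample,
) -> np.ndarray:
    """Advance all patients by ``days`` days; returns new state codes."""
    n = codes.size
    p_death = rescale_probability(params.annual_mortality, 365.0, days)
    p_onset = min(
        1.0,
        rescale_probability(params.monthly_onset_prob, 30.0, days) * onset_multiplier,
    )
    p_heal = _healing_per_grade(params, days, healing_multiplier)

    # One uniform draw per patient per event type keeps the stream layout
    # independent of the current state mix (reproducible and simple).
    u_death = rng.random(n)
    u_event = rng.random(n)
    u_grade = rng.random(n)

    new = codes.copy()
    alive = codes != _DEATH_CODE
    dies = alive & (u_death < p_death)
    new[dies] = _DEATH_CODE

    stays = alive & ~dies
    no_pu = stays & (codes == _NO_PU_CODE)
    onset = no_pu & (u_event < p_onset)
    new[onset] = grade_sample(u_grade[onset])

    has_pu = stays & (codes != _NO_PU_CODE)
    heals = has_pu & (u_event < p_heal[codes])
    new[heals] = _NO_PU_CODE
    return new


def _simulate_month(
    params: CohortParams,
    rng: np.random.Generator,
    initial_codes: np.ndarray,
    patient_ids: np.ndarray,
    period: str,
    onset_multiplier: float = 1.0,
    healing_multiplier: float = 1.0,
) -> tuple[PatientRegistry, np.ndarray]:
    """Simulate one measurement month; returns registry and final codes."""
    offsets = moment_day_offsets(params)
    grade_sample = _grade_sampler(params)
    codes = initial_codes.copy()

    rows_pid, rows_moment, rows_day, rows_state = [], [], [], []
    for m, day in enumerate(offsets, start=1):
        alive = codes != _DEATH_CODE
        rows_pid.append(patient_ids[alive])
        rows_moment.append(np.full(alive.sum(), m, dtype=np.int64))
        rows_day.append(np.full(alive.sum(), day, dtype=np.int64))
        rows_state.append(codes[alive])
        if m < len(offsets):
            dt = float(offsets[m] - day)
            codes = _step(
                codes,
                dt,
                params,
                rng,
                onset_multiplier,
                healing_multiplier,
                grade_sample,
            )

    df = pd.DataFrame(
        {
            "patient_id": np.concatenate(rows_pid),
            "moment_index": np.concatenate(rows_moment),
            "day_offset": np.concatenate(rows_day),
            "state": [
                STATE_ORDER[c].value for c in np.concatenate(rows_state)
            ],
        }
    )
    registry = PatientRegistry(
        records=df, period_label=period, n_patients=params.n_patients
    )
    return registry, codes


def generate_registry(
    params: CohortParams,
    period: str = "baseline",
    rng: np.random.Generator | None = None,
    initial_states: np.ndarray | None = None,
    onset_multiplier: float = 1.0,
    healing_multiplier: float = 1.0,
) -> PatientRegistry:
    """Generate one measurement-month registry.

    Initial states are drawn exactly from ``baseline_state_counts``
    (randomly assigned to patient ids), so the expected -- indeed the
    realized -- point prevalence at the first moment equals the
    configured baseline prevalence. Between moments, onset, healing and
    death events are drawn from the per-gap probabilities derived from
    the monthly / 90-day / annual inputs. Deterministic for a fixed
    ``params.seed`` (or supplied generator).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ids = np.arange(1, params.n_patients + 1)
    if initial_states is None:
        codes = _initial_codes(params, rng)
    else:
        codes = np.asarray(initial_states, dtype=np.int64)
        if codes.size != params.n_patients:
            raise ParameterError("initial_states length must equal n_patients")
    registry, _ = _simulate_month(
        params,
        rng,
        codes,
        ids,
        period,
        onset_multiplier=onset_multiplier,
        healing_multiplier=healing_multiplier,
    )
    return registry


def generate_paired_cohort(
    params: CohortParams,
    effect: InterventionEffect | None = None,
    rng: np.random.Generator | None = None,
    gap_months: int = 11,
) -> tuple[PatientRegistry, PatientRegistry]:
    """Generate baseline and final measurement months one year apart.

    The baseline month runs under the configured dynamics. Patients then
    evolve through ``gap_months`` monthly steps and a final measurement
    month, both with onset/healing probabilities scaled by ``effect``
    (the intervention ramps up over the year; for simplicity the scaled
    dynamics apply to the whole post-baseline period). Patients who die
    in between are absent from the final registry; the final registry's
    denominator stays at ``n_patients``.
    """
    params.validate()
    effect = effect or InterventionEffect()
    effect.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ids = np.arange(1, params.n_patients + 1)
    codes = _initial_codes(params, rng)
    baseline, codes = _simulate_month(params, rng, codes, ids, "baseline")

    grade_sample = _grade_sampler(params)
    for _ in range(gap_months):
        codes = _step(
            codes, 30.0, params, rng, effect.onset, effect.healing, grade_sample
        )

    final, _ = _simulate_month(
        params,
        rng,
        codes,
        ids,
        "final",
        onset_multiplier=effect.onset,
        healing_multiplier=effect.healing,
    )
    return baseline, final


def paired_registries_from_annual_matrix(
    annual_probs: np.ndarray,
    n_patients: int,
    initial_dist: np.ndarray,
    rng: np.random.Generator,
    n_moments: int = 12,
) -> tuple[PatientRegistry, PatientRegistry]:
    """Paired registries whose annual state transitions follow a known matrix.

    Used for parameter-recovery experiments: baseline states are drawn
    from ``initial_dist`` over the nine alive states, final states from
    the corresponding row of ``annual_probs`` (9x9, alive states in
    :data:`STATE_ORDER` order), and each patient holds their state
    constant through the measurement month, so the representative
    monthly state equals the sampled state exactly.
    """
    annual_probs = np.asarray(annual_probs, dtype=float)
    if annual_probs.shape != (9, 9):
        raise ParameterError("annual_probs must be 9x9 over the alive states")
    initial_dist = np.asarray(initial_dist, dtype=float)
    if initial_dist.shape != (9,) or abs(initial_dist.sum() - 1.0) > 1e-9:
        raise ParameterError("initial_dist must be a distribution over 9 states")
    ids = np.arange(1, n_patients + 1)
    base = rng.choice(9, size=n_patients, p=initial_dist)
    final = np.empty(n_patients, dtype=np.int64)
    for s in range(9):
        mask = base == s
        if mask.any():
            final[mask] = rng.choice(9, size=mask.sum(), p=annual_probs[s])

    offsets_params = CohortParams(
        n_patients=n_patients, n_measurement_moments=n_moments
    )
    offsets = moment_day_offsets(offsets_params)

    def build(codes: np.ndarray, period: str) -> PatientRegistry:
        df = pd.DataFrame(
            {
                "patient_id": np.tile(ids, n_moments),
                "moment_index": np.repeat(
                    np.arange(1, n_moments + 1), n_patients
                ),
                "day_offset": np.repeat(offsets, n_patients),
                "state": np.tile(
                    np.array([ALIVE_STATES[c].value for c in codes]), n_moments
                ),
            }
        )
        return PatientRegistry(records=df, period_label=period, n_patients=n_patients)

    return build(base, "baseline"), build(final, "final")


def scaled_params(params: CohortParams, **overrides) -> CohortParams:
    """Copy ``params`` with field overrides (convenience for experiments)."""
    return replace(params, **overrides)
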