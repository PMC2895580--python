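"""Prevalence and incidence measures from a surveillance registry.

Prevalence is the number of patients with any pressure ulcer divided by
the cohort denominator, averaged over the moments of the measurement
month. Incidence is the number of patients who acquire a new ulcer
(a no-PU observation followed by a PU observation) during the month,
counted once per patient, divided by the same denominator. Pre/post
comparisons use a two-sample t-test on per-patient any-PU indicators,
with an optional paired variant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .states import HealthState, SEVERITY_RANK
from .synthetic_data import PatientRegistry


class EmptyRegistryError(ValueError):
    """Raised when a measure is requested from an empty registry."""


def _check_nonempty(registry: PatientRegistry) -> None:
    if registry.records.empty:
        raise EmptyRegistryError("registry contains no records")


def _is_pu(states: pd.Series) -> pd.Series:
    return states.map(lambda v: HealthState(v).is_pu)


def point_prevalence(
    registry: PatientRegistry, moment: int, denominator: int | None = None
) -> float:
    """Fraction of the cohort with any PU at one measurement moment."""
    _check_nonempty(registry)
    denom = denominator or registry.denominator
    states = registry.states_at(moment)
    return float(_is_pu(states).sum()) / denom


def monthly_prevalence(
    registry: PatientRegistry, denominator: int | None = None
) -> float:
    """Mean of the point prevalences over all moments of the month."""
    _check_nonempty(registry)
    moments = registry.moments
    return float(
        np.mean([point_prevalence(registry, m, denominator) for m in moments])
    )


def prevalence_by_grade(
    registry: PatientRegistry, denominator: int | None = None
) -> dict[int, float]:
    """Monthly average prevalence per grade (single + multiple combined)."""
    _check_nonempty(registry)
    denom = denominator or registry.denominator
    moments = registry.moments
    out = {g: 0.0 for g in (1, 2, 3, 4)}
    for m in moments:
        states = registry.states_at(m)
        grades = states.map(lambda v: HealthState(v).grade)
        for g in out:
            out[g] += float((grades == g).sum()) / denom
    return {g: v / len(moments) for g, v in out.items()}


def _patient_sequences(registry: PatientRegistry):
    df = registry.records.sort_values(["patient_id", "moment_index"])
    return df.groupby("patient_id", sort=True)["state"]


def incident_patients(registry: PatientRegistry) -> dict[int, int]:
    """Patient id -> grade at first new PU for each incident patient.

    A patient is incident if a no-PU observation is followed (at any
    later observed moment) by a PU observation; repeated onsets within
    the month still count the patient once. The grade recorded is the
    grade at the first PU observation after a no-PU observation.
    """
    _check_nonempty(registry)
    out: dict[int, int] = {}
    for pid, states in _patient_sequences(registry):
        seen_no_pu = False
        for value in states:
            st = HealthState(value)
            if st is HealthState.NO_PU:
                seen_no_pu = True
            elif st.is_pu and seen_no_pu:
                out[int(pid)] = st.grade
                break
    return out


def monthly_incidence(
    registry: PatientRegistry, denominator: int | None = None
) -> float:
    """Fraction of the cohort acquiring a new PU during the month."""
    _check_nonempty(registry)
    if len(registry.moments) < 2:
        raise ValueError("incidence needs at least two measurement moments")
    denom = denominator or registry.denominator
    return len(incident_patients(registry)) / denom


def incidence_by_grade(
    registry: PatientRegistry, denominator: int | None = None
) -> dict[int, float]:
    denom = denominator or registry.denominator
    grades = list(incident_patients(registry).values())
    return {g: grades.count(g) / denom for g in (1, 2, 3, 4)}


@dataclass
class EffectMeasures:
    """Summary of one measurement month, mirroring a surveillance table."""

    prevalence_by_grade: dict[int, float]
    prevalence_total: float
    incidence_by_grade: dict[int, float]
    incidence_total: float
    denominator: int
    period_label: str = ""


def effect_measures(
    registry: PatientRegistry, denominator: int | None = None
) -> EffectMeasures:
    denom = denominator or registry.denominator
    return EffectMeasures(
        prevalence_by_grade=prevalence_by_grade(registry, denom),
        prevalence_total=monthly_prevalence(registry, denom),
        incidence_by_grade=incidence_by_grade(registry, denom),
        incidence_total=monthly_incidence(registry, denom),
        denominator=denom,
        period_label=registry.period_label,
    )


def patient_pu_indicators(registry: PatientRegistry) -> pd.Series:
    """Per-patient 0/1 indicator of any PU observation during the month."""
    _check_nonempty(registry)
    flags = (
        registry.records.assign(pu=_is_pu(registry.records["state"]))
        .groupby("patient_id", sort=True)["pu"]
        .any()
        .astype(int)
    )
    flags.name = "any_pu"
    return flags


@dataclass
class PrePostTest:
    """Result of the before/after comparison of PU indicators."""

    statistic: float
    pvalue: float
    paired: bool
    degenerate: bool = False  # zero variance in both groups


def compare_pre_post(
    before: pd.Series | np.ndarray,
    after: pd.Series | np.ndarray,
    paired: bool = False,
) -> PrePostTest:
    """Two-sample t-test on per-patient any-PU indicators.

    With ``paired=True`` the vectors are aligned on patient id (both
    must be pandas Series) and a paired t-test is used. When neither
    group shows any variance the statistic is undefined; the result is
    flagged ``degenerate`` with statistic 0 and p-value 1 (identical
    constant groups) rather than raising.
    """
    if paired:
        if not (isinstance(before, pd.Series) and isinstance(after, pd.Series)):
            raise TypeError("paired comparison requires id-indexed Series")
        common = before.index.intersection(after.index)
        if len(common) == 0:
            raise ValueError("no common patient ids for paired comparison")
        b = before.loc[common].to_numpy(dtype=float)
        a = after.loc[common].to_numpy(dtype=float)
    else:
        b = np.asarray(before, dtype=float)
        a = np.asarray(after, dtype=float)

    if np.var(b) == 0 and np.var(a) == 0:
        same_mean = b.size > 0 and a.size > 0 and b[0] == a[0]
        stat, p = (0.0, 1.0) if same_mean else (np.inf, 0.0)
        return PrePostTest(statistic=stat, pvalue=p, paired=paired, degenerate=True)

    if paired:
        res = stats.ttest_rel(b, a)
    else:
        res = stats.ttest_ind(b, a)
    return PrePostTest(
        statistic=float(res.statistic), pvalue=float(res.pvalue), paired=paired
    )


def effects_table(
    before: EffectMeasures, after: EffectMeasures
) -> pd.DataFrame:
    """Surveillance-style table: grades + total, baseline vs final columns."""
    rows = []
    for g in (1, 2, 3, 4):
        rows.append(
            {
                "measure": f"prevalence_grade_{g}",
                "baseline": before.prevalence_by_grade[g],
                "final": after.prevalence_by_grade[g],
            }
        )
    rows.append(
        {
            "measure": "prevalence_total",
            "baseline": before.prevalence_total,
            "final": after.prevalence_total,
        }
    )
    for g in (1, 2, 3, 4):
        rows.append(
            {
                "measure": f"incidence_grade_{g}",
                "baseline": before.incidence_by_grade[g],
                "final": after.incidence_by_grade[g],
            }
        )
    rows.append(
        {
            "measure": "incidence_total",
            "baseline": before.incidence_total,
            "final": after.incidence_total,
        }
    )
    return pd.DataFrame(rows)


def representative_states(registry: PatientRegistry) -> pd.Series:
    """Modal state per patient over the month; ties go to the worse state."""
    _check_nonempty(registry)

    def modal(states: pd.Series) -> str:
        counts = states.value_counts()
        top = counts[counts == counts.max()].index
        return max(top, key=lambda v: SEVERITY_RANK[HealthState(v)])

    out = _patient_sequences(registry).apply(modal)
    out.name = "state"
    return out
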