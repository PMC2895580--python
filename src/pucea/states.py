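"""Health-state vocabulary for the pressure-ulcer cohort model.

The model distinguishes ten mutually exclusive states: no pressure ulcer,
a single ulcer of grade 1-4, multiple ulcers of grade 1-4, and death.
Death is absorbing. Grades run from 1 (non-blanchable erythema) to 4
(full-thickness tissue loss).
"""
from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    NO_PU = "no_pu"
    SINGLE_1 = "single_1"
    SINGLE_2 = "single_2"
    SINGLE_3 = "single_3"
    SINGLE_4 = "single_4"
    MULTI_1 = "multi_1"
    MULTI_2 = "multi_2"
    MULTI_3 = "multi_3"
    MULTI_4 = "multi_4"
    DEATH = "death"

    @property
    def grade(self) -> int | None:
        """Ulcer grade 1-4, or None for the no-PU and death states."""
        if self in (HealthState.NO_PU, HealthState.DEATH):
            return None
        return int(self.value[-1])

    @property
    def is_pu(self) -> bool:
        return self.grade is not None

    @property
    def is_multiple(self) -> bool:
        return self.value.startswith("multi")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical axis order for transition matrices and occupancy vectors.
STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.NO_PU,
    HealthState.SINGLE_1,
    HealthState.SINGLE_2,
    HealthState.SINGLE_3,
    HealthState.SINGLE_4,
    HealthState.MULTI_1,
    HealthState.MULTI_2,
    HealthState.MULTI_3,
    HealthState.MULTI_4,
    HealthState.DEATH,
)

STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_ORDER)}
ALIVE_STATES: tuple[HealthState, ...] = STATE_ORDER[:-1]
PU_STATES: tuple[HealthState, ...] = tuple(s for s in STATE_ORDER if s.is_pu)

# Clinical severity ordering, used only to break ties when summarizing a
# month of observations into one representative state (ties go to the
# worse state). Multiple ulcers of a grade rank above a single ulcer of
# the same grade; any higher grade ranks above any lower grade.
SEVERITY_RANK: dict[HealthState, int] = {
    HealthState.NO_PU: 0,
    HealthState.SINGLE_1: 1,
    HealthState.MULTI_1: 2,
    HealthState.SINGLE_2: 3,
    HealthState.MULTI_2: 4,
    HealthState.SINGLE_3: 5,
    HealthState.MULTI_3: 6,
    HealthState.SINGLE_4: 7,
    HealthState.MULTI_4: 8,
    HealthState.DEATH: 9,
}


def state_for(grade: int, multiple: bool = False) -> HealthState:
    """Return the PU state for a grade/multiplicity combination."""
    if grade not in (1, 2, 3, 4):
        raise ValueError(f"PU grade must be 1-4, got {grade!r}")
    prefix = "multi" if multiple else "single"
    return HealthState(f"{prefix}_{grade}")


def worse(a: HealthState, b: HealthState) -> HealthState:
    """The clinically more severe of two states."""
    return a if SEVERITY_RANK[a] >= SEVERITY_RANK[b] else b
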