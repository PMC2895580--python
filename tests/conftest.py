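import numpy as np
import pandas as pd
import pytest

from pucea.costing import build_cost_profiles
from pucea.markov import UtilityProfile
from pucea.states import HealthState, STATE_ORDER
from pucea.synthetic_data import (
    CohortParams,
    InterventionEffect,
    PatientRegistry,
    generate_paired_cohort,
)


def make_registry(
    states_by_moment: dict[int, list[str]],
    n_patients: int | None = None,
    period: str = "baseline",
    day_per_moment: int = 2,
) -> PatientRegistry:
    """Hand-build a registry: moment -> list of states, one per patient.

    Patient i holds position i in every moment's list; ``None`` entries
    mean the patient is unobserved at that moment (e.g. died).
    """
    rows = []
    for moment, states in sorted(states_by_moment.items()):
        for pid, state in enumerate(states, start=1):
            if state is None:
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "moment_index": moment,
                    "day_offset": (moment - 1) * day_per_moment,
                    "state": state,
                }
            )
    return PatientRegistry(
        records=pd.DataFrame(rows), period_label=period, n_patients=n_patients
    )


def constant_registry(
    n_pu: int, n_total: int, n_moments: int = 12, pu_state: str = "single_1"
) -> PatientRegistry:
    """Registry where the same n_pu patients have a PU at every moment."""
    states = [pu_state] * n_pu + [HealthState.NO_PU.value] * (n_total - n_pu)
    return make_registry(
        {m: list(states) for m in range(1, n_moments + 1)}, n_patients=n_total
    )


@pytest.fixture(scope="session")
def study_params() -> CohortParams:
    return CohortParams(seed=20_260_921)


@pytest.fixture(scope="session")
def paired_registries(study_params):
    return generate_paired_cohort(
        study_params, InterventionEffect(onset=4.5 / 15.0)
    )


@pytest.fixture(scope="session")
def cost_profiles():
    return build_cost_profiles()


@pytest.fixture(scope="session")
def utilities() -> UtilityProfile:
    return UtilityProfile()
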