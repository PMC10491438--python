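import numpy as np
import pytest

from dtas_cea.parameters import (
    CostSet,
    EconSettings,
    HealthState,
    LIVING_STATES,
    ModelOptions,
    MortalityModel,
    ParameterSet,
    Strategy,
    TransitionMatrix,
    TriageParams,
    UtilitySet,
)
from dtas_cea.synthetic import SyntheticSpec, build_paper_like_parameter_set, generate_parameter_set

IDENTITY_ROWS = {
    HealthState.MRS01: [1.0, 0.0, 0.0, 0.0, 0.0],
    HealthState.MRS23: [0.0, 1.0, 0.0, 0.0, 0.0],
    HealthState.MRS4: [0.0, 0.0, 1.0, 0.0, 0.0],
    HealthState.MRS5: [0.0, 0.0, 0.0, 1.0, 0.0],
    HealthState.DEAD: [0.0, 0.0, 0.0, 0.0, 1.0],
}


def make_params(
    outcome_dtas=(1.0, 0.0, 0.0, 0.0, 0.0),
    outcome_iter=(1.0, 0.0, 0.0, 0.0, 0.0),
    t90_rows=None,
    tann_rows=None,
    q0=0.0,
    hr=(1.0, 1.0, 1.0, 1.0),
    utilities=(1.0, 1.0, 1.0, 1.0),
    allow_unordered=False,
    acute=(0.0, 0.0),
    diag=(0.0, 0.0),
    annual_care=(0.0, 0.0, 0.0, 0.0),
    p_lvo=1.0,
    discount_cost=0.0,
    discount_qaly=0.0,
    markov_years=9,
    entry_age=74,
    **options,
) -> ParameterSet:
    """Hand-buildable parameter set for analytic/limit tests (defaults: degenerate)."""
    ages = {a: q0 for a in range(entry_age, entry_age + markov_years + 3)}
    return ParameterSet(
        outcome90d={
            Strategy.DTAS: dict(zip(HealthState, outcome_dtas)),
            Strategy.ITER: dict(zip(HealthState, outcome_iter)),
        },
        t_90d_to_1y=TransitionMatrix(
            kind="NINETY_DAY_TO_ONE_YEAR", rows=t90_rows or IDENTITY_ROWS
        ),
        t_annual=TransitionMatrix(kind="ANNUAL", rows=tann_rows or IDENTITY_ROWS),
        mortality=MortalityModel(baseline_q=ages, hr=dict(zip(LIVING_STATES, hr))),
        utilities=UtilitySet(
            u=dict(zip(LIVING_STATES, utilities)), allow_unordered=allow_unordered
        ),
        costs=CostSet(
            acute_lvo={Strategy.DTAS: acute[0], Strategy.ITER: acute[1]},
            diag_non_lvo={Strategy.DTAS: diag[0], Strategy.ITER: diag[1]},
            annual_care=dict(zip(LIVING_STATES, annual_care)),
        ),
        triage=TriageParams(p_lvo=p_lvo),
        econ=EconSettings(
            discount_cost=discount_cost,
            discount_qaly=discount_qaly,
            markov_years=markov_years,
            entry_age=entry_age,
        ),
        options=ModelOptions(**options),
    )


@pytest.fixture(scope="session")
def paper_like() -> ParameterSet:
    return build_paper_like_parameter_set()


@pytest.fixture(scope="session")
def synth_ps() -> ParameterSet:
    return generate_parameter_set(SyntheticSpec(seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
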