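"""Annual-cycle Markov cohort engine with age- and disability-dependent mortality.

The cohort enters at its 1-year mRS distribution (from the decision tree)
and is propagated for ``markov_years`` one-year cycles. Within a cycle the
event order is: all-cause mortality first (life-table baseline combined
with an mRS-specific hazard ratio on the survival scale), then mRS
transition among survivors using the annual matrix restricted to living
destinations. Costs and QALYs accrue on end-of-cycle occupancy by default
(configurable: start-of-cycle, or their average as a half-cycle
correction) and are discounted at (1+r)^−k for cycle k, with year 1 — the
decision point — undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    DEAD_INDEX,
    LIVING_STATES,
    PROB_TOL,
    HealthState,
    MortalityModel,
    ParameterSet,
    Strategy,
    TransitionMatrix,
)
from .tree import YearOneResult, run_year_one

__all__ = [
    "CohortTrace",
    "StrategyResult",
    "state_death_probability",
    "step",
    "run_markov",
    "run_strategy",
]


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy; row 0 is the 1-year entry distribution."""

    occupancy: np.ndarray  # (markov_years + 1, 5)
    age_at_cycle: np.ndarray  # entry_age + 1 + cycle index


@dataclass(frozen=True)
class StrategyResult:
    """Discounted per-patient totals over the full horizon (year 1 + Markov years)."""

    strategy: Strategy
    total_cost: float
    total_qaly: float
    trace: CohortTrace
    year_one: YearOneResult


def state_death_probability(age: int, state: HealthState, m: MortalityModel) -> float:
    """Annual death probability ``q(s, a) = 1 − (1 − q0(a))^HR_s``.

    Proportional hazards applied on the annual survival scale keeps the
    result in [0, 1] for any HR ≥ 0.
    """
    state = HealthState(state)
    if state is HealthState.DEAD:
        raise ValueError("death probability is defined for living states only")
    hr = m.hr[state]
    if hr < 0:
        raise ValueError(f"hazard ratio for {state.value} is negative")
    q0 = m.q0(age)
    return 1.0 - (1.0 - q0) ** hr


def _living_transition(t_annual: TransitionMatrix):
    """4×4 annual transition among living states with rows renormalized to sum to 1.

    Returns ``(L, degenerate)`` where ``degenerate`` flags origin rows with no
    mass on living destinations; such rows are only an error if survivors
    actually occupy them (checked by the caller).
    """
    mat = t_annual.as_array()[:4, :4]
    sums = mat.sum(axis=1)
    degenerate = sums <= PROB_TOL
    safe = np.where(degenerate, 1.0, sums)
    L = mat / safe[:, None]
    return L, degenerate


def _check_degenerate(survivors: np.ndarray, degenerate: np.ndarray) -> None:
    if np.any(survivors[degenerate] > PROB_TOL):
        bad = [LIVING_STATES[i].value for i in np.where(degenerate)[0]]
        raise ValueError(
            f"annual transition rows {bad} place no mass on living destinations; "
            "survivors cannot be redistributed"
        )


def _death_probs(age: int, m: MortalityModel) -> np.ndarray:
    q0 = m.q0(age)
    return 1.0 - (1.0 - q0) ** np.array([m.hr[s] for s in LIVING_STATES])


def step(dist, age: int, t_annual: TransitionMatrix, m: MortalityModel) -> np.ndarray:
    """Advance the cohort one cycle: mortality, then mRS transition among survivors."""
    dist = np.asarray(dist, dtype=float)
    q = _death_probs(age, m)
    living = dist[:4]
    dying = float(living @ q)
    survivors = living * (1.0 - q)
    L, degenerate = _living_transition(t_annual)
    _check_degenerate(survivors, degenerate)
    out = np.append(survivors @ L, dist[DEAD_INDEX] + dying)
    if abs(out.sum() - 1.0) > PROB_TOL * max(1.0, abs(dist.sum())):
        raise AssertionError(f"occupancy no longer sums to 1: {out.sum():.12f}")
    return out


def run_markov(entry: YearOneResult, params: ParameterSet) -> StrategyResult:
    """Run the cohort for ``markov_years`` cycles and add the year-1 amounts.

    Cycle k (calendar year 1+k) accrues, per suspected-LVO patient,
    ``p_lvo · Σ_s occ(s) · annual_care(s) · (1+r_c)^−k`` in cost and the
    analogous utility-weighted QALY term, where ``occ`` is the accrual-basis
    occupancy (end-of-cycle by default).
    """
    econ, opts = params.econ, params.options
    years = econ.markov_years
    care = params.costs.annual_care_array()
    util = params.utilities.as_array()
    p = params.triage.p_lvo
    L, degenerate = _living_transition(params.t_annual)

    occ = np.asarray(entry.entry_dist, dtype=float)
    trace = np.empty((years + 1, 5))
    trace[0] = occ
    cost, qaly = entry.cost_year1, entry.qaly_year1
    for k in range(1, years + 1):
        age = econ.entry_age + k  # age at the start of Markov cycle k
        q = _death_probs(age, params.mortality)
        survivors = occ[:4] * (1.0 - q)
        _check_degenerate(survivors, degenerate)
        new = np.append(survivors @ L, occ[DEAD_INDEX] + float(occ[:4] @ q))
        if opts.half_cycle_correction:
            basis = 0.5 * (occ + new)
        elif opts.accrual == "start":
            basis = occ
        else:
            basis = new
        dfc = (1.0 + econ.discount_cost) ** (-k)
        dfe = (1.0 + econ.discount_qaly) ** (-k)
        cost += p * float(basis @ care) * dfc
        qaly += p * float(basis @ util) * dfe
        if opts.include_non_lvo_outcomes:
            cost += (1.0 - p) * params.non_lvo.annual_cost * dfc
            qaly += (1.0 - p) * params.non_lvo.annual_utility * dfe
        occ = new
        trace[k] = occ

    return StrategyResult(
        strategy=entry.strategy,
        total_cost=cost,
        total_qaly=qaly,
        trace=CohortTrace(
            occupancy=trace,
            age_at_cycle=np.arange(years + 1) + econ.entry_age + 1,
        ),
        year_one=entry,
    )


def run_strategy(params: ParameterSet, strategy: Strategy) -> StrategyResult:
    """Decision tree followed by the Markov cohort model, for one strategy."""
    return run_markov(run_year_one(params, strategy), params)
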