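"""Year-one decision tree: triage split, 90-day outcomes, and the 1-year entry state.

Patients enter the pathway as *suspected* LVO. With probability ``p_lvo``
the occlusion is confirmed and the patient follows the strategy-specific
90-day mRS outcome distribution, transitions to a 1-year mRS state, and
accrues the acute treatment cost plus first-year care costs and QALYs.
Non-LVO patients contribute only the strategy-specific diagnostic cost:
their downstream costs and outcomes are assumed identical between the two
strategies and are excluded from totals by default (an optional identical
profile can be added back for presentation purposes).

Year-1 amounts are undiscounted — year 1 is the present-value anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    PROB_TOL,
    ParameterSet,
    Strategy,
    TransitionMatrix,
    state_vector,
)

__all__ = ["YearOneResult", "ninety_day_to_one_year", "run_year_one"]


@dataclass(frozen=True)
class YearOneResult:
    """Per-patient expected state distribution, cost and QALY at the end of year 1."""

    strategy: Strategy
    entry_dist: np.ndarray  # over the 5 states, LVO patients only
    cost_year1: float
    qaly_year1: float


def ninety_day_to_one_year(p90, t: TransitionMatrix) -> np.ndarray:
    """Propagate a 90-day state distribution to 1 year: ``p1y = p90 · T``.

    The 90-day→1-year matrix may move mass in either direction on the mRS
    scale (early recovery or deterioration) and into death.
    """
    vec = state_vector(p90) if isinstance(p90, dict) else np.asarray(p90, dtype=float)
    mat = t.as_array()
    if vec.shape != (5,) or mat.shape != (5, 5):
        raise ValueError(f"dimension mismatch: p90 {vec.shape}, matrix {mat.shape}")
    out = vec @ mat
    if abs(out.sum() - 1.0) > PROB_TOL:
        raise ValueError(f"1-year distribution sums to {out.sum():.12f}")
    return out


def run_year_one(params: ParameterSet, strategy: Strategy) -> YearOneResult:
    """Evaluate the decision tree for one strategy.

    Expected year-1 cost per suspected-LVO patient::

        p_lvo · (acute_lvo + Σ_s occ_1y(s) · annual_care(s))
          + (1 − p_lvo) · diag_non_lvo [+ optional identical non-LVO profile]

    and QALYs ``p_lvo · Σ_s occ_1y(s) · u(s)``, both accrued on the 1-year
    (post-transition) state distribution.
    """
    strategy = Strategy(strategy)
    p = params.triage.p_lvo
    entry = ninety_day_to_one_year(params.outcome90d[strategy], params.t_90d_to_1y)
    care = params.costs.annual_care_array()
    util = params.utilities.as_array()
    cost = p * (params.costs.acute_lvo[strategy] + float(entry @ care))
    cost += (1.0 - p) * params.costs.diag_non_lvo[strategy]
    qaly = p * float(entry @ util)
    if params.options.include_non_lvo_outcomes:
        cost += (1.0 - p) * params.non_lvo.annual_cost
        qaly += (1.0 - p) * params.non_lvo.annual_utility
    return YearOneResult(strategy=strategy, entry_dist=entry, cost_year1=cost, qaly_year1=qaly)
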