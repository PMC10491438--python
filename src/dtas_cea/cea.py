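"""Incremental cost-effectiveness: ΔC, ΔE, ICER with dominance, net monetary benefit.

The ICER, ΔC/ΔE, is only meaningful when the intervention is both costlier
and more effective (north-east quadrant) or cheaper and less effective
(south-west). When the signs disagree a dominance label replaces the
number: DOMINANT (no costlier, no less effective) or DOMINATED (the
reverse). Net monetary benefit, NMB(λ) = λ·ΔE − ΔC, is sign-safe in every
quadrant and is the decision rule used for "cost-effective at λ"
(strictly positive; ties are not cost-effective).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

from .markov import StrategyResult
from .parameters import Strategy

__all__ = ["DOMINANT", "DOMINATED", "TIE", "CEAResult", "compute_cea", "icer_value"]

DOMINANT = "DOMINANT"
DOMINATED = "DOMINATED"
TIE = "TIE"


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator (EUR, QALY)."""

    intervention: Strategy
    comparator: Strategy
    delta_cost: float
    delta_qaly: float
    icer: Union[float, str]  # EUR/QALY, or a dominance label
    nmb: Dict[float, float] = field(default_factory=dict)
    cost_effective: Dict[float, bool] = field(default_factory=dict)


def icer_value(delta_cost: float, delta_qaly: float) -> Union[float, str]:
    """Numeric ICER where interpretable, else a dominance label."""
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return TIE
    if delta_cost <= 0.0 and delta_qaly >= 0.0:
        return DOMINANT
    if delta_cost >= 0.0 and delta_qaly <= 0.0:
        return DOMINATED
    return delta_cost / delta_qaly


def compute_cea(
    intervention: StrategyResult,
    comparator: StrategyResult,
    thresholds: Optional[Sequence[float]] = None,
) -> CEAResult:
    """Compare two strategy results run under the same parameter set.

    Increments are computed from the unrounded totals; rounding for
    presentation is left to the reporting layer (rounded increments divided
    by each other generally do not reproduce the unrounded ICER).
    """
    thresholds = list(thresholds or [])
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qaly - comparator.total_qaly
    nmb = {lam: de * lam - dc for lam in thresholds}
    return CEAResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=de,
        icer=icer_value(dc, de),
        nmb=nmb,
        cost_effective={lam: v > 0.0 for lam, v in nmb.items()},
    )
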