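"""Sensitivity analyses: one-way/tornado, scenarios, probabilistic (Monte Carlo), CEAC.

One-way analysis moves a single parameter to each end of its range (±20% of
the base value when no range is given) while holding everything else at base
case, re-runs the full pipeline, and reports the ICER at both ends; entries
sorted by ICER spread give the tornado diagram. When the varied parameter is
one component of a probability vector the remaining components are rescaled
by (1−p′)/(1−p) so the vector stays on the simplex.

The probabilistic sensitivity analysis draws every parameter from its
declared distribution (Dirichlet for outcome vectors and transition rows,
beta for single probabilities and utilities, gamma for costs and hazard
ratios), re-runs both strategies per draw, and summarizes the (ΔC, ΔE)
cloud as cost-effectiveness acceptability curves: the probability that the
intervention's net monetary benefit is positive at each willingness-to-pay
threshold.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from pydantic import BaseModel

from .cea import CEAResult, compute_cea
from .markov import StrategyResult, run_strategy
from .parameters import (
    LIVING_STATES,
    PROB_TOL,
    STATE_ORDER,
    DistributionSpec,
    HealthState,
    ParameterSet,
    ParameterValidationError,
    Strategy,
    apply_scenario,
    get_path,
    renormalize_component,
    set_path,
    validate_parameter_set,
)

__all__ = [
    "TornadoEntry",
    "PSASample",
    "CEACCurve",
    "ScenarioResult",
    "DEFAULT_SEED",
    "one_way",
    "tornado",
    "sample_psa",
    "ceac",
    "default_ceac_grid",
    "run_scenario",
    "set_with_renormalization",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "default_owsa_ranges",
    "default_psa_spec",
]

#: reproducibility default, overridable everywhere a seed is accepted
DEFAULT_SEED = 20230905


# ---------------------------------------------------------------------------
# One-way sensitivity / tornado
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter_path: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_low - self.icer_at_high)


def _numeric_icer(res: CEAResult) -> float:
    if isinstance(res.icer, float):
        return res.icer
    if res.delta_qaly == 0.0:
        return math.inf if res.delta_cost > 0 else (-math.inf if res.delta_cost < 0 else 0.0)
    return res.delta_cost / res.delta_qaly


def _is_prob_mapping(obj) -> bool:
    return (
        isinstance(obj, dict)
        and set(obj) == set(STATE_ORDER)
        and abs(sum(obj.values()) - 1.0) <= 1e-6
    )


def set_with_renormalization(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    """Set a scalar parameter; probability-vector components are simplex-repaired.

    A component of a 5-state outcome vector or of a transition-matrix row is
    replaced and the sibling components rescaled proportionally; any other
    scalar is set directly.
    """
    parts = path.split(".")
    parent = get_path(ps, ".".join(parts[:-1])) if len(parts) > 1 else ps
    last = parts[-1]
    if _is_prob_mapping(parent):
        new_map = renormalize_component(parent, HealthState(last), value)
        return set_path(ps, ".".join(parts[:-1]), new_map)
    if (
        isinstance(parent, list)
        and len(parent) == 5
        and abs(sum(parent) - 1.0) <= 1e-6
    ):
        idx = int(last)
        as_map = dict(zip(STATE_ORDER, parent))
        new_map = renormalize_component(as_map, STATE_ORDER[idx], value)
        return set_path(ps, ".".join(parts[:-1]), [new_map[s] for s in STATE_ORDER])
    return set_path(ps, path, value)


def _cea_for(ps: ParameterSet) -> CEAResult:
    return compute_cea(
        run_strategy(ps, Strategy.DTAS),
        run_strategy(ps, Strategy.ITER),
        ps.econ.thresholds,
    )


def one_way(ps: ParameterSet, parameter_path: str, low: float, high: float) -> TornadoEntry:
    """Re-run the pipeline with one parameter at each bound, all else at base."""
    if low > high:
        raise ValueError(f"low {low} > high {high} for {parameter_path}")
    icers = []
    for bound in (low, high):
        varied = set_with_renormalization(ps, parameter_path, bound)
        violations = validate_parameter_set(varied)
        if violations:
            raise ParameterValidationError(violations)
        icers.append(_numeric_icer(_cea_for(varied)))
    return TornadoEntry(
        parameter_path=parameter_path,
        low_value=low,
        high_value=high,
        icer_at_low=icers[0],
        icer_at_high=icers[1],
    )


def tornado(
    ps: ParameterSet, owsa_ranges: Optional[Dict[str, Tuple[float, float]]] = None
) -> List[TornadoEntry]:
    """One-way analysis over every range, widest ICER spread first."""
    ranges = ps.owsa_ranges if owsa_ranges is None else owsa_ranges
    entries = [one_way(ps, path, lo, hi) for path, (lo, hi) in ranges.items()]
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def default_owsa_ranges(
    ps: ParameterSet, frac: float = 0.2, paths: Optional[Sequence[str]] = None
) -> Dict[str, Tuple[float, float]]:
    """±``frac`` ranges around base values (probabilities capped at 1)."""
    if paths is None:
        paths = (
            [f"outcome90d.{st.value}.{s.value}" for st in Strategy for s in STATE_ORDER]
            + [f"utilities.u.{s.value}" for s in LIVING_STATES]
            + [f"costs.annual_care.{s.value}" for s in LIVING_STATES]
            + [f"costs.acute_lvo.{st.value}" for st in Strategy]
            + [f"costs.diag_non_lvo.{st.value}" for st in Strategy]
            + [f"mortality.hr.{s.value}" for s in LIVING_STATES]
            + ["triage.p_lvo"]
        )
    out: Dict[str, Tuple[float, float]] = {}
    for path in paths:
        base = float(get_path(ps, path))
        lo, hi = base * (1 - frac), base * (1 + frac)
        if "outcome90d" in path or path.endswith("p_lvo") or path.startswith("utilities"):
            hi = min(hi, 1.0)
        out[path] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSASample:
    """One Monte Carlo draw: sampled-parameter digest and the incremental pair."""

    index: int
    digest: str
    delta_cost: float
    delta_qaly: float


def beta_from_mean_se(mean: float, se: float) -> Tuple[float, float]:
    """Moment-matched beta hyperparameters (α, β) for a (0,1) quantity."""
    if not (0 < mean < 1) or se <= 0 or se**2 >= mean * (1 - mean):
        raise ValueError(f"infeasible beta moments mean={mean}, se={se}")
    nu = mean * (1 - mean) / se**2 - 1.0
    return mean * nu, (1 - mean) * nu

def gamma_from_mean_se(mean: float, se: float) -> Tuple[float, float]:
    """Moment-matched gamma (shape, scale) for a positive quantity."""
    if mean <= 0 or se <= 0:
        raise ValueError(f"infeasible gamma moments mean={mean}, se={se}")
    return (mean / se) ** 2, se**2 / mean


def _draw(spec: DistributionSpec, base, rng: np.random.Generator):
    if spec.family == "fixed":
        return base
    if spec.family == "beta":
        if spec.alpha is not None and spec.beta is not None:
            a, b = spec.alpha, spec.beta
        else:
            a, b = beta_from_mean_se(spec.mean, spec.se)
        return float(rng.beta(a, b))
    if spec.family == "gamma":
        if spec.shape is not None and spec.scale is not None:
            k, theta = spec.shape, spec.scale
        else:
            k, theta = gamma_from_mean_se(spec.mean, spec.se)
        return float(rng.gamma(k, theta))
    # dirichlet over the positive-concentration support; zero-alpha components
    # stay exactly zero
    alphas = np.asarray(spec.alphas, dtype=float)
    pos = alphas > 0
    sampled = np.zeros(len(alphas))
    sampled[pos] = rng.dirichlet(alphas[pos])
    if isinstance(base, dict):
        return {s: float(v) for s, v in zip(STATE_ORDER, sampled)}
    return [float(v) for v in sampled]


def _assign_in_place(ps: ParameterSet, path: str, value) -> None:
    parts = path.split(".")
    node = ps
    for part in parts[:-1]:
        if isinstance(node, BaseModel):
            node = getattr(node, part)
        elif isinstance(node, dict):
            node = node[_dict_key(node, part)]
        else:
            node = node[int(part)]
    last = parts[-1]
    if isinstance(node, BaseModel):
        setattr(node, last, value)
    elif isinstance(node, dict):
        node[_dict_key(node, last)] = value
    else:
        node[int(last)] = value


def _dict_key(container: dict, part: str):
    if part in container:
        return part
    for caster in (HealthState, Strategy):
        try:
            key = caster(part)
            if key in container:
                return key
        except ValueError:
            pass
    return int(part)


def _digest(sampled: dict) -> str:
    canon = {
        k: (v if not isinstance(v, dict) else {s.value: p for s, p in v.items()})
        for k, v in sampled.items()
    }
    return hashlib.sha1(json.dumps(canon, sort_keys=True).encode()).hexdigest()[:16]


def sample_psa(
    ps: ParameterSet,
    n: int = 10_000,
    seed: int = DEFAULT_SEED,
    psa_spec: Optional[Dict[str, DistributionSpec]] = None,
) -> List[PSASample]:
    """Monte Carlo over the declared parameter distributions; deterministic per seed."""
    spec_map = ps.psa_spec if psa_spec is None else psa_spec
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if not spec_map:
        raise ValueError("psa_spec is empty: no parameters declared for sampling")
    bases = {path: get_path(ps, path) for path in spec_map}
    rng = np.random.default_rng(seed)
    samples: List[PSASample] = []
    for i in range(n):
        sampled = {path: _draw(spec, bases[path], rng) for path, spec in spec_map.items()}
        work = ps.model_copy(deep=True)
        for path, value in sampled.items():
            _assign_in_place(work, path, value)
        res = compute_cea(
            run_strategy(work, Strategy.DTAS), run_strategy(work, Strategy.ITER)
        )
        samples.append(
            PSASample(
                index=i,
                digest=_digest(sampled),
                delta_cost=res.delta_cost,
                delta_qaly=res.delta_qaly,
            )
        )
    return samples


def default_psa_spec(
    ps: ParameterSet,
    se_frac: float = 0.2,
    outcome_ess: Optional[Dict[Strategy, float]] = None,
    transition_ess: float = 500.0,
) -> Dict[str, DistributionSpec]:
    """Standard distribution assignment when only base-case means are known.

    Outcome vectors and transition rows get Dirichlet concentrations equal to
    the effective sample size of their source (trial arm sizes for 90-day
    outcomes); scalar probabilities and utilities get moment-matched betas and
    costs/hazard ratios gammas, all with SE = ``se_frac`` × mean.
    """
    outcome_ess = outcome_ess or {Strategy.DTAS: 74.0, Strategy.ITER: 73.0}
    spec: Dict[str, DistributionSpec] = {}
    for st in Strategy:
        ess = outcome_ess[st]
        alphas = [ps.outcome90d[st][s] * ess for s in STATE_ORDER]
        spec[f"outcome90d.{st.value}"] = DistributionSpec(family="dirichlet", alphas=alphas)
    for name, tm in (("t_90d_to_1y", ps.t_90d_to_1y), ("t_annual", ps.t_annual)):
        for s in LIVING_STATES:
            alphas = [p * transition_ess for p in tm.rows[s]]
            spec[f"{name}.rows.{s.value}"] = DistributionSpec(
                family="dirichlet", alphas=alphas
            )
    p = ps.triage.p_lvo
    if p < 1.0:
        spec["triage.p_lvo"] = DistributionSpec(
            family="beta", mean=p, se=min(se_frac * p, 0.5 * math.sqrt(p * (1 - p)))
        )
    for s in LIVING_STATES:
        u = ps.utilities.u[s]
        if 0 < u < 1:
            spec[f"utilities.u.{s.value}"] = DistributionSpec(
                family="beta", mean=u, se=min(se_frac * u, 0.5 * math.sqrt(u * (1 - u)))
            )
        cost = ps.costs.annual_care[s]
        if cost > 0:
            spec[f"costs.annual_care.{s.value}"] = DistributionSpec(
                family="gamma", mean=cost, se=se_frac * cost
            )
        spec[f"mortality.hr.{s.value}"] = DistributionSpec(
            family="gamma", mean=ps.mortality.hr[s], se=se_frac * ps.mortality.hr[s]
        )
    for st in Strategy:
        for group in ("acute_lvo", "diag_non_lvo"):
            cost = getattr(ps.costs, group)[st]
            if cost > 0:
                spec[f"costs.{group}.{st.value}"] = DistributionSpec(
                    family="gamma", mean=cost, se=se_frac * cost
                )
    return spec


# ---------------------------------------------------------------------------
# Acceptability curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEACCurve:
    """P(strategy is cost-effective) against willingness-to-pay (model currency)."""

    thresholds: np.ndarray
    p_ce: Dict[Strategy, np.ndarray] = field(default_factory=dict)


def default_ceac_grid(eur_to_usd: float = 1.1827) -> np.ndarray:
    """$0–$150,000 in $1,000 steps expressed in EUR, Dutch thresholds included exactly."""
    usd = np.arange(0, 150_001, 1_000, dtype=float)
    grid = np.union1d(usd / eur_to_usd, [50_000.0, 80_000.0])
    return grid


def ceac(
    samples: Sequence[PSASample],
    grid: Optional[np.ndarray] = None,
    intervention: Strategy = Strategy.DTAS,
    comparator: Strategy = Strategy.ITER,
    eur_to_usd: float = 1.1827,
) -> CEACCurve:
    """Fraction of PSA draws with positive net monetary benefit at each threshold.

    Ties (NMB exactly 0) count toward the comparator, so the two curves are
    exact complements at every grid point.
    """
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    grid = default_ceac_grid(eur_to_usd) if grid is None else np.asarray(grid, dtype=float)
    dc = np.array([s.delta_cost for s in samples])
    de = np.array([s.delta_qaly for s in samples])
    nmb = de[None, :] * grid[:, None] - dc[None, :]
    p_int = (nmb > 0).mean(axis=1)
    return CEACCurve(thresholds=grid, p_ce={intervention: p_int, comparator: 1.0 - p_int})


# ---------------------------------------------------------------------------
# Scenario bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    params: ParameterSet
    results: Dict[Strategy, StrategyResult]
    cea: CEAResult
    tornado: Optional[List[TornadoEntry]] = None
    psa: Optional[List[PSASample]] = None
    ceac: Optional[CEACCurve] = None


def run_scenario(
    scenario: Union[str, int],
    ps: ParameterSet,
    psa_iterations: int = 0,
    seed: int = DEFAULT_SEED,
    with_tornado: bool = False,
) -> ScenarioResult:
    """Apply scenario overrides and run the full pipeline (optionally + OWSA/PSA)."""
    applied = apply_scenario(ps, scenario)
    dtas = run_strategy(applied, Strategy.DTAS)
    iter_ = run_strategy(applied, Strategy.ITER)
    res = compute_cea(dtas, iter_, applied.econ.thresholds)
    torn = tornado(applied) if with_tornado and applied.owsa_ranges else None
    psa = curve = None
    if psa_iterations > 0:
        psa = sample_psa(applied, psa_iterations, seed)
        curve = ceac(psa, eur_to_usd=applied.costs.eur_to_usd)
    return ScenarioResult(
        scenario=str(scenario),
        params=applied,
        results={Strategy.DTAS: dtas, Strategy.ITER: iter_},
        cea=res,
        tornado=torn,
        psa=psa,
        ceac=curve,
    )
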