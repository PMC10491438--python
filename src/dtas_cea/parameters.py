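"""Domain types, parameter schema, validation and file I/O.

The model compares two triage strategies for patients with suspected large
vessel occlusion (LVO) stroke: direct transfer to the angiography suite
(DTAS) versus initial transfer to the emergency room (ITER). All inputs —
90-day modified Rankin Scale (mRS) outcome distributions per strategy,
mRS transition matrices, age- and disability-dependent mortality, state
utilities and costs, and the economic settings — live in a single
JSON-schema'd :class:`ParameterSet` so that every analysis is reproducible
from one human-editable file.

All monetary computation is done in euros; US dollars are a reporting
conversion at a fixed exchange rate.
"""

from __future__ import annotations

import copy
import enum
import json
import math
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = [
    "HealthState",
    "Strategy",
    "LIVING_STATES",
    "STATE_ORDER",
    "DEAD_INDEX",
    "TransitionMatrix",
    "MortalityModel",
    "UtilitySet",
    "CostSet",
    "TriageParams",
    "EconSettings",
    "ModelOptions",
    "NonLVOProfile",
    "DistributionSpec",
    "ParameterSet",
    "ParameterFormatError",
    "ParameterValidationError",
    "SCENARIOS",
    "load_parameters",
    "write_parameters",
    "apply_scenario",
    "base_p_lvo_from_trial",
    "state_vector",
    "vector_to_mapping",
    "get_path",
    "set_path",
    "renormalize_component",
    "paper_like_fixture_path",
]

PROB_TOL = 1e-9


class HealthState(str, enum.Enum):
    """Model health states: mRS bands 0–1, 2–3, 4, 5 and death (mRS 6)."""

    MRS01 = "MRS01"
    MRS23 = "MRS23"
    MRS4 = "MRS4"
    MRS5 = "MRS5"
    DEAD = "DEAD"


STATE_ORDER: Tuple[HealthState, ...] = (
    HealthState.MRS01,
    HealthState.MRS23,
    HealthState.MRS4,
    HealthState.MRS5,
    HealthState.DEAD,
)
LIVING_STATES: Tuple[HealthState, ...] = STATE_ORDER[:4]
DEAD_INDEX = 4
STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}


class Strategy(str, enum.Enum):
    """The two triage comparators."""

    DTAS = "DTAS"
    ITER = "ITER"


def state_vector(mapping: Dict[HealthState, float]) -> np.ndarray:
    """Convert a state→probability mapping into a length-5 array in canonical order."""
    return np.array([float(mapping[s]) for s in STATE_ORDER])


def vector_to_mapping(vec) -> Dict[HealthState, float]:
    return {s: float(v) for s, v in zip(STATE_ORDER, vec)}


# ---------------------------------------------------------------------------
# Schema models
# ---------------------------------------------------------------------------


class TransitionMatrix(BaseModel):
    """Row-stochastic 5×5 mRS transition matrix (row = origin, column = destination)."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal["NINETY_DAY_TO_ONE_YEAR", "ANNUAL"]
    rows: Dict[HealthState, List[float]]

    def as_array(self) -> np.ndarray:
        return np.array([self.rows[s] for s in STATE_ORDER], dtype=float)


class MortalityModel(BaseModel):
    """Age-specific baseline annual death probability with per-state hazard multipliers.

    The state-specific annual death probability is combined on the survival
    scale, ``q(s, a) = 1 − (1 − q0(a))^HR_s``, which stays in [0, 1] for any
    non-negative hazard ratio.
    """

    model_config = ConfigDict(extra="forbid")

    baseline_q: Dict[int, float]
    hr: Dict[HealthState, float]

    def q0(self, age: int, clamp: bool = True) -> float:
        ages = sorted(self.baseline_q)
        if age in self.baseline_q:
            return float(self.baseline_q[age])
        if not clamp:
            raise KeyError(f"age {age} not covered by life table")
        if age < ages[0]:
            return float(self.baseline_q[ages[0]])
        return float(self.baseline_q[ages[-1]])


class UtilitySet(BaseModel):
    """QALY weights per living state; death is 0 by construction."""

    model_config = ConfigDict(extra="forbid")

    u: Dict[HealthState, float]
    allow_unordered: bool = False

    def as_array(self) -> np.ndarray:
        vals = [float(self.u[s]) for s in LIVING_STATES]
        return np.array(vals + [0.0])


class CostSet(BaseModel):
    """Acute and annual care costs (euros unless stated otherwise)."""

    model_config = ConfigDict(extra="forbid")

    acute_lvo: Dict[Strategy, float]
    diag_non_lvo: Dict[Strategy, float]
    annual_care: Dict[HealthState, float]
    currency: Literal["EUR", "USD"] = "EUR"
    eur_to_usd: float = 1.1827

    def annual_care_array(self) -> np.ndarray:
        vals = [float(self.annual_care[s]) for s in LIVING_STATES]
        return np.array(vals + [0.0])


class TriageParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    p_lvo: float


class EconSettings(BaseModel):
    """Discounting, horizon, cohort and willingness-to-pay settings.

    ``thresholds`` are expressed in the model currency (EUR); the Dutch
    defaults €50,000 and €80,000 per QALY correspond to $59,135 and $94,616
    at the fixed 1.1827 exchange rate.
    """

    model_config = ConfigDict(extra="forbid")

    discount_cost: float = 0.04
    discount_qaly: float = 0.015
    markov_years: int = 9
    entry_age: int = 74
    thresholds: List[float] = [50_000.0, 80_000.0]
    cohort_size: int = 10_000


class ModelOptions(BaseModel):
    """Structural switches that a cohort-model implementation must pin down."""

    model_config = ConfigDict(extra="forbid")

    #: accrue cycle rewards on start- or end-of-cycle occupancy
    accrual: Literal["start", "end"] = "end"
    #: average start and end occupancy (overrides ``accrual``)
    half_cycle_correction: bool = False
    #: add an identical non-LVO outcome profile to both strategies' totals
    include_non_lvo_outcomes: bool = False
    #: clamp life-table lookups beyond the tabulated age range
    allow_age_clamp: bool = True


class NonLVOProfile(BaseModel):
    """Identical-across-strategies yearly cost/QALY profile for non-LVO patients."""

    model_config = ConfigDict(extra="forbid")

    annual_cost: float = 0.0
    annual_utility: float = 0.0


class DistributionSpec(BaseModel):
    """Distribution descriptor for one probabilistic-sensitivity-analysis parameter.

    ``beta``/``gamma`` accept either natural hyperparameters or (mean, se)
    which are moment-matched; ``dirichlet`` applies to a whole probability
    vector; ``fixed`` pins the parameter at its base-case value.
    """

    model_config = ConfigDict(extra="forbid")

    family: Literal["beta", "gamma", "dirichlet", "fixed"]
    alpha: Optional[float] = None
    beta: Optional[float] = None
    shape: Optional[float] = None
    scale: Optional[float] = None
    mean: Optional[float] = None
    se: Optional[float] = None
    alphas: Optional[List[float]] = None


class ParameterSet(BaseModel):
    """Complete parameterization of one model scenario."""

    model_config = ConfigDict(extra="forbid")

    outcome90d: Dict[Strategy, Dict[HealthState, float]]
    t_90d_to_1y: TransitionMatrix
    t_annual: TransitionMatrix
    mortality: MortalityModel
    utilities: UtilitySet
    costs: CostSet
    triage: TriageParams
    econ: EconSettings = EconSettings()
    options: ModelOptions = ModelOptions()
    non_lvo: NonLVOProfile = NonLVOProfile()
    owsa_ranges: Dict[str, Tuple[float, float]] = {}
    psa_spec: Dict[str, DistributionSpec] = {}
    notes: Dict[str, object] = {}

    # -- convenience ------------------------------------------------------
    def outcome_vector(self, strategy: Strategy) -> np.ndarray:
        return state_vector(self.outcome90d[strategy])


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class ParameterFormatError(ValueError):
    """The file could not be parsed into the parameter schema."""


class ParameterValidationError(ValueError):
    """One or more domain invariants are violated; ``violations`` lists all of them."""

    def __init__(self, violations: List[str]):
        self.violations = list(violations)
        super().__init__(
            "parameter validation failed:\n  - " + "\n  - ".join(self.violations)
        )


# ---------------------------------------------------------------------------
# Invariant validation
# ---------------------------------------------------------------------------


def _check_prob_vector(name: str, mapping: Dict[HealthState, float], out: List[str]) -> None:
    missing = [s.value for s in STATE_ORDER if s not in mapping]
    if missing:
        out.append(f"{name}: missing states {missing}")
        return
    vec = state_vector(mapping)
    if np.any(vec < -PROB_TOL) or np.any(vec > 1 + PROB_TOL):
        out.append(f"{name}: entries must lie in [0,1], got {vec.tolist()}")
    if abs(vec.sum() - 1.0) > PROB_TOL:
        out.append(f"{name}: entries sum to {vec.sum():.10f}, expected 1")


def _check_matrix(name: str, tm: TransitionMatrix, expected_kind: str, out: List[str]) -> None:
    if tm.kind != expected_kind:
        out.append(f"{name}: kind is {tm.kind}, expected {expected_kind}")
    missing = [s.value for s in STATE_ORDER if s not in tm.rows]
    if missing:
        out.append(f"{name}: missing rows {missing}")
        return
    for s in STATE_ORDER:
        row = tm.rows[s]
        if len(row) != 5:
            out.append(f"{name} row {s.value}: has {len(row)} entries, expected 5")
            continue
        arr = np.asarray(row, dtype=float)
        if np.any(arr < -PROB_TOL) or np.any(arr > 1 + PROB_TOL):
            out.append(f"{name} row {s.value}: entries must lie in [0,1]")
        if abs(arr.sum() - 1.0) > PROB_TOL:
            out.append(f"{name} row {s.value}: sums to {arr.sum():.10f}, expected 1")
    dead = np.asarray(tm.rows[HealthState.DEAD], dtype=float)
    if np.any(np.abs(dead - np.eye(5)[DEAD_INDEX]) > PROB_TOL):
        out.append(f"{name}: DEAD row must be (0,0,0,0,1) — death is absorbing")


def validate_parameter_set(ps: ParameterSet) -> List[str]:
    """Return the list of violated invariants (empty when the set is valid)."""
    v: List[str] = []

    for strat in Strategy:
        if strat not in ps.outcome90d:
            v.append(f"outcome90d: missing strategy {strat.value}")
        else:
            _check_prob_vector(f"outcome90d.{strat.value}", ps.outcome90d[strat], v)

    _check_matrix("t_90d_to_1y", ps.t_90d_to_1y, "NINETY_DAY_TO_ONE_YEAR", v)
    _check_matrix("t_annual", ps.t_annual, "ANNUAL", v)

    if not ps.mortality.baseline_q:
        v.append("mortality.baseline_q: life table is empty")
    for age, q in ps.mortality.baseline_q.items():
        if not (0.0 <= q <= 1.0):
            v.append(f"mortality.baseline_q[{age}]: {q} outside [0,1]")
    for s in LIVING_STATES:
        if s not in ps.mortality.hr:
            v.append(f"mortality.hr: missing state {s.value}")
        elif ps.mortality.hr[s] < 0:
            v.append(f"mortality.hr.{s.value}: hazard ratio {ps.mortality.hr[s]} < 0")
    if HealthState.DEAD in ps.mortality.hr:
        v.append("mortality.hr: DEAD must not carry a hazard ratio")
    if not ps.options.allow_age_clamp and ps.mortality.baseline_q:
        needed = range(ps.econ.entry_age, ps.econ.entry_age + 1 + ps.econ.markov_years + 1)
        missing_ages = [a for a in needed if a not in ps.mortality.baseline_q]
        if missing_ages:
            v.append(
                f"mortality.baseline_q: ages {missing_ages} not covered and "
                "age clamping is disabled"
            )

    for s in LIVING_STATES:
        if s not in ps.utilities.u:
            v.append(f"utilities.u: missing state {s.value}")
        elif not (-1.0 <= ps.utilities.u[s] <= 1.0):
            v.append(f"utilities.u.{s.value}: {ps.utilities.u[s]} outside [-1,1]")
    if all(s in ps.utilities.u for s in LIVING_STATES) and not ps.utilities.allow_unordered:
        vals = [ps.utilities.u[s] for s in LIVING_STATES]
        if any(a < b - 1e-12 for a, b in zip(vals, vals[1:])):
            v.append(
                "utilities.u: expected u(MRS01) ≥ u(MRS23) ≥ u(MRS4) ≥ u(MRS5) "
                "(set allow_unordered to override)"
            )

    for strat in Strategy:
        for field in ("acute_lvo", "diag_non_lvo"):
            mapping = getattr(ps.costs, field)
            if strat not in mapping:
                v.append(f"costs.{field}: missing strategy {strat.value}")
            elif mapping[strat] < 0:
                v.append(f"costs.{field}.{strat.value}: negative cost {mapping[strat]}")
    for s in LIVING_STATES:
        if s not in ps.costs.annual_care:
            v.append(f"costs.annual_care: missing state {s.value}")
        elif ps.costs.annual_care[s] < 0:
            v.append(f"costs.annual_care.{s.value}: negative cost")
    if ps.costs.eur_to_usd <= 0:
        v.append(f"costs.eur_to_usd: {ps.costs.eur_to_usd} must be > 0")

    if not (0.0 < ps.triage.p_lvo <= 1.0):
        v.append(f"triage.p_lvo: {ps.triage.p_lvo} outside (0,1]")

    for field in ("discount_cost", "discount_qaly"):
        r = getattr(ps.econ, field)
        if not (0.0 <= r < 1.0):
            v.append(f"econ.{field}: {r} outside [0,1)")
    if ps.econ.markov_years < 0:
        v.append(f"econ.markov_years: {ps.econ.markov_years} must be ≥ 0")
    if any(t <= 0 for t in ps.econ.thresholds):
        v.append("econ.thresholds: all willingness-to-pay values must be > 0")
    if ps.econ.cohort_size < 1:
        v.append("econ.cohort_size: must be ≥ 1")
    if ps.non_lvo.annual_cost < 0:
        v.append("non_lvo.annual_cost: negative")

    for path, (lo, hi) in ps.owsa_ranges.items():
        try:
            base = get_path(ps, path)
        except (KeyError, AttributeError, IndexError, TypeError):
            v.append(f"owsa_ranges: path '{path}' does not resolve")
            continue
        if not isinstance(base, (int, float)):
            v.append(f"owsa_ranges: path '{path}' is not a scalar")
        elif lo > hi:
            v.append(f"owsa_ranges['{path}']: low {lo} > high {hi}")

    for path, spec in ps.psa_spec.items():
        try:
            base = get_path(ps, path)
        except (KeyError, AttributeError, IndexError, TypeError):
            v.append(f"psa_spec: path '{path}' does not resolve")
            continue
        v.extend(_check_dist_spec(path, spec, base))

    return v


def _check_dist_spec(path: str, spec: DistributionSpec, base) -> List[str]:
    out: List[str] = []
    is_vector = isinstance(base, (dict, list))
    if spec.family == "fixed":
        return out
    if spec.family == "dirichlet":
        if not is_vector:
            out.append(f"psa_spec['{path}']: dirichlet requires a probability vector")
        elif spec.alphas is None:
            out.append(f"psa_spec['{path}']: dirichlet requires 'alphas'")
        else:
            n = len(base)
            if len(spec.alphas) != n:
                out.append(
                    f"psa_spec['{path}']: alphas length {len(spec.alphas)} != vector length {n}"
                )
            if any(a < 0 for a in spec.alphas) or sum(spec.alphas) <= 0:
                out.append(f"psa_spec['{path}']: alphas must be ≥ 0 with positive sum")
        return out
    if is_vector:
        out.append(f"psa_spec['{path}']: {spec.family} applies to scalars only")
        return out
    if spec.family == "beta":
        if spec.alpha is not None and spec.beta is not None:
            if spec.alpha <= 0 or spec.beta <= 0:
                out.append(f"psa_spec['{path}']: beta needs alpha, beta > 0")
        elif spec.mean is not None and spec.se is not None:
            if not (0 < spec.mean < 1) or spec.se <= 0:
                out.append(f"psa_spec['{path}']: beta mean must be in (0,1), se > 0")
            elif spec.se**2 >= spec.mean * (1 - spec.mean):
                out.append(f"psa_spec['{path}']: beta se too large for mean")
        else:
            out.append(f"psa_spec['{path}']: beta needs (alpha,beta) or (mean,se)")
    elif spec.family == "gamma":
        if spec.shape is not None and spec.scale is not None:
            if spec.shape <= 0 or spec.scale <= 0:
                out.append(f"psa_spec['{path}']: gamma needs shape, scale > 0")
        elif spec.mean is not None and spec.se is not None:
            if spec.mean <= 0 or spec.se <= 0:
                out.append(f"psa_spec['{path}']: gamma needs mean, se > 0")
        else:
            out.append(f"psa_spec['{path}']: gamma needs (shape,scale) or (mean,se)")
    return out


# ---------------------------------------------------------------------------
# Loading / writing / scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("base", "1", "2", "3")


def load_parameters(
    path: Union[str, Path], scenario: Optional[str] = None
) -> ParameterSet:
    """Load, validate and (optionally) apply a scenario to a parameter file.

    Scenario overrides: 1 → p_lvo = 0.42 (RACE>4 positive predictive value);
    2 → p_lvo = 0.12 (LVO incidence among all FAST-positive suspected
    strokes); 3 → 4 Markov years instead of 9.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParameterFormatError(
            f"{path}: not valid JSON (line {exc.lineno}, column {exc.colno}): {exc.msg}"
        ) from exc
    try:
        ps = ParameterSet.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ParameterFormatError(f"{path}: schema mismatch ({details})") from exc
    violations = validate_parameter_set(ps)
    if violations:
        raise ParameterValidationError(violations)
    if scenario is not None:
        ps = apply_scenario(ps, scenario)
    return ps


def write_parameters(ps: ParameterSet, path: Union[str, Path]) -> Path:
    """Serialize a ParameterSet to JSON; round-trips through :func:`load_parameters`."""
    path = Path(path)
    payload = ps.model_dump(mode="json")
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def apply_scenario(ps: ParameterSet, scenario: Union[str, int]) -> ParameterSet:
    """Return a copy with the scenario's documented overrides applied (idempotent)."""
    scenario = str(scenario)
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    out = ps.model_copy(deep=True)
    if scenario == "1":
        out.triage.p_lvo = 0.42
    elif scenario == "2":
        out.triage.p_lvo = 0.12
    elif scenario == "3":
        out.econ.markov_years = 4
    return out


def base_p_lvo_from_trial(n_suspected: int, n_confirmed: int) -> float:
    """LVO confirmation rate from trial counts (base-case p_lvo).

    The source trial enrolled 174 suspected-LVO patients of whom 147 had a
    confirmed occlusion, giving p_lvo = 147/174 ≈ 0.845.
    """
    if n_suspected <= 0:
        raise ValueError("n_suspected must be > 0")
    if not (0 < n_confirmed <= n_suspected):
        raise ValueError("need 0 < n_confirmed ≤ n_suspected")
    return n_confirmed / n_suspected


# ---------------------------------------------------------------------------
# Parameter paths (used by sensitivity analyses)
# ---------------------------------------------------------------------------


def _key_for(container: dict, part: str):
    if part in container:
        return part
    for caster in (HealthState, Strategy):
        try:
            key = caster(part)
        except ValueError:
            continue
        if key in container:
            return key
    try:
        key = int(part)
    except ValueError:
        raise KeyError(part)
    if key in container:
        return key
    raise KeyError(part)


def _walk(ps: ParameterSet, parts: List[str]):
    """Yield (parent, key) pairs along a dotted path; parent[key]/getattr resolves."""
    node = ps
    for part in parts[:-1]:
        node = _get_child(node, part)
    return node, parts[-1]


def _get_child(node, part: str):
    if isinstance(node, BaseModel):
        return getattr(node, part)
    if isinstance(node, dict):
        return node[_key_for(node, part)]
    if isinstance(node, (list, tuple)):
        return node[int(part)]
    raise TypeError(f"cannot descend into {type(node).__name__} with {part!r}")


def get_path(ps: ParameterSet, path: str):
    """Resolve a dotted parameter path, e.g. ``costs.annual_care.MRS4``."""
    parent, last = _walk(ps, path.split("."))
    return _get_child(parent, last)


def set_path(ps: ParameterSet, path: str, value) -> ParameterSet:
    """Return a deep copy of ``ps`` with the parameter at ``path`` replaced."""
    out = ps.model_copy(deep=True)
    parent, last = _walk(out, path.split("."))
    if isinstance(parent, BaseModel):
        setattr(parent, last, copy.deepcopy(value))
    elif isinstance(parent, dict):
        parent[_key_for(parent, last)] = copy.deepcopy(value)
    elif isinstance(parent, list):
        parent[int(last)] = copy.deepcopy(value)
    else:
        raise TypeError(f"cannot set into {type(parent).__name__}")
    return out


def renormalize_component(
    mapping: Dict[HealthState, float], state: HealthState, new_value: float
) -> Dict[HealthState, float]:
    """Set one component of a probability vector, rescaling the others onto the simplex.

    All remaining components are multiplied by ``(1 − p′)/(1 − p)`` so the
    vector still sums to one; the rule is the same whether a living state or
    DEAD is varied.
    """
    old = float(mapping[state])
    if not (0.0 <= new_value <= 1.0):
        raise ValueError(f"new probability {new_value} outside [0,1]")
    if math.isclose(old, 1.0):
        if math.isclose(new_value, 1.0):
            return dict(mapping)
        raise ValueError("cannot rescale: varied component carries all the mass")
    scale = (1.0 - new_value) / (1.0 - old)
    out = {s: float(p) * scale for s, p in mapping.items()}
    out[state] = float(new_value)
    return out


def paper_like_fixture_path() -> Path:
    """Path of the packaged example parameter file (see its ``notes`` for provenance)."""
    return Path(__file__).parent / "fixtures" / "params_paperlike.json"
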