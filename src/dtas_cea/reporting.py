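"""Tabular and graphical reporting: results tables, tornado, CE plane, CEAC.

Presentation conventions: monetary cells are rounded to the nearest whole
currency unit and QALYs to two decimals; computation always happens
upstream at full precision. All monetary quantities are stored in EUR and
converted to USD at the fixed rate only here.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .cea import CEAResult
from .markov import StrategyResult
from .parameters import STATE_ORDER, ParameterSet, Strategy
from .uncertainty import CEACCurve, PSASample, ScenarioResult, TornadoEntry

__all__ = [
    "RunManifest",
    "make_manifest",
    "params_digest",
    "report_table2",
    "format_table",
    "trace_to_frame",
    "tornado_to_frame",
    "psa_to_frame",
    "ceac_to_frame",
    "plot_tornado",
    "plot_ce_plane",
    "plot_ceac",
]


def params_digest(ps: ParameterSet) -> str:
    payload = json.dumps(ps.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one run byte-for-byte."""

    timestamp: str
    version: str
    params_digest: str
    scenario: str
    seed: Optional[int]
    options: Dict[str, object]

    def to_dict(self) -> Dict[str, object]:
        return asdict(self)


def make_manifest(
    ps: ParameterSet, scenario: str = "base", seed: Optional[int] = None
) -> RunManifest:
    return RunManifest(
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        version=__version__,
        params_digest=params_digest(ps),
        scenario=str(scenario),
        seed=seed,
        options=ps.options.model_dump(),
    )


def _money(value: float, rate: float, currency: str) -> float:
    return round(value * (rate if currency == "USD" else 1.0))


def report_table2(
    scenario_results: Union[Sequence[ScenarioResult], Dict[str, ScenarioResult]],
    currency: str = "USD",
) -> pd.DataFrame:
    """Per-patient cost-effectiveness results, one block per scenario.

    Columns: strategy totals, increments, and the ICER (or a dominance
    label), in the requested currency.
    """
    if isinstance(scenario_results, dict):
        scenario_results = list(scenario_results.values())
    scenario_results = list(scenario_results)
    if not scenario_results:
        raise ValueError(
            "no scenario results to report — run at least the base scenario "
            "(e.g. run_scenario('base', params))"
        )
    if currency not in ("EUR", "USD"):
        raise ValueError("currency must be EUR or USD")
    rows: List[dict] = []
    for sr in scenario_results:
        rate = sr.params.costs.eur_to_usd
        res: CEAResult = sr.cea
        for st in (Strategy.DTAS, Strategy.ITER):
            r = sr.results[st]
            rows.append(
                {
                    "scenario": sr.scenario,
                    "strategy": st.value,
                    f"total_cost_{currency.lower()}": _money(r.total_cost, rate, currency),
                    "total_qaly": round(r.total_qaly, 2),
                    f"delta_cost_{currency.lower()}": (
                        _money(res.delta_cost, rate, currency) if st is res.intervention else ""
                    ),
                    "delta_qaly": (
                        round(res.delta_qaly, 2) if st is res.intervention else ""
                    ),
                    f"icer_{currency.lower()}_per_qaly": (
                        (
                            _money(res.icer, rate, currency)
                            if isinstance(res.icer, float)
                            else res.icer
                        )
                        if st is res.intervention
                        else ""
                    ),
                }
            )
    return pd.DataFrame(rows)


def format_table(df: pd.DataFrame) -> str:
    return df.to_string(index=False)


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------


def trace_to_frame(result: StrategyResult) -> pd.DataFrame:
    """Long-format cohort trace: cycle, age, state, occupancy."""
    records = []
    for k, row in enumerate(result.trace.occupancy):
        for s, occ in zip(STATE_ORDER, row):
            records.append(
                {
                    "strategy": result.strategy.value,
                    "cycle": k,
                    "age": int(result.trace.age_at_cycle[k]),
                    "state": s.value,
                    "occupancy": float(occ),
                }
            )
    return pd.DataFrame(records)


def tornado_to_frame(entries: Iterable[TornadoEntry], rate: float = 1.1827) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter_path,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "icer_at_low_eur": e.icer_at_low,
                "icer_at_high_eur": e.icer_at_high,
                "icer_at_low_usd": e.icer_at_low * rate,
                "icer_at_high_usd": e.icer_at_high * rate,
                "spread_eur": e.spread,
            }
            for e in entries
        ]
    )


def psa_to_frame(samples: Iterable[PSASample], rate: float = 1.1827) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "draw": s.index,
                "digest": s.digest,
                "delta_cost_eur": s.delta_cost,
                "delta_qaly": s.delta_qaly,
                "delta_cost_usd": s.delta_cost * rate,
            }
            for s in samples
        ]
    )


def ceac_to_frame(curve: CEACCurve, rate: float = 1.1827) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold_eur": curve.thresholds,
            "threshold_usd": curve.thresholds * rate,
            **{f"p_ce_{st.value}": curve.p_ce[st] for st in curve.p_ce},
        }
    )


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------


def plot_tornado(entries: Sequence[TornadoEntry], path, rate: float = 1.1827):
    entries = sorted(entries, key=lambda e: e.spread)  # widest at the top
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(entries) + 2))
    base = None
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low * rate, e.icer_at_high * rate))
        ax.barh(i, hi - lo, left=lo, color="#4878CF", alpha=0.8)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter_path for e in entries])
    ax.set_xlabel("ICER ($/QALY)")
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_ce_plane(
    samples: Sequence[PSASample], path, rate: float = 1.1827, thresholds=(50_000.0, 80_000.0)
):
    de = np.array([s.delta_qaly for s in samples])
    dc = np.array([s.delta_cost for s in samples]) * rate
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(de, dc, s=4, alpha=0.25, color="#4878CF")
    lim = max(1e-9, np.abs(de).max() * 1.1)
    xs = np.linspace(-lim, lim, 3)
    for lam in thresholds:
        ax.plot(xs, xs * lam * rate, lw=1, ls="--", color="grey")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_ceac(curve: CEACCurve, path, rate: float = 1.1827):
    fig, ax = plt.subplots(figsize=(7, 5))
    for st, p in curve.p_ce.items():
        ax.plot(curve.thresholds * rate, p, label=st.value)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    ax.set_title("Cost-effectiveness acceptability curves")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
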