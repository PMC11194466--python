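"""One-way (tornado), probabilistic, and surveillance-interval sensitivity
analyses.

One-way analysis moves a single parameter to its range limits — or, when no
range is available, to ±20% for costs and ±10% for probabilities and
utilities — with everything else at baseline, and records the comparison
outcome at each limit.  The headline comparison is berberine-plus-colonoscopy
vs colonoscopy alone, summarized as incremental net monetary benefit at
$100,000/QALY.

The probabilistic sensitivity analysis redraws every non-fixed parameter from
its moment-matched distribution and re-evaluates all four strategies per
draw.  The inner evaluation defaults to the deterministic cohort evaluator,
so the PSA propagates parameter (second-order) uncertainty only; a
microsimulation inner loop is available for validation at small n.

Scenario analysis re-runs the strategy comparison with alternative
surveillance intervals (e.g. 1-year recall after a high-risk finding, or
10-year recall after a negative exam) under common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import cohort_evaluate, run_cohort
from .interventions import Strategy, standard_strategies
from .parameters import ParameterSet, sample_parameter_set

__all__ = ["TornadoEntry", "ScenarioSpec", "one_way", "tornado",
           "PSAResult", "run_psa", "run_scenarios", "DEFAULT_WTP"]

DEFAULT_WTP = 100_000.0


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low: float
    high: float
    outcome_at_low: dict
    outcome_at_high: dict
    metric: str = "incremental_nmb"

    @property
    def width(self) -> float:
        return abs(self.outcome_at_high[self.metric]
                   - self.outcome_at_low[self.metric])


@dataclass(frozen=True)
class ScenarioSpec:
    """Surveillance-interval override for a scenario run."""

    name: str
    interval_high_grade: int = 3
    interval_low_or_none: int = 5

    def __post_init__(self):
        if self.interval_high_grade < 1 or self.interval_low_or_none < 1:
            raise ValueError("intervals must be >= 1 year")


def _default_range(spec) -> tuple[float, float]:
    """±20% for costs, ±10% for probabilities/utilities when no range exists."""
    rel = 0.20 if spec.units == "usd" else 0.10
    lo, hi = spec.base * (1 - rel), spec.base * (1 + rel)
    if spec.units in ("probability", "utility"):
        hi = min(hi, 1.0)
    return lo, hi


def _evaluate_pair(comparison, params, life, method, n, seed, wtp):
    a, b = comparison
    if method == "cohort":
        cost_a, qaly_a = cohort_evaluate(a, params, life)
        cost_b, qaly_b = cohort_evaluate(b, params, life)
    elif method == "microsim":
        ra = run_cohort(a, params, life, n=n, seed=seed)
        rb = run_cohort(b, params, life, n=n, seed=seed)
        cost_a, qaly_a = ra.mean_cost, ra.mean_qaly
        cost_b, qaly_b = rb.mean_cost, rb.mean_qaly
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "cost_a": cost_a, "qaly_a": qaly_a, "cost_b": cost_b, "qaly_b": qaly_b,
        "incremental_cost": cost_b - cost_a,
        "incremental_qaly": qaly_b - qaly_a,
        "incremental_nmb": wtp * (qaly_b - qaly_a) - (cost_b - cost_a),
    }


def one_way(param_name: str, comparison: tuple[Strategy, Strategy],
            params: ParameterSet, life, method: str = "cohort",
            n: int = 100_000, seed: int = 0,
            wtp: float = DEFAULT_WTP) -> TornadoEntry:
    """Evaluate the comparison outcome with one parameter at its low and high
    limits (all else at baseline).  The microsimulation method reuses the same
    seed at both limits (common random numbers)."""
    if param_name not in params:
        raise KeyError(f"unknown parameter {param_name!r}")
    spec = params.spec(param_name)
    if spec.low is not None and spec.high is not None and spec.low < spec.high:
        lo, hi = spec.low, spec.high
    else:
        lo, hi = _default_range(spec)
    out_lo = _evaluate_pair(comparison, params.with_values(**{param_name: lo}),
                            life, method, n, seed, wtp)
    out_hi = _evaluate_pair(comparison, params.with_values(**{param_name: hi}),
                            life, method, n, seed, wtp)
    return TornadoEntry(param_name, lo, hi, out_lo, out_hi)


def tornado(comparison: tuple[Strategy, Strategy], params: ParameterSet, life,
            parameters: list[str] | None = None, method: str = "cohort",
            n: int = 100_000, seed: int = 0,
            wtp: float = DEFAULT_WTP) -> list[TornadoEntry]:
    """One-way analysis over every non-fixed parameter (or a given subset),
    sorted by descending bar width; ties break lexicographically by name."""
    if parameters is None:
        parameters = [p for p in params.names() if not params.spec(p).is_fixed]
    entries = [one_way(p, comparison, params, life, method=method, n=n,
                       seed=seed, wtp=wtp) for p in parameters]
    return sorted(entries, key=lambda e: (-e.width, e.parameter))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append({
            "parameter": e.parameter, "low": e.low, "high": e.high,
            "nmb_at_low": e.outcome_at_low["incremental_nmb"],
            "nmb_at_high": e.outcome_at_high["incremental_nmb"],
            "incremental_cost_at_low": e.outcome_at_low["incremental_cost"],
            "incremental_cost_at_high": e.outcome_at_high["incremental_cost"],
            "incremental_qaly_at_low": e.outcome_at_low["incremental_qaly"],
            "incremental_qaly_at_high": e.outcome_at_high["incremental_qaly"],
            "width": e.width,
        })
    return pd.DataFrame(rows)


@dataclass
class PSAResult:
    """Per-draw strategy outcomes of the probabilistic sensitivity analysis."""

    names: list[str]
    costs: np.ndarray   # (n_samples, n_strategies)
    qalys: np.ndarray   # (n_samples, n_strategies)
    parameter_draws: pd.DataFrame

    def frame(self) -> pd.DataFrame:
        df = {}
        for j, name in enumerate(self.names):
            df[f"cost_{name}"] = self.costs[:, j]
            df[f"qaly_{name}"] = self.qalys[:, j]
        return pd.DataFrame(df)


def run_psa(params: ParameterSet, life, n_samples: int, seed: int = 0,
            inner: str = "cohort", n_micro: int = 10_000,
            strategies: list[Strategy] | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Each draw samples a full parameter set and evaluates every strategy.
    ``inner='cohort'`` (default) uses the deterministic cohort evaluator, so
    each draw is exact given its parameters; ``inner='microsim'`` nests a
    common-random-number microsimulation of ``n_micro`` patients per draw.
    """
    if n_samples < 1:
        raise ValueError("need at least one PSA sample")
    if strategies is None:
        strategies = standard_strategies()
    names = [s.name for s in strategies]
    costs = np.empty((n_samples, len(strategies)))
    qalys = np.empty((n_samples, len(strategies)))
    draw_rows = []
    root = np.random.SeedSequence([int(seed), 11])
    children = root.spawn(n_samples)
    for i, child in enumerate(children):
        drawn = sample_parameter_set(params, child)
        draw_rows.append(drawn.values())
        for j, strat in enumerate(strategies):
            if inner == "cohort":
                c, q = cohort_evaluate(strat, drawn, life)
            elif inner == "microsim":
                res = run_cohort(strat, drawn, life, n=n_micro, seed=seed + i)
                c, q = res.mean_cost, res.mean_qaly
            else:
                raise ValueError(f"unknown inner evaluator {inner!r}")
            costs[i, j], qalys[i, j] = c, q
    return PSAResult(names, costs, qalys, pd.DataFrame(draw_rows))


def run_scenarios(specs: list[ScenarioSpec], params: ParameterSet, life,
                  n: int = 100_000, seed: int = 0,
                  method: str = "microsim") -> pd.DataFrame:
    """Run the four-strategy comparison under each surveillance-interval
    scenario; microsimulation scenarios share the master seed (common random
    numbers) so differences reflect the interval rules only."""
    rows = []
    for spec in specs:
        strategies = standard_strategies(
            interval_high_grade=spec.interval_high_grade,
            interval_low_or_none=spec.interval_low_or_none,
        )
        for strat in strategies:
            if method == "microsim":
                res = run_cohort(strat, params, life, n=n, seed=seed)
                row = {"scenario": spec.name, "strategy": strat.name,
                       "interval_high_grade": spec.interval_high_grade,
                       "interval_low_or_none": spec.interval_low_or_none,
                       "mean_cost": res.mean_cost, "mean_qaly": res.mean_qaly,
                       "se_cost": res.se_cost, "se_qaly": res.se_qaly}
                row.update({f"tally_{k}": v for k, v in res.tallies.items()})
            elif method == "cohort":
                c, q = cohort_evaluate(strat, params, life)
                row = {"scenario": spec.name, "strategy": strat.name,
                       "interval_high_grade": spec.interval_high_grade,
                       "interval_low_or_none": spec.interval_low_or_none,
                       "mean_cost": c, "mean_qaly": q}
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(row)
    return pd.DataFrame(rows)
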