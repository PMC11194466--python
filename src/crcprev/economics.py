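"""Incremental cost-effectiveness analysis.

Given each strategy's mean discounted cost and QALY, this module computes
pairwise incremental cost-effectiveness ratios (ICERs) with dominance labels,
the efficient frontier with extended dominance removed, net monetary benefit
(NMB = wtp * QALY - cost), and cost-effectiveness acceptability curves (CEAC):
the fraction of probabilistic-sensitivity-analysis samples in which each
strategy has the highest NMB, as a function of the willingness-to-pay
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["icer", "cea_table", "frontier", "nmb", "ceac",
           "DOMINATES", "DOMINATED", "TIE"]

DOMINATES = "dominates"
DOMINATED = "dominated"
TIE = "tie"
EXTENDED_DOMINATED = "extended-dominated"

_QALY_TOL = 1e-12


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float):
    """ICER of strategy B relative to comparator A, or a dominance label.

    Returns the ratio (cost_b - cost_a) / (qaly_b - qaly_a) when B trades cost
    against effect in the same direction; 'dominates' when B is cheaper and
    more effective, 'dominated' in the mirror case, and 'tie' when both
    increments are (numerically) zero.  Equal QALYs with unequal costs yield a
    label rather than a division.
    """
    d_cost = cost_b - cost_a
    d_qaly = qaly_b - qaly_a
    if abs(d_qaly) <= _QALY_TOL:
        if abs(d_cost) <= _QALY_TOL:
            return TIE
        return DOMINATES if d_cost < 0 else DOMINATED
    if d_qaly > 0 and d_cost <= 0:
        return DOMINATES
    if d_qaly < 0 and d_cost >= 0:
        return DOMINATED
    return d_cost / d_qaly


def cea_table(results: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Pairwise incremental analysis in reading order.

    ``results`` maps strategy name -> (mean cost, mean QALY); insertion order
    defines the comparator ordering.  Each strategy row lists its totals, the
    increments vs the previous strategy, and the ICER-or-label against every
    earlier strategy.
    """
    names = list(results)
    rows = []
    for i, name in enumerate(names):
        c, q = results[name]
        row = {"strategy": name, "cost": c, "qaly": q}
        if i > 0:
            c0, q0 = results[names[i - 1]]
            row["incremental_cost"] = c - c0
            row["incremental_qaly"] = q - q0
        for j in range(i):
            cj, qj = results[names[j]]
            row[f"icer_vs_{names[j]}"] = icer(cj, qj, c, q)
        rows.append(row)
    return pd.DataFrame(rows)


def frontier(strategies: list[tuple[str, float, float]]) -> list[str]:
    """Efficient frontier of (name, cost, qaly) points.

    Sorts by effectiveness, drops strongly dominated points, then iteratively
    removes extended-dominated points until the frontier's sequential ICERs
    are non-decreasing.  Returns the surviving names in increasing-QALY order.
    """
    if not strategies:
        raise ValueError("need at least one strategy")
    pts = sorted(strategies, key=lambda s: (s[2], -s[1]))
    # strong dominance: cheaper-or-equal and more effective point exists
    keep = []
    for i, (n, c, q) in enumerate(pts):
        dominated = any(
            (cj <= c and qj >= q) and (cj < c or qj > q)
            for (nj, cj, qj) in pts if nj != n
        )
        if not dominated:
            keep.append((n, c, q))
    # extended dominance: sequential ICERs must be non-decreasing
    changed = True
    while changed and len(keep) > 2:
        changed = False
        for i in range(1, len(keep) - 1):
            _, c0, q0 = keep[i - 1]
            _, c1, q1 = keep[i]
            _, c2, q2 = keep[i + 1]
            icer_low = (c1 - c0) / (q1 - q0)
            icer_high = (c2 - c1) / (q2 - q1)
            if icer_low > icer_high:
                del keep[i]
                changed = True
                break
    return [n for n, _, _ in keep]


def nmb(cost, qaly, wtp: float):
    """Net monetary benefit at a willingness-to-pay threshold ($/QALY)."""
    return wtp * np.asarray(qaly) - np.asarray(cost)


def ceac(costs: np.ndarray, qalys: np.ndarray, names: list[str],
         wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    ``costs`` and ``qalys`` are (n_samples, n_strategies) arrays of PSA
    outcomes.  At each threshold the winner of a sample is the strategy with
    the highest NMB; ties break toward the cheaper strategy (then by column
    order).  Returns a DataFrame indexed by threshold with one probability
    column per strategy; rows sum to one.
    """
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    if costs.ndim != 2 or costs.shape != qalys.shape:
        raise ValueError("costs and qalys must be matching 2-D arrays")
    if costs.shape[0] == 0:
        raise ValueError("need at least one PSA sample")
    if costs.shape[1] != len(names):
        raise ValueError("names must match the strategy axis")
    if wtp_grid is None:
        wtp_grid = np.arange(0, 200_001, 1000)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if np.any(wtp_grid < 0):
        raise ValueError("willingness-to-pay must be non-negative")

    n, s = costs.shape
    probs = np.empty((len(wtp_grid), s))
    # lexicographic tie-break: highest NMB, then lowest cost, then column order
    cost_rank = np.argsort(costs, axis=1, kind="stable")
    tie_key = np.empty_like(costs)
    rows = np.arange(n)[:, None]
    tie_key[rows, cost_rank] = np.arange(s)[None, :]
    for i, wtp in enumerate(wtp_grid):
        benefit = wtp * qalys - costs
        best = benefit.max(axis=1, keepdims=True)
        contenders = benefit >= best - 1e-9
        key = np.where(contenders, tie_key, np.inf)
        winner = key.argmin(axis=1)
        probs[i] = np.bincount(winner, minlength=s) / n
    return pd.DataFrame(probs, index=pd.Index(wtp_grid, name="wtp"),
                        columns=names)
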