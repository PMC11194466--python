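"""Annual-cycle simulation engines with discounted cost/QALY accounting.

Two engines share one cycle model:

* :func:`run_cohort` — a vectorized Markov *microsimulation*: each of ``n``
  patients is walked from age 50 (normal mucosa after polypectomy) to death or
  age 100 with per-patient Bernoulli draws.  Random numbers are drawn from
  per-cycle, per-decision channels keyed only by the master seed, so the same
  uniforms are replayed for every strategy (common random numbers), which
  removes sampling noise from strategy comparisons.

* :func:`cohort_evaluate` — a deterministic *cohort evaluator*: forward
  propagation of the occupancy distribution over the expanded state space
  (health state x berberine-adherence stratum x years-to-next-colonoscopy).
  It computes the exact expected discounted cost and QALY of the identical
  cycle model and serves as the microsimulation's internal oracle.

Cycle event order (see :mod:`crcprev.natural_history`): other-cause death,
scheduled colonoscopy, symptomatic presentation, cancer death, progression/
recurrence, accrual.  Accounting: costs and utilities are discounted at 3%/yr
from model entry at age 50; event costs (procedures, complications, cancer
initial/death costs) accrue when the event happens, annual amounts (state
utility, drug cost, cancer continuing cost) accrue to patients alive at the
end of the cycle.  No half-cycle correction is applied.  The payer block
switches with attained age: commercial under 65, Medicare at 65 and over.
The cost sources print no distant-stage continuing-yearly rate; distant
diagnosed patients accrue the regional continuing rate as a proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interventions import INTERVENTION_END_AGE, Strategy
from .life_tables import AGE_MIN, LifeTable
from .natural_history import HealthState

__all__ = ["AccrualLedger", "CohortResult", "discount", "accrue_cycle",
           "simulate_patient", "run_cohort", "run_strategies",
           "cohort_evaluate"]

# Health-state codes (aligned with HealthState)
SP, LRA, HRA = 0, 1, 2
LOC_PRE, REG_PRE, DIST_PRE = 3, 4, 5
LOC_DX, REG_DX, DIST_DX = 6, 7, 8
D_CRC, D_OTHER, D_COMP = 9, 10, 11

NO_SURVEILLANCE = 127  # due-counter sentinel: no colonoscopy scheduled

# random-number channels (per cycle, strategy-independent => CRN)
(CH_OTHER, CH_ATTEND, CH_DETECT, CH_PERF, CH_PERF_DEATH, CH_BLEED,
 CH_BLEED_DEATH, CH_PRESENT, CH_CRC_DEATH, CH_PROGRESS) = range(10)
_ADHERENCE_KEY = 3
_CYCLE_KEY = 7


def _channel_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


def discount(amount: float, years_since_entry: int, rate: float) -> float:
    """Present value at model entry of an amount accrued ``years`` later."""
    if years_since_entry < 0:
        raise ValueError("years since entry must be non-negative")
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return amount / (1.0 + rate) ** years_since_entry


@dataclass
class AccrualLedger:
    """One patient's discounted totals, with an optional per-cycle trace."""

    discounted_cost: float
    discounted_qaly: float
    trace: list = field(default_factory=list)


@dataclass
class CohortResult:
    """Per-strategy aggregate of n simulated patients."""

    strategy: str
    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    tallies: dict


class _ModelInputs:
    """Parameter values unpacked into plain scalars/arrays for the hot loop."""

    def __init__(self, params, life: LifeTable):
        self.q = life.q
        self.dr = params.discount_rate
        self.p_hra = {"berberine": params.sp_to_hra_berberine,
                      "placebo": params.sp_to_hra_placebo}
        self.p_lra = {"berberine": params.sp_to_lra_berberine,
                      "placebo": params.sp_to_lra_placebo}
        self.lra_to_hra = params.lra_to_hra_placebo
        self.hra_to_crc = params.hra_to_crc_placebo
        self.loc_to_reg = params.local_to_regional
        self.reg_to_dist = params.regional_to_distant
        self.present = np.array([params.present_local, params.present_regional,
                                 params.present_distant])
        self.mort = np.array([params.mort_crc_local, params.mort_crc_regional,
                              params.mort_crc_distant])
        self.mort_new = 1.0 - (1.0 - self.mort) * (1.0 - params.mort_cancer_treatment)
        self.lra_rm = params.lra_removal
        self.hra_rm = params.hra_removal
        self.sens = params.colonoscopy_sensitivity_crc
        self.c_colo = params.compliance_colonoscopy
        self.c_berb = params.compliance_berberine
        self.p_perf = params.perforation_risk
        self.p_bleed = params.bleeding_risk
        self.m_perf = params.mort_perforation
        self.m_bleed = params.mort_bleeding
        self.cost_berb = params.cost_berberine_annual
        self.disutil = params.disutility_colonoscopy
        self.util = np.array([params.utility_non_crc] * 6
                             + [params.utility_crc_local,
                                params.utility_crc_regional,
                                params.utility_crc_distant]
                             + [0.0, 0.0, 0.0])
        self._by_payer = {}
        for payer in ("commercial", "medicare"):
            g = lambda k: params[f"{k}_{payer}"]
            self._by_payer[payer] = {
                "colo": g("cost_colonoscopy"),
                "polyp": g("cost_colonoscopy_polypectomy"),
                "perf": g("cost_perforation"),
                "bleed": g("cost_bleeding"),
                "initial": np.array([g("cost_crc_local_initial"),
                                     g("cost_crc_regional_initial"),
                                     g("cost_crc_distant_initial")]),
                # no distant continuing rate is available; regional is the proxy
                "cont": np.array([g("cost_crc_local_continuing"),
                                  g("cost_crc_regional_continuing"),
                                  g("cost_crc_regional_continuing")]),
                "death": np.array([g("cost_crc_local_death"),
                                   g("cost_crc_regional_death"),
                                   g("cost_crc_distant_death")]),
            }

    def costs(self, age: int) -> dict:
        return self._by_payer["commercial" if age < 65 else "medicare"]


def accrue_cycle(health: HealthState, age: int, params, *,
                 colonoscopy_cost: float = 0.0, attended: bool = False,
                 newly_diagnosed: bool = False, crc_death: bool = False,
                 berberine_exposed: bool = False) -> tuple[float, float]:
    """Undiscounted cost and utility accrued for one cycle, given the cycle's
    events — the single-patient mirror of the engines' accounting rules."""
    cost = colonoscopy_cost
    utility = 0.0
    payer = "commercial" if age < 65 else "medicare"
    g = lambda k: params[f"{k}_{payer}"]
    if health.is_diagnosed_crc:
        stage = health.stage
        if newly_diagnosed:
            cost += [g("cost_crc_local_initial"), g("cost_crc_regional_initial"),
                     g("cost_crc_distant_initial")][stage]
        if crc_death:
            cost += [g("cost_crc_local_death"), g("cost_crc_regional_death"),
                     g("cost_crc_distant_death")][stage]
        elif not newly_diagnosed:
            cost += [g("cost_crc_local_continuing"),
                     g("cost_crc_regional_continuing"),
                     g("cost_crc_regional_continuing")][stage]
    if berberine_exposed:
        cost += params.cost_berberine_annual
    if not crc_death and not health.is_death:
        if health.is_diagnosed_crc:
            utility = [params.utility_crc_local, params.utility_crc_regional,
                       params.utility_crc_distant][health.stage]
        else:
            utility = params.utility_non_crc
        if attended:
            utility -= params.disutility_colonoscopy
    return cost, utility


def run_cohort(strategy: Strategy, params, life: LifeTable, n: int = 100_000,
               seed: int = 0, trace: bool = False) -> CohortResult:
    """Microsimulate ``n`` patients under one strategy.

    Reproducible bit-for-bit for a given ``seed``; the random streams do not
    depend on the strategy, so calling this with each strategy at the same
    seed yields common-random-number comparisons.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mi = _ModelInputs(params, life)
    dr = mi.dr

    health = np.zeros(n, dtype=np.int8)
    due = np.full(n, strategy.first_surveillance_offset if strategy.use_colonoscopy
                  else NO_SURVEILLANCE, dtype=np.int16)
    adherent = _channel_rng(seed, _ADHERENCE_KEY).random(n) < mi.c_berb
    alive = np.ones(n, dtype=bool)
    cost = np.zeros(n)
    qaly = np.zeros(n)

    tallies = {k: 0 for k in
               ("colonoscopies", "polypectomies", "perforations", "bleeds",
                "complication_deaths", "crc_cases_local", "crc_cases_regional",
                "crc_cases_distant", "crc_deaths", "other_deaths")}
    traces = []

    for age in range(AGE_MIN, 100):
        t = age - AGE_MIN
        disc = (1.0 + dr) ** -t
        C = mi.costs(age)
        u = lambda ch: _channel_rng(seed, _CYCLE_KEY, t, ch).random(n)
        ccost = np.zeros(n)

        # 1. other-cause death
        die_o = alive & (u(CH_OTHER) < mi.q[t])
        health[die_o] = D_OTHER
        alive &= ~die_o
        tallies["other_deaths"] += int(die_o.sum())

        start_dx = np.where(alive & (health >= LOC_DX) & (health <= DIST_DX),
                            health, -1)
        new_dx = np.zeros(n, dtype=bool)
        attended = np.zeros(n, dtype=bool)

        # 2. scheduled surveillance colonoscopy
        if strategy.use_colonoscopy and age < INTERVENTION_END_AGE:
            due_now = alive & (due == 0) & (health <= DIST_PRE)
            attended = due_now & (u(CH_ATTEND) < mi.c_colo)
            udet = u(CH_DETECT)
            removed = attended & (((health == LRA) & (udet < mi.lra_rm))
                                  | ((health == HRA) & (udet < mi.hra_rm)))
            found_high = removed & (health == HRA)
            detected = attended & (health >= LOC_PRE) & (health <= DIST_PRE) \
                & (udet < mi.sens)
            ccost[attended] += C["colo"]
            ccost[removed] += C["polyp"] - C["colo"]
            perf = attended & (u(CH_PERF) < mi.p_perf)
            bleed = attended & (u(CH_BLEED) < mi.p_bleed)
            ccost[perf] += C["perf"]
            ccost[bleed] += C["bleed"]
            comp_death = (perf & (u(CH_PERF_DEATH) < mi.m_perf)) \
                | (bleed & (u(CH_BLEED_DEATH) < mi.m_bleed))

            stage_det = health[detected] - LOC_PRE
            ccost[detected] += C["initial"][stage_det]
            health[detected] += 3  # *_PRE -> *_DX
            new_dx |= detected
            due[detected] = NO_SURVEILLANCE
            sched = attended & ~detected
            due[sched] = np.where(found_high[sched],
                                  strategy.interval_high_grade,
                                  strategy.interval_low_or_none)
            health[removed] = SP

            health[comp_death] = D_COMP
            alive &= ~comp_death
            tallies["colonoscopies"] += int(attended.sum())
            tallies["polypectomies"] += int(removed.sum())
            tallies["perforations"] += int(perf.sum())
            tallies["bleeds"] += int(bleed.sum())
            tallies["complication_deaths"] += int(comp_death.sum())
            for k, s in (("crc_cases_local", LOC_PRE),
                         ("crc_cases_regional", REG_PRE),
                         ("crc_cases_distant", DIST_PRE)):
                tallies[k] += int((detected & (health == s + 3)).sum())

        # 3. symptomatic presentation of preclinical cancer
        pre = alive & (health >= LOC_PRE) & (health <= DIST_PRE)
        stage_pre = np.where(pre, health - LOC_PRE, 0)
        present = pre & (u(CH_PRESENT) < mi.present[stage_pre])
        ccost[present] += C["initial"][health[present] - LOC_PRE]
        health[present] += 3
        new_dx |= present
        due[present] = NO_SURVEILLANCE
        for k, s in (("crc_cases_local", LOC_DX), ("crc_cases_regional", REG_DX),
                     ("crc_cases_distant", DIST_DX)):
            tallies[k] += int((present & (health == s)).sum())

        # 4. cancer death in diagnosed states
        dx = alive & (health >= LOC_DX) & (health <= DIST_DX)
        stage_dx = np.where(dx, health - LOC_DX, 0)
        p_die = np.where(new_dx, mi.mort_new[stage_dx], mi.mort[stage_dx])
        die_c = dx & (u(CH_CRC_DEATH) < p_die)
        ccost[die_c] += C["death"][health[die_c] - LOC_DX]
        health[die_c] = D_CRC
        alive &= ~die_c
        tallies["crc_deaths"] += int(die_c.sum())

        # 5. progression / recurrence (single draw against the snapshot state)
        up = u(CH_PROGRESS)
        h0 = health.copy()
        berb_on = strategy.use_berberine and age < INTERVENTION_END_AGE
        grp_b = adherent & berb_on
        p_hra = np.where(grp_b, mi.p_hra["berberine"], mi.p_hra["placebo"])
        p_lra = np.where(grp_b, mi.p_lra["berberine"], mi.p_lra["placebo"])
        sp = alive & (h0 == SP)
        health[sp & (up < p_hra)] = HRA
        health[sp & (up >= p_hra) & (up < p_hra + p_lra)] = LRA
        health[alive & (h0 == LRA) & (up < mi.lra_to_hra)] = HRA
        health[alive & (h0 == HRA) & (up < mi.hra_to_crc)] = LOC_PRE
        health[alive & (h0 == LOC_PRE) & (up < mi.loc_to_reg)] = REG_PRE
        health[alive & (h0 == REG_PRE) & (up < mi.reg_to_dist)] = DIST_PRE

        # 6. accrual
        util = mi.util[health]
        util = np.where(attended, util - mi.disutil, util)
        qaly[alive] += disc * util[alive]
        if berb_on:
            ccost[alive & adherent] += mi.cost_berb
        cont = alive & (start_dx >= 0)
        ccost[cont] += C["cont"][start_dx[cont] - LOC_DX]
        cost += disc * ccost

        step = (due > 0) & (due != NO_SURVEILLANCE)
        due[step] -= 1

        if trace:
            traces.append({"age": age, "health": health.copy(),
                           "cycle_cost": disc * ccost,
                           "alive": alive.copy()})
        if not alive.any():
            break

    result = CohortResult(
        strategy=strategy.name, n=n,
        mean_cost=float(cost.mean()), mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        tallies=tallies,
    )
    result._ledgers = (cost, qaly)
    result._traces = traces
    return result


def simulate_patient(strategy: Strategy, params, life: LifeTable,
                     seed: int = 0, trace: bool = True) -> AccrualLedger:
    """Simulate a single patient's trajectory; returns their ledger with a
    per-cycle trace of state and discounted cost."""
    res = run_cohort(strategy, params, life, n=1, seed=seed, trace=trace)
    cost, qaly = res._ledgers
    tr = [{"age": s["age"], "health": HealthState(int(s["health"][0])),
           "cycle_cost": float(s["cycle_cost"][0])} for s in res._traces]
    return AccrualLedger(float(cost[0]), float(qaly[0]), tr)


def run_strategies(strategies, params, life: LifeTable, n: int = 100_000,
                   seed: int = 0) -> dict[str, CohortResult]:
    """Run several strategies under common random numbers (shared seed)."""
    return {s.name: run_cohort(s, params, life, n=n, seed=seed)
            for s in strategies}


# ---------------------------------------------------------------------------
# deterministic cohort evaluator
# ---------------------------------------------------------------------------

def cohort_evaluate(strategy: Strategy, params, life: LifeTable,
                    max_interval: int = 15) -> tuple[float, float]:
    """Exact expected (discounted cost, discounted QALY) per patient.

    Propagates the occupancy distribution over (adherence stratum x
    years-to-next-colonoscopy x health state) with the same event order and
    accounting as the microsimulation.  The due-counter axis is bounded by the
    largest surveillance interval (guarding the state space); diagnosed and
    dead states carry no counter.
    """
    intervals = (strategy.first_surveillance_offset, strategy.interval_high_grade,
                 strategy.interval_low_or_none)
    if strategy.use_colonoscopy and max(intervals) > max_interval:
        raise ValueError(f"surveillance interval exceeds the {max_interval}-year "
                         "state-space cap")
    mi = _ModelInputs(params, life)
    dr = mi.dr
    dmax = max_interval
    d_none = dmax + 1
    nd_slots = dmax + 2

    # occupancy[s, d, h]: adherence stratum, due counter, living health state
    M = np.zeros((2, nd_slots, 9))
    d0 = strategy.first_surveillance_offset if strategy.use_colonoscopy else d_none
    M[0, d0, SP] = 1.0 - mi.c_berb
    M[1, d0, SP] = mi.c_berb

    total_cost = 0.0
    total_qaly = 0.0

    for age in range(AGE_MIN, 100):
        t = age - AGE_MIN
        disc = (1.0 + dr) ** -t
        C = mi.costs(age)
        cost = 0.0

        # 1. other-cause death
        M = M * (1.0 - mi.q[t])

        groups = [[M, np.zeros((2, 3)), False]]  # occupancy, new-dx, attended?

        # 2. scheduled colonoscopy for due, living, non-diagnosed states
        if strategy.use_colonoscopy and age < INTERVENTION_END_AGE:
            owed = M[:, 0, :6].copy()
            M[:, 0, :6] = owed * (1.0 - mi.c_colo)  # missed: still due next year
            att = owed * mi.c_colo
            n_att = att.sum()
            rem1 = att[:, LRA] * mi.lra_rm
            rem2 = att[:, HRA] * mi.hra_rm
            det = att[:, LOC_PRE:DIST_PRE + 1] * mi.sens  # (2, 3)
            n_rem = rem1.sum() + rem2.sum()
            cost += (n_att - n_rem) * C["colo"] + n_rem * C["polyp"]
            cost += n_att * (mi.p_perf * C["perf"] + mi.p_bleed * C["bleed"])
            cost += float(det.sum(axis=0) @ C["initial"])
            s_comp = (1.0 - mi.p_perf * mi.m_perf) * (1.0 - mi.p_bleed * mi.m_bleed)

            A = np.zeros((2, nd_slots, 9))
            d_hi, d_lo = strategy.interval_high_grade, strategy.interval_low_or_none
            A[:, d_lo, SP] += (att[:, SP] + rem1) * s_comp
            A[:, d_hi, SP] += rem2 * s_comp
            A[:, d_lo, LRA] += att[:, LRA] * (1.0 - mi.lra_rm) * s_comp
            A[:, d_lo, HRA] += att[:, HRA] * (1.0 - mi.hra_rm) * s_comp
            A[:, d_lo, LOC_PRE:DIST_PRE + 1] += \
                att[:, LOC_PRE:DIST_PRE + 1] * (1.0 - mi.sens) * s_comp
            groups.append([A, det * s_comp, True])

        est_dx_after = np.zeros(3)
        alive_att = 0.0
        util = 0.0
        alive_adherent = 0.0

        for g in groups:
            O, ND, was_attended = g
            # 3. symptomatic presentation
            for k in range(3):
                pres = O[:, :, LOC_PRE + k] * mi.present[k]
                O[:, :, LOC_PRE + k] -= pres
                ND[:, k] += pres.sum(axis=1)
                cost += pres.sum() * C["initial"][k]
            # 4. cancer death (established then newly diagnosed)
            for k in range(3):
                d_est = O[:, :, LOC_DX + k] * mi.mort[k]
                cost += d_est.sum() * C["death"][k]
                O[:, :, LOC_DX + k] -= d_est
                d_new = ND[:, k] * mi.mort_new[k]
                cost += d_new.sum() * C["death"][k]
                ND[:, k] -= d_new
            if not was_attended:
                est_dx_after += O[:, :, LOC_DX:DIST_DX + 1].sum(axis=(0, 1))
            # 5. progression / recurrence from the post-event snapshot
            berb_on = strategy.use_berberine and age < INTERVENTION_END_AGE
            p_hra = np.array([mi.p_hra["placebo"],
                              mi.p_hra["berberine" if berb_on else "placebo"]])
            p_lra = np.array([mi.p_lra["placebo"],
                              mi.p_lra["berberine" if berb_on else "placebo"]])
            sp = O[:, :, SP].copy()
            to_hra = sp * p_hra[:, None]
            to_lra = sp * p_lra[:, None]
            lra_out = O[:, :, LRA] * mi.lra_to_hra
            hra_out = O[:, :, HRA] * mi.hra_to_crc
            l2r = O[:, :, LOC_PRE] * mi.loc_to_reg
            r2d = O[:, :, REG_PRE] * mi.reg_to_dist
            O[:, :, SP] = sp - to_hra - to_lra
            O[:, :, LRA] += to_lra - lra_out
            O[:, :, HRA] += to_hra + lra_out - hra_out
            O[:, :, LOC_PRE] += hra_out - l2r
            O[:, :, REG_PRE] += l2r - r2d
            O[:, :, DIST_PRE] += r2d
            # 6. accrual bookkeeping
            util += params.utility_non_crc * O[:, :, :6].sum()
            for k, uk in enumerate((params.utility_crc_local,
                                    params.utility_crc_regional,
                                    params.utility_crc_distant)):
                util += uk * (O[:, :, LOC_DX + k].sum() + ND[:, k].sum())
            if was_attended:
                alive_att += O.sum() + ND.sum()
            alive_adherent += O[1].sum() + ND[1].sum()

        util -= mi.disutil * alive_att
        if strategy.use_berberine and age < INTERVENTION_END_AGE:
            cost += mi.cost_berb * alive_adherent
        cost += float(est_dx_after @ C["cont"])

        total_cost += disc * cost
        total_qaly += disc * util

        # merge groups and fold newly diagnosed into the no-surveillance slot
        M = groups[0][0]
        for g in groups[1:]:
            M = M + g[0]
        for g in groups:
            M[:, d_none, LOC_DX:DIST_DX + 1] += g[1]

        # decrement due counters: d>0 -> d-1; d==0 stays due; none stays none
        nxt = np.zeros_like(M)
        nxt[:, 0, :] = M[:, 0, :] + M[:, 1, :]
        nxt[:, 1:dmax, :] = M[:, 2:dmax + 1, :]
        nxt[:, d_none, :] = M[:, d_none, :]
        M = nxt

    return float(total_cost), float(total_qaly)
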