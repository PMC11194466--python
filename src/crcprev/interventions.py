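"""Prevention strategies, surveillance scheduling, and colonoscopy performance.

Four strategies are compared: no intervention, berberine chemoprevention
alone, surveillance colonoscopy alone, and berberine plus colonoscopy.
Surveillance starts three years after model entry and repeats on a three-year
cycle when the last colonoscopy removed a high-risk adenoma, otherwise on a
five-year cycle; all intervention (drug exposure and surveillance) stops at
age 75.  Attendance at each scheduled colonoscopy is a per-procedure Bernoulli
draw (60% at baseline); a missed procedure remains due and is re-offered the
following year.  Berberine adherence is a single lifelong per-patient draw
(80% at baseline).

A colonoscopy removes a low-risk adenoma with probability 58%, a high-risk
adenoma with 92% (returning the patient to the normal-mucosa state), and
detects preclinical cancer with sensitivity 94.7% (triggering diagnosis).  It
carries perforation (0.04%) and major-bleeding (0.08%) risks with their own
case-fatality rates and costs, and a one-time 0.0025 QALY disutility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .natural_history import HealthState, PatientState, Stage

__all__ = ["Strategy", "STRATEGY_NAMES", "standard_strategies",
           "ColonoscopyOutcome", "due_for_colonoscopy", "perform_colonoscopy",
           "draw_adherence"]

STRATEGY_NAMES = (
    "no_intervention", "berberine", "colonoscopy", "berberine_plus_colonoscopy",
)

INTERVENTION_END_AGE = 75


@dataclass(frozen=True)
class Strategy:
    """Which interventions are active, and the surveillance interval rules."""

    name: str
    use_berberine: bool
    use_colonoscopy: bool
    interval_high_grade: int = 3
    interval_low_or_none: int = 5
    first_surveillance_offset: int = 3

    def __post_init__(self):
        if self.use_colonoscopy:
            if self.interval_high_grade < 1 or self.interval_low_or_none < 1:
                raise ValueError("surveillance intervals must be >= 1 year")
            if self.first_surveillance_offset < 1:
                raise ValueError("first surveillance offset must be >= 1 year")

    @classmethod
    def standard(cls, name: str, **overrides) -> "Strategy":
        if name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {name!r}")
        strat = cls(
            name=name,
            use_berberine="berberine" in name,
            use_colonoscopy="colonoscopy" in name,
        )
        return replace(strat, **overrides) if overrides else strat

    def with_intervals(self, interval_high_grade: int | None = None,
                       interval_low_or_none: int | None = None) -> "Strategy":
        kw = {}
        if interval_high_grade is not None:
            kw["interval_high_grade"] = interval_high_grade
        if interval_low_or_none is not None:
            kw["interval_low_or_none"] = interval_low_or_none
        return replace(self, **kw)


def standard_strategies(**interval_overrides) -> list[Strategy]:
    """The four compared strategies, optionally with scenario intervals."""
    return [Strategy.standard(n, **(interval_overrides if "colonoscopy" in n else {}))
            for n in STRATEGY_NAMES]


@dataclass(frozen=True)
class ColonoscopyOutcome:
    """Result of one scheduled surveillance colonoscopy offer."""

    attended: bool
    detected_and_removed: bool = False
    found_high_grade: bool = False
    diagnosed_crc: bool = False
    perforation: bool = False
    bleeding: bool = False
    died_of_complication: bool = False
    cost: float = 0.0
    disutility: float = 0.0
    new_health: HealthState | None = None


def due_for_colonoscopy(s: PatientState, strategy: Strategy) -> bool:
    """True when a surveillance colonoscopy is owed this cycle: the strategy
    surveils, the patient is inside the intervention window, is not in cancer
    care, and has reached the scheduled age."""
    if not strategy.use_colonoscopy or s.health.is_death:
        return False
    if s.health.is_diagnosed_crc:
        return False
    if s.age >= INTERVENTION_END_AGE:
        return False
    return s.next_colonoscopy_age is not None and s.age >= s.next_colonoscopy_age


def draw_adherence(strategy: Strategy, params, rng) -> bool:
    """Lifelong berberine-complier draw for one patient (False when the
    strategy has no drug component).  Colonoscopy attendance is per-procedure
    and drawn inside :func:`perform_colonoscopy`."""
    if not strategy.use_berberine:
        return False
    return bool(rng.random() < params.compliance_berberine)


def perform_colonoscopy(s: PatientState, params, rng,
                        attendance_prob: float | None = None) -> ColonoscopyOutcome:
    """Offer one scheduled colonoscopy and resolve attendance, detection,
    removal, complications, and cost.

    The procedure cost uses the payer block for the patient's attained age
    (<65 commercial, >=65 Medicare); the with-polypectomy rate applies when a
    polyp was excised.  Complication costs accrue even when the complication
    is fatal.
    """
    if s.health.is_death:
        raise ValueError("cannot perform colonoscopy on a dead patient")
    p_attend = (params.compliance_colonoscopy if attendance_prob is None
                else attendance_prob)
    if rng.random() >= p_attend:
        return ColonoscopyOutcome(attended=False, new_health=s.health)

    h = s.health
    removed = False
    diagnosed = False
    found_high = False
    new_health = h
    cost = 0.0
    u = rng.random()
    if h == HealthState.LRA and u < params.lra_removal:
        removed, new_health = True, HealthState.SP_NORMAL
    elif h == HealthState.HRA and u < params.hra_removal:
        removed, found_high, new_health = True, True, HealthState.SP_NORMAL
    elif h.is_preclinical_crc and u < params.colonoscopy_sensitivity_crc:
        diagnosed = True
        new_health = HealthState(HealthState.CRC_LOCAL_DX + h.stage)

    cost += params.cost("cost_colonoscopy_polypectomy" if removed
                        else "cost_colonoscopy", s.age)

    perforation = rng.random() < params.perforation_risk
    bleeding = rng.random() < params.bleeding_risk
    died = False
    if perforation:
        cost += params.cost("cost_perforation", s.age)
        died |= rng.random() < params.mort_perforation
    if bleeding:
        cost += params.cost("cost_bleeding", s.age)
        died |= rng.random() < params.mort_bleeding
    if died:
        new_health = HealthState.DEATH_COMPLICATION

    return ColonoscopyOutcome(
        attended=True,
        detected_and_removed=removed,
        found_high_grade=found_high,
        diagnosed_crc=diagnosed,
        perforation=perforation,
        bleeding=bleeding,
        died_of_complication=died,
        cost=cost,
        disutility=params.disutility_colonoscopy,
        new_health=new_health,
    )


def next_interval(strategy: Strategy, found_high_grade: bool) -> int:
    """Years until the next surveillance colonoscopy after a procedure."""
    return (strategy.interval_high_grade if found_high_grade
            else strategy.interval_low_or_none)
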