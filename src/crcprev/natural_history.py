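"""Disease natural history: health states and the annual transition kernel.

The natural history follows the adenoma-carcinoma sequence after polypectomy.
Patients start in the normal-mucosa state (status-post polypectomy), may
develop a low-risk (LRA) or directly a high-risk (HRA) adenoma, HRA can
progress to preclinical local colorectal cancer, and preclinical cancer
progresses through local -> regional -> distant while it may at any stage
present symptomatically and become diagnosed.  Diagnosed cancer carries
stage-specific annual mortality; every living state is exposed to age-specific
other-cause mortality.  Death states are absorbing and labelled by cause.

Within an annual cycle events resolve in a fixed order:

1. other-cause death,
2. scheduled surveillance colonoscopy (handled by :mod:`crcprev.interventions`),
3. symptomatic presentation of preclinical cancer,
4. cancer death in diagnosed states (plus a one-time 2% treatment mortality in
   the diagnosis cycle),
5. disease progression / adenoma recurrence,
6. accrual of the cycle's cost and utility.

The chemopreventive agent (berberine) acts only on the adenoma recurrence
rates from the normal-mucosa state, only while the patient is exposed
(ages 50-74, adherent, strategy includes the drug); the LRA->HRA and
HRA->cancer transitions use the same values in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

__all__ = [
    "HealthState", "PatientState", "Stage",
    "transition_distribution", "apply_symptomatic_presentation",
    "active_group", "recurrence_probs", "crc_death_prob",
]


class HealthState(IntEnum):
    """Expanded health-state space.

    The published seven-state structure maps onto this expansion: normal
    mucosa -> SP_NORMAL, adenomas -> LRA/HRA, each cancer stage -> a
    preclinical/diagnosed pair, death -> three cause-labelled absorbing states.
    """

    SP_NORMAL = 0
    LRA = 1
    HRA = 2
    CRC_LOCAL_PRE = 3
    CRC_REGIONAL_PRE = 4
    CRC_DISTANT_PRE = 5
    CRC_LOCAL_DX = 6
    CRC_REGIONAL_DX = 7
    CRC_DISTANT_DX = 8
    DEATH_CRC = 9
    DEATH_OTHER = 10
    DEATH_COMPLICATION = 11

    @property
    def is_death(self) -> bool:
        return self >= HealthState.DEATH_CRC

    @property
    def is_preclinical_crc(self) -> bool:
        return HealthState.CRC_LOCAL_PRE <= self <= HealthState.CRC_DISTANT_PRE

    @property
    def is_diagnosed_crc(self) -> bool:
        return HealthState.CRC_LOCAL_DX <= self <= HealthState.CRC_DISTANT_DX

    @property
    def stage(self) -> "Stage":
        if self.is_preclinical_crc:
            return Stage(self - HealthState.CRC_LOCAL_PRE)
        if self.is_diagnosed_crc:
            return Stage(self - HealthState.CRC_LOCAL_DX)
        raise ValueError(f"{self.name} has no cancer stage")


class Stage(IntEnum):
    LOCAL = 0
    REGIONAL = 1
    DISTANT = 2


N_LIVING = 9  # states 0..8 are alive


@dataclass
class PatientState:
    """One simulated patient's memory between cycles."""

    health: HealthState = HealthState.SP_NORMAL
    age: int = 50
    adherent: bool = True  # lifelong berberine complier/non-complier split
    next_colonoscopy_age: int | None = None
    years_since_dx: int = 0

    def __post_init__(self):
        if not 50 <= self.age <= 100:
            raise ValueError(f"age {self.age} outside [50, 100]")
        if self.years_since_dx and not self.health.is_diagnosed_crc:
            raise ValueError("years_since_dx > 0 only in diagnosed states")


def active_group(age: int, use_berberine: bool, adherent: bool) -> str:
    """'berberine' while exposed (strategy includes the drug, age in the
    50-74 treatment window, patient adherent); otherwise 'placebo'.  The
    protective effect does not persist after exposure ends."""
    return "berberine" if (use_berberine and 50 <= age < 75 and adherent) else "placebo"


def recurrence_probs(group: str, params) -> tuple[float, float]:
    """(annual SP->HRA, annual SP->LRA) for the given exposure group."""
    if group == "berberine":
        return params.sp_to_hra_berberine, params.sp_to_lra_berberine
    if group == "placebo":
        return params.sp_to_hra_placebo, params.sp_to_lra_placebo
    raise ValueError(f"unknown group {group!r}")


def apply_symptomatic_presentation(stage: Stage, params) -> float:
    """Annual probability that a preclinical cancer of this stage presents
    symptomatically and is diagnosed this cycle."""
    if stage == Stage.LOCAL:
        return params.present_local
    if stage == Stage.REGIONAL:
        return params.present_regional
    if stage == Stage.DISTANT:
        return params.present_distant
    raise ValueError(f"unknown stage {stage!r}")


def crc_death_prob(stage: Stage, params, newly_diagnosed: bool = False) -> float:
    """Annual cancer death probability for a diagnosed cancer of this stage.

    In the diagnosis cycle a one-time cancer-treatment mortality acts as an
    independent competing risk on top of the stage mortality.
    """
    p = (params.mort_crc_local, params.mort_crc_regional,
         params.mort_crc_distant)[stage]
    if newly_diagnosed:
        p = 1.0 - (1.0 - p) * (1.0 - params.mort_cancer_treatment)
    return p


def _progression_prob(health: HealthState, params) -> tuple[HealthState, float] | None:
    """Step-5 progression/recurrence move out of a living state (other than
    the SP_NORMAL two-way split), or None when the state does not progress."""
    if health == HealthState.LRA:
        return HealthState.HRA, params.lra_to_hra_placebo
    if health == HealthState.HRA:
        return HealthState.CRC_LOCAL_PRE, params.hra_to_crc_placebo
    if health == HealthState.CRC_LOCAL_PRE:
        return HealthState.CRC_REGIONAL_PRE, params.local_to_regional
    if health == HealthState.CRC_REGIONAL_PRE:
        return HealthState.CRC_DISTANT_PRE, params.regional_to_distant
    return None


def transition_distribution(s: PatientState, params, life, group: str | None = None,
                            newly_diagnosed: bool = False) -> dict[HealthState, float]:
    """Exact one-cycle categorical distribution over destination states for a
    patient outside the colonoscopy pathway (event steps 1, 3, 4, 5).

    ``group`` defaults to placebo; pass 'berberine' for an exposed patient.
    Raises on absorbing input.  Probabilities sum to one.
    """
    if s.health.is_death:
        raise ValueError(f"cannot transition out of absorbing state {s.health.name}")
    group = group or "placebo"
    dist: dict[HealthState, float] = {}
    q = life.q_other(s.age)
    dist[HealthState.DEATH_OTHER] = q
    survive = 1.0 - q

    h = s.health
    if h == HealthState.SP_NORMAL:
        p_hra, p_lra = recurrence_probs(group, params)
        dist[HealthState.HRA] = survive * p_hra
        dist[HealthState.LRA] = survive * p_lra
        dist[HealthState.SP_NORMAL] = survive * (1.0 - p_hra - p_lra)
    elif h.is_preclinical_crc:
        stage = h.stage
        p_present = apply_symptomatic_presentation(stage, params)
        # presents -> diagnosed this cycle -> faces cancer death immediately
        dx = HealthState.CRC_LOCAL_DX + stage
        p_die = crc_death_prob(stage, params, newly_diagnosed=True)
        dist[HealthState.DEATH_CRC] = survive * p_present * p_die
        dist[HealthState(dx)] = survive * p_present * (1.0 - p_die)
        stay = survive * (1.0 - p_present)
        move = _progression_prob(h, params)
        if move is not None:
            nxt, p = move
            dist[nxt] = stay * p
            dist[h] = stay * (1.0 - p)
        else:
            dist[h] = stay
    elif h.is_diagnosed_crc:
        p_die = crc_death_prob(h.stage, params, newly_diagnosed=newly_diagnosed)
        dist[HealthState.DEATH_CRC] = survive * p_die
        dist[h] = survive * (1.0 - p_die)
    else:  # LRA or HRA
        nxt, p = _progression_prob(h, params)
        dist[nxt] = survive * p
        dist[h] = survive * (1.0 - p)

    return {k: v for k, v in dist.items() if v != 0.0 or k == s.health}
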