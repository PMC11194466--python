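"""Age-dependent other-cause mortality for ages 50-100.

The model needs an annual probability of death from causes other than
colorectal cancer at every age from 50 (model entry) to 100 (horizon).  The
packaged table is synthetic: a Gompertz-Makeham law

    hazard(age) = a_M + b * exp(theta * (age - 50))
    q_other(age) = 1 - exp(-hazard(age))

with defaults calibrated to US-like adult mortality: q_other(50) ~ 0.004,
q_other(80) ~ 0.05, and a remaining life expectancy at 50 of about 30 years.
Age 100 is capped at q_other = 1 so every simulated patient is absorbed at the
horizon.  A real life table can be injected from a two-column ``age,q_other``
CSV via :meth:`LifeTable.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LifeTable", "make_life_table", "DEFAULT_MAKEHAM_A",
           "DEFAULT_GOMPERTZ_B", "DEFAULT_GOMPERTZ_THETA"]

AGE_MIN = 50
AGE_MAX = 100

DEFAULT_MAKEHAM_A = 0.002
DEFAULT_GOMPERTZ_B = 0.002
DEFAULT_GOMPERTZ_THETA = 0.107


@dataclass(frozen=True)
class LifeTable:
    """Annual other-cause death probability per integer age in [50, 100]."""

    q: np.ndarray  # shape (51,), q[a - 50] = annual death probability at age a

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (AGE_MAX - AGE_MIN + 1,):
            raise ValueError(f"life table must cover ages {AGE_MIN}..{AGE_MAX}")
        if not (np.all(q > 0.0) and np.all(q <= 1.0)):
            raise ValueError("q_other must lie in (0, 1]")
        if np.any(np.diff(q) < 0):
            raise ValueError("q_other must be non-decreasing in age")
        if q[-1] != 1.0:
            raise ValueError("q_other(100) must equal 1 (model horizon cap)")
        object.__setattr__(self, "q", q)

    def q_other(self, age: int) -> float:
        """Annual other-cause death probability at an integer age."""
        if not AGE_MIN <= age <= AGE_MAX:
            raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
        return float(self.q[int(age) - AGE_MIN])

    def life_expectancy(self, from_age: int = AGE_MIN) -> float:
        """Expected remaining years lived (disease-free), counting a full year
        for each year entered alive."""
        if not AGE_MIN <= from_age <= AGE_MAX:
            raise ValueError(f"age {from_age} outside [{AGE_MIN}, {AGE_MAX}]")
        surv = 1.0
        total = 0.0
        for a in range(from_age, AGE_MAX):
            total += surv
            surv *= 1.0 - self.q_other(a)
        return total

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        """Load an ``age,q_other`` CSV override covering ages 50..100."""
        data = np.genfromtxt(path, delimiter=",", names=True)
        ages = data["age"].astype(int)
        order = np.argsort(ages)
        ages, qs = ages[order], data["q_other"][order]
        if not np.array_equal(ages, np.arange(AGE_MIN, AGE_MAX + 1)):
            raise ValueError("CSV must contain one row per age 50..100")
        return cls(qs)


def make_life_table(
    makeham_a: float = DEFAULT_MAKEHAM_A,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    gompertz_theta: float = DEFAULT_GOMPERTZ_THETA,
) -> LifeTable:
    """Build the synthetic Gompertz-Makeham life table for ages 50-100."""
    if makeham_a <= 0 or gompertz_b <= 0 or gompertz_theta <= 0:
        raise ValueError("all Gompertz-Makeham parameters must be positive")
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_theta * (ages - AGE_MIN))
    q = np.minimum(1.0, -np.expm1(-hazard))
    q[-1] = 1.0
    return LifeTable(q)
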