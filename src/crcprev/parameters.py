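"""Model parameter registry, rate/probability conversions, and PSA distributions.

The model's inputs are annual transition probabilities, procedural risk rates,
cause-specific mortalities, 2022-USD costs split into a commercial (<65 years)
and a Medicare (>=65 years) payer block, and health-state utilities.  Each
parameter carries a baseline value, a plausible range, and a sampling family
(beta for probabilities and utilities, gamma for costs) used by the
probabilistic sensitivity analysis.  Ranges are treated as 95% intervals, so
the sampling standard deviation is (high - low) / 3.92 and every constructed
distribution is moment-matched to the baseline mean.

Adenoma recurrence after polypectomy is reported by the underlying trial as
two-year proportions; the constant-incidence-rate conversion
``rate = -ln(1-p)/t`` / ``probability = 1 - exp(-r t)`` turns those into the
annual probabilities stored here.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "prob_to_rate",
    "rate_to_prob",
    "two_year_to_annual",
    "beta_from_mean_range",
    "gamma_from_mean_range",
    "sample_parameter_set",
    "load_parameters",
    "default_parameters",
]

# Config blocks whose entries are written in percent (as the sources print them)
# and stored internally as probabilities.
_PERCENT_BLOCKS = {"transitions", "compliance", "risks", "mortality", "discount"}

_UNITS_BY_BLOCK = {
    "transitions": "probability",
    "compliance": "probability",
    "risks": "probability",
    "mortality": "probability",
    "costs_shared": "usd",
    "costs_commercial": "usd",
    "costs_medicare": "usd",
    "utilities": "utility",
    "discount": "rate",
}

_PAYER_BY_BLOCK = {
    "costs_commercial": "commercial_under65",
    "costs_medicare": "medicare_65plus",
}

# Range width interpreted as a 95% interval: high - low = 2 * 1.96 sd.
_RANGE_SD_DIVISOR = 3.92


def prob_to_rate(p: float, t: float) -> float:
    """Convert a probability over ``t`` years to a constant annual rate.

    Implements ``rate = -ln(1 - p) / t``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"time horizon must be positive, got {t}")
    return -math.log1p(-p) / t


def rate_to_prob(r: float, t: float) -> float:
    """Convert a constant annual rate to a probability over ``t`` years.

    Implements ``probability = 1 - exp(-r t)``.
    """
    if r < 0:
        raise ValueError(f"rate must be non-negative, got {r}")
    if t <= 0:
        raise ValueError(f"time horizon must be positive, got {t}")
    return -math.expm1(-r * t)


def two_year_to_annual(p2: float) -> float:
    """Annualize a two-year probability assuming a constant incidence rate.

    Composition of the two conversion formulas with t=2 then t=1; algebraically
    ``1 - sqrt(1 - p2)``.
    """
    return rate_to_prob(prob_to_rate(p2, 2.0), 1.0)


def beta_from_mean_range(mean: float, low: float, high: float) -> tuple[float, float]:
    """Method-of-moments Beta(alpha, beta) with the given mean and a standard
    deviation of (high - low)/3.92 (range read as a 95% interval).

    Raises ``ValueError`` when the implied variance is infeasible for a Beta
    distribution (sd^2 >= mean(1-mean)).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    if low >= high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    sd = (high - low) / _RANGE_SD_DIVISOR
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible Beta moments: sd^2={var:.6g} >= mean(1-mean)={mean*(1-mean):.6g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_range(mean: float, low: float, high: float) -> tuple[float, float]:
    """Method-of-moments Gamma(shape, scale) with the given mean and a standard
    deviation of (high - low)/3.92."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if low >= high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    sd = (high - low) / _RANGE_SD_DIVISOR
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: baseline, range, and PSA sampling family."""

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    family: str = "fixed"  # beta | gamma | fixed
    units: str = "probability"  # probability | usd | utility | rate
    payer: str = "n/a"  # commercial_under65 | medicare_65plus | n/a

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.family != "fixed":
            if self.low is None or self.high is None:
                raise ValueError(f"{self.name}: non-fixed parameter needs a range")
            if not self.low <= self.base <= self.high:
                raise ValueError(
                    f"{self.name}: range [{self.low}, {self.high}] does not "
                    f"bracket base {self.base}"
                )
        if self.family == "beta":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValueError(f"{self.name}: beta range outside [0, 1]")
        if self.family == "gamma" and self.low <= 0:
            raise ValueError(f"{self.name}: gamma low must be > 0")

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed"

    def distribution(self) -> tuple[str, tuple[float, float]] | None:
        """Return ('beta'|'gamma', params) or None for a fixed parameter.

        A zero-width (degenerate) range falls back to fixed with a warning so
        partial configs remain runnable.
        """
        if self.family == "fixed":
            return None
        if self.high - self.low <= 0 or math.isclose(self.low, self.high):
            warnings.warn(
                f"{self.name}: degenerate range; treating as fixed", stacklevel=2
            )
            return None
        if self.family == "beta":
            return "beta", beta_from_mean_range(self.base, self.low, self.high)
        return "gamma", gamma_from_mean_range(self.base, self.low, self.high)


class ParameterSet:
    """The complete named registry of model parameters.

    Parameter values are reachable as attributes (``params.sp_to_lra_placebo``)
    or via ``params["name"]``.  ``with_values`` returns a modified copy, which
    the one-way sensitivity analysis uses to move a single parameter to a range
    limit while everything else stays at baseline.
    """

    def __init__(self, specs: Mapping[str, ParameterSpec],
                 values: Mapping[str, float] | None = None,
                 validate: bool = True):
        self._specs = dict(specs)
        self._values = {n: s.base for n, s in self._specs.items()}
        if values is not None:
            for name, v in values.items():
                if name not in self._specs:
                    raise KeyError(f"unknown parameter {name!r}")
                self._values[name] = float(v)
        if validate:
            self.validate()

    # -- access ----------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __getattr__(self, name: str) -> float:
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(f"no parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def names(self) -> list[str]:
        return list(self._values)

    def spec(self, name: str) -> ParameterSpec:
        return self._specs[name]

    def values(self) -> dict[str, float]:
        return dict(self._values)

    @property
    def discount_rate(self) -> float:
        return self._values["discount_rate"]

    def cost(self, name: str, age: float) -> float:
        """Payer-resolved cost: commercial block under 65, Medicare at 65+."""
        suffix = "commercial" if age < 65 else "medicare"
        return self._values[f"{name}_{suffix}"]

    # -- modification ----------------------------------------------------
    def with_values(self, **overrides: float) -> "ParameterSet":
        new = copy.copy(self)
        new._specs = self._specs
        new._values = dict(self._values)
        for name, v in overrides.items():
            if name not in new._values:
                raise KeyError(f"unknown parameter {name!r}")
            new._values[name] = float(v)
        new.validate()
        return new

    def collapsed_ranges(self) -> "ParameterSet":
        """Copy with every range collapsed to the base value (degenerate PSA)."""
        specs = {
            n: ParameterSpec(n, s.base, s.base, s.base, s.family, s.units, s.payer)
            if not s.is_fixed else s
            for n, s in self._specs.items()
        }
        return ParameterSet(specs, self._values)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for msg in self.violations():
            raise ValueError(msg)

    def violations(self) -> list[str]:
        """List every broken parameter-set invariant (empty when valid)."""
        out = []
        for name, spec in self._specs.items():
            v = self._values[name]
            if spec.units == "probability" and not 0.0 <= v <= 1.0:
                out.append(f"{name}: probability {v} outside [0, 1]")
            elif spec.units == "utility" and not 0.0 <= v <= 1.0:
                out.append(f"{name}: utility {v} outside [0, 1]")
            elif spec.units == "usd" and v < 0.0:
                out.append(f"{name}: cost {v} is negative")
        return out


def sample_parameter_set(base: ParameterSet, rng_seed) -> ParameterSet:
    """Draw one PSA realization: every non-fixed parameter independently from
    its moment-matched family; fixed parameters (the discount rate) unchanged.

    ``rng_seed`` may be an int, a SeedSequence, or a Generator.
    """
    rng = np.random.default_rng(rng_seed)
    values = {}
    for name in base.names():
        spec = base.spec(name)
        dist = spec.distribution() if not spec.is_fixed else None
        if dist is None:
            values[name] = base[name]
        elif dist[0] == "beta":
            a, b = dist[1]
            values[name] = float(rng.beta(a, b))
        else:
            shape, scale = dist[1]
            values[name] = float(rng.gamma(shape, scale))
    return ParameterSet(base._specs, values)


def _parse_config(cfg: dict, strict: bool = True) -> ParameterSet:
    specs: dict[str, ParameterSpec] = {}
    spec_errors: list[str] = []
    for block, entries in cfg.items():
        if block == "trial_two_year":
            continue
        if block not in _UNITS_BY_BLOCK:
            raise ValueError(f"unknown config block {block!r}")
        units = _UNITS_BY_BLOCK[block]
        payer = _PAYER_BY_BLOCK.get(block, "n/a")
        scale = 0.01 if block in _PERCENT_BLOCKS else 1.0
        for key, entry in entries.items():
            try:
                base = float(entry["base"]) * scale
                family = entry.get("family", "fixed")
                low = entry.get("low")
                high = entry.get("high")
            except (TypeError, KeyError) as exc:
                raise ValueError(f"malformed entry {block}.{key}: {entry!r}") from exc
            if low is not None:
                low = float(low) * scale
            if high is not None:
                high = float(high) * scale
            name = key if payer == "n/a" else f"{key}_{payer.split('_')[0]}"
            if name in specs:
                raise ValueError(f"duplicate parameter name {name!r}")
            try:
                specs[name] = ParameterSpec(name, base, low, high, family,
                                            units, payer)
            except ValueError as exc:
                if strict:
                    raise
                spec_errors.append(str(exc))
                specs[name] = ParameterSpec(name, base, None, None, "fixed",
                                            units, payer)
    if "discount_rate" not in specs:
        raise ValueError("config must define discount.discount_rate")
    out = ParameterSet(specs, validate=strict)
    out._spec_errors = spec_errors
    return out


def load_parameters(path=None, strict: bool = True) -> ParameterSet:
    """Load a ParameterSet from a YAML config (the packaged default if None).

    With ``strict=False`` an invalid config still loads so that
    :func:`crcprev.reporting.validate_config` can list its violations.
    """
    if path is None:
        text = (
            resources.files("crcprev").joinpath("data/default_parameters.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return _parse_config(yaml.safe_load(text), strict=strict)


def load_trial_two_year(path=None) -> dict[str, float]:
    """The trial's two-year recurrence proportions (as probabilities), used to
    cross-check the derived annual recurrence parameters."""
    if path is None:
        text = (
            resources.files("crcprev").joinpath("data/default_parameters.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    block = yaml.safe_load(text).get("trial_two_year", {})
    return {k: float(v) / 100.0 for k, v in block.items()}


def default_parameters() -> ParameterSet:
    """The packaged baseline parameter set."""
    return load_parameters(None)
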