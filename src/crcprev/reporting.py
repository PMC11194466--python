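"""Run manifests, config validation, and tabular output.

Every command writes a ``manifest.json`` beside its outputs recording the
config hash, master seed, cohort size and strategy list, so any table can be
regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .economics import cea_table
from .engine import CohortResult
from .parameters import ParameterSet, two_year_to_annual

__all__ = ["RunManifest", "base_case_frame", "validate_config"]

# config name -> trial two-year input name for the recurrence cross-check
_TRIAL_CROSSCHECK = {
    "sp_to_lra_berberine": "lra_berberine",
    "sp_to_hra_berberine": "hra_berberine",
    "sp_to_lra_placebo": "lra_placebo",
    "sp_to_hra_placebo": "hra_placebo",
}


@dataclass
class RunManifest:
    """Provenance record for a model run."""

    command: str
    config_sha256: str
    master_seed: int
    n_patients: int
    strategies: list
    package_version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, config_text: str, seed: int, n: int,
               strategies: list[str]) -> "RunManifest":
        return cls(
            command=command,
            config_sha256=hashlib.sha256(config_text.encode()).hexdigest(),
            master_seed=int(seed),
            n_patients=int(n),
            strategies=list(strategies),
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def base_case_frame(results: dict[str, CohortResult]) -> pd.DataFrame:
    """Per-strategy outcome table (2022 USD) joined with the pairwise
    incremental analysis in strategy order."""
    cea = cea_table({k: (r.mean_cost, r.mean_qaly) for k, r in results.items()})
    extra = pd.DataFrame([
        {"strategy": k, "se_cost": r.se_cost, "se_qaly": r.se_qaly, "n": r.n,
         **{f"tally_{t}": v for t, v in r.tallies.items()}}
        for k, r in results.items()
    ])
    return cea.merge(extra, on="strategy")


def validate_config(params: ParameterSet,
                    trial_two_year: dict[str, float] | None = None,
                    tol: float = 5e-5) -> list[str]:
    """Report every violated parameter-set invariant, plus a cross-check of
    the four derived annual recurrence probabilities against the trial's
    two-year proportions via the constant-rate conversion.  Returns an empty
    list for a valid config."""
    report = list(getattr(params, "_spec_errors", [])) + params.violations()
    for name, trial_key in _TRIAL_CROSSCHECK.items():
        if trial_two_year and trial_key in trial_two_year and name in params:
            expected = two_year_to_annual(trial_two_year[trial_key])
            got = params[name]
            if abs(expected - got) > tol:
                report.append(
                    f"{name}: annual value {got:.4f} inconsistent with "
                    f"two-year trial proportion {trial_two_year[trial_key]:.2f} "
                    f"(expected {expected:.4f})"
                )
    return report
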