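"""Categorical decision rules for xenograft engraftment and chemo-resistance.

Engraftment of patient-derived cells in immunodeficient mice is read out by
flow cytometry as the percentage of human CD45+ cells among mouse-derived
cells, and the CD33+ fraction within them:

* **overt leukemia** — hCD45 > 5% with a major CD33+ population (> 60%);
* **non-overt leukemia** — detectable hCD45 below the overt criteria;
* **no engraftment** — hCD45 below the detection threshold.

The detection threshold is 0.1% for bulk transplants and 0.02% for single
HSPCs / single-HSPC-derived subclones, where much lower engraftment is still
informative. The detection threshold is inclusive; the overt thresholds are
strict. Ex vivo chemo-resistance uses a single cutoff: resistant at >= 60%
cell viability after drug exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigError

#: hCD45 detection thresholds (%) by transplant mode
DETECTION_THRESHOLD = {"bulk": 0.1, "single_hspc": 0.02}
OVERT_HCD45 = 5.0
OVERT_CD33 = 60.0
RESISTANCE_VIABILITY = 60.0

ENGRAFTMENT_CATEGORIES = ("overt_leukemia", "non_overt", "no_engraftment")


@dataclass(frozen=True)
class EngraftmentResult:
    hcd45_pct: float
    cd33_pct: float
    mode: str
    category: str


@dataclass(frozen=True)
class ResistanceResult:
    viability_pct: float
    category: str  # "resistant" | "sensitive"


def _check_pct(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise ConfigError(f"{name} must be a percentage in [0, 100], got {value}")


def classify_engraftment(
    hcd45_pct: float, cd33_pct: float, mode: str = "bulk"
) -> EngraftmentResult:
    """Classify one mouse readout as overt / non-overt / no engraftment."""
    _check_pct("hcd45_pct", hcd45_pct)
    _check_pct("cd33_pct", cd33_pct)
    if mode not in DETECTION_THRESHOLD:
        raise ConfigError(f"mode must be one of {sorted(DETECTION_THRESHOLD)}, got {mode!r}")
    if hcd45_pct > OVERT_HCD45 and cd33_pct > OVERT_CD33:
        category = "overt_leukemia"
    elif hcd45_pct >= DETECTION_THRESHOLD[mode]:
        category = "non_overt"
    else:
        category = "no_engraftment"
    return EngraftmentResult(hcd45_pct, cd33_pct, mode, category)


def classify_resistance(viability_pct: float) -> ResistanceResult:
    """Classify ex vivo chemo-resistance: resistant iff viability >= 60%."""
    _check_pct("viability_pct", viability_pct)
    category = "resistant" if viability_pct >= RESISTANCE_VIABILITY else "sensitive"
    return ResistanceResult(viability_pct, category)


def classify_engraftment_table(path_in: str | Path, path_out: str | Path) -> pd.DataFrame:
    """TSV in (sample_id, hcd45_pct, cd33_pct, mode) -> TSV out with category."""
    df = pd.read_csv(path_in, sep="\t")
    df["category"] = [
        classify_engraftment(float(r.hcd45_pct), float(r.cd33_pct), str(r.mode)).category
        for r in df.itertuples()
    ]
    df.to_csv(path_out, sep="\t", index=False)
    return df
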