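"""Published commissioning data from a clinical proton PSQA program.

These are the printed summary tables of a 70–220 MeV pencil-beam-scanning
program's independent-calculation commissioning: per-energy point-dose
differences, single-energy-field and cubic-SOBP gamma passing rates, and the
site-level passing-rate statistics of a 50-plan clinical cohort (five sites,
ten plans each).  They are the *inputs* the statistical pipeline operates on
and the targets the synthetic cohort generator emulates.

Note on the point-dose table: the printed percentage differences were computed
from unrounded doses and are not exactly reproducible from the rounded dose
columns also printed (2.00 -> 2.02 prints 0.78, not 1.0).  Only the printed
differences are treated as data here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortSpec, SiteSpec

__all__ = [
    "point_dose_table",
    "single_energy_rates",
    "cube_rates",
    "range_shifter_rates",
    "clinical_summary",
    "clinical_cohort_spec",
    "SITES",
    "CRITERIA_LABELS",
]

SITES = ("H&N", "Breast", "Chest", "Abdomen", "Pelvis")
CRITERIA_LABELS = ("3%/2mm", "3%/3mm", "5%/3mm")
PLANS_PER_SITE = 10

# energy MeV -> (measured Gy, independently calculated Gy, printed % difference)
_POINT_DOSE = {
    70: (2.00, 2.02, 0.78),
    100: (2.01, 2.03, 0.75),
    130: (1.98, 1.99, 0.48),
    160: (1.99, 2.01, 0.96),
    190: (2.02, 2.03, 0.68),
    200: (2.00, 2.01, 0.58),
}

# energy MeV -> gamma passing rate % (3%/3mm), single-energy 10x10 fields
_SINGLE_ENERGY = {70: 98.0, 100: 99.7, 130: 99.7, 160: 99.8, 190: 99.3, 200: 99.3}

# (cube cm, depth cm) -> gamma passing rate % (3%/3mm)
_CUBES = {
    (3, 10): 95.7, (5, 10): 97.8, (7, 10): 98.5, (10, 10): 99.3, (15, 10): 99.8,
    (3, 15): 100.0, (5, 15): 100.0, (7, 15): 99.7, (10, 15): 99.7, (15, 15): 99.6,
    (3, 20): 99.4, (5, 20): 98.9, (7, 20): 99.5, (10, 20): 99.1, (15, 20): 99.1,
}

# range shifter cm -> gamma passing rate % (10x10x10 cube at 15 cm, 3%/3mm)
_RANGE_SHIFTER = {0: 100.0, 2: 96.8, 3: 97.4, 5: 97.2}

# site -> criteria label -> (mean %, SD %); measurement is the detector array
# at 3%/2mm, the other two columns are the independent recalculation
_CLINICAL = {
    "H&N":     {"3%/2mm": (99.4, 1.2), "3%/3mm": (95.8, 1.9), "5%/3mm": (98.0, 1.3)},
    "Breast":  {"3%/2mm": (99.6, 0.7), "3%/3mm": (95.8, 2.6), "5%/3mm": (98.4, 1.2)},
    "Chest":   {"3%/2mm": (99.0, 1.9), "3%/3mm": (94.6, 2.5), "5%/3mm": (97.0, 1.9)},
    "Abdomen": {"3%/2mm": (98.8, 1.9), "3%/3mm": (95.2, 2.4), "5%/3mm": (96.9, 1.8)},
    "Pelvis":  {"3%/2mm": (99.4, 1.2), "3%/3mm": (98.2, 2.4), "5%/3mm": (99.0, 1.7)},
}

# pooled over all 50 plans, as printed
_CLINICAL_POOLED = {"3%/2mm": (99.2, 1.6), "3%/3mm": (95.9, 2.7), "5%/3mm": (97.9, 1.8)}


def point_dose_table() -> pd.DataFrame:
    """Per-energy measured/calculated point doses and printed % differences."""
    return pd.DataFrame(
        [
            {"energy_mev": e, "measured_gy": m, "calculated_gy": c, "percent_diff": d}
            for e, (m, c, d) in _POINT_DOSE.items()
        ]
    )


def single_energy_rates() -> pd.DataFrame:
    return pd.DataFrame(
        [{"energy_mev": e, "passing_rate": r} for e, r in _SINGLE_ENERGY.items()]
    )


def cube_rates() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cube_cm": c, "depth_cm": d, "passing_rate": r}
            for (c, d), r in _CUBES.items()
        ]
    )


def range_shifter_rates() -> pd.DataFrame:
    return pd.DataFrame(
        [{"shifter_cm": s, "passing_rate": r} for s, r in _RANGE_SHIFTER.items()]
    )


def clinical_summary(include_pooled: bool = True) -> pd.DataFrame:
    """Site x criteria summary statistics (mean, SD) of the clinical cohort."""
    rows = []
    for site, cells in _CLINICAL.items():
        for label, (mean, sd) in cells.items():
            rows.append({"site": site, "criteria": label, "mean": mean, "sd": sd})
    if include_pooled:
        for label, (mean, sd) in _CLINICAL_POOLED.items():
            rows.append({"site": "All regions", "criteria": label, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def clinical_cohort_spec(
    criteria_label: str = "3%/3mm",
    n_per_site: int = PLANS_PER_SITE,
    seed: int = 0,
) -> CohortSpec:
    """CohortSpec targeting the published site statistics for one criteria."""
    if criteria_label not in CRITERIA_LABELS:
        raise ValueError(f"unknown criteria label {criteria_label!r}")
    sites = tuple(
        SiteSpec(site=s, mean=_CLINICAL[s][criteria_label][0],
                 sd=_CLINICAL[s][criteria_label][1], n=n_per_site)
        for s in SITES
    )
    return CohortSpec(sites=sites, criteria_label=criteria_label, seed=seed)
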