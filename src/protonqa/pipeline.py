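"""End-to-end orchestration: simple-plan validation and clinical emulation.

``run_simple_validation`` rebuilds the commissioning exercise at desk scale:
single-energy reference fields, the cube-size x depth SOBP matrix and the
range-shifter set.  Each plan's reference dose comes from the analytic engine;
the "evaluated" member of the pair is a perturbed copy (the stand-in for an
independent recalculation); gamma is scored on the central beam-axis plane.

``run_clinical_emulation`` generates site-labelled passing-rate cohorts at the
published clinical statistics, summarizes them, runs the paired t-tests and
the across-site ANOVA, and derives confidence / tolerance / action limits.

Both stages are deterministic under the config seed and write their tables,
plus a resolved-config sidecar, to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .beam import BeamModel, bragg_range
from .cohort import generate_cohort
from .gamma import GammaCriteria, gamma_map
from .grids import central_slab
from .plans import PerturbSpec, build_cube_plan, build_single_energy_plan, compute_dose, perturb
from .spc import QASeries, limits_report
from .stats import PairedSample, one_way_anova, paired_t, summarize

__all__ = ["PipelineConfig", "run_simple_validation", "run_clinical_emulation"]

SINGLE_ENERGIES_MEV = (70.0, 100.0, 130.0, 160.0, 190.0, 200.0)
CUBE_SIZES_CM = (3.0, 5.0, 7.0, 10.0, 15.0)
CUBE_DEPTHS_CM = (10.0, 15.0, 20.0)
SHIFTERS_CM = (0.0, 2.0, 3.0, 5.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    beam: BeamModel = BeamModel()
    grid_spacing_mm: float = 2.0
    criteria: tuple[GammaCriteria, ...] = (GammaCriteria(3.0, 3.0),)
    perturb: PerturbSpec = PerturbSpec(
        dose_scale_percent=1.0,
        shift_mm=(0.5, 0.0, 0.5),
        noise_percent=0.8,
        range_error_mm=1.0,
    )
    # extra evaluated-side range error per cm of shifter (WET uncertainty)
    shifter_range_error_mm_per_cm: float = 0.3
    single_energies_mev: tuple[float, ...] = SINGLE_ENERGIES_MEV
    cube_sizes_cm: tuple[float, ...] = CUBE_SIZES_CM
    cube_depths_cm: tuple[float, ...] = CUBE_DEPTHS_CM
    shifters_cm: tuple[float, ...] = SHIFTERS_CM
    shifter_cube_cm: float = 10.0
    shifter_depth_cm: float = 15.0
    spot_spacing_mm: float = 2.5
    n_per_site: int = datasets.PLANS_PER_SITE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid spacing must be positive")
        if not self.criteria:
            raise ValueError("at least one gamma criteria set required")


def _write_config(config: PipelineConfig, outdir: Path) -> None:
    doc = dataclasses.asdict(config)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)


def _plan_geometry(plan, config: PipelineConfig):
    """Grid covering the plan: lateral spot extent + 15 mm, depth to the
    distal peak + 20 mm."""
    h = config.grid_spacing_mm
    pos = np.concatenate([l.positions_mm for l in plan.layers])
    margin = 15.0
    x_lo, x_hi = pos[:, 0].min() - margin, pos[:, 0].max() + margin
    y_lo, y_hi = pos[:, 1].min() - margin, pos[:, 1].max() + margin
    z_hi = max(
        (bragg_range(l.energy_mev, config.beam) - plan.range_shifter_cm) * 10.0
        for l in plan.layers
    ) + 20.0
    nx = int(np.ceil((x_hi - x_lo) / h)) + 1
    ny = int(np.ceil((y_hi - y_lo) / h)) + 1
    nz = int(np.ceil(z_hi / h)) + 1
    return (x_lo, y_lo, 0.0), (h, h, h), (nx, ny, nz)


def _score_plan(plan, config: PipelineConfig, plan_seed: int) -> dict:
    """Reference vs perturbed-evaluated gamma rates on the central plane."""
    origin, spacing, shape = _plan_geometry(plan, config)
    reference = compute_dose(plan, origin, spacing, shape, config.beam)
    pspec = dataclasses.replace(
        config.perturb,
        seed=plan_seed,
        range_error_mm=config.perturb.range_error_mm
        + config.shifter_range_error_mm_per_cm * plan.range_shifter_cm,
    )
    evaluated = perturb(reference, pspec)
    ref_plane = central_slab(reference, axis=1)
    out = {"plan": plan.label, "n_spots": plan.n_spots, "n_layers": len(plan.layers)}
    for crit in config.criteria:
        res = gamma_map(ref_plane, evaluated, crit)
        out[crit.label] = round(res.passing_rate, 1)
    return out


def run_simple_validation(config: PipelineConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Single-energy fields, the cube matrix and the range-shifter set,
    scored against their perturbed counterparts.  Returns (and optionally
    writes) one table per exercise."""
    rng = np.random.default_rng(config.seed)

    single_rows = []
    for energy in config.single_energies_mev:
        plan = build_single_energy_plan(energy, spacing_mm=config.spot_spacing_mm)
        row = _score_plan(plan, config, int(rng.integers(2**31)))
        row["energy_mev"] = energy
        single_rows.append(row)

    cube_rows = []
    for depth in config.cube_depths_cm:
        for size in config.cube_sizes_cm:
            plan = build_cube_plan(
                size, depth, "auto", config.beam, spot_spacing_mm=config.spot_spacing_mm
            )
            row = _score_plan(plan, config, int(rng.integers(2**31)))
            row.update({"cube_cm": size, "depth_cm": depth})
            cube_rows.append(row)

    shifter_rows = []
    for shifter in config.shifters_cm:
        plan = build_cube_plan(
            config.shifter_cube_cm,
            config.shifter_depth_cm,
            shifter,
            config.beam,
            spot_spacing_mm=config.spot_spacing_mm,
        )
        row = _score_plan(plan, config, int(rng.integers(2**31)))
        row["shifter_cm"] = shifter
        shifter_rows.append(row)

    tables = {
        "single_energy": pd.DataFrame(single_rows),
        "cubes": pd.DataFrame(cube_rows),
        "range_shifter": pd.DataFrame(shifter_rows),
    }
    if outdir is not None:
        outdir = Path(outdir)
        _write_config(config, outdir)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
    return tables


def run_clinical_emulation(config: PipelineConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Site cohorts at the published statistics -> summary + significance
    table, ANOVA across sites, and the limits table (CL / TL / AL)."""
    rng = np.random.default_rng(config.seed)
    cohorts: dict[str, list[QASeries]] = {}
    for label in datasets.CRITERIA_LABELS:
        spec = datasets.clinical_cohort_spec(
            label, n_per_site=config.n_per_site, seed=int(rng.integers(2**31))
        )
        cohorts[label] = generate_cohort(spec)

    by_site = {
        label: {s.site: s for s in series} for label, series in cohorts.items()
    }
    summary_rows = []
    for site in datasets.SITES:
        meas = by_site["3%/2mm"][site]
        row: dict = {"site": site}
        for label in datasets.CRITERIA_LABELS:
            s = summarize(by_site[label][site].rates)
            row[f"mean_{label}"] = round(s.mean, 1)
            row[f"sd_{label}"] = round(s.sd, 1)
        for label in ("3%/3mm", "5%/3mm"):
            _, p = paired_t(PairedSample(meas.rates, by_site[label][site].rates))
            row[f"p_meas_vs_{label}"] = round(p, 3)
        summary_rows.append(row)

    anova_rows = []
    for label in datasets.CRITERIA_LABELS:
        f, p = one_way_anova([s.rates for s in cohorts[label]])
        anova_rows.append({"criteria": label, "F": round(f, 2), "p": round(p, 4)})

    limit_series = [s for label in ("3%/3mm", "5%/3mm") for s in cohorts[label]]
    limits = limits_report(limit_series)

    tables = {
        "site_summary": pd.DataFrame(summary_rows),
        "anova": pd.DataFrame(anova_rows),
        "limits": limits,
    }
    if outdir is not None:
        outdir = Path(outdir)
        _write_config(config, outdir)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
    return tables
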