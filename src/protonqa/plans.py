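"""Synthetic PBS plan builders, the analytic dose engine, and perturbations.

Plans are lists of energy layers, each an array of lateral spot positions with
non-negative weights.  ``compute_dose`` superposes, for every layer and spot,
the product of the layer's depth-dose curve (evaluated at water-equivalent
depth, i.e. phantom depth plus range-shifter thickness) and a depth-dependent
lateral Gaussian.  The engine is linear in spot weights; an optional
normalization pins the dose at a stated point (e.g. 2 Gy at 2 cm depth on the
central axis, the convention for machine-QA reference fields).

``perturb`` manufactures the "evaluated" member of a QA pair from a reference
grid: rigid shift, distal range shift, systematic dose scaling and voxelwise
Gaussian noise, all reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from . import beam as _beam
from .beam import BeamModel, bragg_range, depth_dose, energy_for_range, lateral_sigma
from .grids import DoseGrid, point_value, trilinear

__all__ = [
    "Layer",
    "PlanSpec",
    "PerturbSpec",
    "build_single_energy_plan",
    "build_cube_plan",
    "compute_dose",
    "perturb",
]

ALLOWED_SHIFTERS_CM = (0.0, 2.0, 3.0, 5.0)
DEFAULT_SPOT_SPACING_MM = 2.5
DEFAULT_SPOT_MU = 100.0


@dataclass
class Layer:
    """One energy layer: spot lateral positions (mm) and weights (MU-like)."""

    energy_mev: float
    positions_mm: np.ndarray  # (n_spots, 2) lateral (x, y)
    weights: np.ndarray  # (n_spots,), >= 0

    def __post_init__(self) -> None:
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.positions_mm.shape[1] != 2:
            raise ValueError("spot positions must be (n, 2) lateral coordinates")
        if len(self.weights) != len(self.positions_mm):
            raise ValueError("one weight per spot required")
        if np.any(self.weights < 0):
            raise ValueError("spot weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("layer must contain at least one spot with positive weight")
        if not _beam.ENERGY_MIN_MEV <= self.energy_mev <= _beam.ENERGY_MAX_MEV:
            raise ValueError(f"layer energy {self.energy_mev} MeV outside machine range")


@dataclass
class PlanSpec:
    """A synthetic PBS plan: layers, range shifter, optional normalization."""

    layers: list[Layer]
    range_shifter_cm: float = 0.0
    normalization: tuple[tuple[float, float, float], float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("plan must contain at least one layer")
        if float(self.range_shifter_cm) not in ALLOWED_SHIFTERS_CM:
            raise ValueError(
                f"range shifter {self.range_shifter_cm} cm not in {ALLOWED_SHIFTERS_CM}"
            )
        self.range_shifter_cm = float(self.range_shifter_cm)

    @property
    def n_spots(self) -> int:
        return sum(len(l.weights) for l in self.layers)


@dataclass(frozen=True)
class PerturbSpec:
    """Discrepancy model applied to a reference grid to emulate an
    independent recalculation: systematic dose offset (%), rigid shift (mm),
    distal range shift (mm), and voxelwise Gaussian noise (% of max dose)."""

    dose_scale_percent: float = 0.0
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_percent: float = 0.0
    range_error_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_percent < 0:
            raise ValueError("noise_percent must be non-negative")


# -- builders --------------------------------------------------------------


def _spot_grid(extent_mm: float, spacing_mm: float) -> np.ndarray:
    """Centered square grid of spots covering [-extent/2, extent/2]."""
    n = int(round(extent_mm / spacing_mm)) + 1
    coords = (np.arange(n) - (n - 1) / 2) * spacing_mm
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel()], axis=1)


def build_single_energy_plan(
    energy_mev: float,
    field_cm: float = 10.0,
    spacing_mm: float = DEFAULT_SPOT_SPACING_MM,
) -> PlanSpec:
    """Single-energy reference field: square spot grid, equal weights,
    normalized to 2 Gy at 2 cm depth on the central axis.

    Defaults give a 10 x 10 cm^2 field at 2.5 mm spot pitch: 41 x 41 = 1681
    spots, the standard machine-QA layout.
    """
    if field_cm <= 0 or spacing_mm <= 0:
        raise ValueError("field size and spot spacing must be positive")
    if spacing_mm > field_cm * 10:
        raise ValueError(f"spot spacing {spacing_mm} mm exceeds field size {field_cm} cm")
    positions = _spot_grid(field_cm * 10.0, spacing_mm)
    layer = Layer(
        energy_mev=energy_mev,
        positions_mm=positions,
        weights=np.full(len(positions), DEFAULT_SPOT_MU),
    )
    return PlanSpec(
        layers=[layer],
        normalization=((0.0, 0.0, 20.0), 2.0),
        label=f"single-{energy_mev:g}MeV-{field_cm:g}cm",
    )


def _auto_shifter(proximal_cm: float, distal_cm: float, model: BeamModel) -> float:
    """Smallest allowed shifter making both span ends reachable in energy."""
    rmin = bragg_range(_beam.ENERGY_MIN_MEV, model)
    rmax = bragg_range(_beam.ENERGY_MAX_MEV, model)
    for shifter in ALLOWED_SHIFTERS_CM:
        if proximal_cm + shifter >= rmin and distal_cm + shifter <= rmax:
            return shifter
    raise ValueError(
        f"target span [{proximal_cm}, {distal_cm}] cm unreachable with any allowed range shifter"
    )


def build_cube_plan(
    cube_cm: float,
    depth_cm: float,
    range_shifter_cm: float | str = 0.0,
    model: BeamModel = BeamModel(),
    spot_spacing_mm: float = DEFAULT_SPOT_SPACING_MM,
    lateral_margin_cm: float = 1.0,
    prescription_gy: float = 2.0,
) -> PlanSpec:
    """Cubic SOBP plan: layer energies span the target depth extent and layer
    weights are solved by non-negative least squares so the central-axis dose
    across the target is flat (within ~3%).

    ``range_shifter_cm`` may be "auto" to select the smallest shifter from
    {0, 2, 3, 5} cm that brings the proximal layer above the 70 MeV minimum
    range (needed e.g. for large shallow cubes).
    """
    if not 2.0 <= cube_cm <= 20.0:
        raise ValueError(f"cube size {cube_cm} cm outside the supported 2-20 cm")
    proximal = depth_cm - cube_cm / 2.0
    distal = depth_cm + cube_cm / 2.0
    if proximal <= 0:
        raise ValueError(f"proximal edge at {proximal} cm; target must sit fully in the phantom")

    if range_shifter_cm == "auto":
        range_shifter_cm = _auto_shifter(proximal, distal, model)
    shifter = float(range_shifter_cm)

    # required ranges in water include the shifter pullback
    r_distal = distal + shifter
    r_proximal = proximal + shifter
    if r_proximal < bragg_range(_beam.ENERGY_MIN_MEV, model) - 1e-9:
        raise ValueError(
            f"proximal range {r_proximal:.2f} cm below the 70 MeV minimum "
            f"({bragg_range(_beam.ENERGY_MIN_MEV, model):.2f} cm); use a thinner shifter "
            "or range_shifter_cm='auto'"
        )
    if r_distal > bragg_range(_beam.ENERGY_MAX_MEV, model) + 1e-9:
        raise ValueError(f"distal range {r_distal:.2f} cm above the 220 MeV maximum")

    # layer ranges from distal to proximal, step ~1.2 local peak sigma
    ranges = []
    r = r_distal
    while r >= r_proximal - 0.3 * model.peak_sigma_frac * r_proximal:
        ranges.append(r)
        r -= max(0.1, 1.2 * model.peak_sigma_frac * r)
    ranges = np.array(ranges)
    energies = np.array([energy_for_range(rr, model) for rr in ranges])

    # flatness solve on the central axis (water depth = phantom depth + shifter)
    z_eval = np.arange(proximal, distal + 1e-9, 0.1)
    design = np.stack([depth_dose(e, z_eval + shifter, model) for e in energies], axis=1)
    layer_weights, _ = nnls(design, np.ones(len(z_eval)))

    positions = _spot_grid((cube_cm + 2 * lateral_margin_cm) * 10.0, spot_spacing_mm)
    layers = [
        Layer(
            energy_mev=e,
            positions_mm=positions,
            weights=np.full(len(positions), w),
        )
        for e, w in zip(energies, layer_weights)
        if w > 1e-12
    ]
    return PlanSpec(
        layers=layers,
        range_shifter_cm=shifter,
        normalization=((0.0, 0.0, depth_cm * 10.0), prescription_gy),
        label=f"cube{cube_cm:g}-d{depth_cm:g}-rs{shifter:g}",
    )


# -- dose engine -----------------------------------------------------------


def _lateral_field_1d(coords_mm: np.ndarray, spots_mm: np.ndarray, sigma_mm: np.ndarray):
    """Sum of normalized 1D Gaussians: (nz, n_coords) for per-depth sigma."""
    d2 = (coords_mm[None, :] - spots_mm[:, None]) ** 2  # (S, n)
    s = sigma_mm[:, None, None]  # (nz, 1, 1)
    g = np.exp(-d2[None, :, :] / (2 * s**2)) / (np.sqrt(2 * np.pi) * s)
    return g.sum(axis=1)  # (nz, n)


def _separable_layout(layer: Layer):
    """If the layer's spots form a uniform-weight cartesian grid, return
    (xs, ys, weight); otherwise None.  Enables the fast separable path."""
    w = layer.weights
    if not np.allclose(w, w[0]):
        return None
    xs = np.unique(layer.positions_mm[:, 0])
    ys = np.unique(layer.positions_mm[:, 1])
    if len(xs) * len(ys) != len(w):
        return None
    order = np.lexsort((layer.positions_mm[:, 1], layer.positions_mm[:, 0]))
    sorted_pos = layer.positions_mm[order]
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    if not np.allclose(sorted_pos, grid):
        return None
    return xs, ys, float(w[0])


def compute_dose(
    plan: PlanSpec,
    origin_mm,
    spacing_mm,
    shape,
    model: BeamModel = BeamModel(),
) -> DoseGrid:
    """Superpose the plan's spots onto a regular grid (beam along +z).

    Dose(x, y, z) = sum over layers, spots of
    weight * depth_dose(E, z + shifter) * Gaussian(x, y; spot, sigma(z)),
    then rescaled so the plan's normalization point receives its stated dose.
    """
    origin = np.asarray(origin_mm, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    nx, ny, nz = (int(s) for s in shape)
    x = origin[0] + spacing[0] * np.arange(nx)
    y = origin[1] + spacing[1] * np.arange(ny)
    z = origin[2] + spacing[2] * np.arange(nz)

    all_pos = np.concatenate([l.positions_mm for l in plan.layers])
    if (
        all_pos[:, 0].min() < x[0] - 1e-9
        or all_pos[:, 0].max() > x[-1] + 1e-9
        or all_pos[:, 1].min() < y[0] - 1e-9
        or all_pos[:, 1].max() > y[-1] + 1e-9
    ):
        raise ValueError("grid does not cover the plan's spot positions laterally")
    peak_depths = [
        (bragg_range(l.energy_mev, model) - plan.range_shifter_cm) * 10.0 for l in plan.layers
    ]
    if max(peak_depths) > z[-1] + spacing[2] or min(peak_depths) < z[0] - spacing[2]:
        raise ValueError("grid z-extent does not cover the plan's Bragg-peak depths")

    z_cm = np.clip(z, 0.0, None) / 10.0
    sigma = lateral_sigma(z_cm, model, plan.range_shifter_cm)  # (nz,) mm

    dose = np.zeros((nx, ny, nz))
    lateral_cache: dict = {}
    for layer in plan.layers:
        dd = depth_dose(layer.energy_mev, z_cm + plan.range_shifter_cm, model)  # (nz,)
        layout = _separable_layout(layer)
        if layout is not None:
            xs, ys, w0 = layout
            key = (xs.tobytes(), ys.tobytes())
            if key not in lateral_cache:
                gx = _lateral_field_1d(x, xs, sigma)  # (nz, nx)
                gy = _lateral_field_1d(y, ys, sigma)  # (nz, ny)
                lateral_cache[key] = gx[:, :, None] * gy[:, None, :]  # (nz, nx, ny)
            dose += (w0 * dd)[:, None, None].transpose(1, 2, 0) * lateral_cache[key].transpose(
                1, 2, 0
            )
        else:
            # general path: per-depth weighted Gaussian matmul over spots
            sx, sy = layer.positions_mm[:, 0], layer.positions_mm[:, 1]
            for k in range(nz):
                s = sigma[k]
                gx = np.exp(-((x[None, :] - sx[:, None]) ** 2) / (2 * s**2))  # (S, nx)
                gy = np.exp(-((y[None, :] - sy[:, None]) ** 2) / (2 * s**2))  # (S, ny)
                norm = 1.0 / (2 * np.pi * s**2)
                dose[:, :, k] += dd[k] * norm * ((gx * layer.weights[:, None]).T @ gy)

    grid = DoseGrid(
        values=dose,
        origin=tuple(origin),
        spacing=tuple(spacing),
        description=plan.label,
    )
    if plan.normalization is not None:
        position, target = plan.normalization
        current = point_value(grid, position)
        if current <= 0:
            raise ValueError(f"zero dose at normalization point {position}")
        grid.values *= target / current
    return grid


# -- perturbation ----------------------------------------------------------


def perturb(grid: DoseGrid, spec: PerturbSpec) -> DoseGrid:
    """Apply the discrepancy model; a zero spec returns the grid unchanged
    (bit-for-bit).  Order: rigid shift, range shift, dose scale, noise;
    negative values after noise are clipped to zero (dose is non-negative)."""
    values = grid.values
    lo, hi = grid.bounds

    if any(s != 0 for s in spec.shift_mm):
        # dose moves by +shift: sample the source at p - shift, zero outside
        xs = grid.axis_coords(0) - spec.shift_mm[0]
        ys = grid.axis_coords(1) - spec.shift_mm[1]
        zs = grid.axis_coords(2) - spec.shift_mm[2]
        xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
        src = DoseGrid(values, grid.origin, grid.spacing)
        values = np.nan_to_num(
            trilinear(src, pts, out_of_bounds="nan"), nan=0.0
        ).reshape(grid.shape)

    if spec.range_error_mm != 0 and grid.shape[2] > 1:
        # depth-proportional stretch: zero displacement at the entrance plane,
        # full range_error at the deepest plane, so the distal edge moves while
        # the entrance stays put
        zs = grid.axis_coords(2)
        frac = (zs - lo[2]) / (hi[2] - lo[2])
        z_src = zs - spec.range_error_mm * frac
        xs, ys = grid.axis_coords(0), grid.axis_coords(1)
        xx, yy, zz = np.meshgrid(xs, ys, z_src, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
        src = DoseGrid(values, grid.origin, grid.spacing)
        values = np.nan_to_num(
            trilinear(src, pts, out_of_bounds="nan"), nan=0.0
        ).reshape(grid.shape)

    if spec.dose_scale_percent != 0:
        values = values * (1.0 + spec.dose_scale_percent / 100.0)

    if spec.noise_percent > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_percent / 100.0 * float(values.max())
        values = np.clip(values + rng.normal(0.0, sd, size=values.shape), 0.0, None)

    if values is grid.values:
        return grid
    return DoseGrid(
        values=values,
        origin=grid.origin,
        spacing=grid.spacing,
        description=grid.description,
    )
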