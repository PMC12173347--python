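"""Regular-lattice absorbed-dose grids and the interpolation primitives shared
by every other module.

A :class:`DoseGrid` is a 3D array of absorbed dose (Gy) on a regular lattice
with physical geometry in millimetres.  The convention follows DICOM RT Dose:
``origin`` is the physical coordinate of the *center* of voxel ``(0, 0, 0)``
and the center of voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.
For synthetic grids the beam travels along +z, so z is depth in the phantom
and x/y are the lateral axes; a one-voxel-thick axis represents a plane, which
is how 2D (detector-style) comparisons are expressed.

Plain-text serialization (:func:`write_grid` / :func:`read_grid`) uses a single
JSON document so test fixtures never require DICOM; the DICOM RT Dose codec
lives in :mod:`protonqa.dicom_rtdose`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DoseGrid",
    "trilinear",
    "point_value",
    "resample",
    "central_slab",
    "write_grid",
    "read_grid",
]

AXIS_LABELS = ("x", "y", "z")


@dataclass
class DoseGrid:
    """Absorbed dose on a regular 3D lattice.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Absorbed dose in Gy; finite and non-negative.
    origin : tuple of 3 floats
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    spacing : tuple of 3 floats
        Voxel pitch per axis (mm); strictly positive.
    description : str
        Free text provenance.
    """

    values: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    description: str = ""
    axis_labels: tuple[str, str, str] = field(default=AXIS_LABELS, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"dose array must be 3D, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValueError("dose array must have at least 1 voxel per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if len(self.origin) != 3 or len(self.spacing) != 3:
            raise ValueError("origin and spacing must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on every axis, got {self.spacing}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) physical coordinates of the voxel-center bounding box."""
        lo = np.array(self.origin)
        hi = lo + (np.array(self.shape) - 1) * np.array(self.spacing)
        return lo, hi

    def voxel_center(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.array(self.origin) + np.array(index) * np.array(self.spacing)

    def copy(self) -> "DoseGrid":
        return replace(self, values=self.values.copy())


def trilinear(
    grid: DoseGrid,
    points: np.ndarray,
    out_of_bounds: str = "error",
) -> np.ndarray:
    """Vectorized trilinear interpolation of a grid at physical points (mm).

    ``out_of_bounds`` is one of ``"error"``, ``"nan"`` (return NaN outside the
    voxel-center bounding box) or ``"clamp"`` (clamp to the nearest edge).
    Size-1 axes carry unit weight (planar grids interpolate in-plane only).
    """
    if out_of_bounds not in ("error", "nan", "clamp"):
        raise ValueError(f"unknown out_of_bounds mode {out_of_bounds!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 3:
        raise ValueError("points must have 3 coordinates")
    shape = np.array(grid.shape)
    t = (pts - np.array(grid.origin)) / np.array(grid.spacing)

    eps = 1e-9
    outside = np.any((t < -eps) | (t > shape - 1 + eps), axis=1)
    if out_of_bounds == "error" and np.any(outside):
        bad = pts[np.argmax(outside)]
        raise ValueError(f"point {tuple(bad)} mm is outside the grid bounding box")

    tc = np.clip(t, 0.0, shape - 1)
    i0 = np.minimum(np.floor(tc).astype(np.intp), np.maximum(shape - 2, 0))
    frac = tc - i0
    # size-1 axes: single sample, zero fractional weight
    for ax in range(3):
        if grid.shape[ax] == 1:
            i0[:, ax] = 0
            frac[:, ax] = 0.0
    i1 = np.minimum(i0 + 1, shape - 1)

    v = grid.values
    fx, fy, fz = frac[:, 0], frac[:, 1], frac[:, 2]
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    x1, y1, z1 = i1[:, 0], i1[:, 1], i1[:, 2]

    out = (
        v[x0, y0, z0] * (1 - fx) * (1 - fy) * (1 - fz)
        + v[x1, y0, z0] * fx * (1 - fy) * (1 - fz)
        + v[x0, y1, z0] * (1 - fx) * fy * (1 - fz)
        + v[x0, y0, z1] * (1 - fx) * (1 - fy) * fz
        + v[x1, y1, z0] * fx * fy * (1 - fz)
        + v[x1, y0, z1] * fx * (1 - fy) * fz
        + v[x0, y1, z1] * (1 - fx) * fy * fz
        + v[x1, y1, z1] * fx * fy * fz
    )
    if out_of_bounds == "nan":
        out = np.where(outside, np.nan, out)
    return out


def point_value(grid: DoseGrid, position) -> float:
    """Dose (Gy) at a physical position (mm) by trilinear interpolation.

    Raises if the position lies outside the voxel-center bounding box — no
    extrapolation is ever performed.
    """
    return float(trilinear(grid, np.asarray(position, dtype=float), out_of_bounds="error")[0])


def resample(grid: DoseGrid, new_spacing) -> DoseGrid:
    """Trilinear resampling onto a lattice with the requested pitch.

    The new lattice starts at the same origin and covers the same physical
    extent (the last sample may be clamped to the source bounding box, so no
    value is ever extrapolated).  Values never leave [min, max] of the source.
    """
    new_spacing = np.broadcast_to(np.asarray(new_spacing, dtype=float), (3,)).copy()
    if np.any(new_spacing <= 0):
        raise ValueError(f"new_spacing must be positive, got {tuple(new_spacing)}")
    lo, hi = grid.bounds
    extent = hi - lo
    n_new = np.maximum(np.floor(extent / new_spacing + 1e-9).astype(int) + 1, 1)
    # include a final clamped sample when the pitch does not divide the extent
    covered = (n_new - 1) * new_spacing
    n_new = n_new + (covered < extent - 1e-9)

    axes = [lo[a] + new_spacing[a] * np.arange(n_new[a]) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    vals = trilinear(grid, pts, out_of_bounds="clamp").reshape(tuple(n_new))
    return DoseGrid(
        values=vals,
        origin=tuple(lo),
        spacing=tuple(new_spacing),
        description=grid.description,
    )


def central_slab(grid: DoseGrid, axis: int = 1, position: float = 0.0) -> DoseGrid:
    """One-voxel-thick plane extracted at the coordinate nearest ``position``.

    Used to score planar (detector-style) gamma comparisons: the returned grid
    has size 1 along ``axis`` and keeps full physical geometry.
    """
    coords = grid.axis_coords(axis)
    k = int(np.argmin(np.abs(coords - position)))
    index = [slice(None)] * 3
    index[axis] = slice(k, k + 1)
    origin = list(grid.origin)
    origin[axis] = float(coords[k])
    return DoseGrid(
        values=grid.values[tuple(index)],
        origin=tuple(origin),
        spacing=grid.spacing,
        description=grid.description,
    )


# -- plain-text serialization ---------------------------------------------


def write_grid(grid: DoseGrid, path) -> None:
    """Write a grid as a single JSON document (text fixture format)."""
    doc = {
        "format": "protonqa-dose-grid",
        "version": 1,
        "origin_mm": list(grid.origin),
        "spacing_mm": list(grid.spacing),
        "shape": list(grid.shape),
        "description": grid.description,
        "values_gy": np.asarray(grid.values, dtype=float).ravel().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_grid(path) -> DoseGrid:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "protonqa-dose-grid":
        raise ValueError(f"{path}: not a protonqa dose-grid document")
    values = np.array(doc["values_gy"], dtype=float).reshape(doc["shape"])
    return DoseGrid(
        values=values,
        origin=tuple(doc["origin_mm"]),
        spacing=tuple(doc["spacing_mm"]),
        description=doc.get("description", ""),
    )
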