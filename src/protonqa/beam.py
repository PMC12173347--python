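"""Analytic proton pencil-beam model: range–energy rule and depth-dose curve.

The model is deliberately simple — a Bragg–Kleeman power law for range in
water, a Gaussian Bragg peak on top of a constant entrance plateau for the
integrated depth dose, and a linearly growing lateral Gaussian for the spot.
It stands in for the clinical beam data of a 70–220 MeV PBS machine at the
qualitative level needed by the QA pipeline; it makes no claim of dosimetric
accuracy (no nuclear halo, no heterogeneity, no straggling model beyond the
peak width parameter).

Depth-dose construction (relative dose, peak = 1, range ``R = alpha * E**p``
in cm, peak width ``s = peak_sigma_frac * R``):

* ``z <= R``:  ``entrance_ratio + (1 - entrance_ratio) * exp(-(z-R)^2 / 2 s^2)``
  — monotone non-decreasing from the entrance plateau to the single peak;
* ``z > R``:  ``exp(-(z-R)^2 / 2 (0.9 s)^2)`` — a slightly sharper distal
  Gaussian, continuous at the peak, below 1% of peak within ``3 s`` beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BeamModel", "bragg_range", "energy_for_range", "depth_dose", "lateral_sigma"]

ENERGY_MIN_MEV = 70.0
ENERGY_MAX_MEV = 220.0

# distal Gaussian is narrowed by this factor so dose < 1% of peak at 3 sigma
_DISTAL_NARROWING = 0.9


@dataclass(frozen=True)
class BeamModel:
    """Parameters of the analytic PBS beam.

    alpha, p
        Bragg–Kleeman coefficients, range(cm) = alpha * E(MeV)**p.  Defaults
        are the literature-standard water values (0.0022, 1.77).
    sigma0 : mm
        Lateral spot sigma at the phantom surface.
    sigma_growth : mm/cm
        Lateral sigma growth per cm of depth (multiple Coulomb scattering).
    peak_sigma_frac
        Gaussian Bragg-peak sigma as a fraction of range (straggling scale).
    entrance_ratio
        Entrance-to-peak dose ratio of the single-spot depth-dose curve.
    shifter_sigma_mm_per_cm : mm/cm
        Extra lateral sigma per cm of range-shifter water-equivalent thickness.
    """

    alpha: float = 0.0022
    p: float = 1.77
    sigma0: float = 4.0
    sigma_growth: float = 0.3
    peak_sigma_frac: float = 0.012
    entrance_ratio: float = 0.35
    shifter_sigma_mm_per_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 1.0 < self.p < 2.0:
            raise ValueError(f"range-energy exponent p={self.p} outside (1, 2)")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if not 0.2 < self.entrance_ratio < 0.5:
            raise ValueError(f"entrance_ratio {self.entrance_ratio} outside (0.2, 0.5)")
        if self.peak_sigma_frac <= 0:
            raise ValueError("peak_sigma_frac must be positive")


def _check_energy(energy_mev: float) -> float:
    energy_mev = float(energy_mev)
    if not ENERGY_MIN_MEV <= energy_mev <= ENERGY_MAX_MEV:
        raise ValueError(
            f"energy {energy_mev} MeV outside the machine range "
            f"[{ENERGY_MIN_MEV:.0f}, {ENERGY_MAX_MEV:.0f}] MeV"
        )
    return energy_mev


def bragg_range(energy_mev: float, model: BeamModel = BeamModel()) -> float:
    """Range in water (cm) by the Bragg–Kleeman rule, alpha * E**p."""
    return model.alpha * _check_energy(energy_mev) ** model.p


def energy_for_range(range_cm: float, model: BeamModel = BeamModel()) -> float:
    """Inverse of :func:`bragg_range`; raises if outside the machine range."""
    if range_cm <= 0:
        raise ValueError("range must be positive")
    energy = (range_cm / model.alpha) ** (1.0 / model.p)
    # tolerate float round-trip jitter at the machine limits
    energy = float(np.clip(energy, ENERGY_MIN_MEV, ENERGY_MAX_MEV)) if (
        abs(energy - ENERGY_MIN_MEV) < 1e-6 or abs(energy - ENERGY_MAX_MEV) < 1e-6
    ) else energy
    return _check_energy(energy)


def depth_dose(energy_mev: float, depth_cm, model: BeamModel = BeamModel()) -> np.ndarray:
    """Relative integrated depth dose (peak = 1) at water depth(s) in cm."""
    r = bragg_range(energy_mev, model)
    s = model.peak_sigma_frac * r
    z = np.asarray(depth_cm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    gauss = np.exp(-((z - r) ** 2) / (2 * s**2))
    proximal = model.entrance_ratio + (1 - model.entrance_ratio) * gauss
    distal = np.exp(-((z - r) ** 2) / (2 * (_DISTAL_NARROWING * s) ** 2))
    out = np.where(z <= r, proximal, distal)
    return out if out.ndim else float(out)


def lateral_sigma(depth_cm, model: BeamModel = BeamModel(), range_shifter_cm: float = 0.0):
    """Lateral spot sigma (mm) at phantom depth(s) in cm, with shifter inflation."""
    z = np.asarray(depth_cm, dtype=float)
    return model.sigma0 + model.sigma_growth * z + model.shifter_sigma_mm_per_cm * range_shifter_cm
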