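"""Independent brute-force gamma oracle for cross-checking the fast engine.

Deliberately naive: exhaustive minimum over every fine-step offset in the
search sphere, with evaluated-dose sampling by scipy's
RegularGridInterpolator rather than the package's own trilinear kernel.
"""

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def gamma_oracle(reference, evaluated, criteria):
    """Gamma map by exhaustive search; NaN below threshold or unevaluable."""
    ref_max = reference.values.max()
    threshold = criteria.threshold_percent / 100.0 * ref_max

    interp = RegularGridInterpolator(
        tuple(evaluated.axis_coords(a) for a in range(3)),
        evaluated.values,
        bounds_error=False,
        fill_value=np.nan,
    )

    step = criteria.dta_mm / criteria.fine_step_fraction
    radius = criteria.search_radius_factor * criteria.dta_mm
    k = int(np.floor(radius / step + 1e-9))
    axes = []
    for a in range(3):
        if evaluated.shape[a] > 1:
            axes.append(np.arange(-k, k + 1) * step)
        else:
            axes.append(np.array([0.0]))
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    offsets = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    d2 = (offsets**2).sum(axis=1)
    keep = d2 <= radius**2 + 1e-9
    offsets, d2 = offsets[keep], d2[keep]

    gamma = np.full(reference.shape, np.nan)
    dta2 = criteria.dta_mm**2
    for idx in np.argwhere(reference.values >= threshold):
        d_ref = reference.values[tuple(idx)]
        if criteria.normalization == "global":
            dnorm = criteria.dose_tol_percent / 100.0 * ref_max
        else:
            dnorm = criteria.dose_tol_percent / 100.0 * d_ref
        point = np.array(reference.origin) + idx * np.array(reference.spacing)
        vals = interp(point[None, :] + offsets)
        g2 = d2 / dta2 + ((vals - d_ref) / dnorm) ** 2
        g2 = g2[~np.isnan(g2)]
        if g2.size:
            gamma[tuple(idx)] = np.sqrt(g2.min())
    return gamma
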