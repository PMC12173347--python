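import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protonqa.grids import DoseGrid

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def smooth_random_grid(rng, shape=(20, 20, 10), spacing=(2.0, 2.0, 2.0), origin=(0.0, 0.0, 0.0)):
    """A smooth, strictly positive random dose grid (gamma-friendly)."""
    from scipy.ndimage import gaussian_filter

    v = gaussian_filter(rng.random(shape), sigma=2.0, mode="nearest")
    v = 0.2 + 1.8 * (v - v.min()) / max(np.ptp(v), 1e-12)
    return DoseGrid(values=v, origin=origin, spacing=spacing, description="random smooth")


@pytest.fixture
def grid_pair_factory(rng):
    """Pairs of (reference, mildly perturbed evaluated) smooth grids."""

    def make(shape=(20, 20, 10), spacing=(2.0, 2.0, 2.0)):
        ref = smooth_random_grid(rng, shape, spacing)
        noise = rng.normal(0.0, 0.015 * ref.values.max(), size=shape)
        shift = np.roll(ref.values, shift=1, axis=0)
        ev = np.clip(0.7 * ref.values + 0.3 * shift + noise, 0.0, None)
        return ref, DoseGrid(values=ev, origin=ref.origin, spacing=spacing)

    return make
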