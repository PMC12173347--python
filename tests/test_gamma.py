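"""Gamma-index engine unit and property tests."""

import numpy as np
import pytest

from protonqa.gamma import (
    GammaCriteria,
    GammaResult,
    gamma_map,
    passing_rate,
    point_dose_difference,
    recompute_passing_rate,
)
from protonqa.grids import DoseGrid

from gamma_oracle import gamma_oracle


class TestGammaMap:
    def test_identity_all_zero(self, grid_pair_factory):
        ref, _ = grid_pair_factory()
        res = gamma_map(ref, ref, GammaCriteria(3.0, 3.0))
        assert res.passing_rate == 100.0
        assert np.nanmax(res.gamma_values) == 0.0

    def test_uniform_plus_3pct_is_borderline(self):
        """A uniform field scaled by +3% under a 3% global criterion forces
        gamma = 1 everywhere (no gradient for DTA to exploit)."""
        ref = DoseGrid(np.full((12, 12, 6), 1.0), (0, 0, 0), (2, 2, 2))
        ev = DoseGrid(ref.values * 1.03, ref.origin, ref.spacing)
        res = gamma_map(ref, ev, GammaCriteria(3.0, 3.0))
        g = res.gamma_values[np.isfinite(res.gamma_values)]
        assert np.all(np.abs(g - 1.0) < 1e-9)
        assert res.passing_rate == 100.0  # ties at gamma = 1 pass

    def test_shift_by_dta_in_flat_region_passes(self):
        """Translating a flat-gradient region by exactly the DTA leaves
        gamma <= 1 there (the distance term alone reaches 1)."""
        z = np.linspace(0, 1, 40)
        vals = np.tile(1.0 + 0.5 * z, (12, 12, 1))
        ref = DoseGrid(vals, (0, 0, 0), (2, 2, 2))
        ev = DoseGrid(np.roll(vals, 1, axis=2), ref.origin, ref.spacing)  # 2 mm shift
        res = gamma_map(ref, ev, GammaCriteria(3.0, 2.0))
        interior = res.gamma_values[:, :, 5:-5]
        assert np.nanmax(interior) <= 1.0 + 1e-6

    def test_criteria_monotonicity(self, grid_pair_factory):
        """Loosening criteria never lowers the passing rate; the three
        criteria share one absolute fine-search step so sampling cannot
        break the ordering."""
        for _ in range(4):
            ref, ev = grid_pair_factory()
            rates = [
                gamma_map(ref, ev, crit).passing_rate
                for crit in (
                    GammaCriteria(3.0, 2.0, fine_step_fraction=10),
                    GammaCriteria(3.0, 3.0, fine_step_fraction=15),
                    GammaCriteria(5.0, 3.0, fine_step_fraction=15),
                )
            ]
            assert rates[0] <= rates[1] <= rates[2]

    def test_oracle_equivalence(self, grid_pair_factory):
        """Optimized shell search equals exhaustive brute force within 0.02
        gamma on random grid pairs (acceptance-grade cross-check at small n
        here; the full 20-pair version runs in the acceptance suite)."""
        crit = GammaCriteria(3.0, 3.0, search_radius_factor=2.0, fine_step_fraction=5)
        for _ in range(3):
            ref, ev = grid_pair_factory(shape=(12, 12, 8))
            fast = gamma_map(ref, ev, crit).gamma_values
            slow = gamma_oracle(ref, ev, crit)
            both = np.isfinite(fast) & np.isfinite(slow)
            assert both.any()
            assert np.abs(fast[both] - slow[both]).max() < 0.02

    def test_local_normalization_differs_from_global(self, grid_pair_factory):
        ref, ev = grid_pair_factory()
        g_global = gamma_map(ref, ev, GammaCriteria(3.0, 3.0, normalization="global"))
        g_local = gamma_map(ref, ev, GammaCriteria(3.0, 3.0, normalization="local"))
        # local criterion is tighter wherever dose < max, so rate cannot rise
        assert g_local.passing_rate <= g_global.passing_rate

    def test_no_overlap_rejected(self):
        a = DoseGrid(np.ones((4, 4, 4)), (0, 0, 0), (1, 1, 1))
        b = DoseGrid(np.ones((4, 4, 4)), (100, 100, 100), (1, 1, 1))
        with pytest.raises(ValueError, match="overlap"):
            gamma_map(a, b, GammaCriteria())

    def test_zero_dose_reference_rejected(self):
        """A reference with no dose has nothing above any threshold (with a
        sub-100% threshold the hottest voxel otherwise always qualifies)."""
        ref = DoseGrid(np.zeros((4, 4, 4)), (0, 0, 0), (1, 1, 1))
        with pytest.raises(ValueError, match="nothing to evaluate"):
            gamma_map(ref, ref, GammaCriteria())

    def test_planar_reference_against_volume(self, grid_pair_factory):
        """A one-voxel-thick reference plane scores against the 3D volume."""
        ref, ev = grid_pair_factory()
        plane = DoseGrid(ref.values[:, 9:10, :], (0, 18.0, 0), ref.spacing)
        res = gamma_map(plane, ev, GammaCriteria(3.0, 3.0))
        assert 0 < res.n_evaluated <= plane.values.size
        assert 0 <= res.passing_rate <= 100


class TestPassingRate:
    def make_result(self, gammas):
        g = np.array(gammas, dtype=float).reshape(1, 1, -1)
        finite = np.isfinite(g)
        return GammaResult(
            gamma_values=g,
            criteria=GammaCriteria(),
            n_evaluated=int(finite.sum()),
            n_passed=int((g[finite] <= 1.0).sum()),
        )

    def test_two_of_three(self):
        assert passing_rate(self.make_result([0.5, 1.0, 1.5])) == pytest.approx(66.7, abs=0.05)

    def test_all_pass(self):
        assert passing_rate(self.make_result([0.1, 0.9, 1.0])) == 100.0

    def test_recount_consistency(self, grid_pair_factory):
        ref, ev = grid_pair_factory(shape=(10, 10, 6))
        res = gamma_map(ref, ev, GammaCriteria(3.0, 3.0, fine_step_fraction=5))
        assert recompute_passing_rate(res) == pytest.approx(res.passing_rate, abs=1e-12)


class TestPointDoseDifference:
    @pytest.mark.parametrize(
        "measured, calculated, expected", [(2.00, 2.00, 0.0), (2.00, 2.02, 1.0), (2.0, 1.9, -5.0)]
    )
    def test_formula(self, measured, calculated, expected):
        assert point_dose_difference(measured, calculated) == pytest.approx(expected)

    def test_zero_measured_rejected(self):
        with pytest.raises(ValueError):
            point_dose_difference(0.0, 2.0)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(dose_tol_percent=0),
        dict(dta_mm=-1),
        dict(threshold_percent=100),
        dict(normalization="other"),
        dict(fine_step_fraction=2),
    ],
)
def test_criteria_validation(kwargs):
    with pytest.raises(ValueError):
        GammaCriteria(**kwargs)
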