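"""Plan builders, the dose engine and the perturbation model."""

import numpy as np
import pytest

from protonqa.beam import BeamModel, bragg_range, depth_dose
from protonqa.grids import DoseGrid, point_value
from protonqa.plans import (
    Layer,
    PerturbSpec,
    PlanSpec,
    build_cube_plan,
    build_single_energy_plan,
    compute_dose,
    perturb,
)

MODEL = BeamModel()


class TestSingleEnergyPlan:
    def test_default_spot_count_is_1681(self):
        plan = build_single_energy_plan(160.0)
        assert len(plan.layers) == 1
        assert len(plan.layers[0].weights) == 41 * 41 == 1681

    def test_5mm_spacing_gives_441(self):
        plan = build_single_energy_plan(160.0, field_cm=10.0, spacing_mm=5.0)
        assert len(plan.layers[0].weights) == 21 * 21 == 441

    def test_equal_weights(self):
        w = build_single_energy_plan(100.0).layers[0].weights
        assert w.max() / w.min() == 1.0

    def test_spacing_larger_than_field_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_single_energy_plan(100.0, field_cm=1.0, spacing_mm=20.0)

    def test_normalization_contract(self):
        assert build_single_energy_plan(70.0).normalization == ((0.0, 0.0, 20.0), 2.0)


def central_axis_sobp(plan, z_cm):
    """Layer-weighted depth dose on the central axis (flatness oracle)."""
    return sum(
        l.weights[0] * depth_dose(l.energy_mev, z_cm + plan.range_shifter_cm, MODEL)
        for l in plan.layers
    )


class TestCubePlan:
    @pytest.mark.parametrize("cube", [3.0, 5.0, 7.0, 10.0, 15.0])
    @pytest.mark.parametrize("depth", [10.0, 15.0, 20.0])
    def test_sobp_flat_within_3pct(self, cube, depth):
        """Central-axis dose across the target stays within +-3% of its mean
        for every cube/depth combination of the validation matrix."""
        plan = build_cube_plan(cube, depth, "auto", MODEL)
        z = np.arange(depth - cube / 2, depth + cube / 2 + 1e-9, 0.05)
        axial = central_axis_sobp(plan, z)
        assert np.abs(axial / axial.mean() - 1).max() < 0.03

    def test_more_layers_for_larger_cube(self):
        assert len(build_cube_plan(15.0, 15.0).layers) > len(build_cube_plan(3.0, 15.0).layers)

    def test_shifter_is_pure_pullback_of_layers(self):
        """A 5 cm shifter plan uses the same water ranges as an unshifted plan
        5 cm deeper, so the shifted SOBP equals the deep SOBP pulled back."""
        shifted = build_cube_plan(10.0, 15.0, 5.0, MODEL)
        deep = build_cube_plan(10.0, 20.0, 0.0, MODEL)
        e_shifted = sorted(l.energy_mev for l in shifted.layers)
        e_deep = sorted(l.energy_mev for l in deep.layers)
        assert np.allclose(e_shifted, e_deep, rtol=1e-9)

    def test_auto_shifter_for_shallow_large_cube(self):
        plan = build_cube_plan(15.0, 10.0, "auto", MODEL)
        assert plan.range_shifter_cm == 2.0  # 2.5 cm proximal edge needs pullback

    def test_infeasible_without_shifter(self):
        with pytest.raises(ValueError, match="70 MeV minimum"):
            build_cube_plan(15.0, 10.0, 0.0, MODEL)


class TestComputeDose:
    GEOM = dict(origin_mm=(-30, -30, 0), spacing_mm=(2, 2, 2), shape=(31, 31, 60))

    def small_plan(self, weights=None):
        plan = build_single_energy_plan(100.0, field_cm=4.0, spacing_mm=5.0)
        if weights is not None:
            layer = plan.layers[0]
            plan = PlanSpec(
                layers=[Layer(layer.energy_mev, layer.positions_mm, weights)],
                normalization=None,
            )
        return plan

    def test_normalization_point(self):
        grid = compute_dose(self.small_plan(), **self.GEOM, model=MODEL)
        assert point_value(grid, (0, 0, 20)) == pytest.approx(2.0, abs=1e-9)

    def test_linearity_in_weights(self, rng):
        w = rng.uniform(0.5, 2.0, 81)
        g1 = compute_dose(self.small_plan(w), **self.GEOM, model=MODEL)
        g2 = compute_dose(self.small_plan(2 * w), **self.GEOM, model=MODEL)
        assert np.allclose(g2.values, 2 * g1.values, rtol=1e-9)

    def test_separable_and_general_paths_agree(self, rng):
        """Uniform-weight grids take the fast separable path; nearly-uniform
        weights take the per-spot path — both must give the same dose."""
        w_uniform = np.full(81, 1.0)
        g_fast = compute_dose(self.small_plan(w_uniform), **self.GEOM, model=MODEL)
        w_almost = w_uniform.copy()
        w_almost[0] *= 1 + 1e-12  # defeats the uniformity check only
        g_slow = compute_dose(self.small_plan(w_almost), **self.GEOM, model=MODEL)
        assert np.allclose(g_fast.values, g_slow.values, rtol=1e-6)

    def test_peak_at_bragg_range(self):
        plan = build_single_energy_plan(70.0, field_cm=4.0, spacing_mm=5.0)
        grid = compute_dose(plan, (-30, -30, 0), (2, 2, 1), (31, 31, 60), MODEL)
        axis = grid.values[15, 15, :]
        z_peak = grid.axis_coords(2)[np.argmax(axis)]
        assert z_peak == pytest.approx(bragg_range(70.0, MODEL) * 10, abs=1.0)

    def test_translation_equivariance(self):
        plan = self.small_plan(np.full(81, 1.0))
        moved = PlanSpec(
            layers=[
                Layer(l.energy_mev, l.positions_mm + np.array([4.0, 0.0]), l.weights)
                for l in plan.layers
            ],
            normalization=None,
        )
        g = compute_dose(plan, **self.GEOM, model=MODEL)
        gm = compute_dose(moved, **self.GEOM, model=MODEL)
        # shifting all spots by 2 voxels shifts the dose by 2 voxels
        assert np.allclose(gm.values[2:, :, :], g.values[:-2, :, :], rtol=1e-9, atol=1e-12)

    def test_grid_not_covering_spots_raises(self):
        with pytest.raises(ValueError, match="spot positions"):
            compute_dose(self.small_plan(), (-5, -5, 0), (2, 2, 2), (6, 6, 60), MODEL)


class TestPerturb:
    def grid(self, rng):
        return DoseGrid(rng.random((12, 12, 12)) * 2, (0, 0, 0), (2, 2, 2))

    def test_zero_spec_is_identity_bit_for_bit(self, rng):
        g = self.grid(rng)
        assert perturb(g, PerturbSpec()) is g

    def test_pure_dose_scale(self, rng):
        g = self.grid(rng)
        out = perturb(g, PerturbSpec(dose_scale_percent=3.0))
        assert np.array_equal(out.values, g.values * 1.03)

    def test_shift_of_uniform_interior(self):
        g = DoseGrid(np.full((15, 15, 15), 1.5), (0, 0, 0), (2, 2, 2))
        out = perturb(g, PerturbSpec(shift_mm=(5.0, 0.0, 0.0)))
        assert np.allclose(out.values[4:, :, :], 1.5, atol=1e-12)

    def test_seed_determinism(self, rng):
        g = self.grid(rng)
        spec = PerturbSpec(noise_percent=2.0, seed=99)
        a, b = perturb(g, spec), perturb(g, spec)
        assert np.array_equal(a.values, b.values)

    def test_range_error_moves_distal_edge(self):
        z = np.arange(20.0)
        vals = np.tile(np.where(z < 12, 1.0, 0.0), (5, 5, 1))
        g = DoseGrid(vals, (0, 0, 0), (2, 2, 2))
        out = perturb(g, PerturbSpec(range_error_mm=4.0))
        # entrance unchanged, distal edge pushed deeper
        assert np.allclose(out.values[:, :, 0], 1.0)
        assert out.values[2, 2, 12] > g.values[2, 2, 12]

    def test_dose_stays_non_negative(self, rng):
        g = self.grid(rng)
        out = perturb(g, PerturbSpec(noise_percent=50.0, seed=1))
        assert out.values.min() >= 0.0
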