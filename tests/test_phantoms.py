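"""Phantom generators: ground-truth accounting, determinism, tumor model."""

import numpy as np
import pytest

import osteofabric as of

VOX = 12.0


class TestPlatePhantom:
    @pytest.mark.parametrize(
        "thickness,spacing,expected",
        [(2, 2, 0.5), (1, 3, 0.25)],
    )
    def test_period_aligned_bvtv_is_exact(self, thickness, spacing, expected):
        vol, truth = of.make_plate_phantom(
            (64, 64, 64), VOX, thickness, spacing, normal_axis=0
        )
        assert truth.true_bvtv == expected
        # brute-force voxel count agrees exactly
        assert (vol.values > 0).sum() == expected * vol.values.size

    def test_truth_matches_voxel_count_off_period(self):
        vol, truth = of.make_plate_phantom((30, 8, 8), VOX, 3, 4, normal_axis=0)
        assert truth.true_bvtv == (vol.values > 0).mean()

    def test_shape_smaller_than_period_rejected(self):
        with pytest.raises(ValueError):
            of.make_plate_phantom((3, 16, 16), VOX, 2, 2, normal_axis=0)

    def test_normal_axis_permutation(self):
        v0, _ = of.make_plate_phantom((16, 16, 16), VOX, 2, 2, normal_axis=0)
        v1, _ = of.make_plate_phantom((16, 16, 16), VOX, 2, 2, normal_axis=1)
        assert np.array_equal(np.swapaxes(v0.values, 0, 1), v1.values)


class TestBooleanPhantom:
    def test_achieved_bvtv_within_tolerance(self, boolean_phantom):
        vol, truth = boolean_phantom
        achieved = (vol.values > 0).mean()
        assert truth.true_bvtv == achieved
        assert 0.28 <= achieved <= 0.32

    def test_same_seed_bit_identical(self):
        a, _ = of.make_isotropic_boolean((32, 32, 32), VOX, 4, 0.3, seed=5)
        b, _ = of.make_isotropic_boolean((32, 32, 32), VOX, 4, 0.3, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            of.make_isotropic_boolean((32, 32, 32), VOX, 4, 0.0, seed=0)
        with pytest.raises(ValueError):
            of.make_isotropic_boolean((32, 32, 32), VOX, 1.0, 0.3, seed=0)


class TestCorticalCylinder:
    def test_solid_rod_is_contractible(self):
        vol, truth = of.make_cortical_cylinder((20, 32, 32), VOX, 12, 0, axis=0)
        assert of.euler_characteristic(vol.values > 0) == 1
        assert truth.betti1 == 0

    def test_hollow_tube_has_one_loop(self, hollow_cylinder):
        vol, truth = hollow_cylinder
        # chi = beta0 - beta1 + beta2 = 1 - 1 + 0 for an annular tube
        assert of.euler_characteristic(vol.values > 0) == 0
        assert truth.betti1 == 1

    def test_axis_permutation_symmetry(self):
        v0, _ = of.make_cortical_cylinder((20, 32, 32), VOX, 10, 6, axis=0)
        v1, _ = of.make_cortical_cylinder((32, 20, 32), VOX, 10, 6, axis=1)
        assert np.array_equal(np.swapaxes(v0.values, 0, 1), v1.values)

    def test_bvtv_close_to_analytic_annulus(self):
        vol, truth = of.make_cortical_cylinder((20, 64, 64), VOX, 24, 18, axis=0)
        analytic = np.pi * (24**2 - 18**2) / (64 * 64)
        assert truth.true_bvtv == pytest.approx(analytic, rel=0.1)

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            of.make_cortical_cylinder((20, 32, 32), VOX, 10, 12, axis=0)
        with pytest.raises(ValueError):
            of.make_cortical_cylinder((20, 32, 32), VOX, 40, 10, axis=0)


class TestMetaphysisLike:
    def test_compartment_truth_partitions_bone(self, metaphysis_phantom):
        _, truth = metaphysis_phantom
        assert not (truth.cortical_mask & truth.trabecular_mask).any()
        assert np.array_equal(
            truth.cortical_mask | truth.trabecular_mask, truth.bone_mask
        )

    def test_element_labels_cover_trabecular_exactly(self, metaphysis_phantom):
        _, truth = metaphysis_phantom
        assert np.array_equal(truth.element_labels > 0, truth.trabecular_mask)

    def test_composite_bvtv_is_sum_of_compartments(self, metaphysis_phantom):
        _, truth = metaphysis_phantom
        assert truth.true_bvtv == pytest.approx(
            truth.cortical_mask.mean() + truth.trabecular_mask.mean(), abs=1e-12
        )

    def test_lattice_slices_restrict_trabecular_extent(self):
        _, truth = of.make_metaphysis_like(
            (40, 64, 64), VOX, lattice_slices=(0, 20), seed=0
        )
        assert truth.trabecular_mask[:20].any()
        assert not truth.trabecular_mask[20:].any()


class TestApplyTumor:
    def test_all_zero_parameters_is_identity(self, metaphysis_phantom):
        vol, truth = metaphysis_phantom
        out = of.apply_tumor(vol, truth, of.TumorParams(0.0, 0.0, False, seed=1))
        assert np.array_equal(out.values, vol.values)

    def test_full_lysis_removes_all_trabecular_bone(self, metaphysis_phantom):
        vol, truth = metaphysis_phantom
        out = of.apply_tumor(vol, truth, of.TumorParams(1.0, 0.0, seed=1))
        assert (out.values[truth.trabecular_mask] > 0).sum() == 0
        # the shell survives untouched
        assert np.array_equal(
            out.values[truth.cortical_mask], vol.values[truth.cortical_mask]
        )

    def test_interior_bone_non_increasing_in_lysis(self, metaphysis_phantom):
        vol, truth = metaphysis_phantom
        counts = [
            (of.apply_tumor(vol, truth, of.TumorParams(f, 0.0, seed=2)).values > 0).sum()
            for f in (0.0, 0.3, 0.6, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_woven_strictly_increases_bone(self, metaphysis_phantom):
        vol, truth = metaphysis_phantom
        base = of.apply_tumor(vol, truth, of.TumorParams(0.0, 0.0, seed=3))
        woven = of.apply_tumor(vol, truth, of.TumorParams(0.0, 0.3, seed=3))
        assert (woven.values > 0).sum() > (base.values > 0).sum()

    def test_breach_opens_cortical_window(self, metaphysis_phantom):
        vol, truth = metaphysis_phantom
        out = of.apply_tumor(vol, truth, of.TumorParams(0.0, 0.0, True, seed=4))
        assert (out.values[truth.cortical_mask] == 0).sum() > 0

    def test_deterministic_under_seed(self, metaphysis_phantom):
        vol, truth = metaphysis_phantom
        p = of.TumorParams(0.5, 0.4, True, seed=7)
        a = of.apply_tumor(vol, truth, p)
        b = of.apply_tumor(vol, truth, p)
        assert np.array_equal(a.values, b.values)

    def test_requires_compartment_truth(self, plate_phantom):
        vol, truth = plate_phantom
        with pytest.raises(ValueError):
            of.apply_tumor(vol, truth, of.TumorParams(0.5, 0.0, seed=0))


class TestAddNoise:
    def test_sigma_zero_is_identity(self, plate_phantom):
        vol, _ = plate_phantom
        assert np.array_equal(of.add_noise(vol, 0.0, seed=1).values, vol.values)

    def test_noise_is_zero_mean(self, plate_phantom):
        vol, _ = plate_phantom
        sigma = 50.0
        noisy = of.add_noise(vol, sigma, seed=2)
        delta = noisy.values - vol.values
        n = delta.size
        assert n >= 1e5
        assert abs(delta.mean()) < 3 * sigma / np.sqrt(n)

    def test_same_seed_same_noise_field(self, plate_phantom):
        vol, _ = plate_phantom
        a = of.add_noise(vol, 30.0, seed=3)
        b = of.add_noise(vol, 30.0, seed=3)
        assert np.array_equal(a.values, b.values)
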