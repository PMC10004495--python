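"""Node grid, densification, SSD cost, solver behaviour, and warping."""

import numpy as np
import pytest
from scipy.ndimage import label as cc_label

from musclereg.errors import ConfigurationError, CoverageError
from musclereg.phantom import PhantomSpec, make_limb_phantom, make_random_field
from musclereg.registration import (
    NodeDisplacementField,
    RegistrationConfig,
    densify,
    load_field,
    make_node_grid,
    register,
    save_field,
    ssd_cost,
    warp_image,
    warp_labels,
)
from musclereg.volumes_io import GreyVolume, LabelVolume


def _grey(data, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return GreyVolume(np.asarray(data, float), spacing, origin)


class TestNodeGrid:
    def test_counts_and_zero_init(self):
        vol = _grey(np.zeros((64, 64, 64)))
        field = make_node_grid(vol, 5.0)
        assert all(m >= 14 for m in field.node_shape)
        assert not field.displacements.any()

    def test_nodal_spacing_larger_than_image_rejected(self):
        vol = _grey(np.zeros((64, 64, 64)))
        with pytest.raises(ConfigurationError):
            make_node_grid(vol, 1000.0)

    @pytest.mark.parametrize("shape", [(16, 24, 40), (33, 17, 21)])
    def test_grid_extent_contains_image_extent(self, shape, rng):
        vol = _grey(rng.uniform(0, 1, shape), spacing=(1.1, 0.9, 2.0), origin=(-3, 4, 7))
        field = make_node_grid(vol, 5.0)
        lo = field.node_origin
        hi = field.node_origin + (np.asarray(field.node_shape) - 1) * field.node_spacing
        assert np.all(lo < vol.origin)
        assert np.all(hi > vol.origin + vol.extent_mm())


class TestDensify:
    def test_constant_node_field_densifies_to_constant(self):
        vol = _grey(np.zeros((12, 12, 12)))
        field = make_node_grid(vol, 4.0)
        field.displacements[...] = [1.5, -2.0, 0.25]
        dense = densify(field, vol)
        np.testing.assert_allclose(dense, np.broadcast_to([1.5, -2.0, 0.25], dense.shape))

    def test_affine_node_field_is_interpolated_exactly(self):
        vol = _grey(np.zeros((12, 12, 12)))
        field = make_node_grid(vol, 4.0)
        ax = [field.node_origin[d] + field.node_spacing * np.arange(field.node_shape[d]) for d in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        field.displacements[..., 0] = 0.1 * X + 0.2 * Y - 0.05 * Z + 1
        field.displacements[..., 1] = -0.03 * X + 0.07 * Z
        field.displacements[..., 2] = 0.01 * Y - 2
        dense = densify(field, vol)
        pts = vol.voxel_centres_world()
        expected = np.stack(
            [
                0.1 * pts[..., 0] + 0.2 * pts[..., 1] - 0.05 * pts[..., 2] + 1,
                -0.03 * pts[..., 0] + 0.07 * pts[..., 2],
                0.01 * pts[..., 1] - 2,
            ],
            axis=-1,
        )
        np.testing.assert_allclose(dense, expected, atol=1e-6)

    def test_zero_field_zero_dense(self):
        vol = _grey(np.zeros((8, 8, 8)))
        dense = densify(make_node_grid(vol, 3.0), vol)
        assert not dense.any()

    def test_coverage_violation_raises(self):
        vol = _grey(np.zeros((8, 8, 8)))
        field = make_node_grid(vol, 3.0)
        far = _grey(np.zeros((8, 8, 8)), origin=(100, 100, 100))
        with pytest.raises(CoverageError):
            densify(field, far)


class TestSSDCost:
    def test_identical_images_zero_cost(self, rng):
        vol = _grey(rng.uniform(0, 10, (10, 10, 10)))
        field = make_node_grid(vol, 4.0)
        assert ssd_cost(vol, vol, field) == 0.0

    def test_constant_images_closed_form(self):
        c1, c2, n = 7.0, 3.0, 10**3
        f = _grey(np.full((10, 10, 10), c1))
        m = _grey(np.full((10, 10, 10), c2))
        field = make_node_grid(f, 4.0)
        assert ssd_cost(f, m, field) == pytest.approx(n * (c1 - c2) ** 2, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        from scipy.ndimage import map_coordinates

        f = _grey(rng.uniform(0, 10, (8, 8, 8)))
        m = _grey(rng.uniform(0, 10, (8, 8, 8)))
        field = make_node_grid(f, 3.0)
        field.displacements[:] = rng.uniform(-1, 1, field.displacements.shape)
        dense = densify(field, f)
        expected = 0.0
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    tgt = np.array([i, j, k], float) + dense[i, j, k]
                    mv = map_coordinates(
                        m.data, tgt.reshape(3, 1), order=1, mode="constant", cval=0.0
                    )[0]
                    expected += (f.data[i, j, k] - mv) ** 2
        assert ssd_cost(f, m, field) == pytest.approx(expected, rel=1e-8)


class TestRegister:
    def test_self_registration_returns_near_zero_field(self, small_phantom):
        grey, _ = small_phantom
        cfg = RegistrationConfig(max_iterations=10)
        field = register(grey, grey, cfg)
        dense = densify(field, grey)
        body = grey.data > 30
        assert np.abs(dense[body]).max() < 0.1

    def test_translation_recovery(self):
        grey, _ = make_limb_phantom(PhantomSpec(shape=(48, 48, 24), body_radius_mm=18, seed=8))
        shift = np.array([2.0, 1.0, 0.0])
        moved = _grey(np.roll(grey.data, (-2, -1), axis=(0, 1)), grey.spacing, grey.origin)
        field = register(grey, moved, RegistrationConfig(pyramid_levels=2))
        dense = densify(field, grey)
        body = grey.data > 30
        mean_rec = dense[body].mean(axis=0)
        assert np.all(np.abs(mean_rec + shift) < 0.5) or np.all(np.abs(mean_rec - shift) < 0.5)

    def test_cost_history_non_increasing_within_levels(self, small_phantom):
        grey, _ = small_phantom
        truth = make_random_field(grey, 5.0, 2.0, seed=21)
        fixed = warp_image(grey, truth)
        field = register(fixed, grey, RegistrationConfig(max_iterations=15))
        by_level = {}
        for h in field.cost_history:
            by_level.setdefault(h["level"], []).append(h["cost"])
        for costs in by_level.values():
            assert all(b <= a for a, b in zip(costs, costs[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            RegistrationConfig(tolerance=0.0)
        with pytest.raises(ConfigurationError):
            RegistrationConfig(nodal_spacing_mm=-1.0)
        with pytest.raises(ConfigurationError):
            RegistrationConfig(smoothing_coefficient=-0.5)


class TestWarp:
    def test_zero_field_is_identity(self, small_phantom):
        grey, labels = small_phantom
        field = make_node_grid(grey, 5.0)
        np.testing.assert_array_equal(warp_image(grey, field).data, grey.data)
        np.testing.assert_array_equal(warp_labels(labels, field).data, labels.data)

    def test_integer_translation_matches_shift_oracle(self, rng):
        data = rng.uniform(0, 10, (12, 12, 12))
        vol = _grey(data)
        field = make_node_grid(vol, 4.0)
        field.displacements[...] = [2.0, 0.0, 0.0]  # pull from x+2
        out = warp_image(vol, field)
        np.testing.assert_allclose(out.data[:10], data[2:], atol=1e-12)

    def test_constant_image_stays_constant_in_domain(self):
        vol = _grey(np.full((12, 12, 12), 5.0))
        field = make_node_grid(vol, 4.0)
        field.displacements[...] = [0.5, -0.5, 0.25]  # stays in-domain for interior
        out = warp_image(vol, field)
        np.testing.assert_allclose(out.data[2:-2, 2:-2, 2:-2], 5.0)

    def test_label_translation_matches_shift_oracle(self):
        data = np.zeros((12, 12, 12), dtype=np.int32)
        data[4:8, 4:8, 4:8] = 3
        lab = LabelVolume(data, (1, 1, 1), (0, 0, 0), {3: "m"})
        vol = _grey(np.zeros((12, 12, 12)))
        field = make_node_grid(vol, 4.0)
        field.displacements[...] = [0.0, 1.0, 0.0]
        out = warp_labels(lab, field)
        np.testing.assert_array_equal(out.data[:, :11], data[:, 1:])

    def test_labels_never_invented(self, small_phantom):
        grey, labels = small_phantom
        field = make_random_field(grey, 5.0, 2.5, seed=3)
        out = warp_labels(labels, field)
        assert set(np.unique(out.data)) <= set(np.unique(labels.data))

    def test_sphere_stays_connected_under_smooth_field(self):
        idx = np.indices((24, 24, 24)) - 11.5
        sphere = (np.sqrt((idx**2).sum(axis=0)) <= 7).astype(np.int32)
        lab = LabelVolume(sphere, (1, 1, 1), (0, 0, 0), {1: "s"})
        vol = _grey(sphere * 100.0)
        field = make_random_field(vol, 6.0, 2.0, seed=5)
        out = warp_labels(lab, field)
        _, n = cc_label(out.data == 1)
        assert n == 1


class TestFieldIO:
    def test_round_trip(self, tmp_path, small_phantom):
        grey, _ = small_phantom
        field = make_random_field(grey, 5.0, 2.0, seed=9)
        save_field(field, tmp_path / "f.nii.gz")
        back = load_field(tmp_path / "f.nii.gz")
        np.testing.assert_allclose(back.displacements, field.displacements)
        assert back.target_shape == tuple(field.target_shape)
        np.testing.assert_allclose(back.node_origin, field.node_origin)
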