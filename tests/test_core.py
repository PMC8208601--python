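"""Displacement-field algebra, NMI and resampling against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sct4d.core import (
    DisplacementField,
    Grid,
    GridMismatchError,
    ImageVolume,
    compose_fields,
    invert_field,
    load_field,
    load_volume,
    nmi,
    resample_to_grid,
    save_field,
    save_volume,
    warp_image,
)
from conftest import (
    gaussian_blob_image,
    sinusoid_field,
    smooth_random_field,
    translation_field,
)


class TestImageVolume:
    def test_ct_values_clamped_to_hu_range(self):
        vol = ImageVolume(np.array([[[-2000.0, 5000.0]]]), (1, 1, 1), modality="ct_hu")
        assert vol.values.min() == -1024 and vol.values.max() == 3071

    def test_rejects_nonpositive_spacing_and_nonfinite(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((2, 2, 2)), (1, 0, 1))
        with pytest.raises(ValueError):
            ImageVolume(np.full((2, 2, 2), np.nan), (1, 1, 1))

    def test_smooth_field_requires_positive_jacobian(self):
        # a fold: u_z = -2*z collapses the mapping
        g = Grid((8, 8, 8), (1, 1, 1))
        u = np.zeros(g.shape + (3,))
        u[..., 2] = -2.0 * np.arange(8)[None, None, :]
        with pytest.raises(ValueError):
            DisplacementField(u, g.spacing, smooth=True)


class TestWarp:
    def test_zero_field_is_identity(self, ramp_image):
        out = warp_image(ramp_image, DisplacementField.zero(ramp_image.grid))
        np.testing.assert_array_equal(out.values, ramp_image.values)

    def test_constant_image_invariant_under_smooth_field(self):
        img = ImageVolume(np.full((16, 16, 16), 7.0), (2, 2, 2))
        fld = sinusoid_field(img.grid, amplitude=2.0, period=40.0)
        out = warp_image(img, fld)
        interior = out.values[:, :, 2:-2]
        np.testing.assert_allclose(interior, 7.0, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(t=st.floats(-6.0, 6.0))
    def test_translated_ramp_matches_analytic_sampling(self, t):
        shape, sp = (8, 8, 20), (2.0, 2.0, 2.0)
        z = np.arange(shape[2]) * sp[2]
        img = ImageVolume(np.broadcast_to(z, shape).copy(), sp)
        fld = translation_field(img.grid, (0, 0, t))
        out = warp_image(img, fld)
        expected = np.clip(z + t, None, z[-1])  # linear interp clamps at border
        in_domain = (z + t >= 0) & (z + t <= z[-1])
        np.testing.assert_allclose(
            out.values[4, 4, in_domain], expected[in_domain], atol=1e-9
        )

    def test_grid_mismatch_raises(self, ramp_image):
        other = DisplacementField.zero(Grid((4, 4, 4), (1, 1, 1)))
        with pytest.raises(GridMismatchError):
            warp_image(ramp_image, other)

    def test_ct_fill_value_is_air(self):
        img = ImageVolume(np.zeros((6, 6, 6)), (2, 2, 2), modality="ct_hu")
        fld = translation_field(img.grid, (0, 0, 50.0))
        out = warp_image(img, fld)
        assert out.values[3, 3, 3] == -1000.0


class TestCompose:
    def test_zero_then_field_is_field(self, ramp_image):
        u = sinusoid_field(ramp_image.grid, 3.0, 60.0)
        composed = compose_fields(DisplacementField.zero(ramp_image.grid), u)
        np.testing.assert_allclose(composed.vectors, u.vectors, atol=1e-12)

    def test_translations_add(self):
        g = Grid((10, 10, 10), (2, 2, 2))
        c = compose_fields(
            translation_field(g, (1, 0, 2)), translation_field(g, (0, -1, 1))
        )
        np.testing.assert_allclose(c.vectors[..., 0], 1.0)
        np.testing.assert_allclose(c.vectors[..., 1], -1.0)
        np.testing.assert_allclose(c.vectors[..., 2], 3.0)

    def test_composed_warp_matches_sequential_warps(self):
        rng = np.random.default_rng(5)
        img = gaussian_blob_image()
        u1 = smooth_random_field(img.grid, rng, amplitude=3.0)
        u2 = smooth_random_field(img.grid, rng, amplitude=3.0)
        sequential = warp_image(warp_image(img, u1), u2)
        oneshot = warp_image(img, compose_fields(u1, u2))
        # bound: twice the linear-interpolation error of the sequential path
        spacing = np.asarray(img.spacing)
        grad = np.abs(np.gradient(img.values, *img.spacing)).max()
        bound = 2 * grad * spacing.max()
        diff = np.abs(sequential.values - oneshot.values)
        assert diff.max() <= bound
        # warp/compose agreement on >= 95% of in-domain voxels at a
        # much tighter tolerance
        tight = 0.02 * img.values.max()
        assert (diff < tight).mean() >= 0.95


class TestInvert:
    def test_constant_translation_inverts_to_negation(self):
        g = Grid((12, 12, 12), (2, 2, 2))
        inv = invert_field(translation_field(g, (2.0, -1.0, 3.0)))
        np.testing.assert_allclose(inv.vectors[..., 0], -2.0, atol=0.02)
        np.testing.assert_allclose(inv.vectors[..., 2], -3.0, atol=0.02)

    def test_zero_field_inverts_to_zero(self):
        g = Grid((8, 8, 8), (1, 1, 1))
        inv = invert_field(DisplacementField.zero(g))
        assert np.abs(inv.vectors).max() == 0.0

    def test_sinusoid_roundtrip_below_tenth_voxel(self):
        g = Grid((24, 24, 40), (3.0, 3.0, 3.0))
        fld = sinusoid_field(g, amplitude=5.0, period=100.0)
        inv = invert_field(fld)
        residual = compose_fields(fld, inv).max_magnitude_mm()
        assert residual < 0.1 * min(g.spacing)

    def test_nonconvergence_warns_not_silent(self):
        g = Grid((8, 8, 16), (1, 1, 1))
        fld = sinusoid_field(g, amplitude=6.0, period=12.0)  # |grad u| > 1
        with pytest.warns(RuntimeWarning):
            invert_field(fld, max_iter=3)


class TestNMI:
    def test_identical_images_score_two(self, ramp_image):
        assert nmi(ramp_image, ramp_image) == pytest.approx(2.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = ImageVolume(rng.uniform(size=(16, 16, 16)), (1, 1, 1))
        b = ImageVolume(rng.uniform(size=(16, 16, 16)), (1, 1, 1))
        assert nmi(a, b) == pytest.approx(nmi(b, a), rel=1e-12)

    def test_independent_noise_approaches_one(self):
        rng = np.random.default_rng(42)
        a = ImageVolume(rng.uniform(size=(64, 64, 64)), (1, 1, 1))
        b = ImageVolume(rng.uniform(size=(64, 64, 64)), (1, 1, 1))
        assert nmi(a, b, bins=32) == pytest.approx(1.0, abs=0.02)

    def test_invariant_under_bin_relabelling(self):
        rng = np.random.default_rng(1)
        a = ImageVolume(rng.uniform(size=(20, 20, 20)), (1, 1, 1))
        b_vals = rng.integers(0, 8, size=(20, 20, 20)).astype(float)
        b = ImageVolume(b_vals, (1, 1, 1))
        # bijective relabelling of b's values
        b2 = ImageVolume(7.0 - b_vals, (1, 1, 1))
        assert nmi(a, b, bins=8) == pytest.approx(nmi(a, b2, bins=8), rel=1e-9)

    def test_constant_image_cases(self):
        const = ImageVolume(np.full((8, 8, 8), 3.0), (1, 1, 1))
        other = ImageVolume(np.arange(512, dtype=float).reshape(8, 8, 8), (1, 1, 1))
        assert nmi(const, const.copy()) == 2.0
        with pytest.raises(ValueError):
            nmi(const, other)


class TestResample:
    def test_identical_grid_is_bitwise(self, ramp_image):
        out = resample_to_grid(ramp_image, ramp_image.grid)
        np.testing.assert_array_equal(out.values, ramp_image.values)

    def test_constant_stays_constant(self):
        img = ImageVolume(np.full((16, 16, 16), 4.5), (2, 2, 2))
        out = resample_to_grid(img, Grid((8, 8, 8), (3.0, 3.0, 3.0), (1.0, 1.0, 1.0)))
        np.testing.assert_allclose(out.values, 4.5)

    def test_ramp_downsampled_hits_analytic_values(self, ramp_image):
        target = Grid((12, 12, 12), (4.0, 4.0, 4.0))
        out = resample_to_grid(ramp_image, target)
        expected = np.arange(12) * 4.0
        np.testing.assert_allclose(out.values[5, 5, :], expected, atol=1e-9)

    def test_no_overlap_raises(self, ramp_image):
        far = Grid((4, 4, 4), (1, 1, 1), (1e4, 1e4, 1e4))
        with pytest.raises(ValueError):
            resample_to_grid(ramp_image, far)


class TestIO:
    def test_volume_roundtrip(self, tmp_path, ramp_image):
        path = tmp_path / "ramp.nii.gz"
        save_volume(ramp_image, path)
        back = load_volume(path, "mr_t1w")
        np.testing.assert_allclose(back.values, ramp_image.values, atol=1e-5)
        assert back.grid.matches(ramp_image.grid)

    def test_field_roundtrip_and_component_check(self, tmp_path):
        g = Grid((10, 10, 10), (2, 2, 2))
        fld = sinusoid_field(g, 3.0, 50.0)
        path = tmp_path / "dvf.nii.gz"
        save_field(fld, path)
        back = load_field(path)
        np.testing.assert_allclose(back.vectors, fld.vectors, atol=1e-5)
        # two-component volume must be rejected
        import nibabel as nib

        bad = tmp_path / "bad.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32),
                                 np.eye(4)), str(bad))
        with pytest.raises(ValueError):
            load_field(bad)
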