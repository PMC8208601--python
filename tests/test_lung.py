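"""Quintic lung model: bias correction, normalisation, sampling, fit,
application and emphysema rescaling."""

import numpy as np
import pytest

from sct4d.core import ImageVolume
from sct4d.lung import (
    LungHUModel,
    TrainingSamples,
    apply_lung_model,
    correct_inhomogeneity,
    fit_lung_polynomial,
    normalize_water,
    rescale_lung_hu,
    sample_training_points,
)

QUINTIC = np.array([-1020.0, 800.0, -900.0, 1200.0, -900.0, 300.0])


def quintic_samples(n=4000, lo=0.1, hi=0.6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n)
    y = np.polynomial.polynomial.polyval(x, QUINTIC)
    if noise:
        y = y + rng.normal(0, noise, size=n)
    return TrainingSamples(
        intensity=x, hu=y, bin_edges=np.linspace(lo, hi, 21),
        bin_counts=np.full(20, n // 20),
    )


class TestCorrectInhomogeneity:
    def test_synthetic_bias_flattened_fivefold(self):
        shape, sp = (40, 40, 24), (3.0, 3.0, 4.0)
        axes = [np.arange(n) * s for n, s in zip(shape, sp)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        bias = 1.0 + 0.3 * np.sin(2 * np.pi * X / 300) * np.cos(2 * np.pi * Y / 250)
        flat_with_bias = ImageVolume(2.0 * bias, sp)
        corrected = correct_inhomogeneity(flat_with_bias, flat_with_bias)
        region = (slice(8, 32), slice(8, 32), slice(6, 18))
        cov = lambda v: v[region].std() / v[region].mean()
        assert cov(flat_with_bias.values) / cov(corrected.values) >= 5.0

    def test_constant_inputs_give_constant_output(self):
        img = ImageVolume(np.full((12, 12, 12), 3.0), (2, 2, 2))
        out = correct_inhomogeneity(img, img)
        assert np.allclose(out.values, out.values.flat[0])

    def test_output_positive_where_input_positive(self, default_phantom):
        t1 = default_phantom.t1_phases[0]
        out = correct_inhomogeneity(t1, default_phantom.scanner_t1)
        assert (out.values[t1.values > 0] > 0).all()


class TestNormalizeWater:
    def test_water_mean_equals_reference_exactly(self, default_phantom):
        t1 = default_phantom.t1_phases[0]
        mask = default_phantom.truth.masks["water"]
        out = normalize_water(t1, mask, 1.0)
        assert out.values[mask].mean() == pytest.approx(1.0, rel=1e-12)

    def test_image_already_at_reference_unchanged(self):
        img = ImageVolume(np.full((8, 8, 8), 2.5), (1, 1, 1))
        mask = np.ones((8, 8, 8), dtype=bool)
        out = normalize_water(img, mask, 2.5)
        np.testing.assert_allclose(out.values, img.values)

    def test_two_images_normalised_to_one_reference_agree(self, default_phantom):
        mask = default_phantom.truth.masks["water"]
        a = normalize_water(default_phantom.t1_phases[0], mask, 0.8)
        b = normalize_water(default_phantom.scanner_t1, mask, 0.8)
        assert a.values[mask].mean() == pytest.approx(b.values[mask].mean())

    def test_empty_mask_raises(self, default_phantom):
        with pytest.raises(ValueError):
            normalize_water(
                default_phantom.t1_phases[0],
                np.zeros(default_phantom.spec.shape, dtype=bool), 1.0,
            )


class TestSampler:
    def test_fixed_seed_reproduces_bit_identical_samples(self, default_phantom):
        t1 = default_phantom.t1_phases[0]
        ct = default_phantom.ct_phases[0]
        lung = default_phantom.truth.masks["lung"]
        kw = dict(n_initial=200_000, n_bins=10, per_bin=500, seed=123)
        s1 = sample_training_points(t1, ct, lung, **kw)
        s2 = sample_training_points(t1, ct, lung, **kw)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)
        np.testing.assert_array_equal(s1.hu, s2.hu)

    def test_populated_bins_yield_exact_quota(self, default_phantom):
        t1 = default_phantom.t1_phases[0]
        ct = default_phantom.ct_phases[0]
        lung = default_phantom.truth.masks["lung"]
        s = sample_training_points(
            t1, ct, lung, n_initial=500_000, n_bins=20, per_bin=1000, seed=0
        )
        populated = s.bin_counts[s.bin_counts >= 1000]
        assert (populated == 1000).all()
        assert len(s.bin_counts) == 20

    def test_underpopulated_bin_returns_everything_with_warning(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.uniform(0, 1, 5000), np.full(100, 5.0)])
        y = np.zeros_like(x)
        shape = (1, 1, x.size)
        with pytest.warns(RuntimeWarning, match="holds only"):
            s = sample_training_points(
                x.reshape(shape), y.reshape(shape),
                np.ones(shape, dtype=bool),
                n_initial=x.size, n_bins=2, per_bin=2000, seed=0,
            )
        assert s.bin_counts[1] == 100
        assert s.bin_counts[0] == 2000

    def test_empty_lung_raises(self, default_phantom):
        with pytest.raises(ValueError):
            sample_training_points(
                default_phantom.t1_phases[0], default_phantom.ct_phases[0],
                np.zeros(default_phantom.spec.shape, dtype=bool),
            )


class TestFit:
    def test_noiseless_quintic_recovered_to_1e6_relative(self):
        model = fit_lung_polynomial(quintic_samples())
        rel = np.abs(model.coefficients - QUINTIC) / np.abs(QUINTIC)
        assert rel.max() < 1e-6

    def test_default_order_is_five(self):
        model = fit_lung_polynomial(quintic_samples())
        assert model.order == 5
        assert len(model.coefficients) == 6

    def test_constant_hu_collapses_to_constant_term(self):
        s = quintic_samples()
        s = TrainingSamples(s.intensity, np.full_like(s.hu, -767.0),
                            s.bin_edges, s.bin_counts)
        model = fit_lung_polynomial(s)
        assert model.coefficients[0] == pytest.approx(-767.0, abs=1e-6)
        assert np.abs(model.coefficients[1:]).max() < 1e-5

    def test_rank_deficient_design_raises(self):
        x = np.full(100, 0.3)
        s = TrainingSamples(x, np.zeros(100), np.linspace(0, 1, 21),
                            np.zeros(20, dtype=int))
        with pytest.raises(ValueError):
            fit_lung_polynomial(s)

    def test_json_roundtrip(self, tmp_path):
        model = fit_lung_polynomial(quintic_samples())
        model.to_json(tmp_path / "model.json")
        back = LungHUModel.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.valid_range == model.valid_range


class TestApply:
    def test_constant_model_bulk_assigns(self, default_phantom):
        lung = default_phantom.truth.masks["lung"]
        model = LungHUModel(
            coefficients=np.array([-767.0, 0, 0, 0, 0, 0]),
            water_reference_mean=1.0, valid_range=(0.0, 1.0),
        )
        out = apply_lung_model(model, default_phantom.t1_phases[0], lung)
        assert (out.values[lung] == -767.0).all()

    def test_non_lung_voxels_untouched(self, default_phantom):
        lung = default_phantom.truth.masks["lung"]
        base = default_phantom.ct_phases[0]
        model = LungHUModel(
            coefficients=QUINTIC, water_reference_mean=1.0,
            valid_range=(0.0, 1.0),
        )
        out = apply_lung_model(model, default_phantom.t1_phases[0], lung, base=base)
        np.testing.assert_array_equal(out.values[~lung], base.values[~lung])

    def test_predictions_clamped_to_lung_window(self):
        model = LungHUModel(
            coefficients=np.array([-5000.0, 0, 0, 0, 0, 0]),
            water_reference_mean=1.0, valid_range=(0.0, 1.0),
        )
        t1 = ImageVolume(np.full((4, 4, 4), 0.5), (1, 1, 1))
        out = apply_lung_model(model, t1, np.ones((4, 4, 4), dtype=bool))
        assert (out.values == -1000.0).all()


class TestRescale:
    def test_median_hits_target_exactly(self, default_phantom):
        ct = default_phantom.ct_phases[0]
        lung = default_phantom.truth.masks["lung"]
        out = rescale_lung_hu(ct, lung, target_median=-865.0)
        assert np.median(out.values[lung]) == pytest.approx(-865.0, abs=1e-9)

    def test_already_at_target_is_identity(self, default_phantom):
        ct = default_phantom.ct_phases[0]
        lung = default_phantom.truth.masks["lung"]
        current = float(np.median(ct.values[lung]))
        out = rescale_lung_hu(ct, lung, target_median=current)
        np.testing.assert_allclose(out.values[lung], ct.values[lung])

    def test_voxel_ordering_preserved(self, default_phantom):
        ct = default_phantom.ct_phases[0]
        lung = default_phantom.truth.masks["lung"]
        out = rescale_lung_hu(ct, lung, target_median=-865.0)
        before = np.argsort(ct.values[lung], kind="stable")
        after = np.argsort(out.values[lung], kind="stable")
        np.testing.assert_array_equal(before, after)

    def test_default_target_is_emphysema_median(self):
        import inspect

        sig = inspect.signature(rescale_lung_hu)
        assert sig.parameters["target_median"].default == -865.0

    def test_zero_median_raises(self):
        ct = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1), modality="ct_hu")
        with pytest.raises(ValueError):
            rescale_lung_hu(ct, np.ones((4, 4, 4), dtype=bool))
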