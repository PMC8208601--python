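"""Motion model: phase selection, chained DVFs, midposition, 4D resynthesis.

Heavy registered-chain accuracy checks against the phantom's analytic
trajectory live in the acceptance suite; here the operations are exercised
on small rigid-trajectory series where oracles are exact.
"""

import numpy as np
import pytest

from sct4d.core import DisplacementField, PhaseSeries, warp_image
from sct4d.motion import (
    MotionModel,
    chain_register,
    compute_midp_field,
    dixon_to_midp,
    generate_4d,
    midp_image,
    select_matching_phase,
)
from conftest import gaussian_blob_image, translation_field


def rigid_series(n_phases=6, amplitude=4.0):
    """Blob series with per-phase rigid z-shift s*sin(2*pi*n/N)."""
    shifts = [amplitude * np.sin(2 * np.pi * n / n_phases) for n in range(n_phases)]
    phases = [gaussian_blob_image(shift_mm=(0, 0, s)) for s in shifts]
    return PhaseSeries(phases), np.array(shifts)


class TestSelectMatchingPhase:
    def test_exact_copy_is_found(self, small_phantom):
        series = small_phantom.t1_phases
        target = series[3].copy()
        target.modality = "mr_dixon_inphase"
        assert select_matching_phase(series, target) == 3

    def test_phantom_exhale_dixon_matches_exhale_phase(self, small_phantom):
        j = select_matching_phase(
            small_phantom.t1_phases, small_phantom.dixon["inphase"]
        )
        assert abs(j - small_phantom.truth.exhale_index) <= 1

    def test_all_identical_phases_tie_break_to_zero(self):
        img = gaussian_blob_image(shape=(16, 16, 16))
        series = PhaseSeries([img.copy() for _ in range(4)])
        assert select_matching_phase(series, img) == 0


class TestChainRegister:
    def test_static_series_gives_null_fields(self, backend):
        img = gaussian_blob_image()
        series = PhaseSeries([img.copy() for _ in range(4)])
        fields = chain_register(series, 1, backend)
        for fld in fields:
            assert fld.max_magnitude_mm() < 0.05 * min(img.spacing)

    def test_rigid_sin_trajectory_recovered(self, backend):
        series, shifts = rigid_series()
        fields = chain_register(series, 0, backend)
        core = series[0].values > 0.5
        for n, s in enumerate(shifts):
            # content shifted +s_n: the pull-back field on phase n samples
            # phase 0 at x + u with u_z = -s_n
            rec = fields[n].vectors[..., 2][core].mean()
            assert abs(rec + s) < 0.5 * min(series.grid.spacing), f"phase {n}"

    def test_chain_agrees_with_direct_registration(self, backend):
        series, _ = rigid_series()
        fields = chain_register(series, 0, backend)
        direct = backend.register(series[2], series[0])
        core = series[0].values > 0.5
        diff = np.sqrt(
            ((fields[2].vectors - direct.vectors) ** 2).sum(-1)
        )[core]
        assert diff.max() < min(series.grid.spacing)

    def test_invalid_reference_raises(self, backend):
        series, _ = rigid_series(n_phases=3)
        with pytest.raises(IndexError):
            chain_register(series, 5, backend)


class TestMidPField:
    def test_zero_fields_average_to_zero(self):
        g = gaussian_blob_image(shape=(12, 12, 12)).grid
        mean = compute_midp_field([DisplacementField.zero(g) for _ in range(5)])
        assert mean.max_magnitude_mm() == 0.0

    def test_constant_translations_average(self):
        g = gaussian_blob_image(shape=(12, 12, 12)).grid
        fields = [translation_field(g, (0, 0, t)) for t in (0.0, 2.0, 4.0)]
        mean = compute_midp_field(fields)
        np.testing.assert_allclose(mean.vectors[..., 2], 2.0)

    def test_uniform_weights_are_permutation_invariant(self):
        g = gaussian_blob_image(shape=(12, 12, 12)).grid
        fields = [translation_field(g, (t, -t, 2 * t)) for t in (1.0, 2.0, 5.0)]
        a = compute_midp_field(fields)
        b = compute_midp_field(fields[::-1])
        np.testing.assert_allclose(a.vectors, b.vectors)

    def test_zero_mean_rigid_trajectory_gives_null_midp(self, backend):
        series, shifts = rigid_series()  # sin over a full cycle: zero mean
        assert abs(shifts.mean()) < 1e-12
        fields = chain_register(series, 0, backend)
        mean = compute_midp_field(fields)
        core = series[0].values > 0.5
        mags = np.sqrt((mean.vectors**2).sum(-1))[core]
        assert mags.mean() < 0.5 * min(series.grid.spacing)

    def test_weight_length_mismatch_raises(self):
        g = gaussian_blob_image(shape=(8, 8, 8)).grid
        with pytest.raises(ValueError):
            compute_midp_field(
                [DisplacementField.zero(g)] * 3, weights=np.ones(4)
            )


class TestDixonToMidP:
    def _dixon_set(self):
        img = gaussian_blob_image()
        return {
            "fat": img.with_values(img.values, "mr_dixon_fat"),
            "water": img.with_values(0.5 * img.values, "mr_dixon_water"),
            "inphase": img.with_values(1.5 * img.values, "mr_dixon_inphase"),
        }

    def test_zero_fields_leave_images_unchanged(self):
        dixon = self._dixon_set()
        g = dixon["fat"].grid
        z = DisplacementField.zero(g)
        out = dixon_to_midp(dixon, z, z)
        for name in dixon:
            np.testing.assert_array_equal(out[name].values, dixon[name].values)

    def test_translations_compose_additively(self):
        dixon = self._dixon_set()
        g = dixon["fat"].grid
        a = translation_field(g, (0, 0, 2.0))
        b = translation_field(g, (0, 0, 1.0))
        out = dixon_to_midp(dixon, a, b)
        oracle = warp_image(dixon["fat"], translation_field(g, (0, 0, 3.0)))
        core = dixon["fat"].values > 0.3
        np.testing.assert_allclose(
            out["fat"].values[core], oracle.values[core], atol=1e-6
        )

    def test_single_composed_warp_matches_sequential(self):
        from conftest import smooth_random_field

        rng = np.random.default_rng(9)
        dixon = self._dixon_set()
        g = dixon["fat"].grid
        u1 = smooth_random_field(g, rng, amplitude=3.0)
        u2 = smooth_random_field(g, rng, amplitude=3.0)
        out = dixon_to_midp(dixon, u1, u2)
        sequential = warp_image(warp_image(dixon["water"], u1), u2)
        grad = np.abs(np.gradient(dixon["water"].values, *g.spacing)).max()
        bound = 2 * grad * max(g.spacing)
        assert np.abs(out["water"].values - sequential.values).max() <= bound

    def test_missing_channel_raises(self):
        dixon = self._dixon_set()
        del dixon["water"]
        g = dixon["fat"].grid
        with pytest.raises(KeyError):
            dixon_to_midp(dixon, DisplacementField.zero(g), DisplacementField.zero(g))


class TestMidPImageAndResynthesis:
    def test_zero_midp_field_returns_reference_phase(self):
        series, _ = rigid_series(n_phases=4)
        out = midp_image(series, 2, DisplacementField.zero(series.grid))
        np.testing.assert_array_equal(out.values, series[2].values)

    def test_static_series_midp_equals_any_phase(self, backend):
        img = gaussian_blob_image()
        series = PhaseSeries([img.copy() for _ in range(3)])
        fields = chain_register(series, 0, backend)
        midp = midp_image(series, 0, compute_midp_field(fields))
        np.testing.assert_allclose(midp.values, img.values, atol=0.01 * img.values.max())

    def test_static_model_replicates_input(self):
        img = gaussian_blob_image()
        g = img.grid
        n = 5
        model = MotionModel(
            reference_index=0,
            fields_j_to_n=[DisplacementField.zero(g) for _ in range(n)],
            field_j_to_midp=DisplacementField.zero(g),
        )
        series = generate_4d(img, model)
        assert len(series) == n
        for phase in series.phases:
            np.testing.assert_array_equal(phase.values, img.values)

    def test_model_requires_zero_field_at_reference(self):
        g = gaussian_blob_image(shape=(8, 8, 8)).grid
        with pytest.raises(ValueError):
            MotionModel(
                reference_index=0,
                fields_j_to_n=[translation_field(g, (1, 0, 0))] * 3,
                field_j_to_midp=DisplacementField.zero(g),
            )

    def test_rigid_roundtrip_recovers_midp_volume(self):
        # known analytic fields: MidP -> phase -> back with the exact inverse
        img = gaussian_blob_image()
        g = img.grid
        t = (0.0, 0.0, 3.0)
        model = MotionModel(
            reference_index=0,
            fields_j_to_n=[
                DisplacementField.zero(g),
                translation_field(g, t),
            ],
            field_j_to_midp=translation_field(g, (0.0, 0.0, 1.5)),
        )
        series = generate_4d(img, model)
        back = warp_image(series[1], translation_field(g, (0.0, 0.0, -1.5)))
        core = img.values > 0.3
        # two linear interpolations of a smooth blob
        assert np.abs(back.values - img.values)[core].max() < 0.05 * img.values.max()
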