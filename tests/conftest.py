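"""Shared fixtures. Heavy artefacts (default phantom, registered pipeline,
atlas cohort) are session-scoped and computed once."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sct4d.core import DisplacementField, Grid, ImageVolume
from sct4d.phantom import PhantomSpec, generate_phantom, phantom_atlas
from sct4d.pipeline import run_pipeline_volumes
from sct4d.registration import DemonsBackend


@pytest.fixture(scope="session")
def default_phantom():
    """The default 20-phase thorax phantom with ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """A lighter phantom for registration-heavy unit tests."""
    return generate_phantom(
        PhantomSpec(shape=(48, 48, 28), spacing=(4.0, 4.0, 5.0), n_phases=6,
                    amplitude_si_mm=8.0, amplitude_ap_mm=2.0, seed=11)
    )


@pytest.fixture(scope="session")
def backend():
    return DemonsBackend()


@pytest.fixture(scope="session")
def atlas5():
    """Five static phantom subjects for leave-one-out cross-validation."""
    return phantom_atlas(5, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(default_phantom, atlas5):
    """Full dsl pipeline (with 4D resynthesis) on the default phantom."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline_volumes(
            default_phantom.t1_phases,
            default_phantom.dixon,
            method="dsl",
            atlas=atlas5[1:],
            scanner_t1=default_phantom.scanner_t1,
            make_4d=True,
            seed=3,
        )


# ---------------------------------------------------------------------------
# small synthetic helpers


@pytest.fixture()
def ramp_image():
    """Linear ramp along z on an isotropic grid."""
    shape, sp = (24, 24, 24), (2.0, 2.0, 2.0)
    z = np.arange(shape[2]) * sp[2]
    vals = np.broadcast_to(z, shape).copy()
    return ImageVolume(vals, sp)


def translation_field(grid: Grid, t) -> DisplacementField:
    u = np.zeros(grid.shape + (3,))
    u[...] = np.asarray(t, dtype=float)
    return DisplacementField(u, grid.spacing, grid.origin, role="translation")


def sinusoid_field(grid: Grid, amplitude=5.0, period=100.0) -> DisplacementField:
    """Smooth z-displacement varying sinusoidally along z."""
    z = np.arange(grid.shape[2]) * grid.spacing[2]
    u = np.zeros(grid.shape + (3,))
    u[..., 2] = amplitude * np.sin(2 * np.pi * z / period)[None, None, :]
    return DisplacementField(u, grid.spacing, grid.origin, role="sinusoid")


def smooth_random_field(grid: Grid, rng, amplitude=4.0, sigma_vox=4.0):
    from scipy import ndimage

    u = rng.normal(size=grid.shape + (3,))
    for c in range(3):
        u[..., c] = ndimage.gaussian_filter(u[..., c], sigma_vox)
    u *= amplitude / max(np.abs(u).max(), 1e-9)
    return DisplacementField(u, grid.spacing, grid.origin, role="random-smooth")


def gaussian_blob_image(shape=(32, 32, 32), spacing=(3.0, 3.0, 3.0),
                        shift_mm=(0.0, 0.0, 0.0), widths=(28.0, 24.0, 20.0)):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    c = [(n - 1) * s / 2 + d for n, s, d in zip(shape, spacing, shift_mm)]
    vals = np.exp(
        -(((X - c[0]) / widths[0]) ** 2
          + ((Y - c[1]) / widths[1]) ** 2
          + ((Z - c[2]) / widths[2]) ** 2)
    )
    return ImageVolume(vals, spacing)
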