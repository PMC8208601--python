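"""Pairwise non-rigid registration.

The pipeline only assumes a callable that maps (fixed, moving) image pairs
to a displacement field, so externally computed fields (e.g. from a
dedicated registration package) can be injected via
:func:`load_external_field`. The bundled backend is a small multiresolution
demons solver with Gaussian (elastic) regularization — dependency-free and
deterministic, adequate for the smooth deformations of the digital phantom.
No equivalence with any specific third-party registration tool is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import (
    DisplacementField,
    ImageVolume,
    GridMismatchError,
    load_field,
)

__all__ = [
    "RegistrationParams",
    "RegistrationDivergenceError",
    "DemonsBackend",
    "register",
    "load_external_field",
]


class RegistrationDivergenceError(RuntimeError):
    """Similarity worsened over two consecutive pyramid levels."""


@dataclass(frozen=True)
class RegistrationParams:
    """Settings for the bundled demons backend.

    levels:
        Pyramid depth; level ``k`` works at downsampling factor
        ``2**(levels-1-k)``.
    smoothing_sigma_mm:
        Per-level Gaussian sigma (mm) applied to the displacement field
        after each update (elastic regularization). Must be non-increasing
        from coarse to fine.
    max_iter:
        Per-level iteration caps.
    regularization_weight:
        Extra multiplier (>= 0) on the field-smoothing sigma; 0 keeps the
        per-level sigmas as given.
    """

    levels: int = 3
    smoothing_sigma_mm: tuple[float, ...] = (6.0, 4.0, 2.5)
    max_iter: tuple[int, ...] = (40, 25, 12)
    regularization_weight: float = 0.0
    histogram_match: bool = True

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.smoothing_sigma_mm) != self.levels:
            raise ValueError("one smoothing sigma per level required")
        if len(self.max_iter) != self.levels:
            raise ValueError("one iteration cap per level required")
        sig = self.smoothing_sigma_mm
        if any(sig[i] < sig[i + 1] for i in range(len(sig) - 1)):
            raise ValueError("sigmas must be non-increasing coarse to fine")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")


def _normalise(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def _downsample(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    smoothed = ndimage.gaussian_filter(values, sigma=factor / 2.0)
    return ndimage.zoom(smoothed, 1.0 / factor, order=1)


def _conditional_remap(moving: np.ndarray, fixed: np.ndarray,
                       bins: int = 64) -> np.ndarray:
    """Map each moving-intensity bin to the mean fixed intensity observed
    there; assumes the pair is already roughly aligned."""
    edges = np.linspace(moving.min(), moving.max(), bins + 1)
    which = np.clip(np.digitize(moving.ravel(), edges) - 1, 0, bins - 1)
    sums = np.bincount(which, weights=fixed.ravel(), minlength=bins)
    counts = np.bincount(which, minlength=bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.isnan(means).any():  # fill unobserved bins by interpolation
        ok = ~np.isnan(means)
        means = np.interp(np.arange(bins), np.flatnonzero(ok), means[ok])
    return means[which].reshape(moving.shape)


def _warp_level(moving: np.ndarray, u: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    idx = np.indices(moving.shape, dtype=float)
    coords = [idx[i] + u[..., i] / spacing[i] for i in range(3)]
    return ndimage.map_coordinates(moving, coords, order=1, mode="nearest")


def _demons_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    u: np.ndarray,
    spacing: np.ndarray,
    sigma_mm: float,
    iters: int,
    max_step: float,
) -> np.ndarray:
    """Symmetric-force demons iterations at one resolution level."""
    sigma_vox = np.maximum(sigma_mm / spacing, 1e-6)
    fluid_vox = np.maximum(0.5 * sigma_mm / spacing, 1e-6)
    grad_f = np.stack(np.gradient(fixed, *spacing), axis=-1)
    # gate updates where the fixed image carries no structure: in
    # noise-only regions both force and gradient are noise-scale and the
    # demons step would otherwise random-walk at O(max_step)
    gmag_f = np.sqrt((grad_f**2).sum(axis=-1))
    gate_threshold = 0.05 * float(np.percentile(gmag_f, 99))
    for _ in range(iters):
        warped = _warp_level(moving, u, spacing)
        diff = fixed - warped
        grad_w = np.stack(np.gradient(warped, *spacing), axis=-1)
        grad = 0.5 * (grad_f + grad_w)
        gnorm2 = (grad ** 2).sum(axis=-1)
        denom = gnorm2 + (diff / max_step) ** 2
        scale = np.where(
            (denom > 1e-12) & (gmag_f > gate_threshold),
            diff / np.maximum(denom, 1e-12),
            0.0,
        )
        update = grad * scale[..., None]
        for c in range(3):
            update[..., c] = ndimage.gaussian_filter(update[..., c], fluid_vox)
        u = u + update
        for c in range(3):
            u[..., c] = ndimage.gaussian_filter(u[..., c], sigma_vox)
    return u


class DemonsBackend:
    """Deterministic multiresolution demons registration."""

    def __init__(self, params: RegistrationParams | None = None):
        self.params = params or RegistrationParams()

    def register(
        self, fixed: ImageVolume, moving: ImageVolume
    ) -> DisplacementField:
        """Estimate the field that warps ``moving`` toward ``fixed``.

        The returned field follows the pull-back convention of
        :func:`sct4d.core.warp_image`; ``warp_image(moving, field)``
        approximates ``fixed``.
        """
        if not fixed.grid.matches(moving.grid):
            raise GridMismatchError(
                "fixed and moving must share one grid; resample first"
            )
        p = self.params
        f_full = _normalise(fixed.values)
        m_full = _normalise(moving.values)
        spacing_full = np.asarray(fixed.spacing)
        if p.histogram_match and fixed.modality != moving.modality:
            # cross-contrast pair: intensities need not map monotonically
            # (e.g. fat-suppressed T1w vs Dixon in-phase), so remap both
            # images into a mutually predictable representation:
            # m' = E[fixed | moving bin] and f' = E[m' | fixed bin]. Detail
            # visible in only one contrast (e.g. T1w lung texture absent
            # from the flat Dixon lung) flattens on both sides instead of
            # driving spurious SSD forces
            m_remapped = _conditional_remap(m_full, f_full)
            f_remapped = _conditional_remap(f_full, m_remapped)
            # the conditional curves can amplify noise where classes abut;
            # a light blur keeps SSD forces edge-driven
            m_full = _normalise(ndimage.gaussian_filter(m_remapped, 1.0))
            f_full = _normalise(ndimage.gaussian_filter(f_remapped, 1.0))

        u = None
        mse_history: list[float] = []
        worsened_streak = 0
        for level in range(p.levels):
            factor = 2 ** (p.levels - 1 - level)
            if min(s // factor for s in fixed.shape) < 8:
                # grid too small at this factor; work at full resolution
                factor = 1
            f_lvl = _downsample(f_full, factor)
            m_lvl = _downsample(m_full, factor)
            spacing = spacing_full * factor
            if u is None:
                u = np.zeros(f_lvl.shape + (3,))
            elif u.shape[:3] != f_lvl.shape:
                zoom = [t / s for t, s in zip(f_lvl.shape, u.shape[:3])] + [1]
                u = ndimage.zoom(u, zoom, order=1)
            sigma = p.smoothing_sigma_mm[level] * (1.0 + p.regularization_weight)
            # MSE is only comparable within one resolution level, so each
            # level is judged against its own starting point
            mse_before = float(((f_lvl - _warp_level(m_lvl, u, spacing)) ** 2).mean())
            # step bound uses the finest spacing at every level: coarse
            # levels otherwise lock aliasing artefacts in at their own
            # (large) voxel scale, which the fine levels cannot undo in
            # low-gradient regions
            max_step = 0.8 * float(spacing_full.min())
            u = _demons_level(f_lvl, m_lvl, u, spacing, sigma,
                              p.max_iter[level], max_step)
            mse = float(((f_lvl - _warp_level(m_lvl, u, spacing)) ** 2).mean())
            if mse > mse_before * (1.0 + 1e-9):
                worsened_streak += 1
                if worsened_streak >= 2:
                    raise RegistrationDivergenceError(
                        f"similarity worsened over two consecutive levels: "
                        f"MSE history {mse_history + [(mse_before, mse)]}"
                    )
            else:
                worsened_streak = 0
            mse_history.append((mse_before, mse))

        if u.shape[:3] != fixed.shape:
            zoom = [t / s for t, s in zip(fixed.shape, u.shape[:3])] + [1]
            u = ndimage.zoom(u, zoom, order=1)

        # the demons force only constrains the field where the image has
        # structure; extrapolate into unsupported (gated) regions from the
        # nearest supported voxel and smooth, so the field stays continuous
        # and invertible instead of dropping to zero at gate borders
        grad_f = np.stack(np.gradient(f_full, *spacing_full), axis=-1)
        gmag = np.sqrt((grad_f**2).sum(axis=-1))
        support = gmag > 0.05 * float(np.percentile(gmag, 99))
        if support.any() and not support.all():
            dist, idx = ndimage.distance_transform_edt(
                ~support, sampling=spacing_full, return_indices=True
            )
            filled = u[idx[0], idx[1], idx[2]]
            # decay toward zero away from support: regions far from any
            # image structure (open air) should not inherit body-edge
            # displacements, and forward/backward fills stay consistent
            filled *= np.exp(-dist / 15.0)[..., None]
            smoothed = np.empty_like(filled)
            for c in range(3):
                smoothed[..., c] = ndimage.gaussian_filter(filled[..., c], 2.0)
            # supported voxels keep their measured displacement exactly
            u = np.where(support[..., None], u, smoothed)

        fld = DisplacementField(u, fixed.spacing, fixed.origin, role="registration")
        fld.smooth = fld.jacobian_positive()
        return fld


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    params: RegistrationParams | None = None,
) -> DisplacementField:
    """Convenience wrapper around :class:`DemonsBackend`."""
    return DemonsBackend(params).register(fixed, moving)


def load_external_field(path: str | Path, role: str = "") -> DisplacementField:
    """Load a precomputed displacement field (4D NIfTI, mm, vectors last).

    Lets users substitute fields produced by an external registration tool
    for the bundled backend. The role tag defaults to the file stem.
    """
    return load_field(path, role=role)
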