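"""Intensity-based tissue masks from MidP Dixon fat/water images.

The recipe is a two-step thresholding scheme. A combined mask ``M``
(background + lungs) comes from thresholding the summed fat+water image at
its mean; the largest connected component of ``M`` (after zero padding, so
the exterior forms a single border-connected component) is the background
``B`` and the remainder is lung ``L``. Inside the body (``1−M``), fat ``F``
is the largest connected component of the fat image above its mean non-zero
intensity, and water ``W`` is everything else. Component analysis uses
6-connectivity. The procedure is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Grid, ImageVolume, GridMismatchError

__all__ = ["TissueMaskSet", "compute_tissue_masks"]

#: Combined label map codes.
LABEL_AIR, LABEL_LUNG, LABEL_FAT, LABEL_SOFT = 0, 1, 2, 3


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 6-connected component of a boolean volume (empty-safe)."""
    labels, n = ndimage.label(mask)  # default structure = faces only
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


@dataclass
class TissueMaskSet:
    """Binary masks: combined M, background B, lung L, fat F, water W."""

    combined: np.ndarray
    background: np.ndarray
    lung: np.ndarray
    fat: np.ndarray
    water: np.ndarray
    grid: Grid

    def __post_init__(self):
        for name in ("combined", "background", "lung", "fat", "water"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} mask shape mismatch")
            setattr(self, name, arr)
        if np.any(self.lung != (self.combined & ~self.background)):
            raise ValueError("lung must equal combined AND NOT background")
        if np.any(self.fat & self.water):
            raise ValueError("fat and water masks must be disjoint")

    def label_map(self) -> ImageVolume:
        """Combined labels: 0 air, 1 lung, 2 fat, 3 soft-tissue."""
        labels = np.full(self.grid.shape, LABEL_SOFT, dtype=float)
        labels[self.fat] = LABEL_FAT
        labels[self.lung] = LABEL_LUNG
        labels[self.background] = LABEL_AIR
        return ImageVolume(labels, self.grid.spacing, self.grid.origin, "label")

    def as_volumes(self) -> dict[str, ImageVolume]:
        return {
            name: ImageVolume(
                getattr(self, name).astype(float),
                self.grid.spacing, self.grid.origin, "label",
            )
            for name in ("combined", "background", "lung", "fat", "water")
        }


def compute_tissue_masks(
    fat: ImageVolume, water: ImageVolume
) -> TissueMaskSet:
    """Derive the tissue mask set from co-registered MidP fat/water images.

    Thresholds are the mean summed image intensity (over all voxels,
    including zeros) for ``M`` and the mean non-zero fat intensity for the
    fat mask; both taken literally from the recipe.
    """
    if not fat.grid.matches(water.grid):
        raise GridMismatchError("fat and water must share one grid")
    summed = fat.values + water.values
    if not np.any(summed != 0):
        raise ValueError("fat and water images are entirely zero")

    threshold = summed.mean()
    combined = summed < threshold

    # Zero padding the summed image marks the pad as background, which
    # guarantees a unique border-connected exterior component.
    padded = np.pad(combined, 1, constant_values=True)
    background = _largest_component(padded)[1:-1, 1:-1, 1:-1]
    lung = combined & ~background
    if not lung.any():
        warnings.warn("lung mask is empty", RuntimeWarning)

    body = ~combined
    fat_values = np.where(body, fat.values, 0.0)
    nonzero = fat.values[fat.values != 0]
    if nonzero.size == 0:
        raise ValueError("fat image is entirely zero")
    fat_mask = _largest_component(fat_values > nonzero.mean())
    water_mask = body & ~fat_mask

    return TissueMaskSet(
        combined=combined,
        background=background,
        lung=lung,
        fat=fat_mask,
        water=water_mask,
        grid=fat.grid,
    )
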