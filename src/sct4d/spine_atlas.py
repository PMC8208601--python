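"""Spine extraction from CT, best-atlas selection, and spine fusion.

The spine recipe: threshold CT to the trabecular/cortical window
[125, 1500] HU, keep the largest connected bone component, tidy it with an
ellipsoid structuring element (radii 1, 1, 2 voxels) by dilation and
closing, crop to a rectangular spine ROI propagated over all axial slices,
and fill interior holes (the vertebral canal) slice-wise by morphological
flood fill.

Atlas fusion: every atlas fat image is registered to the incoming fat
image, its spine mask is carried along, and normalised mutual information
between the incoming and registered fat images — restricted to the warped
spine mask — ranks the candidates. The winner's (warped) CT overrides the
bulk-density synthetic CT inside the warped spine mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DisplacementField, Grid, ImageVolume, warp_image

__all__ = [
    "AtlasEntry",
    "SpineROI",
    "extract_spine",
    "select_best_atlas",
    "fuse_spine",
]

SPINE_HU_WINDOW = (125.0, 1500.0)


def _ellipsoid_structure(radii=(1, 1, 2)) -> np.ndarray:
    rx, ry, rz = radii
    dx, dy, dz = np.mgrid[-rx : rx + 1, -ry : ry + 1, -rz : rz + 1]
    return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0


@dataclass
class AtlasEntry:
    """One atlas subject: co-registered MidP volumes plus its spine mask."""

    midp_t1w: ImageVolume
    midp_fat: ImageVolume
    midp_water: ImageVolume
    midp_inphase: ImageVolume
    midp_ct: ImageVolume
    midp_spine: ImageVolume
    subject_id: str

    def __post_init__(self):
        g = self.midp_t1w.grid
        for name in ("midp_fat", "midp_water", "midp_inphase", "midp_ct", "midp_spine"):
            if not getattr(self, name).grid.matches(g):
                raise ValueError(f"{self.subject_id}: {name} not co-registered")
        if not np.any(self.midp_spine.values > 0.5):
            raise ValueError(f"{self.subject_id}: spine mask is empty")

    @property
    def spine_mask(self) -> np.ndarray:
        return self.midp_spine.values > 0.5


@dataclass(frozen=True)
class SpineROI:
    """Axial rectangle (voxel bounds, inclusive) propagated to all slices."""

    x0: int
    x1: int
    y0: int
    y1: int

    def __post_init__(self):
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError("degenerate ROI box")

    def contains_mask(self, mask: np.ndarray) -> bool:
        sel = np.zeros(mask.shape, dtype=bool)
        sel[self.x0 : self.x1 + 1, self.y0 : self.y1 + 1, :] = True
        return not np.any(mask & ~sel)

    def crop(self, mask: np.ndarray) -> np.ndarray:
        out = np.zeros_like(mask)
        out[self.x0 : self.x1 + 1, self.y0 : self.y1 + 1, :] = mask[
            self.x0 : self.x1 + 1, self.y0 : self.y1 + 1, :
        ]
        return out

    @classmethod
    def default_for(cls, grid: Grid) -> "SpineROI":
        """A box centred on the posterior third of the axial midline."""
        nx, ny, _ = grid.shape
        half_x = max(nx // 8, 2)
        cy = int(round(ny * 2 / 3))
        half_y = max(ny // 8, 2)
        return cls(
            x0=nx // 2 - half_x,
            x1=nx // 2 + half_x,
            y0=max(cy - half_y, 0),
            y1=min(cy + half_y, ny - 1),
        )


def extract_spine(ct: ImageVolume, roi: SpineROI) -> np.ndarray:
    """Spine mask from a CT volume via thresholding + ROI cropping.

    The largest component in the bone HU window is taken as the rib cage
    (which includes the thoracic vertebrae); "first component" orderings by
    label index are implementation artefacts and deliberately not used.
    """
    if ct.modality != "ct_hu":
        raise ValueError("extract_spine expects a ct_hu volume")
    lo, hi = SPINE_HU_WINDOW
    bone = (ct.values >= lo) & (ct.values <= hi)
    if not bone.any():
        raise ValueError(
            f"no voxel inside the bone window [{lo}, {hi}] HU"
        )
    labels, n = ndimage.label(bone)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    ribcage = labels == counts.argmax()

    structure = _ellipsoid_structure((1, 1, 2))
    cleaned = ndimage.binary_dilation(ribcage, structure=structure)
    cleaned = ndimage.binary_closing(cleaned, structure=structure)
    cropped = roi.crop(cleaned)
    # flood-fill holes slice-wise: the vertebral canal runs through the
    # whole stack and is only a hole within each axial slice
    filled = np.empty_like(cropped)
    for z in range(cropped.shape[2]):
        filled[:, :, z] = ndimage.binary_fill_holes(cropped[:, :, z])
    return filled


def _masked_nmi(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """NMI over a restricted voxel set (flat value arrays)."""
    if a.size < 2 or a.max() == a.min() or b.max() == b.min():
        return -np.inf
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = joint / joint.sum()

    def _entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hxy = _entropy(pxy.ravel())
    if hxy == 0:
        return -np.inf
    return (_entropy(pxy.sum(axis=1)) + _entropy(pxy.sum(axis=0))) / hxy


def select_best_atlas(
    incoming_fat: ImageVolume,
    atlas: list[AtlasEntry],
    backend,
    bins: int = 64,
) -> tuple[AtlasEntry, DisplacementField]:
    """Pick the atlas subject whose registered fat image best matches.

    Each atlas fat image is registered to the incoming fat image (field
    role ``D_MidP->D'_MidP``); NMI between incoming and registered fat is
    evaluated inside the warped spine mask (the spine-segmented reading of
    "segmented MidP-Fat"). Returns the winning entry and its field.
    """
    if not atlas:
        raise ValueError("empty atlas")
    best_score = -np.inf
    best: tuple[AtlasEntry, DisplacementField] | None = None
    for entry in atlas:
        field = backend.register(incoming_fat, entry.midp_fat)
        field = field.retag("D_MidP->D'_MidP")
        warped_fat = warp_image(entry.midp_fat, field)
        warped_spine = warp_image(entry.midp_spine, field, interpolation="nearest")
        mask = warped_spine.values > 0.5
        score = _masked_nmi(
            incoming_fat.values[mask], warped_fat.values[mask], bins=bins
        )
        if score > best_score:
            best_score = score
            best = (entry, field)
    assert best is not None
    return best


def fuse_spine(
    sct_d: ImageVolume,
    atlas_ct: ImageVolume,
    warped_spine_mask: np.ndarray,
) -> ImageVolume:
    """Intensity override: atlas CT HU replaces sCT inside the spine mask."""
    mask = np.asarray(warped_spine_mask, dtype=bool)
    if mask.shape != sct_d.shape:
        raise ValueError("spine mask shape mismatch")
    if not mask.any():
        warnings.warn("empty spine mask: nothing fused", RuntimeWarning)
        return sct_d.copy()
    fused = sct_d.values.copy()
    fused[mask] = atlas_ct.values[mask]
    return sct_d.with_values(fused, modality="ct_hu")
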