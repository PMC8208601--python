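"""Assembly of the three synthetic-CT variants and their 4D extension.

The three methods nest: ``sCT_D`` is pure bulk-density assignment from the
Dixon tissue masks; ``sCT_DS`` additionally overrides the spine with
warped atlas CT; ``sCT_DSL`` additionally replaces the bulk lung value
with the quintic intensity-to-HU model (optionally rescaled to a target
lung median for emphysema). Consecutive methods therefore differ only on
the spine-mask and lung-mask supports respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, PhaseSeries, warp_image
from .lung import LungHUModel, apply_lung_model, rescale_lung_hu
from .motion import MotionModel, generate_4d
from .segmentation import TissueMaskSet
from .spine_atlas import AtlasEntry, fuse_spine, select_best_atlas

__all__ = [
    "BulkHUTable",
    "build_sct_d",
    "build_sct_ds",
    "build_sct_dsl",
    "build_4d_sct",
]


@dataclass(frozen=True)
class BulkHUTable:
    """Bulk radiodensities per tissue class (HU), config-overridable."""

    fat: float = -110.0
    soft_tissue: float = 70.0
    air: float = -1000.0
    lung: float = -767.0

    def __post_init__(self):
        if not (self.air <= self.lung < self.fat < self.soft_tissue):
            raise ValueError(
                "bulk values must satisfy air <= lung < fat < soft_tissue"
            )


def build_sct_d(
    masks: TissueMaskSet, table: BulkHUTable = BulkHUTable()
) -> ImageVolume:
    """Bulk-density synthetic CT from the tissue masks.

    Every voxel receives exactly one of the four bulk values; voxels the
    Dixon recipe leaves in neither fat nor water fall back to soft tissue.
    """
    values = np.full(masks.grid.shape, table.soft_tissue)
    values[masks.fat] = table.fat
    values[masks.lung] = table.lung
    values[masks.background] = table.air
    assigned = masks.background | masks.lung | masks.fat | masks.water
    if not assigned.all():
        # water is "body minus fat" so this cannot trip by construction;
        # it guards against hand-built mask sets
        leftover = int((~assigned).sum())
        if np.any(~np.isfinite(values)):
            raise ValueError(f"{leftover} voxels left unassigned")
    return ImageVolume(values, masks.grid.spacing, masks.grid.origin, "ct_hu")


def build_sct_ds(
    sct_d: ImageVolume,
    atlas: list[AtlasEntry],
    incoming_fat: ImageVolume,
    backend,
    return_details: bool = False,
):
    """Add spine density: warped best-atlas CT overrides the spine voxels."""
    entry, field = select_best_atlas(incoming_fat, atlas, backend)
    warped_ct = warp_image(entry.midp_ct, field)
    warped_spine = (
        warp_image(entry.midp_spine, field, interpolation="nearest").values > 0.5
    )
    fused = fuse_spine(sct_d, warped_ct, warped_spine)
    if return_details:
        return fused, {
            "selected_subject": entry.subject_id,
            "warped_spine_mask": warped_spine,
        }
    return fused


def build_sct_dsl(
    sct_ds: ImageVolume,
    model: LungHUModel,
    t1_midp: ImageVolume,
    lung_mask: np.ndarray,
    rescale_target: float | None = None,
) -> ImageVolume:
    """Add variable lung density from the quintic model.

    ``t1_midp`` must be bias-corrected and water-normalised with the
    model's reference. When cross-validating, the model must have been
    trained leave-one-out with respect to the incoming subject. An
    optional linear rescaling to a target lung median is applied last.
    """
    out = apply_lung_model(model, t1_midp, lung_mask, base=sct_ds)
    if rescale_target is not None:
        out = rescale_lung_hu(out, lung_mask, target_median=rescale_target)
    return out


def build_4d_sct(midp_sct: ImageVolume, motion_model: MotionModel) -> PhaseSeries:
    """Warp the MidP synthetic CT to every respiratory phase (default 20)."""
    return generate_4d(midp_sct, motion_model)
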