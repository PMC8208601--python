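"""Validation metrics: regional HU statistics and dose-volume metrics.

Dose-volume quantities are computed by plain voxel counting on the sorted
in-mask dose values (voxel volume = product of spacings) with no
partial-volume interpolation — the only fully auditable choice, and the
one every brute-force oracle can reproduce exactly. Paired comparisons use
the Wilcoxon signed-rank test (exact null distribution for n <= 25 when
free of ties, normal approximation otherwise; zero differences dropped).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from .core import ImageVolume

__all__ = [
    "StructureSet",
    "region_hu_stats",
    "dose_at_volume",
    "near_max_dose",
    "volume_at_dose",
    "conformity_index",
    "paired_signed_rank",
]


@dataclass
class StructureSet:
    """Named binary structure masks on the dose grid."""

    masks: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def __post_init__(self):
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        mask = self.masks[name]
        if not mask.any():
            raise ValueError(f"structure {name!r} is empty")
        return mask

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)


def _as_mask(mask) -> np.ndarray:
    if isinstance(mask, ImageVolume):
        return mask.values > 0.5
    return np.asarray(mask, dtype=bool)


def region_hu_stats(
    sct: ImageVolume, ct: ImageVolume, masks: dict[str, np.ndarray]
) -> dict[str, dict[str, float]]:
    """Median and standard deviation of |sCT − CT| per named region."""
    if not sct.grid.matches(ct.grid):
        raise ValueError("sct and ct must be co-registered on one grid")
    abs_diff = np.abs(sct.values - ct.values)
    out: dict[str, dict[str, float]] = {}
    for name, mask in masks.items():
        m = _as_mask(mask)
        if not m.any():
            warnings.warn(f"region {name!r} is empty: omitted", RuntimeWarning)
            continue
        vals = abs_diff[m]
        out[name] = {
            "median_abs_diff": float(np.median(vals)),
            "std_abs_diff": float(vals.std()),
        }
    return out


def _in_mask_doses(dose: ImageVolume, mask) -> np.ndarray:
    m = _as_mask(mask)
    if not m.any():
        raise ValueError("empty structure mask")
    return dose.values[m]


def dose_at_volume(
    dose: ImageVolume,
    mask,
    percent: float | None = None,
    volume_cc: float | None = None,
) -> float:
    """D_x: maximum dose d with volume receiving >= d at least the request.

    Exactly one of ``percent`` (of the structure volume) or ``volume_cc``
    (absolute) must be given. Computed as the k-th largest in-mask voxel
    dose, k = ceil(requested volume / voxel volume).
    """
    if (percent is None) == (volume_cc is None):
        raise ValueError("give exactly one of percent or volume_cc")
    doses = np.sort(_in_mask_doses(dose, mask))[::-1]
    n = doses.size
    if percent is not None:
        if not 0 < percent <= 100:
            raise ValueError("percent must be in (0, 100]")
        k = math.ceil(percent / 100.0 * n)
    else:
        voxel_cc = dose.grid.voxel_volume_mm3 / 1000.0
        k = math.ceil(volume_cc / voxel_cc)
        if k > n:
            raise ValueError(
                f"structure holds {n * voxel_cc:.3g} cm3 "
                f"< requested {volume_cc} cm3"
            )
    return float(doses[max(k, 1) - 1])


def near_max_dose(dose: ImageVolume, mask, volume_cc: float = 0.5) -> float:
    """Minimum dose within the hottest ``volume_cc`` of the structure."""
    return dose_at_volume(dose, mask, volume_cc=volume_cc)


def volume_at_dose(dose: ImageVolume, mask, threshold_gy: float = 20.0) -> float:
    """V_x: percentage of the structure receiving >= ``threshold_gy``."""
    doses = _in_mask_doses(dose, mask)
    return float(100.0 * (doses >= threshold_gy).sum() / doses.size)


def conformity_index(ptv_mask, dose: ImageVolume, iso_gy: float) -> float:
    """Total PTV volume divided by the total isodose volume (whole grid)."""
    ptv = _as_mask(ptv_mask)
    iso = dose.values >= iso_gy
    if not iso.any():
        raise ValueError(f"no voxel receives >= {iso_gy} Gy")
    return float(ptv.sum() / iso.sum())


def paired_signed_rank(
    x, y, alpha: float = 0.05
) -> dict[str, float | bool | int]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; if none remain the samples are
    indistinguishable (p = 1). The exact distribution is used for n <= 25
    when the absolute differences are tie-free, otherwise the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    nonzero = diff[diff != 0]
    n = int(nonzero.size)
    if n == 0:
        return {"p": 1.0, "significant": False, "n": 0}
    has_ties = np.unique(np.abs(nonzero)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    p = float(res.pvalue)
    return {"p": p, "significant": p < alpha, "n": n}
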