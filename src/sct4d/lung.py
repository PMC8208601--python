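"""Variable lung density: quintic intensity-to-HU model.

Lung radiodensity varies substantially between and within patients, and a
single bulk value (−767 HU) can misrepresent it badly. This module models
HU in the lung as a fifth-order polynomial of normalised T1w intensity:

1. bias correction — the T1w volume is divided by a smoothed (3D median +
   guided filter) scanner-reconstructed T1w volume, removing the
   multiplicative coil profile;
2. water normalisation — intensities are scaled so the mean over the water
   (soft-tissue) mask equals a common reference, making subjects
   comparable;
3. sampling — ten million non-zero lung voxel pairs (T1w, HU) are drawn,
   then re-balanced over 20 equal-width intensity bins at 5000 random
   pairs per bin so sparse intensity ranges still constrain the fit;
4. ordinary least squares on the quintic Vandermonde design.

An emphysema-style linear rescaling utility matches the lung HU median to
a target (e.g. −865 HU from a reference CT) without reordering voxels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import ImageVolume, clamp_hu

__all__ = [
    "LungHUModel",
    "TrainingSamples",
    "correct_inhomogeneity",
    "normalize_water",
    "sample_training_points",
    "fit_lung_polynomial",
    "apply_lung_model",
    "rescale_lung_hu",
    "fit_from_atlas",
]

#: HU clamp window for lung predictions.
LUNG_HU_CLAMP = (-1000.0, 100.0)
DEFAULT_RESCALE_MEDIAN_HU = -865.0


@dataclass
class LungHUModel:
    """Quintic map from normalised T1w intensity to lung HU."""

    coefficients: np.ndarray  # ascending powers, length order+1
    water_reference_mean: float
    valid_range: tuple[float, float]
    training_meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1:
            raise ValueError("coefficients must be a vector")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        lo, hi = self.valid_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"invalid valid_range {self.valid_range}")
        self.valid_range = (float(lo), float(hi))

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def predict(self, intensity: np.ndarray) -> np.ndarray:
        """Evaluate the polynomial, clamping inputs to the trained range."""
        x = np.clip(np.asarray(intensity, dtype=float), *self.valid_range)
        return np.polynomial.polynomial.polyval(x, self.coefficients)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "water_reference_mean": self.water_reference_mean,
            "valid_range": list(self.valid_range),
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LungHUModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            coefficients=np.asarray(payload["coefficients"]),
            water_reference_mean=payload["water_reference_mean"],
            valid_range=tuple(payload["valid_range"]),
            training_meta=payload.get("training_meta", {}),
        )


@dataclass
class TrainingSamples:
    """Paired (normalised T1w intensity, HU) samples with bin bookkeeping."""

    intensity: np.ndarray
    hu: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray  # pairs contributed per bin

    def __post_init__(self):
        if self.intensity.shape != self.hu.shape:
            raise ValueError("intensity/HU sample length mismatch")


# ---------------------------------------------------------------------------
# Bias correction


def _box_mean(values: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.uniform_filter(values, size=2 * radius + 1, mode="nearest")


def guided_filter(
    image: np.ndarray, radius: int = 4, eps: float | None = None
) -> np.ndarray:
    """Self-guided edge-aware smoothing (box-filter guided filter).

    ``eps`` defaults to ``(0.1 * intensity range)**2``; larger values move
    the output toward a plain box blur.
    """
    image = np.asarray(image, dtype=float)
    if eps is None:
        rng = float(image.max() - image.min())
        eps = (0.1 * rng) ** 2 if rng > 0 else 1e-6
    mean_i = _box_mean(image, radius)
    corr_i = _box_mean(image * image, radius)
    var_i = np.maximum(corr_i - mean_i**2, 0.0)
    a = var_i / (var_i + eps)
    b = (1.0 - a) * mean_i
    return _box_mean(a, radius) * image + _box_mean(b, radius)


def correct_inhomogeneity(
    t1: ImageVolume,
    scanner_t1: ImageVolume | None = None,
    median_size: int = 3,
    guided_radius: int = 8,
    guided_eps: float | None = None,
) -> ImageVolume:
    """Divide out the multiplicative receive-coil intensity profile.

    The scanner-reconstructed T1w volume (default: the input itself) is
    passed through a 3D median filter and a guided filter; the input is
    divided by the result. Division is guarded below a small epsilon.

    The filter here estimates the smooth coil profile, so its defaults are
    deliberately coarse (radius 8 voxels, eps = (0.4 x intensity range)^2,
    i.e. close to a plain box blur): an edge-preserving setting would keep
    tissue detail in the divisor and cancel the very intensity information
    the lung model fits.
    """
    if scanner_t1 is None:
        scanner_t1 = t1
    elif not scanner_t1.grid.matches(t1.grid):
        raise ValueError("t1 and scanner_t1 must share one grid")
    smoothed = ndimage.median_filter(scanner_t1.values, size=median_size)
    if guided_eps is None:
        rng = float(smoothed.max() - smoothed.min())
        guided_eps = (0.4 * rng) ** 2 if rng > 0 else 1e-6
    filtered = guided_filter(smoothed, radius=guided_radius, eps=guided_eps)
    eps = 1e-6 * max(abs(filtered).max(), 1.0)
    bad = filtered <= eps
    if bad.mean() > 0.01:
        warnings.warn(
            f"{bad.mean():.1%} of the filtered reference is non-positive; "
            "correction is unreliable there",
            RuntimeWarning,
        )
    corrected = t1.values / np.maximum(filtered, eps)
    return t1.with_values(corrected)


def normalize_water(
    t1: ImageVolume, water_mask: np.ndarray, reference_mean: float
) -> ImageVolume:
    """Scale so the mean over the water mask equals ``reference_mean``."""
    mask = np.asarray(water_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty water mask")
    current = float(t1.values[mask].mean())
    if current == 0:
        raise ValueError("water-mask mean is zero; cannot normalise")
    return t1.with_values(t1.values * (reference_mean / current))


# ---------------------------------------------------------------------------
# Sampling and fitting


def sample_training_points(
    t1_midp: ImageVolume | np.ndarray,
    ct_midp: ImageVolume | np.ndarray,
    lung_mask: np.ndarray,
    n_initial: int = 10_000_000,
    n_bins: int = 20,
    per_bin: int = 5000,
    seed: int | np.random.Generator = 0,
) -> TrainingSamples:
    """Draw binned (intensity, HU) training pairs from the lung.

    ``n_initial`` non-zero lung points are selected at random (without
    replacement when the lung holds enough voxels, with replacement
    otherwise), then sorted into ``n_bins`` equal-width intensity bins;
    each adequately populated bin contributes exactly ``per_bin`` pairs,
    under-populated bins contribute everything they have with a warning.
    """
    t1v = t1_midp.values if isinstance(t1_midp, ImageVolume) else np.asarray(t1_midp)
    ctv = ct_midp.values if isinstance(ct_midp, ImageVolume) else np.asarray(ct_midp)
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lung mask")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x_all = t1v[mask]
    y_all = ctv[mask]
    nonzero = x_all != 0
    x_all, y_all = x_all[nonzero], y_all[nonzero]
    if x_all.size == 0:
        raise ValueError("no non-zero lung intensities to sample")
    replace = x_all.size < n_initial
    pick = rng.choice(x_all.size, size=n_initial, replace=replace)
    x, y = x_all[pick], y_all[pick]

    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    # np.digitize puts the maximum in its own overflow bin; fold it back
    which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    xs, ys, counts = [], [], np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        idx = np.flatnonzero(which == b)
        if idx.size == 0:
            continue
        if idx.size >= per_bin:
            take = rng.choice(idx.size, size=per_bin, replace=False)
            idx = idx[take]
        else:
            warnings.warn(
                f"bin {b} holds only {idx.size} points (< {per_bin}); "
                "using all of them",
                RuntimeWarning,
            )
        counts[b] = idx.size
        xs.append(x[idx])
        ys.append(y[idx])
    return TrainingSamples(
        intensity=np.concatenate(xs),
        hu=np.concatenate(ys),
        bin_edges=edges,
        bin_counts=counts,
    )


def fit_lung_polynomial(
    samples: TrainingSamples,
    order: int = 5,
    water_reference_mean: float = 1.0,
) -> LungHUModel:
    """Ordinary least squares quintic fit of HU against intensity."""
    x, y = samples.intensity, samples.hu
    if np.unique(x).size < order + 1:
        raise ValueError(
            f"need at least {order + 1} distinct intensities for order {order}"
        )
    design = np.vander(x, order + 1, increasing=True)
    if np.linalg.matrix_rank(design) < order + 1:
        raise ValueError("rank-deficient polynomial design")
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    residual_rms = float(np.sqrt(((design @ coeffs - y) ** 2).mean()))
    return LungHUModel(
        coefficients=coeffs,
        water_reference_mean=water_reference_mean,
        valid_range=(float(x.min()), float(x.max())),
        training_meta={
            "order": order,
            "n_samples": int(x.size),
            "bin_counts": samples.bin_counts.tolist(),
            "residual_rms_hu": residual_rms,
        },
    )


def apply_lung_model(
    model: LungHUModel,
    t1_midp: ImageVolume,
    lung_mask: np.ndarray,
    base: ImageVolume | None = None,
) -> ImageVolume:
    """Replace lung voxels by the modelled HU; everything else untouched.

    ``t1_midp`` must already be bias-corrected and water-normalised with
    the model's reference. Predictions are clamped to [−1000, 100] HU.
    ``base`` supplies the non-lung voxels (zeros if omitted).
    """
    mask = np.asarray(lung_mask, dtype=bool)
    if base is None:
        out = np.zeros(t1_midp.shape)
    else:
        if base.shape != t1_midp.shape:
            raise ValueError("base volume shape mismatch")
        out = base.values.copy()
    intensities = t1_midp.values[mask]
    lo, hi = model.valid_range
    n_clamped = int(((intensities < lo) | (intensities > hi)).sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} lung intensities outside the trained range were "
            "clamped to its endpoints",
            RuntimeWarning,
        )
    pred = np.clip(model.predict(intensities), *LUNG_HU_CLAMP)
    out[mask] = pred
    return ImageVolume(
        clamp_hu(out), t1_midp.spacing, t1_midp.origin, "ct_hu"
    )


def rescale_lung_hu(
    sct: ImageVolume,
    lung_mask: np.ndarray,
    target_median: float = DEFAULT_RESCALE_MEDIAN_HU,
) -> ImageVolume:
    """Linearly (multiplicatively) rescale lung HU to a target median.

    A pure multiplicative scaling is the only linear map that keeps
    −1000-anchored air moving consistently toward more negative HU; with a
    positive scale factor the ordering of lung voxel HUs is preserved and
    the post-hoc median equals the target exactly.
    """
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lung mask")
    current = float(np.median(sct.values[mask]))
    if current == 0:
        raise ValueError("current lung median is zero; cannot rescale")
    out = sct.values.copy()
    out[mask] = out[mask] * (target_median / current)
    return sct.with_values(clamp_hu(out))


# ---------------------------------------------------------------------------
# Atlas-level training


def fit_from_atlas(
    entries,
    n_initial: int = 10_000_000,
    n_bins: int = 20,
    per_bin: int = 5000,
    seed: int = 0,
    order: int = 5,
) -> LungHUModel:
    """Train the lung model on a (typically leave-one-out) atlas.

    Each subject's T1w is bias-corrected against itself (the atlas MidP-T1w
    volume is the scanner-reconstructed image) and water-normalised to the
    first subject's water mean; lung voxel pairs are pooled across subjects
    before the binned sampling.
    """
    from .segmentation import compute_tissue_masks

    if not entries:
        raise ValueError("no atlas entries to train on")
    rng = np.random.default_rng(seed)
    pooled_x, pooled_y = [], []
    reference_mean: float | None = None
    for entry in entries:
        masks = compute_tissue_masks(entry.midp_fat, entry.midp_water)
        corrected = correct_inhomogeneity(entry.midp_t1w)
        if reference_mean is None:
            reference_mean = float(corrected.values[masks.water].mean())
        normalised = normalize_water(corrected, masks.water, reference_mean)
        lung = masks.lung
        x = normalised.values[lung]
        y = entry.midp_ct.values[lung]
        keep = x != 0
        pooled_x.append(x[keep])
        pooled_y.append(y[keep])
    x_all = np.concatenate(pooled_x)
    y_all = np.concatenate(pooled_y)
    samples = sample_training_points(
        x_all.reshape(1, 1, -1),
        y_all.reshape(1, 1, -1),
        np.ones((1, 1, x_all.size), dtype=bool),
        n_initial=n_initial,
        n_bins=n_bins,
        per_bin=per_bin,
        seed=rng,
    )
    model = fit_lung_polynomial(
        samples, order=order, water_reference_mean=reference_mean
    )
    model.training_meta["n_subjects"] = len(entries)
    model.training_meta["seed"] = seed
    return model
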