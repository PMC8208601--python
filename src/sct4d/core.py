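"""Grid-aware image volumes and displacement-field algebra.

All images live on axis-aligned 3D voxel grids. Arrays are indexed
``(x, y, z)`` and physical coordinates are millimetres from the volume
origin (centre of voxel ``(0, 0, 0)``). Displacement fields follow the
pull-back convention used by common resampling implementations: the field
``u`` that maps image ``A`` onto the grid of ``B`` is applied as

    out(x) = A(x + u(x))

so composition order is explicit and warping is a single interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "MODALITIES",
    "Grid",
    "ImageVolume",
    "DisplacementField",
    "PhaseSeries",
    "warp_image",
    "compose_fields",
    "invert_field",
    "nmi",
    "resample_to_grid",
    "load_volume",
    "save_volume",
    "load_field",
    "save_field",
    "clamp_hu",
]

#: Recognised modality tags.
MODALITIES = frozenset(
    {
        "ct_hu",
        "mr_t1w",
        "mr_dixon_fat",
        "mr_dixon_water",
        "mr_dixon_inphase",
        "dose_gy",
        "label",
    }
)

HU_MIN, HU_MAX = -1024.0, 3071.0

#: Out-of-domain fill value per modality (CT-like air, zero otherwise).
_DEFAULT_FILL = {"ct_hu": -1000.0}


class GridMismatchError(ValueError):
    """Raised when two objects that must share a voxel grid do not."""


@dataclass(frozen=True)
class Grid:
    """Axis-aligned voxel grid: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid is strictly three-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def coordinates_mm(self) -> np.ndarray:
        """Physical coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def matches(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


def _require_same_grid(a, b, what: str = "operands"):
    if not a.grid.matches(b.grid):
        raise GridMismatchError(
            f"{what} must share one grid: {a.grid} vs {b.grid}"
        )


@dataclass
class ImageVolume:
    """A scalar 3D volume with physical geometry and a modality tag.

    ``ct_hu`` volumes are clamped to the representable HU range
    [−1024, 3071] on construction.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "mr_t1w"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.modality == "ct_hu":
            np.clip(self.values, HU_MIN, HU_MAX, out=self.values)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def grid(self) -> Grid:
        return Grid(self.values.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "ImageVolume":
        return ImageVolume(
            np.asarray(values), self.spacing, self.origin,
            self.modality if modality is None else modality,
        )

    def copy(self) -> "ImageVolume":
        return self.with_values(self.values.copy())


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement in mm on a reference grid.

    ``role`` is a free-text tag naming the transform the field realises
    (e.g. ``"Tj->Tn"``, ``"Tj->MidP"``, ``"Dj->Tj"``). When ``smooth`` is
    set the field asserts a positive Jacobian determinant of ``x + u(x)``
    everywhere.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = ""
    smooth: bool = False

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"vectors must have shape (nx, ny, nz, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("field components must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.smooth and not self.jacobian_positive():
            raise ValueError("smooth field has non-positive Jacobian determinant")

    @property
    def grid(self) -> Grid:
        return Grid(self.vectors.shape[:3], self.spacing, self.origin)

    @classmethod
    def zero(cls, grid: Grid, role: str = "") -> "DisplacementField":
        return cls(
            np.zeros(grid.shape + (3,)), grid.spacing, grid.origin,
            role=role, smooth=True,
        )

    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.vectors ** 2).sum(axis=-1)).max())

    def jacobian_determinant(self) -> np.ndarray:
        """Voxelwise det of the Jacobian of the mapping x -> x + u(x)."""
        jac = np.empty(self.vectors.shape[:3] + (3, 3))
        for c in range(3):
            grads = np.gradient(self.vectors[..., c], *self.spacing)
            for a in range(3):
                jac[..., c, a] = grads[a] + (1.0 if a == c else 0.0)
        return np.linalg.det(jac)

    def jacobian_positive(self) -> bool:
        return bool(self.jacobian_determinant().min() > 0)

    def retag(self, role: str) -> "DisplacementField":
        return replace(self, role=role)


@dataclass
class PhaseSeries:
    """Ordered respiratory-phase volumes with per-phase weights.

    Weights default to uniform: phases are equal-width sorted bins of the
    respiratory cycle, so each contributes the same fraction of time.
    """

    phases: list[ImageVolume]
    weights: np.ndarray | None = None
    reference_index: int | None = None

    def __post_init__(self):
        if not self.phases:
            raise ValueError("PhaseSeries needs at least one phase")
        g0 = self.phases[0].grid
        for p in self.phases[1:]:
            if not p.grid.matches(g0):
                raise GridMismatchError("all phases must share one grid")
        n = len(self.phases)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError("one weight per phase required")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights must sum to a positive value")
            self.weights = self.weights / total
        if self.reference_index is not None and not (
            0 <= self.reference_index < n
        ):
            raise IndexError(f"reference_index {self.reference_index} out of range")

    def __len__(self) -> int:
        return len(self.phases)

    def __getitem__(self, n: int) -> ImageVolume:
        return self.phases[n]

    @property
    def grid(self) -> Grid:
        return self.phases[0].grid


# ---------------------------------------------------------------------------
# Field algebra


def _sample_vectors(vectors: np.ndarray, coords_vox: np.ndarray) -> np.ndarray:
    """Linearly sample a vector field at fractional voxel coordinates.

    Out-of-domain samples take the nearest edge value, which keeps
    composition and inversion stable near the boundary.
    """
    out = np.empty(coords_vox.shape[:-1] + (3,))
    pts = [coords_vox[..., i] for i in range(3)]
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            vectors[..., c], pts, order=1, mode="nearest"
        )
    return out


def warp_image(
    image: ImageVolume,
    fld: DisplacementField,
    interpolation: str = "linear",
    fill_value: float | None = None,
) -> ImageVolume:
    """Resample ``image`` through a displacement field (pull-back).

    ``out(x) = image(x + u(x))``; out-of-domain samples are filled with a
    per-modality constant (−1000 for CT, 0 otherwise) unless overridden.
    """
    _require_same_grid(image, fld, "image and field")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if fill_value is None:
        fill_value = _DEFAULT_FILL.get(image.modality, 0.0)
    order = 1 if interpolation == "linear" else 0
    spacing = np.asarray(image.spacing)
    idx = np.indices(image.shape, dtype=float)
    coords = [idx[i] + fld.vectors[..., i] / spacing[i] for i in range(3)]
    warped = ndimage.map_coordinates(
        image.values, coords, order=order, mode="constant", cval=fill_value
    )
    return image.with_values(warped)


def compose_fields(
    first: DisplacementField, second: DisplacementField, role: str = ""
) -> DisplacementField:
    """Compose two pull-back fields: ``first`` A→B then ``second`` B→C.

    Warping an image with the returned field equals warping with ``first``
    and then with ``second``, up to interpolation error:

        u(x) = u2(x) + u1(x + u2(x))
    """
    _require_same_grid(first, second, "fields")
    spacing = np.asarray(first.spacing)
    idx = np.indices(first.grid.shape, dtype=float)
    coords = np.stack(
        [idx[i] + second.vectors[..., i] / spacing[i] for i in range(3)], axis=-1
    )
    sampled_first = _sample_vectors(first.vectors, coords)
    return DisplacementField(
        second.vectors + sampled_first,
        first.spacing,
        first.origin,
        role=role or f"({first.role})*({second.role})",
    )


def invert_field(
    fld: DisplacementField,
    max_iter: int = 80,
    tol_mm: float = 0.01,
    relaxation: float = 0.5,
) -> DisplacementField:
    """Invert a smooth displacement field by fixed-point iteration.

    Iterates ``v_{k+1}(x) = −u(x + v_k(x))`` (under-relaxed, which widens
    the convergence region for fields with steeper local gradients) until
    the largest update drops below ``tol_mm``. Non-convergence raises a
    warning (never silent) and the final residual is available by
    composing field and inverse.
    """
    spacing = np.asarray(fld.spacing)
    idx = np.indices(fld.grid.shape, dtype=float)
    v = np.zeros_like(fld.vectors)
    converged = False
    for _ in range(max_iter):
        coords = np.stack(
            [idx[i] + v[..., i] / spacing[i] for i in range(3)], axis=-1
        )
        target = -_sample_vectors(fld.vectors, coords)
        v_new = v + relaxation * (target - v)
        delta = np.sqrt(((target - v) ** 2).sum(axis=-1)).max()
        v = v_new
        if delta < tol_mm:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"invert_field did not converge in {max_iter} iterations "
            f"(last update {delta:.3g} mm)",
            RuntimeWarning,
        )
    return DisplacementField(
        v, fld.spacing, fld.origin, role=f"inv({fld.role})"
    )


# ---------------------------------------------------------------------------
# Similarity


def nmi(a: ImageVolume, b: ImageVolume, bins: int = 64) -> float:
    """Normalised mutual information (H(a)+H(b))/H(a,b), range (1, 2].

    Joint histogram over equal-width bins spanning each image's observed
    range. Two identical constant images are maximally informative about
    each other (2.0); a single constant image carries zero entropy and the
    score is undefined.
    """
    _require_same_grid(a, b, "images")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    av, bv = a.values.ravel(), b.values.ravel()
    a_const = av.max() == av.min()
    b_const = bv.max() == bv.min()
    if a_const or b_const:
        if a_const and b_const and av[0] == bv[0]:
            return 2.0
        raise ValueError("NMI undefined for a constant image (zero entropy)")
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def _entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    return (_entropy(px) + _entropy(py)) / _entropy(pxy.ravel())


# ---------------------------------------------------------------------------
# Resampling and IO


def resample_to_grid(image: ImageVolume, target: Grid) -> ImageVolume:
    """Linearly resample onto ``target`` in physical (mm) coordinates."""
    if image.grid.matches(target):
        return image.copy()
    lo_src = np.asarray(image.origin)
    hi_src = lo_src + (np.asarray(image.shape) - 1) * np.asarray(image.spacing)
    lo_tgt = np.asarray(target.origin)
    hi_tgt = lo_tgt + (np.asarray(target.shape) - 1) * np.asarray(target.spacing)
    if np.any(hi_src < lo_tgt) or np.any(hi_tgt < lo_src):
        raise ValueError("source and target grids have no physical overlap")
    fill = _DEFAULT_FILL.get(image.modality, 0.0)
    idx = np.indices(target.shape, dtype=float)
    coords = [
        (lo_tgt[i] + idx[i] * target.spacing[i] - lo_src[i]) / image.spacing[i]
        for i in range(3)
    ]
    order = 0 if image.modality == "label" else 1
    vals = ndimage.map_coordinates(
        image.values, coords, order=order, mode="constant", cval=fill
    )
    return ImageVolume(vals, target.spacing, target.origin, image.modality)


def clamp_hu(values: np.ndarray) -> np.ndarray:
    return np.clip(values, HU_MIN, HU_MAX)


def _read_any(path: str | Path):
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Returns (data array indexed x,y,z[,vec], spacing, origin).
    """
    path = Path(path)
    if path.suffix.lower() in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x[, vec])
        if data.ndim == 4:
            data = np.moveaxis(data, (0, 1, 2), (2, 1, 0))
        else:
            data = data.transpose(2, 1, 0)
        return data, tuple(img.GetSpacing()[:3]), tuple(img.GetOrigin()[:3])
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return data, spacing, origin


def load_volume(path: str | Path, modality: str = "mr_t1w") -> ImageVolume:
    data, spacing, origin = _read_any(path)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return ImageVolume(data, spacing, origin, modality)


def save_volume(image: ImageVolume, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(image.values, dtype=np.float32),
                        image.grid.affine()),
        str(path),
    )


def load_field(path: str | Path, role: str = "") -> DisplacementField:
    """Load a displacement field from 4D NIfTI (vector dimension last, mm)."""
    data, spacing, origin = _read_any(path)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention (x,y,z,t,vec)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: expected 3 vector components last, got shape {data.shape}"
        )
    if not role:
        stem = Path(path).name
        for suffix in (".nii.gz", ".nii", ".mha", ".mhd"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        role = stem
    return DisplacementField(data, spacing, origin, role=role)


def save_field(fld: DisplacementField, path: str | Path) -> None:
    grid = fld.grid
    nib.save(
        nib.Nifti1Image(np.asarray(fld.vectors, dtype=np.float32), grid.affine()),
        str(path),
    )
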