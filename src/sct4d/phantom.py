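"""Synthetic 4D digital thorax with paired CT / T1w / Dixon volumes.

The phantom provides everything the pipeline consumes, with analytic
ground truth: an elliptical body with a fat shell and soft-tissue core,
two lungs whose CT radiodensity is a known quintic function of the
(noise- and bias-free) T1w lung intensity, a spine with a vertebral canal
plus detached rib arcs, and a spherical tumour. Respiratory motion is a
diaphragm-weighted displacement affine in the cranio-caudal coordinate,

    z -> z + A_n * (1 + beta * z),      A_n = amp * sin^2(pi n / N),

plus a uniform anterior-posterior translation with the same time course,
so every per-phase mapping is exactly invertible in closed form. Phase 0
is exhale (zero displacement) and the time-averaged (midposition)
displacement is exactly ``amp / 2`` at the diaphragm. MR volumes carry a
multiplicative smooth bias field (fixed in the scanner frame) and
Gaussian noise on the magnitude (adequate above SNR 20, where the Rician
distribution is near-Gaussian). Everything is deterministic per seed.

The spine ground truth includes a thin low-density peri-cortical margin
(below the 125 HU bone threshold); recovering that margin is precisely
what the dilation step of the spine extraction recipe is for.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import DisplacementField, Grid, ImageVolume, PhaseSeries
from .spine_atlas import AtlasEntry, SpineROI

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomBundle",
    "generate_phantom",
    "phantom_atlas",
    "tumour_centroid_mm",
]

#: Default quintic (ascending powers) mapping normalised T1w in ~[0.13, 0.57]
#: to lung HU around −800; the constant term is re-anchored so the lung
#: median hits the spec's base median exactly at the reference phase.
DEFAULT_QUINTIC = (-1020.0, 800.0, -900.0, 1200.0, -900.0, 300.0)


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the digital thorax."""

    shape: tuple[int, int, int] = (80, 80, 44)
    spacing: tuple[float, float, float] = (3.0, 3.0, 4.0)
    n_phases: int = 20
    amplitude_si_mm: float = 12.0
    amplitude_ap_mm: float = 3.0
    lung_base_median_hu: float = -808.0
    lung_texture_scale_mm: float = 60.0
    lung_quintic: tuple[float, ...] = DEFAULT_QUINTIC
    lung_map: str = "quintic"  # or "piecewise" (misspecified stress variant)
    bias_strength: float = 0.3
    bias_scale_mm: float = 150.0
    noise_sigma: float = 0.01
    ct_noise_hu: float = 5.0
    emphysema: bool = False
    emphysema_median_hu: float = -865.0
    tumour_centre_mm: tuple[float, float, float] | None = None
    tumour_radius_mm: float = 10.0
    diaphragm_weight_min: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        extent = min(n * s for n, s in zip(self.shape, self.spacing))
        if max(self.amplitude_si_mm, self.amplitude_ap_mm) >= extent / 4:
            raise ValueError("motion amplitude too large for the grid")
        if self.lung_map not in ("quintic", "piecewise"):
            raise ValueError(f"unknown lung_map {self.lung_map!r}")
        if len(self.lung_quintic) != 6:
            raise ValueError("lung_quintic needs exactly 6 coefficients")

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing)


@dataclass
class PhantomTruth:
    """Analytic ground truth shipped with every phantom."""

    masks: dict[str, np.ndarray]          # reference (exhale) frame
    masks_midp: dict[str, np.ndarray]     # midposition frame
    fields: list[DisplacementField]       # pull-back DVF(T0 -> Tn)
    field_midp: DisplacementField         # pull-back DVF(T0 -> MidP)
    bias_field: np.ndarray
    quintic: np.ndarray                   # calibrated, ascending powers
    trajectory_mm: np.ndarray             # (n_phases, 3) tumour centre, mm
    midp_centre_mm: np.ndarray            # time-averaged tumour centre, mm
    lung_median_hu: float
    exhale_index: int = 0
    spine_roi: SpineROI | None = None


@dataclass
class PhantomBundle:
    spec: PhantomSpec
    ct_phases: PhaseSeries
    t1_phases: PhaseSeries
    dixon: dict[str, ImageVolume]         # exhale fat / water / inphase
    scanner_t1: ImageVolume               # scanner-reconstructed exhale T1w
    truth: PhantomTruth


# ---------------------------------------------------------------------------


def _smooth_texture(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    scale_mm: float,
    rng: np.random.Generator,
    n_waves: int = 4,
) -> np.ndarray:
    """Smooth pseudo-random field in [-1, 1] (sum of random plane cosines)."""
    x, y, z = coords
    out = np.zeros(np.broadcast(x, y, z).shape)
    for _ in range(n_waves):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        k = 2 * np.pi / scale_mm
        out += np.cos(k * (direction[0] * x + direction[1] * y + direction[2] * z) + phase)
    return out / n_waves


class _Anatomy:
    """Continuous tissue model of one subject in its reference frame."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator,
                 jitter: dict | None = None):
        self.spec = spec
        j = jitter or {}
        nx, ny, nz = spec.shape
        sx, sy, sz = spec.spacing
        self.centre = np.array([(nx - 1) * sx, (ny - 1) * sy, 0.0]) / 2
        self.centre[2] = (nz - 1) * sz / 2
        self.z_extent = (nz - 1) * sz

        self.body_semi = np.array([100.0, 75.0]) * j.get("body_scale", 1.0)
        self.fat_inner_scale = 0.88
        lung_dx = 40.0 + j.get("lung_shift_mm", 0.0)
        self.lung_centres = [
            np.array([+lung_dx, -6.0, 0.0]),
            np.array([-lung_dx, -6.0, 0.0]),
        ]
        self.lung_semi = np.array([28.0, 38.0, 58.0]) * j.get("lung_scale", 1.0)
        self.spine_centre = np.array([0.0, 48.0 + j.get("spine_shift_mm", 0.0)])
        self.spine_truth_r = 15.0 * j.get("spine_scale", 1.0)
        # peri-cortical margin of sub-threshold density: sized so that the
        # spine recipe's threshold bleed plus (1,1,2)-ellipsoid dilation
        # recovers the full anatomical extent
        self.spine_rim = 1.7 * sx
        self.canal_r = 4.0
        self.rib_scales = (0.80, 0.86)
        self.rib_band_period = 24.0
        self.rib_band_half = 4.0
        # keep band edges off the voxel lattice: edges aligned with voxel
        # centres would make whole rib planes jump by a full voxel under
        # sub-voxel motion
        self.rib_band_offset = 1.7
        self.rib_edge_mm = 2.0
        self.rib_excluded_angle = 0.6  # rad around the posterior midline
        if spec.tumour_centre_mm is None:
            self.tumour_centre = self.lung_centres[0] + np.array([0.0, 0.0, -25.0])
        else:
            self.tumour_centre = np.asarray(spec.tumour_centre_mm, dtype=float) - self.centre
        self.tumour_r = spec.tumour_radius_mm

        rel = (self.tumour_centre - self.lung_centres[0]) / self.lung_semi
        margin = self.tumour_r / self.lung_semi.min()
        if np.sqrt((rel**2).sum()) + margin > 1.0:
            raise ValueError("tumour does not fit inside the right lung")

        # lung texture (material frame) and its quintic HU map
        self.texture_rng_state = rng.spawn(1)[0]
        self.s0, self.s_amp = 0.35, 0.22
        self.texture_scale = spec.lung_texture_scale_mm
        self._texture_waves = self._draw_waves(self.texture_rng_state, 4,
                                               self.texture_scale)
        self._pocket_waves = self._draw_waves(rng.spawn(1)[0], 5, 25.0)
        self.quintic = np.asarray(spec.lung_quintic, dtype=float).copy()
        self._calibrate_lung_median()

    @staticmethod
    def _draw_waves(rng, n, scale):
        waves = []
        for _ in range(n):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            waves.append((2 * np.pi / scale * d, rng.uniform(0, 2 * np.pi)))
        return waves

    # -- geometry ----------------------------------------------------------

    def _grid_coords(self):
        g = self.spec.grid
        axes = [np.arange(n) * s for n, s in zip(g.shape, g.spacing)]
        return np.meshgrid(*axes, indexing="ij")

    def _centred(self, X, Y, Z):
        return X - self.centre[0], Y - self.centre[1], Z - self.centre[2]

    def _body_e(self, qx, qy):
        return (qx / self.body_semi[0]) ** 2 + (qy / self.body_semi[1]) ** 2

    def masks_at(self, X, Y, Z) -> dict[str, np.ndarray]:
        """Crisp tissue indicators at material coordinates (mm)."""
        qx, qy, qz = self._centred(X, Y, Z)
        e = self._body_e(qx, qy)
        body = e <= 1.0
        fat = body & (e > self.fat_inner_scale**2)
        lung = np.zeros_like(body)
        for c in self.lung_centres:
            lung |= (
                ((qx - c[0]) / self.lung_semi[0]) ** 2
                + ((qy - c[1]) / self.lung_semi[1]) ** 2
                + ((qz - c[2]) / self.lung_semi[2]) ** 2
            ) <= 1.0
        tc = self.tumour_centre
        tumour = (
            (qx - tc[0]) ** 2 + (qy - tc[1]) ** 2 + (qz - tc[2]) ** 2
        ) <= self.tumour_r**2
        lung_only = lung & ~tumour

        r_sp = np.sqrt((qx - self.spine_centre[0]) ** 2 + (qy - self.spine_centre[1]) ** 2)
        spine = r_sp <= self.spine_truth_r
        spine_bone = (r_sp <= self.spine_truth_r - self.spine_rim) & (r_sp > self.canal_r)
        canal = r_sp <= self.canal_r
        rim = spine & ~spine_bone & ~canal

        lo, hi = self.rib_scales
        band = (np.mod(Z - self.rib_band_offset, self.rib_band_period)
                < 2 * self.rib_band_half)
        theta = np.arctan2(qy, qx)
        away_from_spine = np.abs(theta - np.pi / 2) > self.rib_excluded_angle
        ribs = (
            (e >= lo**2) & (e <= hi**2) & band & away_from_spine
            & body & ~lung & ~spine
        )

        soft = body & ~fat & ~lung & ~spine & ~ribs
        background = ~body
        return {
            "body": body,
            "background": background,
            "fat": fat,
            "soft": soft,
            "lung": lung_only,
            "tumour": tumour,
            "spine": spine,
            "spine_bone": spine_bone,
            "canal": canal,
            "rim": rim,
            "ribs": ribs,
            "water": soft,
        }

    # -- intensities -------------------------------------------------------

    def rib_weight(self, X, Y, Z) -> np.ndarray:
        """Continuous rib indicator: crisp in-plane ring, smooth z-bands.

        The axial band edges are rendered with analytic partial volume so
        the imaged rib position moves sub-voxel-continuously with motion.
        """
        qx, qy, qz = self._centred(X, Y, Z)
        e = self._body_e(qx, qy)
        lo, hi = self.rib_scales
        theta = np.arctan2(qy, qx)
        in_plane = (
            (e >= lo**2) & (e <= hi**2)
            & (np.abs(theta - np.pi / 2) > self.rib_excluded_angle)
            & (e <= 1.0)
        )
        m = np.mod(Z - self.rib_band_offset, self.rib_band_period)
        dz = np.abs(m - self.rib_band_half)
        wz = np.clip(
            (self.rib_band_half + self.rib_edge_mm / 2 - dz) / self.rib_edge_mm,
            0.0, 1.0,
        )
        return in_plane * wz

    def _texture(self, X, Y, Z, waves):
        out = np.zeros(np.broadcast(X, Y, Z).shape)
        for k, phase in waves:
            out += np.cos(k[0] * X + k[1] * Y + k[2] * Z + phase)
        return out / len(waves)

    def lung_t1(self, X, Y, Z) -> np.ndarray:
        return self.s0 + self.s_amp * self._texture(X, Y, Z, self._texture_waves)

    def _pockets(self, X, Y, Z) -> np.ndarray:
        if not self.spec.emphysema:
            return np.zeros(np.broadcast(X, Y, Z).shape, dtype=bool)
        return self._texture(X, Y, Z, self._pocket_waves) > 0.45

    def lung_hu_map(self, s: np.ndarray) -> np.ndarray:
        if self.spec.lung_map == "quintic":
            return np.polynomial.polynomial.polyval(s, self.quintic)
        # misspecified stress variant: two-slope piecewise-linear map
        base = np.polynomial.polynomial.polyval(self.s0, self.quintic)
        lo_slope, hi_slope = 350.0, 900.0
        d = s - self.s0
        return base + np.where(d < 0, lo_slope * d, hi_slope * d)

    def _calibrate_lung_median(self, edge_sigma: float = 0.5):
        """Anchor the constant term so the exhale lung median hits spec.

        The median is evaluated on the rendered (imaging-blurred) CT, the
        volume the pipeline actually sees: blur mixes boundary voxels with
        the brighter surrounding soft tissue, so a crisp-field calibration
        would land visibly high.
        """
        from scipy import ndimage as ndi

        X, Y, Z = self._grid_coords()
        lung = self.masks_at(X, Y, Z)["lung"]
        target = (
            self.spec.emphysema_median_hu
            if self.spec.emphysema
            else self.spec.lung_base_median_hu
        )
        med = None
        for _ in range(6):
            rendered = ndi.gaussian_filter(self.ct_at(X, Y, Z), edge_sigma)
            med = float(np.median(rendered[lung]))
            if abs(med - target) < 0.5:
                break
            self.quintic[0] += target - med
        self._lung_median = med

    def ct_at(self, X, Y, Z) -> np.ndarray:
        m = self.masks_at(X, Y, Z)
        hu = np.full(np.broadcast(X, Y, Z).shape, -1000.0)
        hu[m["fat"]] = -90.0
        hu[m["soft"]] = 45.0
        hu[m["rim"]] = 90.0
        hu[m["spine_bone"]] = 700.0
        hu[m["canal"]] = 30.0
        rib_w = self.rib_weight(X, Y, Z)
        hu = hu + (400.0 - hu) * rib_w
        lung = m["lung"]
        s = self.lung_t1(X, Y, Z)
        lung_hu = self.lung_hu_map(s)
        lung_hu[self._pockets(X, Y, Z)] = -980.0
        hu[lung] = lung_hu[lung]
        hu[m["tumour"]] = 40.0
        return hu

    def t1_at(self, X, Y, Z) -> np.ndarray:
        m = self.masks_at(X, Y, Z)
        v = np.full(np.broadcast(X, Y, Z).shape, 0.02)
        v[m["fat"]] = 0.12
        v[m["soft"]] = 1.0
        v[m["rim"]] = 0.20
        v[m["spine_bone"]] = 0.25
        v[m["canal"]] = 0.30
        v = v + (0.25 - v) * self.rib_weight(X, Y, Z)
        lung = m["lung"]
        s = self.lung_t1(X, Y, Z)
        s = np.where(self._pockets(X, Y, Z), 0.03, s)
        v[lung] = s[lung]
        v[m["tumour"]] = 0.85
        return v

    def dixon_at(self, X, Y, Z) -> tuple[np.ndarray, np.ndarray]:
        m = self.masks_at(X, Y, Z)
        fat = np.full(np.broadcast(X, Y, Z).shape, 0.02)
        water = np.full_like(fat, 0.03)
        fat[m["fat"]] = 1.30
        water[m["fat"]] = 0.12
        fat[m["soft"]] = 0.08
        water[m["soft"]] = 0.75
        for bone_key in ("rim", "canal"):
            fat[m[bone_key]] = 0.12
            water[m[bone_key]] = 0.35
        # vertebral bodies are fatty marrow: bright on the fat image, which
        # is what makes spine-masked similarity ranking informative
        fat[m["spine_bone"]] = 0.50
        water[m["spine_bone"]] = 0.30
        rib_w = self.rib_weight(X, Y, Z)
        fat = fat + (0.12 - fat) * rib_w
        water = water + (0.35 - water) * rib_w
        fat[m["lung"]] = 0.05
        water[m["lung"]] = 0.08
        fat[m["tumour"]] = 0.08
        water[m["tumour"]] = 0.80
        return fat, water


# ---------------------------------------------------------------------------


def _phase_amplitudes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    n = np.arange(spec.n_phases)
    s2 = np.sin(np.pi * n / spec.n_phases) ** 2
    return spec.amplitude_si_mm * s2, spec.amplitude_ap_mm * s2


def _motion_beta(spec: PhantomSpec) -> float:
    """z-weighting slope: full amplitude at z=0 (inferior), min at the top."""
    z_extent = (spec.shape[2] - 1) * spec.spacing[2]
    return -(1.0 - spec.diaphragm_weight_min) / z_extent


def _material_coords(anat: _Anatomy, a_si: float, a_ap: float):
    """Grid coords mapped back to the material (reference) frame."""
    X, Y, Z = anat._grid_coords()
    beta = _motion_beta(anat.spec)
    return X, Y - a_ap, (Z - a_si) / (1.0 + a_si * beta)


def _pullback_field(spec: PhantomSpec, a_si: float, a_ap: float,
                    role: str) -> DisplacementField:
    grid = spec.grid
    beta = _motion_beta(spec)
    z = np.arange(grid.shape[2]) * grid.spacing[2]
    uz_1d = (z - a_si) / (1.0 + a_si * beta) - z
    u = np.zeros(grid.shape + (3,))
    u[..., 1] = -a_ap
    u[..., 2] = uz_1d[None, None, :]
    return DisplacementField(u, grid.spacing, grid.origin, role=role, smooth=True)


def _smooth_and_noise(values, sigma_vox, noise_sigma, rng, clip_min=None):
    out = ndimage.gaussian_filter(values, sigma=sigma_vox)
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    if clip_min is not None:
        out = np.maximum(out, clip_min)
    return out


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Build the full 4D phantom bundle with ground truth."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    anat = _Anatomy(spec, rng)
    grid = spec.grid

    # static multiplicative bias in the scanner frame
    X, Y, Z = anat._grid_coords()
    bias_rng = rng.spawn(1)[0]
    bias = 1.0 + spec.bias_strength * 0.5 * _smooth_texture(
        (X, Y, Z), spec.bias_scale_mm, bias_rng, n_waves=3
    )

    a_si, a_ap = _phase_amplitudes(spec)
    noise_rng = rng.spawn(1)[0]
    edge_sigma = 0.5  # voxels of imaging blur applied to every volume

    ct_list, t1_list, fields = [], [], []
    for n in range(spec.n_phases):
        Xm, Ym, Zm = _material_coords(anat, a_si[n], a_ap[n])
        ct_vals = _smooth_and_noise(
            anat.ct_at(Xm, Ym, Zm), edge_sigma, spec.ct_noise_hu, noise_rng
        )
        t1_vals = _smooth_and_noise(
            anat.t1_at(Xm, Ym, Zm) * bias, edge_sigma, spec.noise_sigma,
            noise_rng, clip_min=0.0,
        )
        ct_list.append(ImageVolume(ct_vals, spec.spacing, modality="ct_hu"))
        t1_list.append(ImageVolume(t1_vals, spec.spacing, modality="mr_t1w"))
        fields.append(_pullback_field(spec, a_si[n], a_ap[n], role=f"T0->T{n}"))

    # exhale Dixon (phase 0 geometry)
    fat_vals, water_vals = anat.dixon_at(X, Y, Z)
    fat_img = ImageVolume(
        _smooth_and_noise(fat_vals * bias, edge_sigma, spec.noise_sigma,
                          noise_rng, clip_min=0.0),
        spec.spacing, modality="mr_dixon_fat",
    )
    water_img = ImageVolume(
        _smooth_and_noise(water_vals * bias, edge_sigma, spec.noise_sigma,
                          noise_rng, clip_min=0.0),
        spec.spacing, modality="mr_dixon_water",
    )
    inphase_img = ImageVolume(
        _smooth_and_noise((fat_vals + water_vals) * bias, edge_sigma,
                          spec.noise_sigma, noise_rng, clip_min=0.0),
        spec.spacing, modality="mr_dixon_inphase",
    )
    scanner_t1 = ImageVolume(
        _smooth_and_noise(anat.t1_at(X, Y, Z) * bias, edge_sigma,
                          spec.noise_sigma, noise_rng, clip_min=0.0),
        spec.spacing, modality="mr_t1w",
    )

    # ground truth
    masks_ref = anat.masks_at(X, Y, Z)
    a_si_mid, a_ap_mid = float(a_si.mean()), float(a_ap.mean())
    Xm, Ym, Zm = _material_coords(anat, a_si_mid, a_ap_mid)
    masks_midp = anat.masks_at(Xm, Ym, Zm)
    field_midp = _pullback_field(spec, a_si_mid, a_ap_mid, role="T0->MidP")

    beta = _motion_beta(spec)
    centre_abs = anat.tumour_centre + anat.centre
    trajectory = np.stack(
        [
            np.array([
                centre_abs[0],
                centre_abs[1] + a_ap[n],
                centre_abs[2] + a_si[n] * (1.0 + beta * centre_abs[2]),
            ])
            for n in range(spec.n_phases)
        ]
    )
    midp_centre = np.array([
        centre_abs[0],
        centre_abs[1] + a_ap_mid,
        centre_abs[2] + a_si_mid * (1.0 + beta * centre_abs[2]),
    ])

    sx = spec.spacing[0]
    roi_half = anat.spine_truth_r + 6.0
    cx_vox = int(round((anat.centre[0] + anat.spine_centre[0]) / sx))
    cy_vox = int(round((anat.centre[1] + anat.spine_centre[1]) / spec.spacing[1]))
    hx = int(np.ceil(roi_half / sx))
    hy = int(np.ceil(roi_half / spec.spacing[1]))
    roi = SpineROI(
        x0=max(cx_vox - hx, 0), x1=min(cx_vox + hx, spec.shape[0] - 1),
        y0=max(cy_vox - hy, 0), y1=min(cy_vox + hy, spec.shape[1] - 1),
    )

    truth = PhantomTruth(
        masks=masks_ref,
        masks_midp=masks_midp,
        fields=fields,
        field_midp=field_midp,
        bias_field=bias,
        quintic=anat.quintic.copy(),
        trajectory_mm=trajectory,
        midp_centre_mm=midp_centre,
        lung_median_hu=anat._lung_median,
        exhale_index=0,
        spine_roi=roi,
    )
    return PhantomBundle(
        spec=spec,
        ct_phases=PhaseSeries(ct_list, reference_index=0),
        t1_phases=PhaseSeries(t1_list, reference_index=0),
        dixon={"fat": fat_img, "water": water_img, "inphase": inphase_img},
        scanner_t1=scanner_t1,
        truth=truth,
    )


def phantom_atlas(
    n_subjects: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[AtlasEntry]:
    """A cohort of static (MidP) phantom subjects with anatomical jitter.

    Each subject gets its own organ-size jitter, lung median in
    [−830, −780] HU and a perturbed quintic, emulating inter-patient
    variability for leave-one-out cross-validation.
    """
    if n_subjects < 2:
        raise ValueError("an atlas needs at least 2 subjects")
    base_spec = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    entries = []
    for i in range(n_subjects):
        sub_rng = master.spawn(1)[0]
        sub_seed = int(sub_rng.integers(0, 2**31 - 1))
        spec = replace(
            base_spec,
            seed=sub_seed,
            amplitude_si_mm=0.0,
            amplitude_ap_mm=0.0,
            n_phases=2,  # static: both phases identical, only [0] is used
            lung_base_median_hu=float(sub_rng.uniform(-830.0, -780.0)),
            lung_quintic=tuple(
                c * (1.0 + 0.03 * sub_rng.standard_normal())
                for c in base_spec.lung_quintic
            ),
        )
        jitter = {
            "body_scale": float(sub_rng.uniform(0.96, 1.04)),
            "lung_scale": float(sub_rng.uniform(0.94, 1.06)),
            "lung_shift_mm": float(sub_rng.uniform(-3.0, 3.0)),
            "spine_scale": float(sub_rng.uniform(0.92, 1.08)),
            "spine_shift_mm": float(sub_rng.uniform(-3.0, 3.0)),
        }
        bundle = _generate_static(spec, jitter)
        entries.append(
            AtlasEntry(
                midp_t1w=bundle["t1w"],
                midp_fat=bundle["fat"],
                midp_water=bundle["water"],
                midp_inphase=bundle["inphase"],
                midp_ct=bundle["ct"],
                midp_spine=bundle["spine"],
                subject_id=f"phantom-{i:02d}",
            )
        )
    return entries


def _generate_static(spec: PhantomSpec, jitter: dict) -> dict:
    """One static subject at its midposition (no motion)."""
    rng = np.random.default_rng(spec.seed)
    anat = _Anatomy(spec, rng, jitter=jitter)
    X, Y, Z = anat._grid_coords()
    bias_rng = rng.spawn(1)[0]
    bias = 1.0 + spec.bias_strength * 0.5 * _smooth_texture(
        (X, Y, Z), spec.bias_scale_mm, bias_rng, n_waves=3
    )
    noise_rng = rng.spawn(1)[0]
    edge_sigma = 0.5
    ct = ImageVolume(
        _smooth_and_noise(anat.ct_at(X, Y, Z), edge_sigma, spec.ct_noise_hu, noise_rng),
        spec.spacing, modality="ct_hu",
    )
    t1 = ImageVolume(
        _smooth_and_noise(anat.t1_at(X, Y, Z) * bias, edge_sigma,
                          spec.noise_sigma, noise_rng, clip_min=0.0),
        spec.spacing, modality="mr_t1w",
    )
    fat_vals, water_vals = anat.dixon_at(X, Y, Z)
    fat = ImageVolume(
        _smooth_and_noise(fat_vals * bias, edge_sigma, spec.noise_sigma,
                          noise_rng, clip_min=0.0),
        spec.spacing, modality="mr_dixon_fat",
    )
    water = ImageVolume(
        _smooth_and_noise(water_vals * bias, edge_sigma, spec.noise_sigma,
                          noise_rng, clip_min=0.0),
        spec.spacing, modality="mr_dixon_water",
    )
    inphase = ImageVolume(
        _smooth_and_noise((fat_vals + water_vals) * bias, edge_sigma,
                          spec.noise_sigma, noise_rng, clip_min=0.0),
        spec.spacing, modality="mr_dixon_inphase",
    )
    spine = ImageVolume(
        anat.masks_at(X, Y, Z)["spine"].astype(float),
        spec.spacing, modality="label",
    )
    return {"ct": ct, "t1w": t1, "fat": fat, "water": water,
            "inphase": inphase, "spine": spine}


def tumour_centroid_mm(
    volume: ImageVolume,
    search_centre_mm: np.ndarray,
    search_radius_mm: float,
    threshold: float,
) -> np.ndarray:
    """Centroid (mm) of above-threshold voxels near an expected position.

    Used to track the tumour through CT-like volumes: the sphere is the
    only above-threshold object within the searched lung neighbourhood.
    """
    g = volume.grid
    axes = [np.arange(n) * s for n, s in zip(g.shape, g.spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    near = (
        (X - search_centre_mm[0]) ** 2
        + (Y - search_centre_mm[1]) ** 2
        + (Z - search_centre_mm[2]) ** 2
    ) <= search_radius_mm**2
    sel = near & (volume.values > threshold)
    if not sel.any():
        raise ValueError("no above-threshold voxels in the search region")
    return np.array([X[sel].mean(), Y[sel].mean(), Z[sel].mean()])
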