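"""End-to-end synthetic-CT pipeline: configuration, orchestration, provenance.

The workflow mirrors the processing chain: pick the T1w phase matching the
Dixon acquisition, build chained inter-phase DVFs, average them into the
MidP field, carry Dixon (and optionally the scanner T1w) to MidP, segment
tissue, and assemble the requested synthetic-CT variant; optionally warp
the MidP result to all phases. Every written volume gets a sidecar JSON
recording the configuration hash, seeds and intermediate diagnostics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .builder import BulkHUTable, build_4d_sct, build_sct_d, build_sct_ds, build_sct_dsl
from .core import ImageVolume, PhaseSeries, load_volume, save_field, save_volume, warp_image
from .lung import LungHUModel, correct_inhomogeneity, fit_from_atlas, normalize_water
from .motion import (
    MotionModel,
    chain_register,
    compute_midp_field,
    dixon_to_midp,
    midp_image,
    select_matching_phase,
)
from .registration import DemonsBackend, RegistrationParams
from .segmentation import compute_tissue_masks
from .spine_atlas import AtlasEntry

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "run_pipeline_volumes",
    "load_atlas",
    "save_atlas",
]

_METHODS = ("d", "ds", "dsl")
_ATLAS_FILES = {
    "midp_t1w": "t1w.nii.gz",
    "midp_fat": "fat.nii.gz",
    "midp_water": "water.nii.gz",
    "midp_inphase": "inphase.nii.gz",
    "midp_ct": "ct.nii.gz",
    "midp_spine": "spine.nii.gz",
}
_ATLAS_MODALITIES = {
    "midp_t1w": "mr_t1w",
    "midp_fat": "mr_dixon_fat",
    "midp_water": "mr_dixon_water",
    "midp_inphase": "mr_dixon_inphase",
    "midp_ct": "ct_hu",
    "midp_spine": "label",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings (YAML-serialisable).

    Defaults encode the pipeline constants: bulk HUs −1000/−767/−110/70,
    20 respiratory phases, order-5 lung polynomial trained on 20 bins of
    5000 points each, spine threshold window 125–1500 HU.
    """

    method: str = "dsl"
    t1_4d: str | None = None
    dixon_fat: str | None = None
    dixon_water: str | None = None
    dixon_inphase: str | None = None
    scanner_t1: str | None = None
    atlas_dir: str | None = None
    lung_model: str | None = None
    exclude_subject: str | None = None
    out_dir: str = "sct_out"
    bulk_hu: dict = dc_field(
        default_factory=lambda: {
            "fat": -110.0, "soft_tissue": 70.0, "air": -1000.0, "lung": -767.0
        }
    )
    registration: dict = dc_field(default_factory=dict)
    lung_fit: dict = dc_field(
        default_factory=lambda: {
            "n_initial": 10_000_000, "n_bins": 20, "per_bin": 5000, "order": 5
        }
    )
    rescale_median: float | None = None
    make_4d: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.method in ("ds", "dsl") and self.atlas_dir is None:
            raise ValueError(f"method {self.method!r} requires atlas_dir")
        if self.method == "dsl" and self.atlas_dir is None and self.lung_model is None:
            raise ValueError("method 'dsl' requires atlas_dir or lung_model")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, in memory."""

    reference_index: int
    motion_model: MotionModel
    midp_t1: ImageVolume
    midp_dixon: dict[str, ImageVolume]
    masks: object
    sct: ImageVolume
    sct_d: ImageVolume
    sct_ds: ImageVolume | None = None
    series_4d: PhaseSeries | None = None
    lung_model: LungHUModel | None = None
    details: dict = dc_field(default_factory=dict)


def run_pipeline_volumes(
    t1_series: PhaseSeries,
    dixon: dict[str, ImageVolume],
    method: str = "dsl",
    atlas: list[AtlasEntry] | None = None,
    lung_model: LungHUModel | None = None,
    backend=None,
    table: BulkHUTable | None = None,
    scanner_t1: ImageVolume | None = None,
    rescale_median: float | None = None,
    make_4d: bool = False,
    lung_fit: dict | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the pipeline on in-memory volumes.

    ``atlas`` must already exclude the incoming subject when
    cross-validating. When ``lung_model`` is omitted for method ``dsl`` it
    is trained on the supplied atlas (leave-one-out by construction).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    backend = backend or DemonsBackend()
    table = table or BulkHUTable()

    j = select_matching_phase(t1_series, dixon["inphase"])
    fields = chain_register(t1_series, j, backend)
    field_midp = compute_midp_field(fields, t1_series.weights)
    field_dixon_to_j = backend.register(t1_series[j], dixon["inphase"])
    model = MotionModel(
        reference_index=j,
        fields_j_to_n=fields,
        field_j_to_midp=field_midp,
        field_dixon_to_j=field_dixon_to_j,
    )

    midp_t1 = midp_image(t1_series, j, field_midp)
    midp_dixon = dixon_to_midp(dixon, field_dixon_to_j, field_midp)
    masks = compute_tissue_masks(midp_dixon["fat"], midp_dixon["water"])

    details: dict = {"reference_index": j}
    sct_d = build_sct_d(masks, table)
    sct: ImageVolume = sct_d
    sct_ds = None
    if method in ("ds", "dsl"):
        if not atlas:
            raise ValueError("atlas required for methods ds/dsl")
        sct_ds, ds_info = build_sct_ds(
            sct_d, atlas, midp_dixon["fat"], backend, return_details=True
        )
        details["selected_subject"] = ds_info["selected_subject"]
        sct = sct_ds
    if method == "dsl":
        if lung_model is None:
            lung_model = fit_from_atlas(atlas, seed=seed, **(lung_fit or {}))
        if scanner_t1 is not None:
            # the scanner-reconstructed T1w is acquired near phase j;
            # carry it to MidP so both volumes share one frame
            scanner_midp = warp_image(scanner_t1, field_midp)
            corrected = correct_inhomogeneity(midp_t1, scanner_midp)
        else:
            corrected = correct_inhomogeneity(midp_t1)
        normalised = normalize_water(
            corrected, masks.water, lung_model.water_reference_mean
        )
        sct = build_sct_dsl(
            sct, lung_model, normalised, masks.lung,
            rescale_target=rescale_median,
        )
        details["lung_model_meta"] = dict(lung_model.training_meta)

    series_4d = build_4d_sct(sct, model) if make_4d else None
    return PipelineResult(
        reference_index=j,
        motion_model=model,
        midp_t1=midp_t1,
        midp_dixon=midp_dixon,
        masks=masks,
        sct=sct,
        sct_d=sct_d,
        sct_ds=sct_ds,
        series_4d=series_4d,
        lung_model=lung_model,
        details=details,
    )


def _load_t1_series(path: str) -> PhaseSeries:
    """A 4D T1w series: either a directory of per-phase NIfTIs or 4D NIfTI."""
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.nii*"))
        if not files:
            raise FileNotFoundError(f"no NIfTI phases in {p}")
        return PhaseSeries([load_volume(f, "mr_t1w") for f in files])
    import nibabel as nib

    img = nib.load(str(p))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{p}: expected 4D T1w data, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return PhaseSeries(
        [
            ImageVolume(data[..., n], spacing, origin, "mr_t1w")
            for n in range(data.shape[-1])
        ]
    )


def load_atlas(atlas_dir: str | Path, exclude: str | None = None) -> list[AtlasEntry]:
    """Read an atlas directory (one subdirectory of fixed filenames per subject)."""
    atlas_dir = Path(atlas_dir)
    manifest = atlas_dir / "atlas.json"
    if manifest.exists():
        subjects = json.loads(manifest.read_text())["subjects"]
    else:
        subjects = sorted(d.name for d in atlas_dir.iterdir() if d.is_dir())
    entries = []
    for sid in subjects:
        if sid == exclude:
            continue
        sub = atlas_dir / sid
        volumes = {
            key: load_volume(sub / fname, _ATLAS_MODALITIES[key])
            for key, fname in _ATLAS_FILES.items()
        }
        entries.append(AtlasEntry(subject_id=sid, **volumes))
    if not entries:
        raise ValueError(f"no atlas subjects found under {atlas_dir}")
    return entries


def save_atlas(entries: list[AtlasEntry], atlas_dir: str | Path) -> None:
    atlas_dir = Path(atlas_dir)
    atlas_dir.mkdir(parents=True, exist_ok=True)
    for entry in entries:
        sub = atlas_dir / entry.subject_id
        sub.mkdir(exist_ok=True)
        for key, fname in _ATLAS_FILES.items():
            save_volume(getattr(entry, key), sub / fname)
    (atlas_dir / "atlas.json").write_text(
        json.dumps({"subjects": [e.subject_id for e in entries]}, indent=2)
    )


def _sidecar(path: Path, config: PipelineConfig, extra: dict) -> None:
    payload = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        **extra,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(payload, indent=2, default=str)
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline entry point: load inputs, run, write outputs."""
    stage = "loading inputs"
    try:
        t1_series = _load_t1_series(config.t1_4d)
        dixon = {
            "fat": load_volume(config.dixon_fat, "mr_dixon_fat"),
            "water": load_volume(config.dixon_water, "mr_dixon_water"),
            "inphase": load_volume(config.dixon_inphase, "mr_dixon_inphase"),
        }
        scanner = (
            load_volume(config.scanner_t1, "mr_t1w")
            if config.scanner_t1 else None
        )
        atlas = (
            load_atlas(config.atlas_dir, exclude=config.exclude_subject)
            if config.atlas_dir else None
        )
        model = (
            LungHUModel.from_json(config.lung_model)
            if config.lung_model else None
        )
        params = (
            RegistrationParams(**config.registration)
            if config.registration else None
        )

        stage = "pipeline execution"
        result = run_pipeline_volumes(
            t1_series,
            dixon,
            method=config.method,
            atlas=atlas,
            lung_model=model,
            backend=DemonsBackend(params),
            table=BulkHUTable(**config.bulk_hu),
            scanner_t1=scanner,
            rescale_median=config.rescale_median,
            make_4d=config.make_4d,
            lung_fit={
                k: v for k, v in config.lung_fit.items()
                if k in ("n_initial", "n_bins", "per_bin", "order")
            },
            seed=config.seed,
        )

        stage = "writing outputs"
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        name = f"sct_{config.method}.nii.gz"
        save_volume(result.sct, out / name)
        _sidecar(out / name, config, result.details)
        save_volume(result.midp_t1, out / "midp_t1w.nii.gz")
        save_field(result.motion_model.field_j_to_midp, out / "dvf_j_to_midp.nii.gz")
        if result.lung_model is not None:
            result.lung_model.to_json(out / "lung_model.json")
        if result.series_4d is not None:
            for n, vol in enumerate(result.series_4d.phases):
                save_volume(vol, out / f"sct_phase{n:02d}.nii.gz")
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc
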