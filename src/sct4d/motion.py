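"""Respiratory motion model: chained inter-phase DVFs and midposition.

The midposition (MidP) is the time-weighted mean position of the anatomy
over the respiratory cycle. Given a phase-resolved T1w series, a reference
phase ``j`` is chosen as the phase best matching the (exhale) Dixon
acquisition; fields ``DVF(Tj->Tn)`` to every other phase are built by
registering adjacent phases stepping outward from ``j`` and composing along
the chain, which keeps each individual registration small. The MidP field
is the weighted arithmetic mean of the forward fields (uniform weights:
phases are equal-width sorted bins of the cycle). Dixon volumes reach MidP
through the composition ``DVF(Dj->Tj) * DVF(Tj->MidP)``, and a MidP volume
is carried back to every phase through ``inv(DVF(Tj->MidP)) * DVF(Tj->Tn)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DisplacementField,
    ImageVolume,
    PhaseSeries,
    compose_fields,
    invert_field,
    nmi,
    warp_image,
)

__all__ = [
    "MotionModel",
    "select_matching_phase",
    "chain_register",
    "compute_midp_field",
    "dixon_to_midp",
    "midp_image",
    "generate_4d",
]


@dataclass
class MotionModel:
    """All fields needed to move volumes between phases, MidP and Dixon."""

    reference_index: int
    fields_j_to_n: list[DisplacementField]
    field_j_to_midp: DisplacementField
    field_dixon_to_j: DisplacementField | None = None

    def __post_init__(self):
        j = self.reference_index
        if not (0 <= j < len(self.fields_j_to_n)):
            raise IndexError("reference index outside the phase range")
        g = self.field_j_to_midp.grid
        for f in self.fields_j_to_n:
            if not f.grid.matches(g):
                raise ValueError("all model fields must share one grid")
        if self.fields_j_to_n[j].max_magnitude_mm() > 1e-9:
            raise ValueError("field at the reference phase must be zero")

    @property
    def n_phases(self) -> int:
        return len(self.fields_j_to_n)


def select_matching_phase(
    t1_series: PhaseSeries, dixon_inphase: ImageVolume, bins: int = 64
) -> int:
    """Index of the T1w phase most similar (NMI) to the Dixon in-phase image.

    Ties break toward the lowest index. The Dixon volume must already be
    resampled onto the series grid.
    """
    if len(t1_series) == 0:
        raise ValueError("empty phase series")
    scores = np.array(
        [nmi(phase, dixon_inphase, bins=bins) for phase in t1_series.phases]
    )
    return int(np.argmax(scores))


def chain_register(
    t1_series: PhaseSeries, j: int, backend
) -> list[DisplacementField]:
    """Fields ``DVF(Tj->Tn)`` for every phase ``n``, built by chaining.

    Adjacent phases are registered stepping outward from ``j`` in both
    directions and the per-step fields are composed, so each registration
    only bridges one (small) respiratory step. The entry at ``n == j`` is
    the zero field.
    """
    n_phases = len(t1_series)
    if not (0 <= j < n_phases):
        raise IndexError(f"reference index {j} outside 0..{n_phases - 1}")
    grid = t1_series.grid
    fields: list[DisplacementField | None] = [None] * n_phases
    fields[j] = DisplacementField.zero(grid, role=f"T{j}->T{j}")

    for step in (+1, -1):
        prev = fields[j]
        n = j + step
        while 0 <= n < n_phases:
            fixed, moving = t1_series[n], t1_series[n - step]
            try:
                step_field = backend.register(fixed, moving)
            except Exception as exc:  # noqa: BLE001 - annotate the failing pair
                raise RuntimeError(
                    f"registration failed for phase pair "
                    f"({n - step} -> {n}): {exc}"
                ) from exc
            # prev warps Tj to T(n-step); step_field warps T(n-step) to Tn
            prev = compose_fields(prev, step_field, role=f"T{j}->T{n}")
            fields[n] = prev
            n += step

    return fields  # type: ignore[return-value]


def compute_midp_field(
    fields_j_to_n: list[DisplacementField],
    weights: np.ndarray | None = None,
) -> DisplacementField:
    """Weighted arithmetic mean of the forward fields, tagged ``Tj->MidP``.

    Uniform weights by default (each phase represents the same fraction of
    the breathing cycle).
    """
    if not fields_j_to_n:
        raise ValueError("no fields given")
    n = len(fields_j_to_n)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"need {n} weights, got shape {w.shape}")
        w = w / w.sum()
    grid = fields_j_to_n[0].grid
    mean = np.zeros(grid.shape + (3,))
    for wi, f in zip(w, fields_j_to_n):
        if not f.grid.matches(grid):
            raise ValueError("fields must share one grid")
        mean += wi * f.vectors
    return DisplacementField(
        mean, grid.spacing, grid.origin, role="Tj->MidP"
    )


def dixon_to_midp(
    dixon_set: dict[str, ImageVolume],
    field_dixon_to_j: DisplacementField,
    field_j_to_midp: DisplacementField,
) -> dict[str, ImageVolume]:
    """Warp Dixon water/fat/in-phase to MidP with a single composed field."""
    for channel in ("fat", "water", "inphase"):
        if channel not in dixon_set:
            raise KeyError(f"missing Dixon channel {channel!r}")
    composed = compose_fields(
        field_dixon_to_j, field_j_to_midp, role="Dj->MidP"
    )
    return {
        name: warp_image(img, composed) for name, img in dixon_set.items()
    }


def midp_image(
    t1_series: PhaseSeries, j: int, field_j_to_midp: DisplacementField
) -> ImageVolume:
    """The MidP volume: reference phase warped by the mean field.

    Works identically for a CT series (MidP-CT is computed independently
    from 4D-CT the same way MidP-T1w is from 4D-T1w).
    """
    return warp_image(t1_series[j], field_j_to_midp)


def generate_4d(
    midp_volume: ImageVolume,
    model: MotionModel,
    inversion_tol_mm: float = 0.05,
) -> PhaseSeries:
    """Resynthesise all respiratory phases from a MidP volume.

    Phase ``n`` = ``warp(midp, inv(DVF(Tj->MidP)) * DVF(Tj->Tn))``. An
    inversion residual above tolerance is reported as a warning and carried
    on, never silently dropped.
    """
    inv_midp = invert_field(model.field_j_to_midp, tol_mm=inversion_tol_mm / 5)
    residual = compose_fields(model.field_j_to_midp, inv_midp).max_magnitude_mm()
    if residual > inversion_tol_mm:
        warnings.warn(
            f"MidP field inversion residual {residual:.3g} mm exceeds "
            f"{inversion_tol_mm} mm",
            RuntimeWarning,
        )
    phases = []
    for n, f_j_to_n in enumerate(model.fields_j_to_n):
        total = compose_fields(inv_midp, f_j_to_n, role=f"MidP->T{n}")
        phases.append(warp_image(midp_volume, total))
    return PhaseSeries(phases, reference_index=model.reference_index)
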