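"""Rigid 3D drift correction of time-lapse z-stacks.

During a ~45-minute sequential-tracer session the brain drifts slowly under
the objective; downstream intensity statistics are only meaningful after the
time-Z-stack is re-aligned.  Drift here is purely translational, so shifts
are estimated by phase correlation on the vessel channel — the vessel label
is static over the session, whereas tracer intensity changes by design —
and the same shift is applied to every channel of a timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DegenerateInputError, StructuralError
from ._utils import translate_volume
from .synthetic_imaging import Hyperstack

__all__ = ["ShiftVector", "estimate_shift", "register_hyperstack"]

#: Below this normalized-correlation confidence a shift is flagged unreliable.
DEFAULT_CONFIDENCE_FLOOR = 0.2


@dataclass(frozen=True)
class ShiftVector:
    """Estimated translation of a moving frame relative to a reference.

    ``(dx, dy, dz)`` are voxel displacements of the moving frame's content;
    applying the negated vector re-aligns it.  ``confidence`` is the
    normalized cross-correlation between reference and back-shifted moving
    frame, clipped to [0, 1]; ``reliable`` is False when it falls below the
    configured floor (e.g. on pure-noise frames).
    """

    dx: float
    dy: float
    dz: float
    confidence: float
    reliable: bool = True

    @property
    def zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)


def _correlation_surfaces(
    reference: np.ndarray, moving: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-correlation and plain cross-correlation surfaces.

    conj(F_ref) * F_mov puts the peak at +s when moving = reference
    translated by s (content moved by +s voxels).  The phase-normalized
    surface has a sharp, unambiguous integer peak; the un-normalized one is
    smooth around it and suits the quadratic subpixel fit.
    """
    f_ref = np.fft.fftn(reference)
    f_mov = np.fft.fftn(moving)
    cross = np.conj(f_ref) * f_mov
    cc = np.real(np.fft.ifftn(cross))
    phase = np.real(np.fft.ifftn(cross / np.maximum(np.abs(cross), 1e-30)))
    return phase, cc


def _quadratic_peak_offset(surface: np.ndarray, peak: tuple[int, ...]) -> np.ndarray:
    """Per-axis quadratic interpolation of the correlation peak (subpixel).

    Fitted on the log of the (positive) correlation values, which is exact
    for a Gaussian-shaped peak — the shape the autocorrelation of a
    band-limited image takes near its maximum.
    """
    offsets = np.zeros(surface.ndim)
    for ax in range(surface.ndim):
        idx_m = list(peak)
        idx_p = list(peak)
        idx_m[ax] = (peak[ax] - 1) % surface.shape[ax]
        idx_p[ax] = (peak[ax] + 1) % surface.shape[ax]
        c0 = surface[tuple(peak)]
        cm = surface[tuple(idx_m)]
        cp = surface[tuple(idx_p)]
        if min(c0, cm, cp) > 0:
            c0, cm, cp = np.log(c0), np.log(cm), np.log(cp)
        denom = cm - 2.0 * c0 + cp
        if abs(denom) > 1e-12:
            offsets[ax] = float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))
    return offsets


def _normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, 0.0, 1.0))


def estimate_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    subpixel: bool = False,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> ShiftVector:
    """Estimate the rigid translation of ``moving`` relative to ``reference``.

    Phase correlation: the normalized cross-power spectrum's inverse FFT
    peaks at the translation that best superimposes the two volumes.  The
    integer peak is optionally refined by a local quadratic fit
    (``subpixel=True``; off by default since stage drift between one-minute
    stacks is well captured at voxel resolution).

    Raises :class:`DegenerateInputError` on constant (zero-variance) input.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise StructuralError("reference and moving frames must share a shape")
    if reference.std() == 0 or moving.std() == 0:
        raise DegenerateInputError("cannot register a constant (zero-variance) frame")

    surface, cc = _correlation_surfaces(
        reference - reference.mean(), moving - moving.mean()
    )
    peak = np.unravel_index(np.argmax(surface), surface.shape)
    shape = np.asarray(surface.shape)
    shift = np.asarray(peak, dtype=float)
    shift[shift > shape / 2] -= shape[shift > shape / 2]

    if subpixel:
        # re-localize on the smooth cross-correlation surface: the phase
        # peak can land one lattice step off the true fractional optimum
        neighborhood = list(np.ndindex((3,) * cc.ndim))
        candidates = [
            tuple((np.asarray(peak) + np.asarray(d) - 1) % shape)
            for d in neighborhood
        ]
        center = max(candidates, key=lambda idx: cc[idx])
        shift = np.asarray(center, dtype=float)
        shift[shift > shape / 2] -= shape[shift > shape / 2]
        shift = shift + _quadratic_peak_offset(cc, center)

    confidence = _normalized_correlation(
        reference, translate_volume(moving, tuple(-shift), fill=float(np.median(moving)))
    )
    dz, dy, dx = (float(s) for s in shift)
    return ShiftVector(
        dx=dx,
        dy=dy,
        dz=dz,
        confidence=confidence,
        reliable=confidence >= confidence_floor,
    )


def register_hyperstack(
    stack: Hyperstack,
    reference_policy: str = "first",
    subpixel: bool = False,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    estimation_channel: str = "vessel",
) -> tuple[Hyperstack, pd.DataFrame]:
    """Register every timepoint of a hyperstack to a common reference.

    ``reference_policy`` is ``"first"`` (align all timepoints to the
    baseline stack, the default, matching concatenated baseline-then-time
    acquisition) or ``"running"`` (align each timepoint to the previous
    registered one and accumulate shifts; tolerant of slow morphing).

    Shifts are estimated on ``estimation_channel`` only and applied to all
    channels of the timepoint; exposed out-of-frame voxels are filled with
    that frame's median (a robust background level).  Returns the
    registered stack and a shift log with one row per timepoint
    ``(timepoint, dx, dy, dz, confidence, reliable)``.
    """
    if reference_policy not in ("first", "running"):
        raise ValueError(f"unknown reference policy {reference_policy!r}")
    ch = stack.channel_index(estimation_channel)
    n_t = stack.n_timepoints
    log_cols = ["timepoint", "dx", "dy", "dz", "confidence", "reliable"]
    if n_t < 2:
        return stack, pd.DataFrame(columns=log_cols)

    data = stack.data.astype(float).copy()
    reference = data[0, ch]
    rows = [{"timepoint": 0, "dx": 0.0, "dy": 0.0, "dz": 0.0, "confidence": 1.0, "reliable": True}]
    cumulative = np.zeros(3)
    for t in range(1, n_t):
        sv = estimate_shift(
            reference, data[t, ch], subpixel=subpixel, confidence_floor=confidence_floor
        )
        shift_zyx = np.asarray(sv.zyx)
        if reference_policy == "running":
            cumulative = cumulative + shift_zyx
            applied = cumulative
        else:
            applied = shift_zyx
        for c in range(data.shape[1]):
            fill = float(np.median(data[t, c]))
            data[t, c] = translate_volume(data[t, c], tuple(-applied), fill=fill)
        if reference_policy == "running":
            reference = data[t, ch]
        rows.append(
            {
                "timepoint": t,
                "dx": float(applied[2]),
                "dy": float(applied[1]),
                "dz": float(applied[0]),
                "confidence": sv.confidence,
                "reliable": sv.reliable,
            }
        )

    registered = Hyperstack(
        data=data,
        voxel_spacing=stack.voxel_spacing,
        channels=stack.channels,
        timestamps=stack.timestamps.copy(),
    )
    return registered, pd.DataFrame(rows, columns=log_cols)
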