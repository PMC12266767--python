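"""Relative BBB permeability: extravascular I/I0 time series and AUC.

For each sequentially injected tracer, the mean green-channel intensity
over the brain parenchyma (everything outside the dilated vessel mask and
autofluorescent particles) is tracked through that tracer's 15-minute
window and normalized to the last pre-injection frame (I0).  The area
under the (I/I0 - 1) curve is the relative-permeability statistic: zero
for an intact barrier, growing with tracer extravasation, and invariant to
detector gain because the normalization cancels any global multiplicative
factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from ._errors import (
    DegenerateInputError,
    ParameterError,
    ScheduleError,
    StructuralError,
)
from .segmentation import DEFAULT_DEPTH_WINDOW, depth_window_mip
from .synthetic_imaging import Hyperstack, TracerSpec

__all__ = [
    "TracerSchedule",
    "PermeabilityCurve",
    "PermeabilityResult",
    "build_parenchyma_mask",
    "extravascular_series",
    "permeability_auc",
    "analyze_session",
]


@dataclass
class TracerSchedule:
    """Ordered sequential-injection schedule (largest tracer first)."""

    tracers: list[TracerSpec]

    def __post_init__(self) -> None:
        if not self.tracers:
            raise ScheduleError("schedule contains no tracers")
        weights = [t.molecular_weight_kda for t in self.tracers]
        if any(b >= a for a, b in zip(weights, weights[1:])):
            raise ScheduleError("molecular weights must be strictly decreasing")
        prev_end = -1
        for t in self.tracers:
            if t.injection_frame <= prev_end:
                raise ScheduleError("tracer frame ranges must be disjoint and ordered")
            if t.injection_frame < 1:
                raise ScheduleError(
                    "each tracer needs at least one pre-injection baseline frame"
                )
            prev_end = t.frame_range[-1]


@dataclass
class PermeabilityCurve:
    """Baseline-normalized extravascular intensity curve for one tracer.

    ``times`` are minutes from the tracer's baseline frame (t=0, value 1 by
    construction); ``values`` are I(t)/I0.
    """

    tracer_id: float | str
    times: np.ndarray
    values: np.ndarray
    baseline_intensity: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise StructuralError("times and values must align")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise StructuralError("times must start at 0 and increase strictly")
        if not np.isclose(self.values[0], 1.0):
            raise StructuralError("the baseline point must have value 1")
        if self.baseline_intensity <= 0:
            raise DegenerateInputError("baseline intensity I0 must be positive")


@dataclass
class PermeabilityResult:
    """AUC of (I/I0 - 1) over a tracer window, in dimensionless minutes."""

    tracer_id: float | str
    auc: float
    n_frames: int


def build_parenchyma_mask(
    vessel_mask_with_particles: np.ndarray,
    dilation_px: int = 2,
) -> np.ndarray:
    """Parenchyma = complement of the dilated vessel+particle mask.

    The subtraction mask must come from the permeability mask variant
    (autofluorescent particles retained) so their signal never contaminates
    the parenchymal mean.  The dilation margin (default 2 px) excludes
    perivascular point-spread bloom.
    """
    mask = np.asarray(vessel_mask_with_particles, dtype=bool)
    if dilation_px < 0:
        raise ParameterError("dilation margin must be >= 0")
    if dilation_px > 0:
        mask = morphology.dilation(mask, morphology.disk(dilation_px))
    parenchyma = ~mask
    if not parenchyma.any():
        raise DegenerateInputError("no parenchyma remains outside the vessel mask")
    return parenchyma


def extravascular_series(
    tracer_frames: list[np.ndarray] | np.ndarray,
    parenchyma: np.ndarray,
    baseline_frame: np.ndarray,
    frame_interval: float = 1.0,
    tracer_id: float | str = "tracer",
) -> PermeabilityCurve:
    """Mean parenchymal intensity per frame, normalized to the baseline.

    I(t) is the mean green intensity over the parenchyma mask at frame t
    (the mean, not the sum, so I/I0 is invariant to the mask's size); I0 is
    the same statistic on the last pre-injection frame.
    """
    parenchyma = np.asarray(parenchyma, dtype=bool)
    baseline_frame = np.asarray(baseline_frame, dtype=float)
    if baseline_frame.shape != parenchyma.shape:
        raise StructuralError("baseline frame and parenchyma mask must share a shape")
    i0 = float(baseline_frame[parenchyma].mean())
    if i0 <= 0:
        raise DegenerateInputError("degenerate baseline: I0 <= 0")

    values = [1.0]
    times = [0.0]
    for j, frame in enumerate(tracer_frames):
        frame = np.asarray(frame, dtype=float)
        if frame.shape != parenchyma.shape:
            raise StructuralError("tracer frame and parenchyma mask must share a shape")
        values.append(float(frame[parenchyma].mean()) / i0)
        times.append((j + 1) * frame_interval)
    return PermeabilityCurve(
        tracer_id=tracer_id,
        times=np.asarray(times),
        values=np.asarray(values),
        baseline_intensity=i0,
    )


def permeability_auc(curve: PermeabilityCurve) -> PermeabilityResult:
    """Trapezoidal AUC of (I/I0 - 1) over the tracer window.

    Negative excursions (photobleaching below baseline) are retained, not
    clipped, so a constant curve at 1 integrates to exactly 0.
    """
    if len(curve.times) < 2:
        raise ParameterError("AUC needs at least 2 curve points")
    auc = float(np.trapezoid(curve.values - 1.0, curve.times))
    return PermeabilityResult(
        tracer_id=curve.tracer_id, auc=auc, n_frames=len(curve.times) - 1
    )


def analyze_session(
    stack: Hyperstack,
    schedule: TracerSchedule | list[TracerSpec],
    parenchyma: np.ndarray,
    depth_window: tuple[float, float] = DEFAULT_DEPTH_WINDOW,
    tracer_channel: str = "tracer",
    return_curves: bool = False,
):
    """Per-tracer permeability results over a registered session hyperstack.

    Each tracer's baseline is the last frame before its own injection, so
    residual extravascular signal from earlier (larger) tracers is absorbed
    into I0 and the AUC isolates the new tracer's leak.  Green-channel MIPs
    reuse the 50-150 um depth window.

    Returns a list of :class:`PermeabilityResult` (with the matching
    :class:`PermeabilityCurve` list when ``return_curves``).
    """
    if not isinstance(schedule, TracerSchedule):
        schedule = TracerSchedule(list(schedule))
    if schedule.tracers[-1].frame_range[-1] >= stack.n_timepoints:
        raise ScheduleError("schedule frame ranges extend past the hyperstack")

    def green_mip(t: int) -> np.ndarray:
        return depth_window_mip(
            stack,
            z_min=depth_window[0],
            z_max=depth_window[1],
            timepoint=t,
            channel=tracer_channel,
        ).data

    results: list[PermeabilityResult] = []
    curves: list[PermeabilityCurve] = []
    for tracer in schedule.tracers:
        baseline = green_mip(tracer.injection_frame - 1)
        frames = [green_mip(t) for t in tracer.frame_range]
        curve = extravascular_series(
            frames,
            parenchyma,
            baseline,
            frame_interval=tracer.frame_interval,
            tracer_id=tracer.molecular_weight_kda,
        )
        curves.append(curve)
        results.append(permeability_auc(curve))
    if return_curves:
        return results, curves
    return results
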