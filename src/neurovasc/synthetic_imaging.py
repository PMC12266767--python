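"""Synthetic two-photon acquisition generator.

Produces ground-truthed hyperstacks that emulate an intravital BBB
permeability session: a 3D cortical vessel network labelled in the red
(vessel) channel, sequential FITC-dextran tracer injections whose
extravasation into parenchyma follows a well-mixed leak model in the green
(tracer) channel, photon (Poisson) noise over a Gaussian read-noise floor,
per-timepoint rigid drift, and small autofluorescent particles visible in
both channels.

Conventions
-----------
Voxel arrays are indexed ``(z, y, x)``; z index 0 is the cortical surface,
so depth in micrometres is ``z_index * z_spacing``.  Public parameters that
describe physical geometry use micrometre ``(x, y, z)`` triples, mirroring
how acquisition software reports voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._errors import ParameterError, ScheduleError, StructuralError
from ._utils import translate_volume

__all__ = [
    "VesselNetwork",
    "TracerSpec",
    "Hyperstack",
    "GroundTruth",
    "generate_vessel_network",
    "rasterize_network",
    "well_mixed_extravascular",
    "simulate_tracer_timecourse",
    "inject_drift",
    "add_autofluorescent_particles",
    "apply_noise",
    "simulate_session",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VesselNetwork:
    """Ground-truth vascular centerlines.

    segments
        Polylines as ``(n_vertices, 3)`` arrays of ``(x, y, z)`` micrometre
        coordinates.
    radius_per_segment
        One radius (micrometres) per polyline.
    bounds
        ``(x, y, z)`` extent of the imaged volume in micrometres.
    """

    segments: list[np.ndarray]
    radius_per_segment: list[float]
    bounds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.radius_per_segment):
            raise StructuralError("one radius is required per segment")
        bounds = np.asarray(self.bounds, dtype=float)
        if bounds.shape != (3,) or np.any(bounds <= 0):
            raise ParameterError("bounds must be a positive (x, y, z) triple")
        for r in self.radius_per_segment:
            if r <= 0:
                raise ParameterError("all vessel radii must be positive")
        for seg in self.segments:
            pts = np.asarray(seg, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3:
                raise StructuralError("segments must be (n, 3) coordinate arrays")
            if np.any(pts < -1e-9) or np.any(pts > bounds + 1e-9):
                raise ParameterError("polyline vertex outside the volume bounds")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_length(self) -> float:
        """Summed centerline length (micrometres) over all polylines."""
        total = 0.0
        for seg in self.segments:
            pts = np.asarray(seg, dtype=float)
            if len(pts) > 1:
                total += float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        return total


@dataclass(frozen=True)
class TracerSpec:
    """One injected fluorescent dextran tracer.

    ``leak_coefficient`` is the first-order BBB leak rate k (per minute) of
    the well-mixed extravascular model; ``injection_frame`` indexes the
    session hyperstack frame at which the tracer first appears.
    """

    molecular_weight_kda: float
    leak_coefficient: float
    injection_frame: int
    n_frames: int = 15
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.molecular_weight_kda <= 0:
            raise ParameterError("molecular weight must be positive")
        if self.leak_coefficient < 0:
            raise ParameterError("leak coefficient k must be >= 0")
        if self.n_frames < 2:
            raise ParameterError("a tracer time course needs at least 2 frames")
        if self.frame_interval <= 0:
            raise ParameterError("frame interval must be positive")
        if self.injection_frame < 0:
            raise ParameterError("injection frame must be >= 0")

    @property
    def frame_range(self) -> range:
        """Session frame indices covered by this tracer's acquisition window."""
        return range(self.injection_frame, self.injection_frame + self.n_frames)


@dataclass
class Hyperstack:
    """Multi-channel time-lapse z-stack.

    data
        Array of shape ``(T, C, Z, Y, X)``, nonnegative intensities.
    voxel_spacing
        ``(x, y, z)`` micrometres; z spacing defaults to the 5 um acquisition
        z-interval.
    channels
        Channel labels; the vessel (red) and tracer (green) channels are
        required by downstream stages.
    timestamps
        Acquisition time of each timepoint in minutes, strictly increasing.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    channels: tuple[str, ...] = ("vessel", "tracer")
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise StructuralError("hyperstack data must be (T, C, Z, Y, X)")
        if self.data.shape[1] != len(self.channels):
            raise StructuralError("channel axis does not match channel labels")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ParameterError("voxel spacing must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.data.shape[0], dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.data.shape[0],):
            raise StructuralError("one timestamp per timepoint is required")
        if self.data.shape[0] > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise StructuralError("timestamps must be strictly increasing")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def z_spacing(self) -> float:
        return float(self.voxel_spacing[2])

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise StructuralError(
                f"channel {name!r} not present (have {self.channels})"
            ) from None

    def volume(self, timepoint: int, channel: str) -> np.ndarray:
        """The (Z, Y, X) volume for one timepoint and channel."""
        return self.data[timepoint, self.channel_index(channel)]


@dataclass
class GroundTruth:
    """Truth recorded by the simulator for testing downstream stages."""

    vessel_mask: np.ndarray  # (Z, Y, X) bool, pre-noise, pre-drift
    drift_schedule: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3))
    )  # per-timepoint (dx, dy, dz) voxels
    leak_coefficients: dict[float, float] = field(default_factory=dict)
    particles: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.drift_schedule = np.asarray(self.drift_schedule, dtype=float)
        if self.drift_schedule.size and not np.all(np.isfinite(self.drift_schedule)):
            raise ParameterError("drift vectors must be finite")


# ---------------------------------------------------------------------------
# Vessel network generation
# ---------------------------------------------------------------------------


def generate_vessel_network(
    volume_size: tuple[float, float, float] = (192.0, 192.0, 200.0),
    n_vessels: int = 6,
    radius_range: tuple[float, float] = (3.0, 6.0),
    branching_prob: float = 0.08,
    seed: int | None = 0,
    step_um: float = 8.0,
) -> VesselNetwork:
    """Grow a random cortical-like vessel network inside a volume.

    Each seed vessel is a persistent random walk from a random interior
    point; at every step a side branch may sprout with ``branching_prob``.
    Walks terminate on leaving the volume (the last vertex is clipped to the
    boundary) or after spanning roughly twice the longest volume dimension.
    Deterministic for a fixed seed.
    """
    bounds = np.asarray(volume_size, dtype=float)
    if bounds.shape != (3,) or np.any(bounds <= 0):
        raise ParameterError("volume_size must be a positive (x, y, z) triple")
    r_lo, r_hi = float(radius_range[0]), float(radius_range[1])
    if r_lo <= 0 or r_hi < r_lo:
        raise ParameterError("radius_range must be positive and ordered")
    if n_vessels < 0:
        raise ParameterError("n_vessels must be >= 0")
    if not 0 <= branching_prob <= 1:
        raise ParameterError("branching_prob must be a probability")

    rng = np.random.default_rng(seed)
    max_steps = int(np.ceil(2.0 * bounds.max() / step_um))
    segments: list[np.ndarray] = []
    radii: list[float] = []

    # (start, direction, radius) tuples still to be grown
    queue: list[tuple[np.ndarray, np.ndarray, float]] = []
    for _ in range(n_vessels):
        start = rng.uniform(0.1, 0.9, size=3) * bounds
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        queue.append((start, direction, rng.uniform(r_lo, r_hi)))

    while queue:
        pos, direction, radius = queue.pop(0)
        pts = [pos.copy()]
        for _ in range(max_steps):
            direction = direction + rng.normal(scale=0.25, size=3)
            direction /= np.linalg.norm(direction)
            nxt = pts[-1] + step_um * direction
            if np.any(nxt < 0) or np.any(nxt > bounds):
                pts.append(np.clip(nxt, 0, bounds))
                break
            pts.append(nxt)
            if rng.random() < branching_prob:
                branch_dir = direction + rng.normal(scale=0.8, size=3)
                branch_dir /= np.linalg.norm(branch_dir)
                queue.append(
                    (nxt.copy(), branch_dir, max(r_lo, radius * rng.uniform(0.5, 0.9)))
                )
        if len(pts) > 1:
            segments.append(np.asarray(pts))
            radii.append(radius)

    return VesselNetwork(segments=segments, radius_per_segment=radii, bounds=tuple(bounds))


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _grid_shape(bounds, voxel_spacing) -> tuple[int, int, int]:
    sx, sy, sz = voxel_spacing
    bx, by, bz = bounds
    return (int(np.ceil(bz / sz)), int(np.ceil(by / sy)), int(np.ceil(bx / sx)))


def rasterize_network(
    network: VesselNetwork,
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 5.0),
    blur_sigma: float = 0.0,
    background: float = 0.0,
    foreground: float = 100.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize a network into a vessel-channel frame plus a truth mask.

    A voxel belongs to the truth mask when its centre lies within the radius
    of the nearest centerline (computed with an exact Euclidean distance
    transform under anisotropic voxel spacing).  The intensity frame is
    ``background + foreground * mask`` optionally blurred by a Gaussian PSF
    of ``blur_sigma`` micrometres.  ``seed`` is accepted for signature
    symmetry with the other generators; rasterization itself is
    deterministic and noise-free.

    Returns ``(frame, mask)``, both ``(Z, Y, X)``.
    """
    del seed  # rasterization is deterministic
    spacing = np.asarray(voxel_spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ParameterError("voxel_spacing must be a positive (x, y, z) triple")
    shape = _grid_shape(network.bounds, voxel_spacing)
    mask = np.zeros(shape, dtype=bool)

    if network.n_segments:
        # Rasterize centerlines as labelled voxels, then assign every voxel
        # the radius of its nearest centerline via EDT feature indices.
        seg_id = np.zeros(shape, dtype=np.int32)
        sx, sy, sz = spacing
        sample_step = float(min(spacing)) / 2.0
        for i, seg in enumerate(network.segments):
            pts = np.asarray(seg, dtype=float)
            for a, b in zip(pts[:-1], pts[1:]):
                length = np.linalg.norm(b - a)
                n = max(2, int(np.ceil(length / sample_step)) + 1)
                line = a + np.linspace(0, 1, n)[:, None] * (b - a)
                # nearest voxel *centre* (centre of voxel i is at (i + 0.5) * s)
                iz = np.clip(np.round(line[:, 2] / sz - 0.5).astype(int), 0, shape[0] - 1)
                iy = np.clip(np.round(line[:, 1] / sy - 0.5).astype(int), 0, shape[1] - 1)
                ix = np.clip(np.round(line[:, 0] / sx - 0.5).astype(int), 0, shape[2] - 1)
                seg_id[iz, iy, ix] = i + 1
        dist, indices = ndimage.distance_transform_edt(
            seg_id == 0, sampling=(sz, sy, sx), return_indices=True
        )
        nearest = seg_id[indices[0], indices[1], indices[2]]
        radii = np.asarray([0.0] + list(network.radius_per_segment))
        mask = dist <= radii[nearest]

    frame = background + foreground * mask.astype(float)
    if blur_sigma > 0:
        frame = ndimage.gaussian_filter(frame, sigma=blur_sigma / spacing[::-1])
    return frame, mask


# ---------------------------------------------------------------------------
# Tracer leakage
# ---------------------------------------------------------------------------


def well_mixed_extravascular(v0: float, k: float, t_minutes) -> np.ndarray | float:
    """Well-mixed extravascular tracer level E(t) = V0 * (1 - exp(-k t)).

    The closed-form compartment level before spatial deposition; the basis
    of the simulated green-channel extravascular signal.
    """
    if v0 <= 0:
        raise ParameterError("intravascular level V0 must be positive")
    if k < 0:
        raise ParameterError("leak coefficient k must be >= 0")
    return v0 * (1.0 - np.exp(-k * np.asarray(t_minutes, dtype=float)))


def _deposition_weights(
    truth_mask: np.ndarray,
    voxel_spacing: tuple[float, float, float],
    deposition_sigma_um: float,
) -> np.ndarray:
    """Distance-decaying spatial kernel for extravasated tracer.

    Weight ``exp(-d^2 / (2 sigma^2))`` of the distance d (um) from the
    vessel wall; 0 inside vessels, since intravascular voxels carry the
    intravascular level instead.
    """
    sx, sy, sz = voxel_spacing
    dist = ndimage.distance_transform_edt(~truth_mask, sampling=(sz, sy, sx))
    w = np.exp(-(dist**2) / (2.0 * deposition_sigma_um**2))
    w[truth_mask] = 0.0
    return w


def apply_noise(
    frame: np.ndarray,
    rng: np.random.Generator,
    photon_scale: float = 2.0,
    read_noise_sd: float = 1.0,
) -> np.ndarray:
    """Poisson photon noise plus a Gaussian read-noise floor.

    ``photon_scale`` is the expected photon count per intensity unit; larger
    values mean lower relative shot noise.  Output clipped to >= 0.
    """
    if photon_scale <= 0:
        raise ParameterError("photon_scale must be positive")
    noisy = rng.poisson(np.clip(frame, 0, None) * photon_scale) / photon_scale
    if read_noise_sd > 0:
        noisy = noisy + rng.normal(scale=read_noise_sd, size=frame.shape)
    return np.clip(noisy, 0, None)


def simulate_tracer_timecourse(
    truth_mask: np.ndarray,
    tracer: TracerSpec,
    v0: float = 100.0,
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 5.0),
    deposition_sigma_um: float = 15.0,
    background: float = 0.0,
    photon_scale: float | None = None,
    read_noise_sd: float = 1.0,
    seed: int | None = 0,
) -> np.ndarray:
    """Simulate the green (tracer) channel over one tracer's 15-min window.

    Frame j (j = 0 .. n_frames-1) is acquired ``(j + 1) * frame_interval``
    minutes after injection.  Intravascular voxels carry the constant
    plasma level V0; extravascular voxels carry the well-mixed level
    ``E(t) = V0 (1 - e^{-k t})`` shaped by a Gaussian distance-decay kernel
    from the vessel wall.  Photon noise is applied only when
    ``photon_scale`` is given.  Deterministic per seed.

    Returns an array of shape ``(n_frames, Z, Y, X)``.
    """
    if v0 <= 0:
        raise ParameterError("intravascular level V0 must be positive")
    truth_mask = np.asarray(truth_mask, dtype=bool)
    weights = _deposition_weights(truth_mask, voxel_spacing, deposition_sigma_um)
    rng = np.random.default_rng(seed)

    frames = np.empty((tracer.n_frames,) + truth_mask.shape, dtype=float)
    for j in range(tracer.n_frames):
        t = (j + 1) * tracer.frame_interval
        extravascular = well_mixed_extravascular(v0, tracer.leak_coefficient, t)
        frame = background + extravascular * weights
        frame[truth_mask] = background + v0
        if photon_scale is not None:
            frame = apply_noise(frame, rng, photon_scale, read_noise_sd)
        frames[j] = frame
    return frames


# ---------------------------------------------------------------------------
# Drift and particles
# ---------------------------------------------------------------------------


def inject_drift(
    frames: np.ndarray,
    drift_schedule: np.ndarray,
    fill: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a per-timepoint rigid translation to a frame sequence.

    ``frames`` is ``(T, Z, Y, X)`` or ``(T, C, Z, Y, X)``; the same shift is
    applied to every channel of a timepoint.  ``drift_schedule`` rows are
    ``(dx, dy, dz)`` voxel shifts (possibly fractional).  Returns the
    shifted frames and the schedule as applied (the recorded truth).
    """
    frames = np.asarray(frames)
    if frames.ndim not in (4, 5):
        raise ParameterError("frames must be (T, Z, Y, X) or (T, C, Z, Y, X)")
    schedule = np.atleast_2d(np.asarray(drift_schedule, dtype=float))
    if schedule.shape != (frames.shape[0], 3):
        raise ParameterError("drift_schedule must provide one (dx, dy, dz) per frame")

    out = np.empty_like(frames, dtype=float)
    for t, (dx, dy, dz) in enumerate(schedule):
        shift_zyx = (dz, dy, dx)
        if frames.ndim == 4:
            out[t] = translate_volume(frames[t], shift_zyx, fill=fill)
        else:
            for c in range(frames.shape[1]):
                out[t, c] = translate_volume(frames[t, c], shift_zyx, fill=fill)
    return out, schedule.copy()


def add_autofluorescent_particles(
    frame: np.ndarray,
    n_particles: int = 20,
    area_range: tuple[float, float] = (4.0, 40.0),
    intensity: float = 120.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, list[dict]]:
    """Deposit small bright autofluorescent blobs into a (Z, Y, X) volume.

    Each particle is a filled disk of the requested pixel area placed in a
    single random z slice (debris is optically thin compared with the 5 um
    z step).  Returns the modified volume and a truth list of particle
    records ``{"z", "y", "x", "radius_px", "pixels"}``.
    """
    from skimage.draw import disk as draw_disk

    frame = np.asarray(frame, dtype=float).copy()
    if frame.ndim != 3:
        raise ParameterError("frame must be a (Z, Y, X) volume")
    if n_particles < 0:
        raise ParameterError("n_particles must be >= 0")
    lo, hi = float(area_range[0]), float(area_range[1])
    if lo < 1 or hi < lo:
        raise ParameterError("particle areas must be >= 1 px^2 and ordered")

    rng = np.random.default_rng(seed)
    nz, ny, nx = frame.shape
    truth: list[dict] = []
    for _ in range(n_particles):
        area = rng.uniform(lo, hi)
        radius = max(0.5, np.sqrt(area / np.pi))
        z = int(rng.integers(0, nz))
        y = float(rng.uniform(radius, ny - radius))
        x = float(rng.uniform(radius, nx - radius))
        rr, cc = draw_disk((y, x), radius, shape=(ny, nx))
        frame[z, rr, cc] += intensity
        truth.append(
            {"z": z, "y": y, "x": x, "radius_px": float(radius), "pixels": int(len(rr))}
        )
    return frame, truth


# ---------------------------------------------------------------------------
# Whole-session assembly
# ---------------------------------------------------------------------------

#: Default tracer panel: molecular weight (kDa) -> leak coefficient (1/min).
#: Smaller dextrans cross the barrier faster.
DEFAULT_TRACER_PANEL: tuple[tuple[float, float], ...] = (
    (40.0, 0.01),
    (3.0, 0.04),
    (0.3, 0.10),
)


def simulate_session(
    volume_size: tuple[float, float, float] = (192.0, 192.0, 200.0),
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 5.0),
    n_vessels: int = 6,
    radius_range: tuple[float, float] = (3.0, 6.0),
    tracer_panel: tuple[tuple[float, float], ...] = DEFAULT_TRACER_PANEL,
    n_frames_per_tracer: int = 15,
    frame_interval: float = 1.0,
    v0: float = 100.0,
    background: float = 5.0,
    vessel_intensity: float = 100.0,
    blur_sigma: float = 1.0,
    deposition_sigma_um: float = 15.0,
    photon_scale: float | None = 2.0,
    read_noise_sd: float = 1.0,
    max_drift_voxels: int = 0,
    n_particles: int = 0,
    particle_area_range: tuple[float, float] = (4.0, 40.0),
    seed: int | None = 0,
) -> tuple[Hyperstack, GroundTruth, list[TracerSpec]]:
    """Simulate a complete sequential-tracer BBB imaging session.

    Frame 0 is the vessel-label baseline; each tracer then occupies
    ``n_frames_per_tracer`` consecutive one-per-minute frames.  All injected
    tracers share the green channel, so intravascular green intensity steps
    up by V0 at each injection and extravascular signal accumulates; each
    tracer's leak is frozen at the end of its own acquisition window (its
    plasma supply is superseded by the next injection), which is what makes
    per-tracer baseline re-anchoring meaningful downstream.

    Drift is a cumulative integer random walk bounded by
    ``max_drift_voxels`` per axis.  Set ``photon_scale=None`` for noise-free
    output.  Returns ``(hyperstack, ground_truth, tracer_specs)``.
    """
    if sorted((mw for mw, _ in tracer_panel), reverse=True) != [
        mw for mw, _ in tracer_panel
    ]:
        raise ScheduleError("tracer panel must be ordered by decreasing molecular weight")

    rng = np.random.default_rng(seed)
    network = generate_vessel_network(
        volume_size,
        n_vessels=n_vessels,
        radius_range=radius_range,
        seed=int(rng.integers(2**31)),
    )
    vessel_frame, truth_mask = rasterize_network(
        network,
        voxel_spacing,
        blur_sigma=blur_sigma,
        background=background,
        foreground=vessel_intensity,
    )
    weights = _deposition_weights(truth_mask, voxel_spacing, deposition_sigma_um)

    tracers = [
        TracerSpec(
            molecular_weight_kda=mw,
            leak_coefficient=k,
            injection_frame=1 + i * n_frames_per_tracer,
            n_frames=n_frames_per_tracer,
            frame_interval=frame_interval,
        )
        for i, (mw, k) in enumerate(tracer_panel)
    ]
    n_timepoints = 1 + n_frames_per_tracer * len(tracers)

    data = np.empty((n_timepoints, 2) + truth_mask.shape, dtype=float)
    for t in range(n_timepoints):
        green = np.full(truth_mask.shape, background, dtype=float)
        n_injected = sum(t >= tr.injection_frame for tr in tracers)
        extravascular = 0.0
        for tr in tracers:
            if t < tr.injection_frame:
                continue
            minutes = (t - tr.injection_frame + 1) * frame_interval
            minutes = min(minutes, tr.n_frames * frame_interval)  # leak freezes
            extravascular += well_mixed_extravascular(
                v0, tr.leak_coefficient, minutes
            )
        green += extravascular * weights
        green[truth_mask] = background + v0 * n_injected
        data[t, 0] = vessel_frame
        data[t, 1] = green

    particles: list[dict] = []
    if n_particles > 0:
        particle_seed = int(rng.integers(2**31))
        # identical debris in both channels (autofluorescence is broadband)
        bumped, particles = add_autofluorescent_particles(
            np.zeros(truth_mask.shape),
            n_particles=n_particles,
            area_range=particle_area_range,
            seed=particle_seed,
        )
        data += bumped[None, None]

    drift = np.zeros((n_timepoints, 3))
    if max_drift_voxels > 0:
        steps = rng.integers(-1, 2, size=(n_timepoints, 3))
        steps[0] = 0
        drift = np.clip(np.cumsum(steps, axis=0), -max_drift_voxels, max_drift_voxels)
        data, drift = inject_drift(data, drift, fill=background)

    if photon_scale is not None:
        for t in range(n_timepoints):
            for c in range(2):
                data[t, c] = apply_noise(data[t, c], rng, photon_scale, read_noise_sd)

    stack = Hyperstack(
        data=data,
        voxel_spacing=voxel_spacing,
        channels=("vessel", "tracer"),
        timestamps=np.arange(n_timepoints) * frame_interval,
    )
    truth = GroundTruth(
        vessel_mask=truth_mask,
        drift_schedule=drift,
        leak_coefficients={tr.molecular_weight_kda: tr.leak_coefficient for tr in tracers},
        particles=particles,
    )
    return stack, truth, tracers
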