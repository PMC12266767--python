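"""Microvascular morphometry: area density (%) and length density (um/um^2).

Both readouts are computed on the processed 2D binary mask of the depth
window's maximum-intensity projection.  Area density is the foreground
fraction of the projection.  Length density divides the summed centerline
length of the skeletonized mask by the projection area.

Skeleton length is measured by tracing each skeleton branch as an ordered
pixel path and summing chord lengths over short windows of the path
(default 4 steps).  Chord sampling is exact for axis-aligned and 45-degree
runs and keeps the digital-geometry bias of oblique lines well under the
5% the naive axial-1/diagonal-sqrt(2) step sum incurs at ~30 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import morphology

from ._errors import DegenerateInputError
from .segmentation import (
    DEFAULT_DEPTH_WINDOW,
    PixelClassifier,
    depth_window_mip,
    segmentation_masks,
)
from .synthetic_imaging import Hyperstack

__all__ = [
    "Skeleton",
    "MorphometryResult",
    "area_density",
    "skeletonize_mask",
    "skeleton_length",
    "length_density",
    "morphometry_report",
]


@dataclass
class Skeleton:
    """Unit-width centerline image with its physical pixel size (um)."""

    data: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise DegenerateInputError("skeleton must be a 2D grid")


@dataclass
class MorphometryResult:
    area_density_pct: float
    length_density_um_per_um2: float
    voi_area_um2: float
    total_length_um: float
    intermediates: dict = field(default_factory=dict)


def area_density(mask: np.ndarray) -> float:
    """Vascular area coverage: 100 * foreground pixels / total pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise DegenerateInputError("cannot compute area density of an empty grid")
    return 100.0 * float(mask.sum()) / mask.size


def skeletonize_mask(mask: np.ndarray, pixel_size: float = 1.0) -> Skeleton:
    """Topology-preserving thinning of the vessel mask to centerlines."""
    mask = np.asarray(mask, dtype=bool)
    return Skeleton(data=morphology.skeletonize(mask), pixel_size=pixel_size)


_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def _trace_paths(skel: np.ndarray) -> list[list[tuple[int, int]]]:
    """Decompose a skeleton into ordered pixel paths.

    Branches run between nodes of degree != 2 (endpoints and junctions);
    leftover pure cycles are traced from an arbitrary start.  Every
    8-adjacency edge is used exactly once across all returned paths.
    """
    coords = set(zip(*np.nonzero(skel)))
    neighbors: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for p in coords:
        neighbors[p] = [
            (p[0] + dy, p[1] + dx)
            for dy, dx in _NEIGHBOR_OFFSETS
            if (p[0] + dy, p[1] + dx) in coords
        ]

    visited_edges: set[frozenset] = set()
    paths: list[list[tuple[int, int]]] = []

    def walk(start, nxt):
        path = [start, nxt]
        visited_edges.add(frozenset((start, nxt)))
        while len(neighbors[path[-1]]) == 2:
            a, b = neighbors[path[-1]]
            step = a if frozenset((path[-1], a)) not in visited_edges else b
            if frozenset((path[-1], step)) in visited_edges:
                break  # closed loop back onto itself
            visited_edges.add(frozenset((path[-1], step)))
            path.append(step)
        return path

    nodes = [p for p in coords if len(neighbors[p]) != 2]
    for node in nodes:
        for nb in neighbors[node]:
            if frozenset((node, nb)) not in visited_edges:
                paths.append(walk(node, nb))
    # remaining edges belong to cycles with all-degree-2 pixels
    for p in coords:
        for nb in neighbors[p]:
            if frozenset((p, nb)) not in visited_edges:
                paths.append(walk(p, nb))
    return paths


def skeleton_length(skeleton: Skeleton | np.ndarray, pixel_size: float | None = None,
                    chord_step: int = 4) -> float:
    """Total centerline length in micrometres.

    Each traced branch is measured as the sum of Euclidean chords between
    path pixels ``chord_step`` apart (remainder as a final shorter chord).
    """
    if isinstance(skeleton, Skeleton):
        skel = skeleton.data
        pixel_size = skeleton.pixel_size if pixel_size is None else pixel_size
    else:
        skel = np.asarray(skeleton, dtype=bool)
        pixel_size = 1.0 if pixel_size is None else pixel_size

    total = 0.0
    for path in _trace_paths(skel):
        pts = np.asarray(path, dtype=float)
        for i in range(0, len(pts) - 1, chord_step):
            j = min(i + chord_step, len(pts) - 1)
            total += float(np.linalg.norm(pts[j] - pts[i]))
    return total * pixel_size


def length_density(skeleton: Skeleton, chord_step: int = 4) -> float:
    """Vascular length density: centerline length / projection area (um/um^2)."""
    if skeleton.data.size == 0:
        raise DegenerateInputError("cannot compute length density of an empty grid")
    area_um2 = skeleton.data.size * skeleton.pixel_size**2
    return skeleton_length(skeleton, chord_step=chord_step) / area_um2


def morphometry_report(
    stack: Hyperstack,
    classifier: PixelClassifier,
    timepoint: int = 0,
    depth_window: tuple[float, float] = DEFAULT_DEPTH_WINDOW,
    prob_threshold: float = 0.5,
    max_particle_area: int = 20,
    smooth_radius: int = 2,
) -> MorphometryResult:
    """Full morphometry chain on a registered stack.

    MIP over the depth window -> pixel classification -> particle filter ->
    closing -> area density; skeletonization of the smoothed mask -> length
    density.  All intermediate images are kept in ``intermediates`` so both
    mask variants can be inspected or persisted.
    """
    projection = depth_window_mip(
        stack, z_min=depth_window[0], z_max=depth_window[1], timepoint=timepoint
    )
    masks = segmentation_masks(
        projection,
        classifier,
        prob_threshold=prob_threshold,
        max_particle_area=max_particle_area,
        smooth_radius=smooth_radius,
    )
    mask = masks["morphometry"]
    skel = skeletonize_mask(mask, pixel_size=projection.pixel_size)
    voi_area = mask.size * projection.pixel_size**2
    total_len = skeleton_length(skel)
    return MorphometryResult(
        area_density_pct=area_density(mask),
        length_density_um_per_um2=total_len / voi_area,
        voi_area_um2=voi_area,
        total_length_um=total_len,
        intermediates={"projection": projection, **masks, "skeleton": skel},
    )
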