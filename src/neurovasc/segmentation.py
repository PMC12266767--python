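"""Vessel segmentation on depth-windowed maximum-intensity projections.

The quantified field of view is the 50-150 um depth window of the cortex:
the uppermost 50 um is dominated by meningeal vessels and is excluded.  The
windowed z-stack is collapsed to a 2D maximum-intensity projection, vessels
are separated from parenchyma by a supervised pixel classifier (an ensemble
of decision trees over a multi-scale intensity/gradient/tubeness feature
bank, trained from sparse user scribbles), and the binary mask is cleaned
by a small-particle exclusion filter and morphological closing.

Two mask variants feed downstream stages: the morphometry mask (particles
removed, edges smoothed) and the permeability mask (particles retained so
that their autofluorescence is subtracted from parenchyma together with the
vessels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from ._errors import DegenerateInputError, ParameterError, StructuralError
from .synthetic_imaging import Hyperstack

__all__ = [
    "ProjectionImage",
    "PixelClassifier",
    "depth_window_mip",
    "compute_pixel_features",
    "train_pixel_classifier",
    "segment_vessels",
    "filter_particles",
    "smooth_mask",
]

DEFAULT_SIGMAS_UM = (1.0, 2.0, 4.0)
DEFAULT_DEPTH_WINDOW = (50.0, 150.0)


@dataclass
class ProjectionImage:
    """A 2D maximum-intensity projection plus its provenance."""

    data: np.ndarray
    pixel_size: float
    depth_window: tuple[float, float]
    channel: str = "vessel"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise StructuralError("projection data must be 2D")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        z_min, z_max = self.depth_window
        if z_min >= z_max:
            raise ParameterError("depth window must satisfy z_min < z_max")


@dataclass
class PixelClassifier:
    """Trained vessel/background pixel classifier.

    Wraps the tree ensemble together with the feature configuration it was
    trained on, so a mismatched feature bank at prediction time is caught
    instead of silently producing garbage.
    """

    model: RandomForestClassifier
    sigmas_um: tuple[float, ...]
    pixel_size: float
    holdout_accuracy: float = float("nan")
    classes: tuple[str, str] = ("vessel", "background")
    extra: dict = field(default_factory=dict)


def depth_window_mip(
    volume: np.ndarray | Hyperstack,
    z_spacing: float | None = None,
    z_min: float = DEFAULT_DEPTH_WINDOW[0],
    z_max: float = DEFAULT_DEPTH_WINDOW[1],
    pixel_size: float | None = None,
    timepoint: int = 0,
    channel: str = "vessel",
) -> ProjectionImage:
    """Maximum-intensity projection over slices with depth in [z_min, z_max).

    Accepts either a raw ``(Z, Y, X)`` volume (with ``z_spacing`` and
    ``pixel_size`` given explicitly) or a :class:`Hyperstack`, from which
    one timepoint/channel volume and the spacings are taken.  Slice depth is
    ``z_index * z_spacing``.  Raises :class:`ParameterError` when the window
    does not intersect the stack extent.
    """
    if isinstance(volume, Hyperstack):
        stack = volume
        vol = stack.volume(timepoint, channel)
        z_spacing = stack.z_spacing
        pixel_size = float(stack.voxel_spacing[0])
    else:
        vol = np.asarray(volume, dtype=float)
        if z_spacing is None:
            raise ParameterError("z_spacing is required for a raw volume")
        if pixel_size is None:
            pixel_size = 1.0
    if vol.ndim != 3:
        raise StructuralError("expected a (Z, Y, X) volume")
    if z_min >= z_max:
        raise ParameterError("depth window must satisfy z_min < z_max")

    depths = np.arange(vol.shape[0]) * float(z_spacing)
    included = (depths >= z_min) & (depths < z_max)
    if not included.any():
        raise ParameterError(
            f"depth window [{z_min}, {z_max}) um selects no slices "
            f"(stack spans 0-{depths[-1]:g} um)"
        )
    return ProjectionImage(
        data=vol[included].max(axis=0),
        pixel_size=float(pixel_size),
        depth_window=(z_min, z_max),
        channel=channel,
    )


def compute_pixel_features(
    image: ProjectionImage | np.ndarray,
    sigmas_um: tuple[float, ...] = DEFAULT_SIGMAS_UM,
    pixel_size: float | None = None,
) -> np.ndarray:
    """Multi-scale per-pixel feature bank for vessel classification.

    For each scale sigma (micrometres): Gaussian smoothing, gradient
    magnitude, and the two Hessian eigenvalues (the smallest is strongly
    negative on bright tubular structures — the classic tubeness cue),
    plus the raw intensity.  Returns ``(H, W, 1 + 4 * len(sigmas))``.
    """
    if isinstance(image, ProjectionImage):
        data = image.data
        pixel_size = image.pixel_size
    else:
        data = np.asarray(image, dtype=float)
        pixel_size = 1.0 if pixel_size is None else pixel_size
    if not len(sigmas_um):
        raise ParameterError("sigma set must be non-empty")
    if not np.all(np.isfinite(data)):
        raise ParameterError("input image contains non-finite pixels")

    feats = [data]
    for sigma_um in sigmas_um:
        sigma_px = float(sigma_um) / pixel_size
        smoothed = ndimage.gaussian_filter(data, sigma_px)
        grad = ndimage.gaussian_gradient_magnitude(data, sigma_px)
        h = hessian_matrix(
            data, sigma=sigma_px, order="rc", mode="reflect",
            use_gaussian_derivatives=False,
        )
        eig_hi, eig_lo = hessian_matrix_eigvals(h)  # sorted descending
        feats.extend([smoothed, grad, eig_lo, eig_hi])
    return np.stack(feats, axis=-1)


def train_pixel_classifier(
    image: ProjectionImage,
    labels: np.ndarray,
    sigmas_um: tuple[float, ...] = DEFAULT_SIGMAS_UM,
    n_trees: int = 100,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> PixelClassifier:
    """Train the vessel/background classifier from sparse pixel annotations.

    ``labels`` is an integer image aligned with the projection: 0 =
    unlabelled, 1 = vessel, 2 = background.  A stratified holdout split
    reports generalization accuracy.  Deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    if labels.shape != image.data.shape:
        raise StructuralError("label image must match the projection shape")
    present = np.unique(labels[labels > 0])
    if len(present) < 2:
        raise ParameterError("training requires annotations for both classes")

    features = compute_pixel_features(image, sigmas_um)
    idx = labels > 0
    x = features[idx]
    y = labels[idx]

    if 0 < holdout_fraction < 1 and np.all(np.bincount(y)[1:] >= 2):
        x_tr, x_ho, y_tr, y_ho = train_test_split(
            x, y, test_size=holdout_fraction, stratify=y, random_state=seed
        )
    else:
        x_tr, x_ho, y_tr, y_ho = x, x, y, y

    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(x_tr, y_tr)
    accuracy = float(model.score(x_ho, y_ho))
    return PixelClassifier(
        model=model,
        sigmas_um=tuple(float(s) for s in sigmas_um),
        pixel_size=image.pixel_size,
        holdout_accuracy=accuracy,
    )


def segment_vessels(
    image: ProjectionImage,
    classifier: PixelClassifier,
    prob_threshold: float = 0.5,
) -> np.ndarray:
    """Classify every pixel; vessel where P(vessel) >= threshold.

    A pixel whose probability lands exactly on the threshold counts as
    vessel (>= rule).  Raises :class:`StructuralError` when the projection's
    pixel size differs from the classifier's training configuration.
    """
    if not np.isclose(image.pixel_size, classifier.pixel_size):
        raise StructuralError(
            "projection pixel size differs from the classifier's training "
            f"configuration ({image.pixel_size} vs {classifier.pixel_size})"
        )
    features = compute_pixel_features(image, classifier.sigmas_um)
    flat = features.reshape(-1, features.shape[-1])
    proba = classifier.model.predict_proba(flat)
    vessel_col = list(classifier.model.classes_).index(1)
    p_vessel = proba[:, vessel_col].reshape(image.data.shape)
    return p_vessel >= prob_threshold


def _component_circularity(region) -> float:
    perimeter = region.perimeter_crofton
    if perimeter <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * region.area / perimeter**2)


def filter_particles(
    mask: np.ndarray,
    max_area: int = 20,
    circularity_range: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Remove small autofluorescent-particle components from a binary mask.

    An 8-connected component is removed when its area is <= ``max_area``
    pixels AND its circularity (4*pi*area/perimeter^2, Crofton perimeter,
    clipped to <= 1) lies inside ``circularity_range`` (inclusive).  The
    default range [0, 1] admits every shape, so the filter acts on area
    alone.  Never adds pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    labelled = measure.label(mask, connectivity=2)
    out = mask.copy()
    lo, hi = circularity_range
    for region in measure.regionprops(labelled):
        if region.area <= max_area and lo <= _component_circularity(region) <= hi:
            out[labelled == region.label] = False
    return out


def smooth_mask(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Smooth vessel edges by morphological closing with a disk.

    Maximum filter (dilation) followed by minimum filter (erosion): fills
    gaps and concavities narrower than the structuring element without
    shrinking vessels.  ``radius=0`` is the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    if radius == 0:
        return mask.copy()
    return morphology.closing(mask, morphology.disk(radius))


def segmentation_masks(
    image: ProjectionImage,
    classifier: PixelClassifier,
    prob_threshold: float = 0.5,
    max_particle_area: int = 20,
    smooth_radius: int = 2,
) -> dict[str, np.ndarray]:
    """Produce both downstream mask variants from one classification.

    Returns ``{"raw", "morphometry", "permeability"}``: the raw classifier
    mask, the particle-filtered and smoothed morphometry mask, and the
    particle-retaining permeability mask (smoothed only).
    """
    raw = segment_vessels(image, classifier, prob_threshold)
    morpho = smooth_mask(filter_particles(raw, max_particle_area), smooth_radius)
    permeability = smooth_mask(raw, smooth_radius)
    if raw.size and not raw.any():
        raise DegenerateInputError("classifier produced an empty vessel mask")
    return {"raw": raw, "morphometry": morpho, "permeability": permeability}
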