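"""Shared fixtures: small simulated sessions and trained classifiers.

Session-scoped so the expensive phantoms are built once per run.
"""

import numpy as np
import pytest

from neurovasc import segmentation as seg
from neurovasc import synthetic_imaging as si


def truth_projection(truth, z_spacing, z_min=50.0, z_max=150.0):
    """Ground-truth vessel mask projected over the quantification window."""
    depths = np.arange(truth.vessel_mask.shape[0]) * z_spacing
    sel = (depths >= z_min) & (depths < z_max)
    return truth.vessel_mask[sel].any(axis=0)


def sample_training_labels(truth_mip, n_per_class=500, seed=0):
    """Sparse scribble labels (1=vessel, 2=background) from the truth MIP."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(truth_mip.shape, dtype=int)
    for cls, pool in ((1, np.argwhere(truth_mip)), (2, np.argwhere(~truth_mip))):
        pick = pool[rng.choice(len(pool), min(n_per_class, len(pool)), replace=False)]
        labels[pick[:, 0], pick[:, 1]] = cls
    return labels


@pytest.fixture(scope="session")
def default_session():
    """One noisy single-tracer session with ground truth (no drift/particles)."""
    stack, truth, tracers = si.simulate_session(
        volume_size=(192.0, 192.0, 200.0),
        voxel_spacing=(2.0, 2.0, 5.0),
        n_vessels=6,
        tracer_panel=((40.0, 0.05),),
        seed=11,
    )
    return stack, truth, tracers


@pytest.fixture(scope="session")
def trained_classifier(default_session):
    """Pixel classifier trained on 500 scribbles per class from the truth."""
    stack, truth, _ = default_session
    projection = seg.depth_window_mip(stack, timepoint=0)
    truth_mip = truth_projection(truth, stack.z_spacing)
    labels = sample_training_labels(truth_mip, n_per_class=500, seed=0)
    classifier = seg.train_pixel_classifier(projection, labels, seed=0)
    return projection, truth_mip, classifier
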