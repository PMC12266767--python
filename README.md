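# neurovasc

Quantification pipeline for three readouts of neurovascular aging:

1. **Blood–brain-barrier permeability** from intravital two-photon
   sequential-tracer sessions — 3D drift correction, vessel segmentation,
   and the per-tracer extravascular *I/I₀* AUC statistic;
2. **Microvascular morphometry** — vascular area density (%) and skeleton
   length density (µm/µm²) on depth-windowed maximum-intensity
   projections;
3. **Single-cell senescence** — per-cell rank-based (recovery-curve AUC)
   gene-set enrichment scores, QC filtering, distribution-based
   senescent/non-senescent classification, signature annotation, and
   flow-cytometry gating fractions.

It is written for labs quantifying tracer extravasation and vascular
senescence, and for anyone who needs a tested, scriptable re-implementation
of this ImageJ/AUCell-style workflow. A ground-truthed synthetic
acquisition generator makes every stage testable without microscope or
sequencer data.

## The statistics at the core

**Relative permeability.** For each sequentially injected FITC-dextran
tracer, the mean green-channel intensity over brain parenchyma (outside
the dilated vessel + particle mask) is tracked through the tracer's
15-minute window and normalized to its own pre-injection baseline *I₀*:

    AUC = ∫₀ᵀ ( I(t)/I₀ − 1 ) dt        (trapezoidal, T = 15 min)

Zero for an intact barrier, strictly increasing in the leak rate *k*, and
invariant to detector gain. Each tracer's baseline is the last frame
before its own injection, absorbing residual signal from earlier tracers.

**Morphometry.** Area density = 100 × foreground / total pixels of the
processed binary mask; length density = skeleton centerline length /
projection area, measured by branch tracing with Euclidean chord sampling
(exact on axial and 45° runs, ≲1.5% on oblique tubes).

**Senescence score.** Genes are ranked per cell by expression; the score
is the area under the gene-set recovery curve across the top 5% of the
ranking, normalized to the maximal achievable area — a value in [0, 1].
Cells are thresholded at the minimum-density valley between the two score
modes (fallback: mean + 2 SD).

## Worked example

```python
import numpy as np
from neurovasc import synthetic_imaging as si, registration as reg
from neurovasc import segmentation as seg, morphometry as morpho, permeability as perm

# simulate a drifting three-tracer session (40, 3, 0.3 kDa)
stack, truth, tracers = si.simulate_session(max_drift_voxels=3, n_particles=20, seed=0)

# 1) drift correction, estimated on the vessel channel
registered, shifts = reg.register_hyperstack(stack)

# 2) pixel classifier from 500 scribbles per class (here sampled from truth)
projection = seg.depth_window_mip(registered, timepoint=0)
depths = np.arange(truth.vessel_mask.shape[0]) * stack.z_spacing
truth_mip = truth.vessel_mask[(depths >= 50) & (depths < 150)].any(axis=0)
rng = np.random.default_rng(0)
labels = np.zeros(truth_mip.shape, int)
for cls, pool in ((1, np.argwhere(truth_mip)), (2, np.argwhere(~truth_mip))):
    pick = pool[rng.choice(len(pool), 500, replace=False)]
    labels[pick[:, 0], pick[:, 1]] = cls
classifier = seg.train_pixel_classifier(projection, labels, seed=0)
masks = seg.segmentation_masks(projection, classifier)

# 3) morphometry on the particle-filtered, smoothed mask
report = morpho.morphometry_report(registered, classifier)
print(f"vascular area density: {report.area_density_pct:.1f} %")
print(f"vascular length density: {report.length_density_um_per_um2:.4f} um/um^2")

# 4) per-tracer permeability AUC
parenchyma = perm.build_parenchyma_mask(masks["permeability"])
for r in perm.analyze_session(registered, tracers, parenchyma):
    print(f"tracer {r.tracer_id:>5} kDa: AUC = {r.auc:.2f}")
```

Output:

```
vascular area density: 24.5 %
vascular length density: 0.0236 um/um^2
tracer  40.0 kDa: AUC = 4.48
tracer   3.0 kDa: AUC = 11.98
tracer   0.3 kDa: AUC = 9.79
```

A quarter of the projected field is vascular, and the 3 kDa dextran leaks
far more than the 40 kDa one. The 0.3 kDa ratio-AUC reads *lower* than the
3 kDa one despite its faster leak because residual signal from the earlier
tracers inflates its baseline *I₀*; within one session, leak rates are
compared on the un-normalized integral `auc * curve.baseline_intensity`
(see `docs/methods.md`).

The same stages are available from the shell:

```bash
neurovasc simulate --seed 0 --out-dir session/
neurovasc register --stack session/hyperstack.tiff --out registered.tiff --log shifts.csv
neurovasc segment --stack registered.tiff --train-labels labels.tiff --out-dir masks/
neurovasc morph --mask masks/mask_morphometry.tiff --pixel-size 2.0 --out-csv morph.csv
neurovasc perm --stack registered.tiff --schedule session/schedule.json \
               --vessel-mask masks/mask_permeability.tiff --out-dir perm/
neurovasc senescence --counts counts.csv --out-csv scores.csv
```

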