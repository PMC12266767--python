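# Methods

This note documents the models, conventions, and numerical choices behind
`neurovasc`, and what the synthetic study conditions do and do not
establish about real acquisitions.

## Synthetic two-photon sessions

The generator emulates a sequential-tracer blood–brain-barrier (BBB)
imaging session through a chronic cranial window: a red channel carrying a
static vessel label (WGA-like) and a green channel shared by all injected
FITC-dextran tracers.

**Vessel network.** Seed vessels are persistent 3D random walks (8 µm
steps, Gaussian angular jitter, branch probability 0.08 per step) inside
the imaged volume; each polyline carries one radius drawn from 3–6 µm.
The default volume is 192 × 192 × 200 µm at (2, 2, 5) µm voxel spacing —
the 5 µm z-step matches the acquisition convention, and 200 µm of depth
covers the quantified 50–150 µm window. Voxelization assigns every voxel
the radius of its nearest centerline via an anisotropic Euclidean distance
transform; the resulting truth mask is a capsule around each polyline
(hemispherical end caps are an inherent property of the distance-based
construction and are accounted for in the geometry tests).

**Leak model.** Extravascular tracer follows a well-mixed compartment,
E(t) = V₀(1 − e^(−kt)), with k the tracer's leak coefficient (min⁻¹) and
V₀ the constant intravascular level during that tracer's window. The
compartment level is shaped spatially by a Gaussian distance-decay kernel
from the vessel wall (σ = 15 µm). This was chosen over a reaction–diffusion
model because it admits closed forms for every downstream statistic while
preserving the monotone dependence on k that the AUC statistic must track.
Frame j of a window is acquired (j + 1) minutes post injection; each
tracer leaks only during its own 15-minute window and its extravascular
signal then freezes (its plasma supply is superseded by the next
injection), so per-tracer baseline re-anchoring is well-posed. All tracers
share the green channel, so intravascular intensity steps up by V₀ per
injection and extravascular signal accumulates across the session.

Default tracer panel: 40, 3, 0.3 kDa with k = 0.01, 0.04, 0.10 min⁻¹ —
smaller dextrans cross the barrier faster; the k values are chosen once as
plausible relative rates spanning an order of magnitude (no measured
coefficients exist for this model).

**Noise and artifacts.** Poisson photon noise at 2 expected photons per
intensity unit plus a Gaussian read floor (σ = 1 a.u.), applied after
drift. Drift is a cumulative integer random walk per timepoint (bounded
per axis); integer shifts keep exact recovery assertable, and a subpixel
mode exists but is off by default. Autofluorescent debris is simulated as
small bright disks (4–40 px²) deposited in single z-slices of both
channels. Not modelled: depth attenuation/scattering, photobleaching,
hemodynamics, bolus decay.

## Drift correction

Shifts are estimated by phase correlation: the inverse FFT of the
normalized cross-power spectrum peaks at the translation relating two
volumes. Estimation uses the vessel channel only — the tracer channel
changes intensity by design — and the shift is applied to all channels of
the timepoint. The default reference is the baseline (first) timepoint; a
running-reference mode accumulates frame-to-frame shifts for slowly
morphing fields. Subpixel refinement (optional) re-localizes the peak on
the un-normalized cross-correlation surface and interpolates per axis with
a log-parabola, exact for a Gaussian-shaped peak. Confidence is the
Pearson correlation between reference and back-shifted moving frame
(clipped to [0, 1]); estimates under 0.2 are flagged unreliable, the
behaviour observed on pure-noise pairs. Exposed voxels after shifting are
filled with the frame median rather than zero so extravascular means are
not biased downward. Rotation, scaling, and non-rigid deformation are out
of scope; drift at this timescale is translational.

## Vessel segmentation

The 50–150 µm depth window (slice depth = z-index × z-spacing; the first
50 µm of meningeal vessels excluded) is collapsed by maximum-intensity
projection. Pixels are classified vessel/background by a random forest
(100 trees, seeded) over a multi-scale feature bank: raw intensity plus,
at each σ ∈ {1, 2, 4} µm, Gaussian smoothing, gradient magnitude, and both
Hessian eigenvalues (the most negative eigenvalue is the classic tubeness
cue). The bank and ensemble mirror the spirit of interactive
pixel-classification tools; the exact feature set and tree count are
configurable since no single canonical choice exists. A probability at
exactly the 0.5 threshold counts as vessel.

Post-processing produces two mask variants from one classification:

* **morphometry mask** — 8-connected components with area ≤ 20 px² are
  removed (autofluorescent debris; circularity 4πA/P², Crofton perimeter,
  is computed and configurable, but the default [0, 1] range excludes
  nothing by shape, making the filter area-only), then edges are smoothed
  by morphological closing with a 2 px disk;
* **permeability mask** — particles retained, so their autofluorescence is
  subtracted from parenchyma together with the vessels.

## Morphometry

*Area density* = 100 × foreground / total pixels of the processed mask.
*Length density* = skeleton centerline length / projection area (µm/µm²),
with the mask thinned by topology-preserving skeletonization. Both
readouts use the smoothed, particle-filtered mask; all intermediates are
retained.

Skeleton length is measured by decomposing the skeleton into branches
(paths between endpoints/junctions; each 8-adjacency edge used once) and
summing Euclidean chords between path pixels 4 steps apart. A naive
per-step sum (1 for axial, √2 for diagonal) systematically overestimates
oblique straight lines — by cos θ + (√2 − 1) sin θ, up to +7.3% near 30° —
whereas chord sampling is exact for axial and 45° runs and keeps straight
tubes within ~1.5% at any angle.

## Permeability statistic

Parenchyma is the complement of the dilated (2 px margin, against
point-spread bloom) permeability mask. For each tracer, I(t) is the mean
green MIP intensity over parenchyma (the mean, not the sum, so the ratio
is mask-size invariant); I₀ is the same statistic on the last frame before
that tracer's injection, which absorbs residual signal from earlier,
larger tracers. The relative-permeability readout is the trapezoidal AUC
of I(t)/I₀ − 1 over the 15-minute window: exactly 0 for an intact
barrier, strictly increasing in k, and invariant to detector gain.
Negative excursions (bleaching) are retained, not clipped.

One consequence of ratio normalization worth stating: residual signal from
a previous tracer inflates the next tracer's I₀, scaling its ratio-AUC
down even though its absolute extravasation is unchanged. Comparisons of
leak rates across tracers *within* one session are therefore read off the
un-normalized extravascular integral (AUC × I₀ = ∫(I − I₀)dt), while the
ratio-AUC is the comparison statistic across sessions sharing a baseline.
No compartmental (e.g. Patlak) fitting of a physical permeability
coefficient is attempted.

## Senescence scoring

**Score.** Within each cell, genes are ranked by descending count; ties —
in particular the zero-count bulk — are broken by a random permutation
seeded from a CRC32 of the cell id, deterministic yet unbiased across
cells. Walking the top ⌈5% × n_genes⌉ ranks, the cumulative count of
gene-set members traces a recovery curve; the score is its area divided by
the maximal achievable area (all members packed at the top, or the window
size when the set is larger). Scores live in [0, 1], depend only on
member positions inside the window, and never decrease when a member
improves its rank. The 5% window is the established convention for this
score family; the same scorer drives both senescence scoring and
signature annotation (one tested code path).

**Classification.** The default strategy fits a Gaussian KDE to the score
distribution; when two prominent modes exist (second peak ≥ 5% prominence
and the valley below half the smaller peak) the threshold is the
minimum-density valley between them, otherwise mean + 2 SD. Cells at or
above the threshold are called senescent. The strategy is pluggable
(valley / mean + 2 SD / explicit value) because no single thresholding
rule is canonical for this score family beyond "distribution-based".

**Annotation.** Each signature (truncated to its top 20 markers) is scored
per cell with the shared scorer over one shared ranking; a cell is
labelled with the argmax signature when its score exceeds 0.25, otherwise
"unassigned"; exact ties go to the first signature in name order and are
flagged.

**QC.** Cells with mitochondrial read fraction strictly greater than 0.15
are removed (a cell at exactly 0.15 is retained); unique-gene counts
outside the 1st–99th percentile of the per-cell distribution (or explicit
bounds) are removed; the log records every violated rule per cell.

**Synthetic counts.** Gamma–Poisson (negative binomial) counts with
lognormal gene baselines (σ = 1.5), lognormal library sizes (mean 5000,
σ = 0.3), dispersion 0.3; a planted senescent fraction has gene-set
members shifted by a log2 effect; 30 "mt-" genes are calibrated to ~5% of
reads, boosted ~7-fold above the QC bound in planted high-mito cells. The
generator reproduces the marginal count statistics the scorer consumes; it
does not emulate ambient RNA, doublets, batch effects, or gene–gene
correlation structure, so passing recovery tests demonstrates correctness
of the scoring machinery, not robustness to those real-data artifacts.

**Gating.** The cytometry fraction is #(events positive for all numerator
markers) / #(events positive for all denominator markers) on a boolean
event table, with the numerator population required to be nested.

## Problem sizes

Simulated sessions in the tests and the acceptance script use
128–192 µm fields at (2, 2, 5) µm spacing, 4–6 vessels, 15 frames per
tracer; count-matrix experiments use 2000 cells × 10 000 genes with a
100-gene planted set, 5 recovery seeds and 10 null seeds. These sizes are
the package's chosen study conditions: large enough that every statistic
is estimated stably, small enough to iterate on quickly.

## Known limitations

* The leak model is well-mixed, not spatially resolved; kinetics more
  complex than a single exponential (e.g. biphasic uptake) are not
  represented.
* Drift is rigid translation only.
* Segmentation quality on real data depends on annotation quality; the
  Dice ≥ 0.9 result holds for the phantom noise model with 500 labels per
  class.
* The bundled senescence gene list is a small convenience set; serious use
  should supply a curated list (e.g. SenMayo).
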