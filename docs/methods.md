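# Methods

This note documents the models, algorithms and numerical conventions behind
`aortaquant`, and what the synthetic validation does and does not establish.

## The measurement problem

Thoracic aortic aneurysm severity is monitored by the maximal vessel
diameter, measured in planes perpendicular to the vessel centerline —
oblique, axial measurements systematically overestimate. The package
automates the full chain on CT-like volumes: segment the aorta, locate the
five standard landmarks (aortic root, brachiocephalic, left common carotid,
left subclavian, celiac), extract an arc-length-parameterized centerline with
local cross-section frames, partition it into ascending / arch / descending
sections, report each section's maximal average diameter with its location,
and screen for aortic dissection from the straightened volume.

## Synthetic phantom (the validation oracle)

Clinical CT with expert annotations is not redistributable, so validation
uses a parametric "candy cane" phantom whose ground truth is analytic:

* Centerline: vertical ascending limb (length `limb_length_mm`, default
  60 mm), half-torus arch (radius `arch_radius_mm`, default 35 mm), vertical
  descending limb, all in one plane. Total arc length L = 2·limb + πR.
* Outer vessel radius along arc length s:
  `r(s) = r0 + A · exp(−(s−s0)² / (2σ_s²))` — a Gaussian aneurysm bulge of
  amplitude A centred at s0 with width σ_s. r(s) is the *outer wall* radius;
  aortic diameters are conventionally outer-wall to outer-wall, so the
  ground-truth diameter at s is exactly 2·r(s) and the global maximum is
  2·(r0 + A). The wall occupies the outermost 2 mm; the lumen fills the rest.
* Intensities (HU): contrast lumen 300 / non-contrast lumen 40, wall 50,
  dissection flap 60, graft 500, background −50; additive Gaussian noise
  (default sd 10 HU). These are plausible CT regimes chosen so that contrast
  and non-contrast scans genuinely differ.
* Dissection: a planar membrane of thickness 2 mm through the centerline
  splitting the lumen into two channels over a configurable arc range
  (default: the central 60 % of the descending section). The membrane plane
  is the plane normal to the candy-cane plane, so both channels run the full
  flap range.
* Partial volume: voxels near a tissue boundary get the occupancy-weighted
  HU mixture from 3×3×3 sub-voxel sampling, which makes sub-voxel diameter
  recovery measurable. Default raster: 1 mm isotropic, auto-sized to the
  geometry plus a 12 mm margin (≈ 140×70×165 voxels).
* Landmarks: the phantom has no branch vessels, so the three arch landmarks
  are defined at fixed arch arc fractions (15 % / 50 % / 85 %); root and
  celiac are the centerline ends. Brachiocephalic and left subclavian double
  as the section boundaries, matching the manual-reading definitions
  (ascending ends at the brachiocephalic origin; descending starts at the
  left subclavian).

Everything is deterministic in the case description (including its seed).
Cohorts draw
case parameters reproducibly from declared ranges (r0 ∈ [13, 17] mm,
A ∈ [0, 8] mm, σ_s ∈ [12, 20] mm, limb ∈ [50, 70] mm, R ∈ [30, 40] mm, mixed
contrast and bulge section), with exactly `round(n · prevalence)` dissection
cases.

What the phantom does *not* emulate: surrounding anatomy (lungs, spine,
branch vessels), ECG-gated motion, beam hardening, scanner-specific noise
texture, eccentric or crescentic false lumens, thrombus. Passing tests
establish correctness of the measurement chain against analytic truth, not
clinical performance.

## Segmentation

A 3D U-Net operating at 2 mm isotropic resolution: encoder blocks of two
3×3×3 convolutions with batch normalization and ReLU, filters doubling per
level, 2× max pooling, nearest-neighbour upsampling with skip concatenation,
and a 1×1×1 sigmoid head trained with voxelwise binary cross-entropy using
Adam at learning rate 1e-4. Augmentation: window jitter (random linear
intensity rescale within ±20 %) and additive Gaussian noise (sd drawn from
[0, 20] HU). Input HU are normalized by a fixed [−100, 400] window.

The network and its backpropagation are implemented directly in numpy
(im2col convolutions against BLAS matmuls), sized for single-CPU training:
depth 3, 8 base filters, 32³-voxel training crops (2 per case per epoch,
biased toward aorta-containing regions), ≤ 20 epochs on 40 phantoms with a
deterministic 20 % validation split. Since each training "batch" is a single
crop normalized by its own spatial statistics, inference also normalizes by
the input's own statistics (instance-style evaluation); running averages are
retained for reference. Full volumes are padded to the pooling stride and
segmented in one forward pass (tiled inference with averaged overlaps is
available for inputs too large for that).

The inclusion cutoff is *picked*, not assumed: after training, the cutoff is
selected from a 0.30–0.90 grid by maximizing Dice on up to eight training
cases (never on validation data). A partially converged sigmoid head is not
centred on 0.5, so the cutoff acts as a calibration parameter; passing an
explicit ``cutoff`` overrides the selection. Post-processing: threshold,
keep the largest connected component, fill holes.

Validation Dice is reported at the 2 mm network resolution;
``dice_at_native`` rescores a segmentation after resampling the mask back to
the input raster, since the two resolutions weight boundary voxels
differently.

The classical segmenter is the deterministic reference path: an HU band
covering all vessel tissues, with the lower edge at the background/wall HU
midpoint (the half-occupancy isosurface) unless noise forces it higher, then
3×3×3 morphological closing (bridges the thin flap, so both lumina join one
component), largest component, hole filling. On noiseless phantoms it
recovers the ground-truth mask at Dice ≥ 0.98, which makes the downstream
geometry and diametry stages testable independently of network training.

## Landmark detection

Per-resolution Q-learning navigation agents, run coarse to fine. State: the
9³-voxel normalized intensity patch centred on the agent (a patch this size
spans 36–144 mm depending on resolution); actions: the six unit-voxel axis
moves; reward: the decrease in Euclidean distance to the target in mm, plus
a terminal bonus when within one voxel. Training uses an experience replay
buffer (10⁴ transitions, minibatch 32), a periodically synced target
network, discount 0.9, and an epsilon-greedy schedule from 1.0 to 0.1 over
the episodes. The Q-function is a small dense network (729→64→64→6).

The coarsest agent trains from uniformly random start positions; finer
agents train from starts within ±6 voxels of the target, because at run time
they only ever take over from the next-coarser agent's estimate. Inference
runs the coarsest agent from several random starts, pools terminal positions
by geometric median (Weiszfeld), and hands the pooled point (with one-voxel
jitter) down the resolution pyramid; greedy rollouts stop when the agent
revisits a position (the oscillation around a target) or after `max_steps`,
in which case the result is flagged low-confidence rather than raised.

Two non-learned providers keep the rest of the pipeline independent of agent
convergence: a ground-truth passthrough (phantom oracle) and JSON-file
input.

## Centerline and sections

Within the mask, the centerline is the shortest path between the root and
celiac landmarks in the 26-connected voxel graph with edge cost
`length · 1/(1 + EDT²)` averaged over the edge's endpoints, where EDT is the
Euclidean distance transform — the cost strongly prefers medial voxels, so
the path follows the locus of maximal inscribed spheres. Landmarks outside
the mask snap to the nearest mask voxel within 10 mm. The voxel path is
smoothed (moving average, window 5), resampled at a uniform 2 mm arc-length
step, and given rotation-minimizing frames: tangents by central differences,
in-plane vectors (u, v) by parallel transport of an arbitrary seed vector
with re-orthogonalization at every step. Frames are orthonormal to machine
precision and change by < 15° between consecutive samples on phantoms.

Sections come from projecting the landmarks onto the centerline:
ascending = [root, brachiocephalic), arch = [brachiocephalic,
left subclavian), descending = [left subclavian, end]. Projections must be
in anatomical order, else the offending landmark is named in the error. The
descending terminus is the celiac landmark; manual reading conventions stop
at the diaphragm, but on phantoms the two coincide by construction — the
discrepancy is documented rather than resolved.

## Diameter measurement

At each centerline sample the mask is sampled nearest-neighbour on the
(u, v) plane (80×80 mm window, 0.5 mm grid) — diameter is a property of the
segmentation, not the raw HU. The in-plane connected component containing
the centerline point is isolated; on dissection phantoms the morphologically
closed mask spans both channels, so the measured contour is the outer
envelope. The **average diameter** is the mean of centroid-chord lengths
over 90 uniformly spaced angles (2° apart), with chord endpoints located
sub-pixel by linear interpolation of the component indicator along each ray.
This definition is rotation-robust, reduces to the true diameter on circles,
and lies strictly between the minor and major axes on ellipses. Alternative
conventions (equivalent-area diameter, min/max axis mean) are computable
from the same cross-section object.

Per section, the reported maximum excludes samples within 5 mm of the
section boundaries (partition jitter); the arch profile is computed but not
reported as a maximum, mirroring the two clinical outputs (ascending,
descending). Empty in-plane components are recorded as measurement gaps, not
errors.

Verified accuracy on phantoms: |reported − 2(r0+A)| ≤ max(1 voxel, 5 %)
across a seeded spec grid; a 45°-tilted cylinder measures 30 mm, not 30·√2;
90° volume rotations change the maxima by < 1 %; the maximum is strictly
increasing in bulge amplitude.

## Dissection screening

The volume is straightened along the centerline: one slice per 2.0 mm arc
step, sampled at 1.0 mm in-plane over an 80 mm window (HU trilinear, mask
nearest), masked to the in-plane aortic component; slice count is
floor(L/2)+1. Each slice yields a fixed 18-value feature vector (order is
part of the contract): area, equivalent diameter, eccentricity; mean / sd /
skewness / kurtosis of HU inside the component; an 8-bin histogram over
[−100, 500] HU; the maximum Sato dark-ridge (membrane) response inside the
component eroded by 3 px; the fraction of pixels more than 50 HU below the
component median; and the variance of the radial mean-intensity profile
(8 bins). The membrane features are the discriminative core: a flap crossing
a bright lumen produces a strong dark ridge and a heavy dark-pixel fraction.

Slices are scored by an RBF-kernel SVM (features standardized with training
statistics; C ∈ {1, 10, 100} × γ ∈ {scale, 0.1, 0.01} by 3-fold grid search;
probabilities from the SVM's internal cross-validated sigmoid calibration,
seeded). Classifiers are trained **per intensity regime**: a flap reads dark
against contrast-enhanced blood (≈300 HU) but is nearly isointense on
non-contrast scans (60 vs 40 HU), so contrast and non-contrast scans get
separate models and each case is scored by the model matching its protocol. Patient-level pooling is the mean of the top-k slice probabilities
with k = max(3, ⌈10 % of slices⌉) — chosen over the maximum (noise-brittle)
and the plain mean (diluted when the dissected segment is short); pooling is
monotone in every slice probability. The decision threshold is 0.5. Fewer
than 3 valid slices flags the result indeterminate.

## Agreement and diagnostic statistics

* ICC(2,1): two-way ANOVA of the n×2 targets×raters table;
  `ICC = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`, k = 2. Bands:
  < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent. Zero total
  variance returns 1.0 with a degeneracy flag.
* Bland–Altman: d = auto − manual; bias = mean(d); LoA = bias ± 1.96·sd(d)
  with the n−1 sample sd.
* Wilcoxon signed rank: zero differences dropped (flagged); mid-ranks for
  ties; exact two-sided tail for n ≤ 25 via a dynamic program over the
  doubled-rank sum distribution (ties make mid-ranks half-integral; doubling
  keeps the support integral), tie-corrected normal approximation beyond.
  The folded two-sided convention `P(|W − E[W]| ≥ |w − E[W]|)` matches full
  2ⁿ enumeration exactly.
* Spearman correlation via mid-ranks; Kolmogorov–Smirnov normality check of
  the differences against a normal with fitted mean/sd (the Lilliefors
  caveat — fitted parameters make the p-value conservative — is flagged in
  the output).
* Quartiles by linear interpolation (numpy default), so reported IQRs are
  exactly reproducible.
* Sensitivity / specificity / accuracy with exact Clopper–Pearson intervals
  from beta quantiles: lower = B(α/2; x, n−x+1), upper = B(1−α/2; x+1, n−x),
  with closed ends at 0 and 1. Clopper–Pearson is used because it is the
  exact interval consistent with the worked example 37/42 → 74.4–96.0 %
  (Wilson gives ≈ 75.0–94.8 %).

## Problem sizes and budgets

All validation runs are sized for one desktop CPU core: segmentation trains
on 40 phantoms (32 train / 8 validation) for 20 epochs of 2×32³ crops per
case (~10 min); landmark agents train 300 episodes per resolution at
16/8/4 mm on 32 phantoms (~2–4 min); the dissection screen processes a
60-case cohort end to end (~3–5 min); the measurement property suite runs in
~2 min. The 2 mm working resolution for geometry and diametry matches the
segmentation network's native raster.

## Known limitations

* The phantom's circular cross-sections and planar flap are idealized; the
  average-diameter estimator is rotation-robust but untested against
  strongly crescentic or thrombosed lumens.
* The landmark agents are trained per landmark and per phantom family; they
  learn this family's geometry, not general thoracic anatomy. The reported
  localization error is a best-effort restaging at a small training budget —
  the oracle provider exists precisely so downstream results never depend on
  agent convergence.
* Dice ≈ 0.93 at 2 mm resolution is boundary-limited: a one-voxel shell on a
  30–40 mm vessel is ~20 % of its volume, so small boundary offsets dominate
  the metric.
* The straightened stack resamples planes independently; strongly curved
  segments can double-sample tissue between adjacent planes (standard curved
  planar reformation behaviour).
* Statistics assume exchangeable paired measurements; no multiple-testing
  correction is applied anywhere.
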