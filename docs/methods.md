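# Methods

This note records the scientific and numerical choices behind `glaucroi`:
what each stage computes, where the design was genuinely open and what was
decided, what the phantom generator does and does not emulate, and the
known limitations.

## Texture enface construction

The descriptor follows the slab-texture recipe: lift the 70 µm sub-ILM
slab (`ceil(70 / axial_res)` depth pixels, edge-replicated and flagged
where the slab under-runs the volume), band-pass each B-scan with a
difference of Gaussians (σ₁ = 1 px, σ₂ = 2 px, reflective padding),
normalise locally, quantise into equal-frequency "homogeneous" bins, and
average over slab depth per A-scan.

Three internals of the published recipe are not specified anywhere and were
decided here; all are config-exposed:

* **What is binned.** The *magnitude* of the normalised response.  The
  signed response is symmetric about zero, so its depth-mean is mid-grey
  everywhere; the magnitude is a texture-energy measure and renders
  fibre-bundle texture as brightness.
* **Binning scope.** Equal-frequency bin edges are pooled over the whole
  slab volume, not per B-scan.  Per-B-scan edges force every B-scan to a
  uniform bin marginal, which erases exactly the between-B-scan intensity
  differences an enface map is supposed to show.  `texture_descriptor`
  retains the per-B-scan contract (and is what the unit tests exercise);
  `build_enface` passes shared volume-wide edges.
* **Normalisation strength.** z-normalisation uses the 9×9 window mean and
  standard deviation with an ε-guard proportional to the B-scan-wide
  response scale, `z = (DoG − μ₉)/(σ₉ + eps_rel·sd(DoG))`, default
  `eps_rel = 1`.  This is a genuine trade-off: as `eps_rel → 0` the
  descriptor becomes invariant to any locally smooth contrast change but
  also erases the texture-amplitude signal (σ₉ *is* the signal); as
  `eps_rel → ∞` it degenerates to a global DoG magnitude.  The default
  keeps the enface signal; consequences: invariance to *affine* intensity
  maps is exact (all stages are scale-relative), invariance to nonlinear
  monotone warps holds approximately in the gentle regime (≥ 90% bin
  agreement at γ = 1.1 on random images) and degrades for strong warps.

The "2–6 mm grid" baselines are means over the annulus between circles of
2 mm and 6 mm diameter centred on the ONH, pixel membership by the
centre-point rule; scores are negated so that larger = more glaucoma-like.
The default axial resolution is 2.6 µm/px (device value unpublished).

## Autoencoders

Five dense layers `[D, 256, 64, 256, D]` on flattened inputs (widths are
not published; these are small enough for CPU training while keeping a
compressive bottleneck), tanh hidden activations with a linear output,
Glorot-uniform initialisation, Adam at lr 10⁻³, batch 50, 150 epochs, MSE
loss.  Published training values (optimiser, rate, batch, epochs,
activation, init, "lowest reconstruction error" model selection) are kept
as defaults.  Decisions taken here:

* Inputs are rescaled from [0, 1] to [−0.9, 0.9] to keep tanh units out of
  saturation; the output layer is linear.
* "Lowest reconstruction error" selection is measured on a held-out 10%
  validation split of the training eyes, patient-disjoint when patient ids
  are supplied; the best-epoch weights are returned.
* Per-pixel error is the squared residual (the printed ‖x−x′‖₂ is read as
  a per-pixel squared residual field), optionally 3×3 mean-smoothed
  (default on); maps resized to the model grid bilinearly, error maps
  returned to native resolution by nearest-neighbour upsampling.
* The implementation is plain NumPy (float32 GEMMs, hand-written Adam and
  backprop).  At these sizes a tensor framework adds dependency weight
  without speed: a full 200-eye, 5-fold, 2-autoencoder experiment trains
  in about a minute on one CPU.

Determinism: weights, shuffling and the validation split derive from the
config seed; identical data + config + seed reproduce the checkpoint
byte-for-byte.

## MRF segmentation

The published description names the model family (2-feature MRF in the
style of colour-texture segmentation) but not the energy, estimator,
neighbourhood or optimiser.  Choices: bivariate-Gaussian class likelihoods,
Potts pairwise term (default β = 1.5), 4-neighbourhood, ICM with
raster-order updates from the per-pixel maximum-likelihood labelling, ties
resolved to healthy-like (conservative toward no disease).  ICM accepts
only locally energy-lowering moves, so the per-sweep energy trace is
non-increasing (asserted at runtime); convergence = a sweep with no label
change, capped at 50 sweeps.  With β = 0 the labelling equals the
pixelwise ML assignment exactly; on a 3×4 fixture the ICM energy matches
the exhaustive minimum over all 4096 labelings.

Class models are estimated per image by a deterministic, permutation-
invariant two-means split (initialised at the median of the healthy-error
channel), which also makes segmentation equivariant to horizontal
mirroring.  The component with the larger mean healthy-AE error is the
glaucoma-like class.

**Degeneracy guard.**  Healthy eyes often contain no glaucoma-like region,
a case the published method is silent on.  An image is declared "no ROI"
when the gap between the two component means *along the healthy-AE-error
channel* falls below `separation_tau` (default 0.05 in error units).  The
channel-restricted gap replaced a Euclidean gap after phantom measurement:
the glaucoma-AE error channel is noisy enough that splitting pure noise
yields Euclidean gaps of 0.03–0.06 in defect-free eyes, while the
healthy-error gap is ≤ 0.001 for defect-free eyes and ≥ 0.2 for defect
eyes across map sizes — the channel that defines glaucoma-likeness carries
the whole separation.

## ROI-Based Glaucoma Score

`GLS = 0.5·ROI_size/Total_area + 0.5·clamp(1 − Mean_ROI/Mean_Healthy, 0, 1)`.

* The intensity term is clamped to [0, 1]: the raw formula goes negative
  when the ROI is brighter than the healthy reference; such ROIs are
  treated as non-evidence so GLS stays a score in [0, 1].
* The score domain defaults to the 2–6 mm annulus so all four compared
  models look at the same region ("total image area" is available via
  `domain="full_map"`).
* Empty ROI ⇒ GLS = 0 (the published formula leaves Mean_ROI undefined).
* Mean_ROI is *texture intensity* inside the ROI (not reconstruction
  error), matching the score's reading as "intensity reduction due to
  thinning".
* Mean_Healthy is recomputed per cross-validation fold from that fold's
  healthy training eyes only.

## Evaluation

* Patient-level stratified 5-fold CV; every eye tested exactly once, never
  by models trained on its own patient (violations raise, they are not
  warnings).
* Minority-class balancing by horizontal mirroring, applied to training
  folds only; mirrored copies inherit their source patient id.
* AUROC by the tie-corrected rank formula; AUPRC by step-interpolated
  precision–recall integration (both cross-checked against scikit-learn in
  the tests, which is deliberately *not* the implementation).
* Sensitivity at specificity: the smallest observed score cut with
  empirical specificity ≥ the target; no ROC interpolation.
* Inference: percentile bootstrap (default n_boot = 1000) resampling
  patients with replacement, keeping all eyes of a sampled patient
  ("eye-level clusters" is read as patient clusters of eyes); replicates
  missing a class are redrawn and counted.  All models share each
  replicate's resample, so AUROC differences use the paired Wald test
  `z = Δ / sd(paired replicate differences)`.  Measured coverage of the
  95% CI on a known-AUROC clustered generator: 95.5% over 200 runs.
* Covariate adjustment (age, image quality, axial length — the published
  covariate sentence is truncated; the model family is unstated) uses
  placement values: an OLS of score on covariates among controls, each
  case's residual placed in the control-residual distribution; the mean
  placement value is the adjusted AUROC.  With uninformative covariates it
  reduces exactly to the ordinary AUROC.
* Axial-length categories: < 24.5 mm, [24.5, 26.0] mm, > 26.0 mm.
  Proportions are compared by chi-square without continuity correction
  (Fisher when an expected cell < 5), means by Welch t-tests.

## The phantom generator

The generator defines the study conditions for every statistical claim the
tests make.  It emulates: a dim disc with bright superior/inferior arcuate
bundles (smoothly graded so intensities are spread rather than
piecewise-flat); wedge-shaped angular defects anchored at the disc margin
in the arcuate zones, multiplying intensity by (1 − depth), 1–3 wedges of
20–60°, depth 0.5–0.7 by default; a latent per-eye brightness offset
(sd 0.03) shared within a patient at correlation 0.5; age-related decline
(0.002 intensity/year around 50); additive Gaussian pixel noise (sd 0.05);
axial length drawn per diagnosis (24.9 ± 1.25 mm healthy, 25.6 ± 1.05 mm
glaucoma, truncated at 22–28 mm) so the glaucoma group is longer; matched
RNFL thickness maps as an affine transform (30 + 110·pattern µm, noise
sd 4 µm) of the same latent pattern; and full layered volumes whose
sub-ILM slab carries the pattern as ILM-aligned lamellar texture whose
modulation *amplitude* is proportional to the pattern, with an ILM bowl
tilted in proportion to (AL − 24.5).

Ages are drawn from one distribution for both groups: diagnosis influences
the maps only through defects, so a zero-depth cohort is an exact null
(verified bit-for-bit by relabelling in the tests).  The number of two-eye
patients is the deterministic round(p_both·n) so cohort size is
reproducible.  All randomness flows from one root seed through named
substreams (stage, patient, eye), making cohorts byte-identical across
runs and eye patterns re-derivable from the manifest ids.

What it does **not** emulate: speckle physics, peripapillary atrophy, disc
tilt/ovality in the 2D maps, device artefacts, segmentation failures, or
any age-by-diagnosis confounding.  Passing tests therefore show that the
pipeline recovers localized wedge-shaped intensity loss under correlated
nuisance variation — not that it detects glaucoma in clinical scans.

Two measured properties of the generator–descriptor pair worth knowing:

* The volume→enface path reproduces the anatomical pattern with Pearson
  r ≈ 0.80–0.85 on defect-bearing eyes; defect-free eyes sit near 0.74
  because rank quantisation compresses their narrow dynamic range.  The
  correlation check in the tests is the mean over glaucoma eyes.
* Amplitude-coded and granule-density-coded slab textures were tried and
  rejected: the contrast-normalised descriptor saturates on both (r capped
  at ~0.45–0.73).  The lamellar design encodes the pattern where the
  descriptor can read it.

## Problem sizes and statistical bands

The end-to-end checks run three 200-eye, 64×64 cross-validated experiments
(defect depth 0.5–0.7) plus three zero-depth null cohorts; one experiment
(10 autoencoder trainings, 200 segmentations, bootstrap) takes roughly
80 s on one CPU.  The null-calibration band [0.43, 0.57] is checked on the
mean over the three null cohorts: with ~125 patient clusters a single
cohort leaves the baselines' null AUROC with sd ≈ 0.05–0.06 (measured over
20 cohorts), so a single-cohort check would fail a correct implementation
for a quarter of seeds.

## Known limitations

* ICM is a local optimiser; only the small-fixture test asserts global
  optimality.  Graph cuts would be exact for this binary Potts energy but
  are out of scope by design.
* GLS is a score, not a calibrated probability; no normative percentiles.
* The dense autoencoder ignores spatial structure beyond what 64×64
  flattened inputs retain; convolutional variants are out of scope.
* On deep-defect phantom cohorts several models saturate at AUROC 1.0, so
  the dual-vs-single *gap* reported on clinical data is reproduced only
  qualitatively (dual ≥ single); shallower defects (see the README worked
  example) de-saturate the comparison.
* The phantom's free parameters are design choices, not estimates fitted
  to any clinical distribution.
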