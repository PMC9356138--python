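# Methods

This note documents the models, conventions and numerical choices behind
`srscell`, and what the synthetic phantoms do and do not establish about
real imaging data.

## Spectral phasor transform

A pixel spectrum `I_k` over `N` acquired channels is embedded at

    g = Σ_k I_k cos(2πhk/N) / Σ_k I_k,   s = Σ_k I_k sin(2πhk/N) / Σ_k I_k,

with harmonic `h = 1` by default — the standard phasor convention, which
maximizes spread for single-peaked spectra; `h` is exposed for completeness.
Two properties drive the design and are enforced by property tests:

* **unit-disc containment** — any non-negative spectrum satisfies
  `g² + s² ≤ 1` (triangle inequality on the complex sum), so the phasor
  plane is a bounded gating space;
* **mixture linearity** — the phasor of a per-channel mixture `αA + (1−α)B`
  lies on the segment between the phasors of A and B at the DC-weighted
  position, which is what makes cluster positions chemically interpretable;
* the transform is invariant to global scaling `I → cI`, so segmentation is
  robust to laser-power drift.

Pixels whose total (DC) intensity is at or below a floor are flagged
invalid and never clustered.  The default floor is
`median + 5 × 1.4826 × MAD` of the DC values in the four image corners — a
robust background-noise estimate standing in for a user-marked background
region.  Pass `dc_floor` explicitly when the field of view has no clean
corners.

## Phasor clustering and component naming

Default clustering is a Gaussian mixture on the valid pixels' `(g, s)`
coordinates, with k-means and polygon gates (for parity with interactive
phasor tools) as alternatives.  DC weighting is implemented by fitting on a
seeded resample of valid pixels drawn with probability proportional to DC
and then predicting all valid pixels; the standard mixture fitter has no
per-sample weights, and this resampling achieves the same emphasis on
bright, information-bearing pixels.  Boundary pixels go to the
maximum-responsibility cluster; exact ties break toward the lower cluster
id.  Cluster ids are relabelled 1..k by descending total DC (0 is
background), making outputs deterministic for a fixed seed.

Clusters are mapped to semantic components ("nuclei", "lipid", "CC", "CD")
by one-to-one greedy matching between cluster centroids and the phasors of
user-supplied reference spectra; without references, names are applied in
DC order.  The interactive gate selection used in manual phasor workflows
is not recoverable from published material, so reference-anchored automatic
mapping is the documented substitute, with polygon gates available for
manual override.

The least-squares route (`unmix_dual_probe`) solves a per-pixel
non-negative two-component problem in closed form: the unconstrained 2×2
normal-equation solution is kept where feasible, and pixels with a negative
coefficient fall back to the better of the two single-component
projections (exact NNLS for two variables).  References whose smallest
singular value is below 1e-8 of the largest are rejected as collinear.
Phasor clustering and unmixing agree per-pixel wherever abundances are
pure; this dual route is tested and is the internal consistency check of
the segmentation.

## Segmentation conventions

* Nuclei: Otsu threshold (override available), connected components,
  distance-transform watershed to split touching nuclei (marker separation
  scaled to the minimum nucleus area), size filter, consecutive relabel.
* Cells: nucleus-seeded watershed on inverted intensity over the foreground
  mask (Otsu by default).  When bright droplets dominate the DC histogram,
  Otsu lands above the cytoplasm level; pass `cell_threshold` explicitly in
  that regime.  Nuclei outside the foreground warn and still grow a cell.
* Droplets: threshold, distance-watershed split, minimum diameter 3 px
  (sub-resolution specks at a high-NA objective are noise), centroid-based
  cell assignment with clipping to the owning cell, background-centroid
  droplets dropped with a logged count.
* Edge-touching cells are excluded from the cell table by default because
  truncated cells bias intensity histograms.

Equivalence to the original interactive cytometry stage is functional
(metric-level), not pixel-level: its module chain and parameters are
unpublished.

## Per-cell metrics and subpopulations

Integrated intensity counts a cell's *signal pixels* (positive pixels of
the masked component image), not all cell pixels; mean = integrated /
signal-pixel count with the zero-signal case defined as 0 and flagged;
area fraction = signal pixels / cell area.  These conventions keep
`integrated = mean × signal pixels` an identity.

Subpopulation detection fits Gaussian mixtures on log-intensity for
k = 1..4 and selects k by BIC (histogram inspection in the source
literature never states a criterion; BIC is the conventional choice and the
candidate set is a parameter).  For k = 2 the low-mean component is
"lipid-poor".  Working in log space makes the classification invariant to
global intensity scaling.  Group comparisons share a single pooled
two-component fit so both conditions use one poor/rich boundary; the
rich-fraction difference carries a bootstrap percentile CI (cells resampled
within group under the fixed pooled model) and a Welch t test on the raw
metric.  Histogram binning defaults to Freedman–Diaconis; pass shared edges
when comparing groups.

## The metabolic index

`M = F/(F+G)` with `F, G ≥ 0`; `F + G = 0` yields NaN and exclusion with a
count, never a silent 0.  The default per-cell metric is signal area
fraction (how C–D signal is conventionally reported in this assay);
`integrated` and `mean` modes exist because bulk-intensity comparisons use
mean intensity, and the choice is a parameter.  The per-sample index is the
mean of per-cell indices (the per-patient averaging convention), reported
with SEM = sd/√n (sample sd; 0 and flagged at n = 1).

## Resistance statistics

* **4PL fit**: `v(d) = bottom + (top − bottom)/(1 + (d/ic50)^hill)`
  parameterized on log10 dose, bounds top ∈ [50, 120] %, bottom ∈ [−10, 50] %,
  hill ∈ [0.2, 5], log10 IC50 within two decades of the dosed range;
  multi-start from the dose quartiles with two hill starts, best RSS wins.
  Bounded multi-start converges deterministically without fitter tuning.
  Flat data (range < 1e-6) returns `converged=False`.  The IC50 CI is a
  normal-theory interval on log10 IC50 using the bootstrap SE over
  replicate-within-dose case resampling, inflated by √(n/(n−1)) — the
  standard finite-sample correction for the variance deflation of
  resampling n replicates — at B = 100 resamples.
* **OLS** via the closed form with `R² = 1 − RSS/TSS`; constant x is a
  degenerate design (error); constant y returns slope 0 with R² defined as
  0 and flagged.
* **ROC**: AUC by the rank (Mann–Whitney) formulation with half credit for
  ties — identical to concordant-pair counting and invariant under
  monotone score transforms; the operating threshold maximizes Youden's
  J = sensitivity + specificity − 1 and is reported as the midpoint between
  adjacent distinct scores, ties in J breaking toward the lower threshold
  (higher sensitivity).  The threshold rule in the source analysis is
  unstated; Youden's J is the conventional choice and is configurable by
  reading the returned curve.
* **Assay arithmetic**: OCR = fluorescence slope/min/cell;
  FAO = OCR_total − OCR_etomoxir with negative values returned under a
  warning (impossible biologically, useful QC); ΔCt = control − target so
  higher means more expressed; tumor volume = length × width²/2 with a
  warned swap when width exceeds length; Student's t pooled by default
  (Welch optional).  Seahorse metrics follow the standard mitochondrial
  stress-test convention: non-mito = mean after rotenone/antimycin,
  basal = last pre-injection point − non-mito, ATP-linked = basal −
  (oligomycin mean − non-mito), maximal = FCCP mean − non-mito; reductions
  are control − etomoxir.

## Synthetic data: what it emulates and what it does not

Phantoms are fields of non-overlapping disc cells with concentric nuclei
and cytoplasmic droplet annuli, rendered as exact linear mixtures of
Gaussian-peak component spectra (~50 channels over the stated Raman
windows), with signal-dependent Gaussian noise `sd = shot_scale·√signal`
plus additive Gaussian read noise — photodetection statistics without a
full Poisson renderer.  The lipid-poor/lipid-rich structure scales droplet
abundance per class; the ×10 default contrast is a choice (no per-class
abundance ratio is published) picked to give clearly bimodal
integrated-intensity histograms.  Geometry is deliberately idealized
(watershed-separable by construction): passing the recovery tests shows
the *algorithms* are correct on their stated assumptions, not that the
pipeline is robust to touching cells, irregular morphology, spectral
baselines or stitching artifacts, none of which the generator produces.
Dose–response tables use the exact 4PL form with i.i.d. Gaussian noise and
6 replicates per dose; cohorts draw per-cell indices from class-mean
normals truncated to [0, 1] by resampling.  All generators route
randomness through one seeded `numpy` generator per call and are
bit-reproducible.

## Problem sizes and determinism

Tests run phantoms at 192–512 px and 40–50 channels, populations at
n = 300–600, and the IC50 coverage study at 500 seeds × (8 doses × 6
replicates, B = 100), sizes at which every recovery statistic is stable;
the acceptance script uses the 7 + 4 cohort with 30 cells per sample and a
201×201 index grid plus 20 000 random pairs.  Every stochastic routine
takes an explicit seed; fixed seeds give bit-identical outputs.

## Known limitations

No physical SRS signal model (cross-sections, chirp, laser noise); no 3-D
geometry, stitching artifacts or sub-pixel registration; no absolute flux
calibration of the index; no learned segmentation; dose–response fitting
assumes the 4PL form and homoscedastic replicate noise.
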