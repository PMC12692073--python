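# Methods

This note records the models, conventions and numerical choices behind
`peelfusion`, and what the synthetic-data tests do and do not establish
about real data.

## Study design emulated by the generator

Six citrus peel classes — yellow grapefruit, red grapefruit, lemon, orange,
clementine, kumquat — each measured on three analytical blocks: 3
physicochemical parameters, 4 spectrophotometric assays and 37 ATR-FTIR
band intensities, with 10 replicates per class (60 samples). The built-in
class specifications carry the published class means and standard
deviations for all 44 features.

**Noise model.** Replicates are drawn independently per feature from
Normal(mean, SD) at the printed statistics and clipped at zero (all
quantities are non-negative). No within-class covariance is modeled: the
source tables publish only marginal mean ± SD, so independent Gaussians are
the simplest consistent model, and cross-feature correlation enters only
through the class means. Consequences worth keeping in mind:

- Between-feature correlations over replicates are driven almost entirely
  by class separation; within-class correlation structure of real
  replicates (e.g. correlated FTIR bands from shared chemistry) is absent.
- With the small printed SDs (coefficient of variation mostly ≤ 0.2),
  clipping at zero is essentially inactive; the bias it introduces is
  below 1% of the mean (verified at n = 10⁴).
- Classification accuracies on synthetic replicates are therefore
  *optimistic*: the printed SDs imply near-total class separation, so the
  reported real-data accuracies act as lower bounds that the synthetic
  design comfortably meets. Passing tests show the pipeline's machinery is
  correct, not that real peels are this separable.

An FTIR band printed as absent ("-") in a class is treated as exactly zero
intensity, not missing data: fusion needs a complete matrix, and an absent
band contributes no absorbance.

**Seeding.** One master seed; per-(block, class) substreams are derived
with `numpy.random.SeedSequence(entropy=seed, spawn_key=...)`, so each
block is reproducible independently and whole runs are byte-identical per
seed.

**Synthetic spectra.** A spectrum is a sum of Gaussian peaks (one per
present band, amplitude drawn like any other replicate value) on a
descending grid over 4000–499 cm⁻¹ at 1 cm⁻¹ step, plus optional i.i.d.
trace noise. The 1 cm⁻¹ step ensures every band center — including
odd-valued midpoints of range labels such as 1370–1360 (1365) — lies on
the grid, so windowed-maximum extraction recovers generated amplitudes
exactly. Default peak width 4 cm⁻¹ (the acquisition resolution); the
consistency tests use width 3 cm⁻¹ because at width 4 the 1200/1182 cm⁻¹
neighbours (18 cm⁻¹ apart) leak ~3×10⁻⁶ of tail absorbance into each
other's windows. Baseline curvature, scattering and instrument drift are
deliberately out of scope.

**Synthetic peel images.** A uniform gray base field plus Gaussian pixel
noise plus dark elliptical blotches (Poisson count at `blotch_density` per
10⁴ px, random orientation and semi-axes around `blotch_scale`, darkened by
45% of the base intensity). The built-in per-class specs encode the
observed uniformity ranking — lemon and yellow grapefruit most uniform,
orange and kumquat intermediate, clementine and red grapefruit least — via
increasing noise SD and blotch density. The model emulates texture
contrast, not peel color, shape, gloss or segmentation.

## Texture features

Fifteen features per region of interest (ROI):

- **First-order** (raw 8-bit gray levels, population moments, ddof 0):
  mean intensity, SD, skewness m₃/σ³, Fisher kurtosis m₄/σ⁴ − 3. A
  constant ROI has skewness = kurtosis = 0 by convention.
- **GLCM** (distance 1, four directions 0°/45°/90°/135°, symmetrized,
  summed over directions, normalized): contrast Σ P(i−j)², dissimilarity
  Σ P|i−j|, ASM Σ P², energy √ASM (so the two listed features are distinct
  but consistent, energy² ≡ ASM), homogeneity Σ P/(1+(i−j)²), correlation
  Σ P(i−μᵢ)(j−μⱼ)/(σᵢσⱼ) with the σ = 0 case fixed at 1.
- **GLRLM** (same four directions, runs = maximal straight sequences of
  equal quantized level, counts summed over directions; Galloway's
  normalized forms): SRE, LRE, GLN, RLN, RP = N_runs/N_pixels with
  N_pixels counted once per direction so RP ≤ 1.

Images are quantized to 32 equal-width gray bins before either matrix is
built (full 256 available as an option); pair counting delegates to
`skimage.feature.graycomatrix`, the run-length accumulator is implemented
here. Grayscale conversion uses BT.601 weights 0.299/0.587/0.114, rounded
half-up. The ROI protocol defaults to four 64×64 ROIs on a deterministic
corner-anchored grid (a single ROI is centered); the per-image feature is
the mean over ROIs, with per-ROI values also reported.

All GLCM/GLRLM features are validated exactly against an independent
brute-force pair/run enumerator on thousands of small random images.

## Band extraction

Band intensity is the **maximum absorbance** inside the labeled position
(or range midpoint) ± 8 cm⁻¹ — a peak height, matching single-value band
tables; integrated area is exposed as an option. A linear local baseline
through the window endpoints can be subtracted, off by default on the
assumption that tabulated intensities are already-processed peak heights.

## Univariate statistics

Tie-corrected Kruskal–Wallis H with a χ² p-value (df = k − 1), then Dunn's
pairwise z-tests on the pooled ranks with the standard tie correction,
Holm-adjusted across the 15 class pairs (α = 0.05). Dunn + Holm is the
conventional Kruskal–Wallis follow-up; Conover–Iman was evaluated and
rejected — its extra power splits class groups that the published letter
patterns keep together. No multiplicity correction is applied *across*
features, matching the source analysis. The compact letter display uses
insert-and-absorb: start with one letter covering all classes, split every
letter containing a significantly different pair, absorb subset letters,
and assign a..z in order of first use by class order (deterministic). Both
display postconditions — significantly different pairs never share a
letter, all other pairs share at least one — are verified exhaustively
over all 2¹⁵ significance patterns for six groups.

## Discriminant modeling

Auto-scaling divides by the population SD (ddof 0), erroring on
zero-variance features by name. LDA solves `eigh(S_b, S_w + γ·(tr S_w/p)·I)`
with γ = 10⁻⁶; axes are unit-norm with the largest-magnitude loading made
positive (sign determinism). Explained-variance fractions are eigenvalue
shares over the (k − 1)-dimensional discriminant spectrum. Classification
is nearest class centroid in the **full** discriminant space; LD1/LD2 are
for score plots only.

Cross-validation is stratified 5-fold with seeded shuffling. The default
`scale_mode="global"` scales once on the full data set before CV — the
protocol of scaling prior to analysis. This leaks fold statistics into
training; with 10 replicates per class the effect is small, but
`scale_mode="per_fold"` re-fits the scaler inside each training fold for a
leakage-free estimate. The original study's printed explained variances
(44.98% / 30.85% for the FTIR block) depend on unpublished raw replicates
and are not reproducible from class summaries; the solver is instead
validated against a dense generalized-eigen oracle (principal angle
< 10⁻⁶ rad on random full-rank problems).

## Correlation analysis

Two explicit Pearson modes: `replicate` (over all samples) and
`class_mean` (average within class first, correlate the six class means).
The published assay correlation table corresponds numerically to the
class-mean mode — note that its "antiradical" column matches the FRAP
class means and its "antioxidant" column the ABTS means, the reverse of
the assay definitions; the package keys results to the numeric identity
(feature names), surfacing rather than resolving the labeling discrepancy.
Top cross-block pairs rank by |r| with lexicographic tie-break. The
network keeps isolated nodes, tags nodes by block of origin, flags edges
bold at |r| ≥ 0.80, and uses `networkx.spring_layout` (Fruchterman–
Reingold, 50 iterations, seeded; a single node sits at the origin).
Heatmap/score-plot rendering is intentionally out of scope — CSV, JSON and
GraphML exports are the contract.

## Problem sizes used in the test and acceptance runs

- Fusion accuracy summaries: 20 generator seeds × 60 samples × 5-fold CV.
- Texture oracle sweep: 10⁴ random 3-level images up to 6×6, exact match.
- Uniformity direction recovery: 100 seeded image pairs (192×192, four
  64×64 ROIs), each of 7 features in the expected direction ≥ 95% of draws.
- Letter-pattern recovery: 200 simulated studies at n = 10/class; the
  two-letter grapefruit-vs-rest structure appears in ≥ 80% (measured 96%).
- Marginal recovery of the generator: n = 10⁴ per class, 3-standard-error
  tolerance.

## Known limitations

- Independent-Gaussian replicates cannot probe methods that depend on
  within-class covariance (e.g. the leakage of global scaling, or
  replicate-mode correlation structure beyond class means).
- The image model produces stationary textures; real peel photographs have
  illumination gradients, specular highlights and curvature that the ROI
  protocol would average over but the generator does not produce.
- Band extraction assumes well-separated peaks; heavily overlapping bands
  (< ~20 cm⁻¹ apart at width 4) cross-contaminate at the 10⁻⁶–10⁻⁴
  absorbance level, and no deconvolution is attempted.
- The compact letter display is a greedy construction; it is sound and
  complete w.r.t. its postconditions but not guaranteed minimal in letter
  count for adversarial significance patterns.
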