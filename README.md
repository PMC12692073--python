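# peelfusion

Multi-block chemometric analysis of citrus peel by-products: image texture
profiling, ATR-FTIR band tables, nonparametric class comparison, LDA-based
data fusion and correlation networks — with a synthetic-data generator that
reproduces the statistical design of a six-class citrus peel study.

## The problem

Citrus peels are the main by-product of citrus processing and a rich source
of polyphenols, flavonoids and pectin. Comparative studies characterize them
with several independent analytical families at once:

- **physicochemical** parameters — fresh-peel moisture (%), ascorbic acid
  (mg/100 g DW), total soluble solids (°Brix);
- **spectrophotometric** assays — total phenolic content (TPC, mg GAE/g DW),
  total flavonoid content (TFC, mg QE/g DW), FRAP antioxidant activity
  (mg Fe(II)/g DW), ABTS•+ antiradical activity (mg Trolox/g DW);
- **ATR-FTIR** fingerprints — absorbance at 37 characteristic band regions
  over 4000–499 cm⁻¹;
- **image texture** — 15 grayscale features per peel photograph: 4
  first-order histogram moments, 6 gray-level co-occurrence (GLCM)
  statistics and 5 gray-level run-length (GLRLM) statistics.

Each family alone discriminates the six classes (yellow grapefruit, red
grapefruit, lemon, orange, clementine, kumquat) only partially. The package
implements the *multi-block fusion* workflow: auto-scale each block
(mean 0, population SD 1 per feature), horizontally concatenate any
combination of blocks, fit linear discriminant analysis (LDA), and report
stratified 5-fold cross-validated accuracy. Cross-feature structure is
explored with Pearson correlation heatmaps, top cross-block pairs, and a
correlation network (edges at |r| ≥ 0.60, bold at |r| ≥ 0.80,
Fruchterman–Reingold layout).

LDA solves the generalized eigenproblem **S**_b **w** = λ **S**_w **w**
(between- vs within-class scatter), with a small ridge
**S**_w + γ·(tr **S**_w / p)·**I** (γ = 10⁻⁶) so the solver stays defined
when features outnumber within-class degrees of freedom. Classification is
by nearest class centroid in the full discriminant space. Univariate class
differences use the tie-corrected Kruskal–Wallis H followed by Dunn's
pairwise z-tests with Holm adjustment, summarized as a compact letter
display (classes sharing a letter do not differ at α = 0.05).

Because only class means ± SDs are published, the `datagen` module draws
replicates (default 10 per class) as independent Gaussians at the printed
statistics, clipped at zero; absent FTIR bands contribute zero absorbance.
The same module synthesizes Gaussian-peak spectra and blotchy peel images,
so every downstream stage is testable without any downloads.

## Worked example

```python
import peelfusion as pf
from peelfusion.pipeline import PipelineConfig, fused_cv_accuracies, reproduce_table3

mb = pf.generate_replicate_blocks(cfg=pf.GeneratorConfig(n_per_class=10, seed=42))
cv = fused_cv_accuracies(mb, PipelineConfig(seed=42))
for name, res in cv.items():
    print(f"{name:22s} {res.mean:.3f} +/- {res.sd:.3f}")
```

```
ftir                   1.000 +/- 0.000
spectro                0.967 +/- 0.041
physico                0.583 +/- 0.167
ftir+spectro           1.000 +/- 0.000
ftir+physico           1.000 +/- 0.000
spectro+physico        1.000 +/- 0.000
ftir+spectro+physico   1.000 +/- 0.000
```

The physicochemical block alone is weakly discriminative (0.58); every
fusion that includes the FTIR fingerprint separates all six classes, and
even the two weaker blocks fused reach full accuracy on this draw — the
progression single-block ≤ cross-block ≤ multi-block.

Class-mean Pearson correlations among the four assays
(`reproduce_table3().r.round(4)`):

```
         tpc    tfc    frap    abts
tpc   1.0000  0.859  0.5344  0.8100
tfc   0.8590  1.000  0.6770  0.8530
frap  0.5344  0.677  1.0000  0.8389
abts  0.8100  0.853  0.8389  1.0000
```

TPC correlates strongly with TFC (0.859) and ABTS (0.810): phenolics, and
flavonoids in particular, drive the antioxidant capacity of the peels.

Per-feature letter displays (`pf.compare_classes(mb["spectro"])`) mirror a
summary table's superscripts; e.g. TPC on the same draw gives H = 54.6,
p ≈ 0, letters `a / ab / bc / abc / cd / d` from yellow grapefruit down to
kumquat — grapefruit peels richest in phenolics, kumquat poorest.

The same stages are scriptable from a shell:

```bash
peelfusion simulate --n-per-class 10 --seed 42 --out sim/
peelfusion fuse --blocks ftir,spectro --seed 42
peelfusion reproduce --seed 42 --out report/
```

## Layout

```
src/peelfusion/
  datagen.py    synthetic replicate tables, spectra, peel images
  imgtex.py     15 texture features (first-order, GLCM, GLRLM)
  spectra.py    spectrum I/O, band picking, band-table assembly
  blocks.py     FeatureBlock / MultiBlock model, auto-scaling, fusion
  stats.py      Kruskal-Wallis, Dunn post hoc, compact letter display
  fusion.py     LDA estimator, explained variance, stratified CV
  network.py    Pearson matrices, top pairs, correlation network
  pipeline.py   end-to-end orchestration and report bundle
  cli.py        `peelfusion` command-line interface
docs/methods.md  modeling assumptions, parameters, limitations
```
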