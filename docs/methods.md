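# Methods notes

## Synthetic strip cohort

The generator emulates scanned nitrocellulose strips: a light background
(default 220 intensity units) from which Gaussian band profiles are
subtracted (dark = antibody reactivity), constant across the lane width,
plus i.i.d. Gaussian pixel noise (default σ = 6). Default raster is
300×60 px per strip; row 0 is the top of the strip (highest molecular
weight), band centers are fractions of strip height.

Class structure follows the serology the study reports qualitatively:

* **cancer** and **healthy** each own a catalog of 4 candidate bands with
  mutually disjoint, well-separated centers (minimum separation 0.025 of
  strip height); every strip expresses 3 of its 4 catalog bands, so the
  within-class patterns are homogeneous and the two classes are mutually
  distinct;
* **benign** strips express 6 bands: by default one third drawn from the
  cancer catalog, one third from the healthy catalog, and the rest from a
  benign-only catalog — heterogeneous patterns overlapping both other
  classes.

Band amplitudes (uniform 120–200, rescaled 0.7–1.1 per strip) and widths
(2.5–5 px at 300 px height) mimic serum-to-serum intensity variation; band
centers get a small positional jitter (σ = 0.004 of height). The published
work does not quantify band counts per class, so the catalog sizes and
diversities above are free parameters chosen once to satisfy the
qualitative description; they were fixed before any benchmark was run and
are config-exposed.

What the generator does **not** model: electrophoresis physics, transfer
efficiency, inter-membrane staining differences (the control-serum
matching step), band-shape asymmetry, or scanner artifacts. Passing tests
therefore demonstrate that the pipeline recovers the *intended* class
geometry, not that it would reach any particular accuracy on patient
strips — synthetic classes are cleaner and more separable than real sera,
and desk-scale benchmarks routinely saturate near 100%.

A second fixture (`separable_cohort`) produces all-dark vs all-light
squares; it is deliberately trivial and is used only to smoke-test
training and evolution plumbing.

## Profile extraction

One profile per strip spanning the full lane: grayscale conversion
(ITU-R 709 luminance weights — the original tool converts internally
without stating weights), then the row-wise **mean** over the selected
columns (mean rather than sum so the profile scale is
resolution-independent). Manual area selection is emulated by offsetting
the lane window's top and bottom independently by up to `jitter_fraction`
(default 0.1) of the height, producing the dissimilar lengths the DTW
stage exists to handle. Whether the original authors took one area per
lane or one per band is not stated in their description; one whole-lane
profile per strip is this package's recorded choice.

Smoothing treatments:

* **space domain** — convolution with a unit-sum Gaussian kernel, radius
  ⌈3σ⌉, σ ∈ {0.5, 1.5, 2.5} px, mirror-about-edge boundary (avoids edge
  darkening on short series; constants are preserved exactly);
* **frequency domain** — full DFT, multiply by H(u) = exp(−u²/2σ²) with u
  the signed bin distance from DC, inverse DFT, real part. σ ∈
  {50, 150, 250} is in frequency-bin units of the length-n spectrum (the
  study gives magnitudes without units). The imaginary residue is
  numerically zero (checked < 1e−9 of signal norm) because H is even.

Both operators are linear and length-preserving.

## DTW and KNN

Local cost is the absolute difference (unstated in the study; absolute
cost keeps single-point distances scale-honest). The restriction window is
a fraction w of the **longer** series; the band half-width is
max(⌈w·max(n,m)⌉, |n−m|) — the widening is required for feasibility when
lengths differ by more than the window, which jittered lanes routinely do.
w = 0 disables the band. The DP is O(nm) (numba-compiled); no
lower-bounding or early abandoning, unnecessary at cohort size ~149.

KNN ties are fully deterministic: neighbors tied at the cutoff distance
are taken in training order; vote ties go to the smaller summed distance,
then to the fixed label order cancer < benign < healthy. This makes
10-run averages bit-reproducible.

## Metrics and protocol

Accuracy = trace/total. Precision, sensitivity, specificity are
one-vs-rest: micro (pool TP/FP/FN/TN over classes, the default for
3-class tables), macro (average per-class ratios, NaN-excluded), or
per-class with cancer positive (the 2-class default). Undefined ratios
are carried as NaN. Useful exact identities under micro pooling, for any
class distribution: sensitivity = accuracy, and
specificity = 1 − (1 − accuracy)/(C − 1) (pooled TN = (C−2)·total +
trace, pooled FP = total − trace). The published 3-class tables obey the
second identity at printed precision, which pins down their aggregation
scheme; the published 2-class rows (sensitivity = accuracy but
specificity ≠ accuracy) fit no single scheme, so both are computed and
the per-class view is merely a default.

Splits are stratified (the study is silent; unstratified 70/30 splits are
noisy at ~50 per class), per-class train count = round(0.7·n_c) clamped
to keep both sides non-empty, deterministic in (seed, run). 750 balanced
images yield exactly 525/225. Percentages print at 2 decimals, half-up.

Cross-method comparison: pairwise Welch t-tests on per-run accuracies,
Holm step-down at α = 0.05, compact letters assigned greedily by
descending mean (the study does not name its test; this choice is a
config-exposed default). Zero-variance pairs use an exact-equality rule.

## CNN engine and architectures

No deep-learning framework is required: `seroblot.nn` is a float32 CPU
engine with same-padded im2col convolution, batch normalization (momentum
0.1, ε = 1e−5), ReLU, non-overlapping max pooling (remainder rows
dropped; tied maxima split gradient mass evenly), dense layers, softmax
cross-entropy and Adam. He-normal init; every draw comes from a
caller-supplied generator, so training is bit-reproducible. Gradients are
verified against central finite differences in the tests.

The experimental architecture is conv(20)–BN–ReLU–pool, conv(40)–BN–
ReLU–pool, conv(80)–BN–ReLU, flatten, dense softmax; all kernels take the
grid value {3, 7, 9}. "Padding" is read as same-size padding — otherwise
three 9×9 convolutions plus pools shrink dimensions inconsistently with
the published layer list. For the narrow Fourier raster the two pools act
along the row axis only (2×1), keeping the stack shape-safe. Optimizer,
batch size and learning rate are unstated in the study; defaults are
Adam, batch 16, 1e−3, all overridable. Epochs: 20 (color/gray), 70
(Fourier), 10 (neuroevolution fitness).

Image treatments: color 256×256×3 (synthetic grayscale strips are tinted
with a fixed brown-on-cream diaminobenzidine palette), gray 256×256×1,
Fourier 256×15×1 — per-row DFT magnitude of the 15 lowest non-negative
bins (DC included), log(1+·), min–max scaled; which 15 coefficients and
what scaling the study used is unstated, so this construction is a
recorded default. The raster edge size is a parameter; desk-scale runs
use 64 (and 32 for evolution smoke tests) so the suite fits a single CPU.
Note that for width-constant synthetic strips the off-DC bins carry only
noise, so the Fourier treatment is intentionally information-poor on
synthetic data — consistent with it being the weakest treatment in the
published 3-class comparison.

Augmentation tops each class up to 250 (originals retained; whether the
published 5× augmentation kept originals inside the 250 is not fully
explicit — keeping them is the recorded choice). Each synthetic image is
one original under one uniformly chosen transform: rotation 10–30° (random
sign, about the center), translation 0.1–0.3 of the side per axis (random
sign), scaling 0.5–1 about the center, or Gaussian blur with a 7-sample
kernel (σ = radius/3). Affine transforms use edge-replication fill.

## Neuroevolution

The genome encoding and operators are this package's own (the study
configures but does not define them): 1–6 conv genes (filters 2–64,
kernel ∈ {3,5,7,9}, pool flag) plus 1–3 dense genes (2–128 neurons).
One-point crossover acts independently on the two gene lists with cut
points uniform over the length-bound-preserving pairs; mutation applies
exactly one operation chosen uniformly among the feasible ones (perturb a
value, add a gene, remove a gene, toggle a pool). Decoding repairs
shape-unsafe pool flags by disabling them (recorded in the spec notes)
rather than failing. Fitness is plain test accuracy after 10 training
epochs on a single stratified 70/30 split, cached per genome and
deterministic in (genome, seed). Selection is tournament (size 4),
elitism 1 — hence a non-decreasing best-fitness trajectory. Fitness is
single-objective; the multi-objective trade-offs of the underlying
neuroevolution tool are out of scope. The published best architecture
(conv filters 5, 2, 6, 4; dense 8, 3 — its caption says "3 fully
connected layers of 8 and 3 neurons", read here as two hidden dense
blocks ahead of the class layer; kernel sizes unreported, default 3) is
available canned as `best_published_genome()`.

## Problem sizes

Desk-scale defaults used by the test suite, the analysis drivers and the
acceptance script — chosen as this package's own benchmark conditions:
64×64 rasters (32×32 for evolution), 5–10 epochs, 3 holdout runs for CNN
stages, 10 for KNN; evolution at population 4 / 3 generations with
narrowed gene bounds (filters ≤ 8). The full study settings (256×256,
kernels {3,7,9}, 20/70 epochs, population 20 / 50 generations) remain the
config defaults of the corresponding classes.

## Known limitations

* Synthetic separability is by construction higher than patient sera;
  published accuracies on the real cohort are not reproducible without
  the images and are not targets of this package.
* The numpy engine is single-threaded-friendly but slow at full 256×256
  study scale; desk-scale rasters are the intended operating point.
* The 2-class aggregation of the published tables is ambiguous (their
  sensitivity equals accuracy while specificity differs); this package
  reports both micro and per-class views rather than guessing.
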