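# Methods

## Scope and design

The package studies one question at a controlled, fully reproducible
scale: when a CNN classifies cardiomyocyte culture fields into maturation
stages (day 2 / 6 / 14), does mixing GAN-generated synthetic images into
its training set improve generalization to an unseen acquisition batch?
Because the original recordings are proprietary, every input is produced
by a procedural phantom simulator whose ground truth is known; all claims
the test suite makes are therefore claims about this simulator, not about
real microscopy (see *Limitations*).

## Phantom microscopy simulator

A field is a 300×300 RGB composite of textured ellipses over a noisy
background, 8-bit quantized at render time so disk round trips are exact.
Per-class presets control

| parameter | day 2 | day 6 (difficulty d) | day 14 | units |
|---|---|---|---|---|
| cell_density | 7 | 13 − 4d | 22 | expected cells/field |
| cell_area_range | 1200–2600 | (3000 − 1700d)–5200 | 6000–9000 | px² |
| elongation_range | 1.0–1.5 | (1.5 − 0.4d)–2.5 | 3.0–5.0 | axis ratio |
| alignment_kappa | 0.5 | 1.5 | 4.0 | von Mises κ |
| intensity_fg / bg | 0.55 / 0.15 | ≈0.6 / 0.15 | 0.70 / 0.15 | [0,1] |
| noise_sd | 0.02 + 0.02d | same | same | [0,1] |

Cell sizes are chosen so cells remain resolved through the acquisition
path (300 px native → 128 px classifier input → 64 px GAN input): day-2
cells span ~40 px, day-14 cells ~100 px, and the day-14 field is
near-confluent. `difficulty` ∈ [0,1] pulls day-6 morphology toward day 2
(disjoint area ranges at 0; ≥50% overlap of the day-2 interval at 1),
mirroring the overlap of the two early stages observed in practice.
Orientations are von Mises; texture is a Gaussian-smoothed noise field
(length scale 6 px) modulating the foreground by ±25%.

**Unseen domain.** A second culture batch is modeled as a deterministic
mean shift of every preset parameter by `unseen_shift` of its own spread:
density and areas +35% relative per SD (batch-to-batch growth
variability), elongation +1 uniform SD, background +0.03, noise +0.02.
The direction is fixed and identical for all classes, so each class
drifts toward the morphology of the next timepoint — the kind of
"outlier features" that make the unseen batch genuinely harder.
Two earlier candidate directions were rejected during design: a pure
noise/contrast shift left the classifier unaffected (no domain gap to
study), and a pure illumination shift collapsed accuracy through a
trivial brightness cue; the growth-dominant direction produces a
moderate, morphology-driven gap (seen ≈ 0.92, unseen ≈ 0.77 at the
default study size) comparable in spirit to the motivating data.

**Beating clips.** A clip is one centred near-circular cell (radius 30%
of the 64×64 frame, bright membrane rim, textured interior) whose
boundary contracts radially toward the centroid with per-frame
displacement (0, A/2, A, A/2, 0) px at 5 FPS; the texture contracts with
the material so block matching sees true motion. Longer sequences repeat
the profile periodically (default one beat per 0.8–1 s) for the 20 s
normalization window.

## GAN

DCGAN-style, one unconditional model per class. Generator: linear
projection of the 64-dim latent to an (S/16)² map of `width` channels,
then four transposed convolutions (kernel 4, stride 2, pad 1) halving the
channel count each step, batch norm + ReLU between, Tanh head.
Discriminator mirrors with four stride-2 convolutions, LeakyReLU(0.2),
batch norm after the first layer, Sigmoid head. Real images are kept 25%
larger than the model size and randomly cropped and flipped every batch —
the same augmentation used at acquisition — which also prevents a
degenerate failure mode where batch norm lets the discriminator separate
real from fake by batch statistics alone when training batches repeat.
Losses are the minimax cross-entropy; the generator uses the
non-saturating form by default (saturating available by config), and
one-sided label smoothing is available but off by default. Defaults
(lr 2e-4, β = (0.5, 0.999), batch 64, 2000 epochs, 128 px, latent 64)
follow the original training setup; tests and the acceptance script train
at 32–64 px with width 64 and 300–2000 steps, which one CPU core handles
in seconds to minutes.

## Classifier

Three conv layers (kernel 3, pad 1; channels 32/16/4), each followed by a
4×4 max pool. The printed activation grid halves per stage (96→48→24→12),
which a 4×4 window achieves with stride 2 and padding 1; that overlapping
pool is used throughout. Head: 576→64→3 with softmax. "Weight norm
regularization" is implemented as an L2 penalty (default 1e-4) on conv
and linear weights. Training crops 96×96 at random (+ horizontal flip)
from 128×128 inputs every epoch; evaluation center-crops; inputs are in
[−1,1] so real and GAN images share one preprocessing path. Ablation
architectures: a 5-layer fully connected model on raw 96×96 pixels
(27648→4096→1024→256→64→3), a smaller CNN (16→4 channels, pools of 3 and
4, flatten 256), and a discriminator-like model consuming the full
128×128 input (flatten 4·16·16 = 1024 — the printed 48×48 grid cannot
arise from integer downsampling of 128, so halving stages are used).

## Evaluation

Domain reports carry seen/unseen/pooled accuracy; pooled is
sample-weighted, and the plain mean of the two domain accuracies is also
reported since summary "total accuracy" conventions differ. Confusion
matrices are 3×3, true-by-row. PCA and the four conventional baselines
(RBF SVM, 100-tree random forest, 5-NN, Gaussian naive Bayes) share one
featurization — 32×32 grayscale pixels, 1024 features — so distribution
comparisons are like-for-like; baselines repeat over re-seeded cycles
(default 10). PCA is sklearn's exact SVD solver; tests check it against a
brute-force eigendecomposition oracle at 1e-8 up to sign.

## Contractility

Blocks of 8×8 px, exhaustive ±8 px integer search, sum of absolute
differences. Background/featureless blocks are excluded by variance:
below max(1e-4, 4× the median block variance) — the median is
background-dominated for single-cell frames, which rejects sensor-noise
blocks whose matches would be arbitrary. The reference frame defaults to
the first (relaxed) frame so the trace estimates cumulative contraction
and its peak estimates the amplitude A; `reference="previous"` gives
frame-to-frame steps (≈ A/2 for the 5-point profile). Peaks are local
maxima above mean + 2 SD of the lower half of the trace; a flat trace
reports zero with a `no_peaks` flag. Phantom validation recovers rigid
2 px translation exactly and contraction amplitudes of 2–5 px within
12–25%; interior blocks move less than the boundary, so the estimate is
biased slightly low — within the stated 25% envelope.

## Numerical core

`cardiogan.nn` implements the layers with manual backpropagation in
float32: convolutions as a single GEMM over an im2col buffer, transposed
convolutions as the conv adjoint, the overlapping max pool as separable
numba kernels with argmax routing, batch norm with running statistics,
and Adam with bias correction (eps 1e-8). Gradients are verified against
central differences in float64 (tolerance 1e-4; probes crossing
ReLU/pool kinks are re-checked at smaller eps). Determinism: all
randomness flows through `numpy.random.Generator` seeded per stage by
SHA-256 of (global seed, stage name); identical seeds give bitwise
identical phantoms, histories and reports on a fixed BLAS.

## Study sizes used by the test suite and acceptance script

The augmentation experiment runs with difficulty 0.7, unseen shift 1.0,
60 training images/class, 40 test images/class per domain, GANs at 64 px
(width 64, 300 epochs, batch 16), a 100 image/class synthetic library
upsampled to 128 px, and classifiers trained 8 epochs at batch 16 — sizes
at which the complete experiment, including all five classifier seeds,
fits in minutes on one CPU core while leaving the qualitative phenomena
intact (a clear seen→unseen gap and a non-negative median augmentation
gain). Memorization smoke tests run at 32 px with 1000–2000 steps;
their pass thresholds were frozen from pilot runs committed under
`tests/fixtures/` and sit well below the constant-image baseline.

## Limitations

* The phantom presets realize the qualitative morphology descriptions
  (sparse/small vs dense/elongated); no quantitative calibration to real
  cardiomyocyte measurements exists, so absolute accuracies here do not
  predict accuracies on real recordings.
* At desk scale the GANs are far from photorealistic: synthetic fields
  reproduce density/coverage/brightness statistics and partial shape
  structure. The video GAN in particular memorizes a single clip only to
  ~0.2–0.3 MAE; its samples are temporally coherent but blurry.
* The augmentation gain is a median over classifier seeds and is small at
  this scale; individual seeds can be negative.
* Block matching is integer-resolution; sub-pixel contraction amplitudes
  below ~1 px are not resolvable.
* One unconditional GAN per class was chosen over a conditional design;
  with three classes this triples training cost but keeps each model's
  objective exactly the printed two-player game.
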