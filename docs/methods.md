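# Methods

## Model

Segmentation is cast as center-pixel classification: each pixel of an axial
slice is described by co-centered square multimodal windows (channels T1,
T1c, T2, FLAIR in fixed order) at several scales, and a CNN per scale maps
its window to a feature vector. Convolutions are multi-channel valid
cross-correlations, `M_s = b_s + Σ_c W_sc * X_c`, each followed by a
rectified-linear activation, so a layer with kernel `k` shrinks each spatial
side by `k − 1`. The reference architecture uses input scales 48, 28 and 12:

| pathway | conv kernels | map widths (reference) | pool | output |
|---|---|---|---|---|
| 48 | 11, 11, 11, 11, 5 | 12, 32, 96, 256, 1024 | (1, 4) max | 1024 × 4×1 |
| 28 | 11, 11, 5 | 12, 32, 72 | — | 72 × 4×4 |
| 12 | 5, 5 | 12, 16 | — | 16 × 4×4 |

Only the printed anchors of this architecture are fixed (C1 = 12 maps of
38×38 for the 48-pathway; pathway outputs 1024@4×1, 72@4×4, 16@4×4; fused
length 5504). The interior map widths are free choices; construction
asserts the declared outputs and fails loudly on any mismatch. The 4×1
pooled size of the 48-pathway is realized as a (1, 4) max pool over its 4×4
final maps — the only non-degenerate window with that output shape whose map
count × area (1024·4) is consistent with the fused length 5504.

Flattened pathway outputs are concatenated largest-scale-first into the
fused vector, standardized per dimension (mean/sd estimated on the training
set and stored with the model), and classified by a three-layer fully
connected head (hidden sizes 256, 64 at reference widths) with a softmax
output over the five tissue classes. Ties in the argmax go to the lowest
class index, making inference deterministic.

## Training

Pathways are trained **separately**, each with a temporary fully connected
head of its own, minimizing multinomial cross-entropy by plain mini-batch
SGD; an *iteration* is one mini-batch update and the default budget is 1000
iterations. The reference optimizer configuration is batch 128 and learning
rate 0.01; momentum is exposed but defaults to 0 — at these learning rates
momentum 0.9 makes the five-layer 48-pathway oscillate, while plain SGD
converges reliably. Weights use He-normal initialization and float32
arithmetic throughout; all randomness flows from explicit integer seeds, so
identical seeds give bit-identical losses, weights and predictions.

The multiscale stage freezes the trained pathways and fits the fused-feature
head on standardized features (the frozen pathway outputs are precomputed
once, which makes this stage cheap). Optional joint fine-tuning backpropagates
through the pathways afterwards at a tenth of the head learning rate;
gradients through feature dimensions whose training sd hit the numerical
floor (dead ReLU features) are zeroed, since `1/sd` would otherwise explode.
Whether the original procedure fine-tuned jointly or trained only the head is
ambiguous ("learnt separately and then combined"); frozen is the default.

### The "desk" profile

The package ships two width profiles with identical scales, kernels and
layer counts. `"reference"` is the full-width architecture above; `"desk"` thins the map widths
(48-pathway 4, 4, 6, 8, 16; 28-pathway 4, 6, 16; 12-pathway 6, 8; head
48, 24; batch 32) so the complete pipeline — sampling, three pathway
trainings at 1000 iterations, head training and full-volume inference — runs
in a few minutes on one CPU core. All architecture-arithmetic checks use the
reference widths; behavioral experiments use desk widths.

## Numerical implementation

Convolutions above a small work threshold are evaluated through the FFT:
real 2D FFTs of inputs and kernels, a per-frequency batched complex GEMM
contracting the channel axis, and an inverse FFT from which the valid region
is sliced. Because the transform length is at least the input side, the
circular convolution equals the linear one on the valid region, so the FFT
route computes exactly the same sums as the sliding-window route (verified
to ~1e-13 in float64); it is 30–60× faster for 11×11 kernels, where NumPy
cannot map the direct 6D contraction onto BLAS. Weight and input gradients
have the same FFT forms (frequency-domain correlation and true convolution
respectively). Small convolutions use the direct einsum.

Sliding-window inference is computed densely: all pathway layers are
stride-1 valid convolutions, so running the conv stack once over a
reflect-padded slice produces planes in which each pixel's final patch maps
appear as shifted windows; per-pixel max pooling and head evaluation then
vectorize over the whole slice. This is exactly equivalent to extracting one
patch per pixel (asserted in tests against a naive per-pixel reference) and
two orders of magnitude faster. Under the `skip` border policy the band
where the largest window does not fit is labeled 0 and flagged in the result
provenance. A `stride > 1` option classifies a subsampled grid with
nearest-neighbor fill; the default classifies every pixel.

## Patch geometry

Even side lengths have no central pixel. The convention everywhere is that
the center sits at window index `scale // 2`, i.e. windows span
`[c − scale//2, c + scale − scale//2)`. With this half-open convention the
12×12 patch is exactly the central crop of the 28×28 patch, which is exactly
the central crop of the 48×48 patch — an invariant the tests assert. Borders
are mirror-reflected by default (`reflect`, no edge duplication), keeping
every brain pixel classifiable; `skip` is available for training-set purity.
Training sets are class-balanced by per-class quotas with centers drawn
uniformly within each class mask — tumor classes occupy a tiny volume
fraction and unbalanced sampling would trivially bias the classifier toward
background. The sampling strategy, quotas and train/test splits are not
dictated by the method and are exposed as configuration.

## Intensity normalization

MRI gray values are scanner-dependent, so volumes are normalized per channel
by z-scoring the nonzero (brain) voxels; exactly-zero background stays zero,
which preserves the brain mask and makes the transform idempotent. The step
is switchable (`method="none"`) since the original pipeline's preprocessing
is unspecified.

## Prior scale selection

Before training, `ceil(fraction · total)` axial slices (default fraction
0.01) are drawn without replacement, and every candidate patch size is scored
by the held-out accuracy (20% holdout) of a cheap proxy network — two 3×3
conv layers, a 2×2 pool when the map divides, and a small head, trained for
200 iterations — on class-balanced patches from those slices. Patch accuracy
is used as the ranking metric because the prior step must stay cheap; Dice
would require full-slice inference. The top three scales win; ties prefer
the larger scale, since global context is the scarcer signal. Each candidate
derives an independent sub-seed from (master seed, scale), so enlarging the
candidate grid never changes an existing candidate's score. The candidate
grid itself is a user decision (default 12, 20, 28, 36, 48).

## The phantom

The generator emulates a BRATS-style case: a brain ellipsoid (optionally
squashed along z) inside zero-intensity air, one ellipsoidal CSF pocket, and
a tumor of concentric spherical shells — necrotic core (label 1), enhancing
rim (4), nonenhancing shell (3), edema halo (2) — clipped to the brain mask.
Each tissue has a per-modality mean intensity and voxels get additive
Gaussian noise inside the brain. The default means encode the clinically
relevant contrasts: the enhancing rim is the T1/T1c-brightest tissue (bright
tumor border), all tumor classes exceed normal tissue on T2, and edema is
FLAIR-bright while CSF is FLAIR-suppressed, so FLAIR separates edema from
CSF; these orderings are validated at construction. Intensities are float —
MRI gray scales are scanner-dependent, so no canonical integer quantization
exists.

What the phantom deliberately lacks: anatomy (no tissue atlas), bias fields,
partial-volume mixing, non-Gaussian noise, inter-case registration error,
and irregular tumor shapes. Passing tests on phantoms therefore demonstrates
the mechanics and the scale-fusion property of the pipeline, not clinical
performance; headline benchmark numbers on real BRATS data are out of scope
here.

## Study conditions used by the test suite

* **End-to-end recovery**: one 64³ phantom (brain radius 28; shell radii
  9/4/4/8), noise sd 3 — below 10% of the smallest inter-class mean
  separation (~35 intensity units in 4-channel Euclidean distance); 2000
  patches per class; 1000 pathway iterations at desk widths; full-volume
  inference; whole-tumor Dice ≥ 0.85 required.
* **Scale preference**: a thin-slab phantom (384×384×8) whose tumor rings
  are all 42 px wide with noise sd 40 — single-pixel intensity is genuinely
  ambiguous there, so accuracy must come from spatial context; candidate 48
  must outrank candidate 8 in ≥ 4 of 5 seeds.
* **Fusion benefit**: six phantoms with whole-tumor radii from 5 to 30 px
  (noise sd 10), 600 patches/class, 400-iteration pathways; over 3 seeds the
  three-pathway median whole-tumor Dice must be within 0.02 of (or above)
  the best single pathway's. Evaluation uses the three central slices of
  held-out phantoms of the same geometry population.

Problem sizes (volume shapes, quotas, iteration counts of the experiments)
are the package's own desk-scale choices; Dice is always computed on every
pixel of the evaluated slices.

## Degenerate inputs and edge cases

* Two empty masks have Dice 1 (perfect agreement on absence), so tumor-free
  slices do not poison case averages; this is logged.
* Constant channels are rejected by z-score normalization; single-class
  training sets are rejected; iteration counts < 1 are rejected.
* Candidate scales larger than the slice (or too small for the proxy) are
  excluded from ranking with a warning; a single feasible candidate yields a
  degenerate top-3 with a warning.
* Label volumes must contain only codes 0–4; misaligned modality shapes are
  rejected rather than resampled (BRATS cases ship co-registered).
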