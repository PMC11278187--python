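# Methods

`ctstroke` implements a desk-scale version of a hybrid ischemic-stroke CT
workflow: image enhancement with quantitative quality metrics, a
closed-form ensemble classifier, box-guided segmentation evaluation, and a
synthetic phantom generator that makes every stage testable without
clinical data. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## The SPEM enhancement chain

The stroke precision enhancement model (SPEM) is a fixed four-stage chain
applied to 8-bit grayscale CT slices:

1. **Morphological erosion** — a sliding-window minimum over a
   `(2r+1)×(2r+1)` square element (default `r = 1`), border handled by edge
   replication. Suppresses small bright noise before contrast manipulation.
2. **CLAHE** — per-tile histogram equalization with the histogram clipped
   at `clip_limit ×` the uniform bin height (default clip limit 4, 256
   bins), the clipped excess redistributed uniformly over all bins in one
   pass, and the per-tile mappings blended by bilinear interpolation
   between tile centers. A constant tile maps through the identity ramp, so
   constant images are fixed points.
3. **LoG edge enhancement** — Gaussian blur at `log_sigma` (default 1.5 px)
   followed by the discrete 5-point Laplacian; the signed response is
   *subtracted* with weight `edge_weight` (default 0.3). Subtraction is the
   textbook Laplacian-sharpening convention: with a negative-center
   stencil, *adding* the response is a diffusion (smoothing) step.
4. **Unsharp masking** — `clip(x + amount · (x − G_σ x))` with
   `unsharp_sigma = 2.0`, `amount = 1.0`.

All stages compute in float; quantization (round half away from zero, then
clip to `[0, 255]`) happens once, on the final output. Round-half-away was
chosen over banker's rounding for platform independence.

### CLAHE tile geometry

The tile grid defaults to *size-adaptive*: the grid is chosen so tiles are
roughly 80 px on a side (`default_tile_grid`), which gives the conventional
8×8 grid on a 640-px slice and a 2×2 grid on the 128-px phantoms used in
tests. The invariant worth preserving across image scales is the tile
*size*, not the tile *count*: each local histogram should see the same
amount of anatomical context, and a histogram needs enough samples to be
stable. A 16-px tile has 256 pixels spread over 256 bins — its empirical
mapping degenerates into a per-tile rank transform of the noise, which
amplifies noise without adding usable contrast. Explicit `tiles=` arguments
override the adaptive default everywhere.

### Quality metrics

* **EME** (effective measure of enhancement): partition into `K₁×K₂` blocks
  (the last block in each dimension absorbs remainder pixels) and average
  `20·log₁₀((I_max + ε)/(I_min + ε))` per block. The raw ratio is undefined
  when a block minimum is 0, so a configurable `ε` (default 1.0) is added
  to both numerator and denominator; EME stays finite and monotone in
  contrast.
* **MSE / PSNR**: mean squared pixel difference, and
  `10·log₁₀(255² / MSE)` in dB. Identical images report PSNR = +∞ (an
  explicit sentinel, not an overflow).

EME is only meaningful on images whose dynamic range is not already
saturated by extreme structures. A whole-head slice spans air (0) to bone
(~230), and equalization necessarily raises the black floor, *lowering*
EME; the metric is therefore evaluated on the low-contrast parenchymal
interior (`brain_window_crop`), which is also the clinically relevant
region.

## The edRVFL classifier

A random vector functional link (RVFL) layer is a hidden layer with frozen
random weights plus *direct links*: the output layer sees
`D = [act(XW + b) | X | 1]` — hidden activations, raw features, and a
constant column that implements the output bias. The deep ensemble stacks
`L` layers (`H₁ = act(XW₁ + b₁)`, and `H_l = act([H_{l−1} | X]·W_l + b_l)`
for `l ≥ 2`), gives each layer its own output head solved in closed form,

    W_l = (D_lᵀD_l + λI)⁻¹ D_lᵀ Y,

with one-hot targets `Y`, and aggregates per-layer scores by their mean
(majority voting over per-layer argmaxes is available). Under the default
`inverse_c` convention `λ = 1/C` with `C = reg_c` — large `C` means weak
regularization, the dominant convention in the RVFL literature; the
`direct_lambda` convention (`λ = reg_c`) is exposed because "regularization
parameter = 100" does not by itself disambiguate the two.

Defaults are 10 enhancement nodes per layer, `C = 100`, 10 layers, tanh
activation. "Nodes per layer" (rather than total) is the assumed reading of
the node count; it is configurable. Hidden weights and biases are drawn
uniformly from `[−1, 1]`; inputs are standardized to zero mean and unit
variance using training-split statistics only, since bounded random weights
need bounded inputs to keep tanh out of saturation. The regularized normal
equations are solved directly as a symmetric positive-definite system —
design widths here are at most a few hundred columns, so iterative solvers
would add nothing. A `bagging_fraction < 1` trains each layer's head on its
own seeded row subsample ("each network sees a different segment of the
data"); the default 1.0 gives every layer the full training set, which is
what the permutation-invariance and ridge-reduction tests assume.

Ties in the argmax decision rule break toward the class earliest in the
model's (sorted) class order — deterministic and documented, and the reason
the zero-score limit predicts the first class everywhere.

With `n_layers = 1, n_nodes = 0` the model reduces exactly to ridge
regression of one-hot targets on `[X | 1]`; the test suite pins the
implementation to an independent normal-equations solution in that regime
(both ridge conventions, max |Δ| ≤ 1e-8).

## Segmentation evaluation

The Dice similarity coefficient `DSC = 2|A∩B| / (|A| + |B|)` scores
predicted against true masks. Two empty masks score 1.0 by default —
correct agreement on the *absence* of a lesion, which is the right
convention when normal slices flow through the same harness; strict
benchmarking can set the convention to 0.0.

The reference segmenter (`otsu_box_segment`) mirrors a detector→segmenter
hand-off: an Otsu threshold computed from the 256-bin histogram of the
*box interior only* (so skull and background cannot skew it), keeping the
hypodense side (the ischemic CT appearance), reduced to the largest
4-connected component (the simplest defensible connectivity; documented
rather than argued). A constant box yields an empty mask with a warning.
Foundation segmentation and detection models stay outside the package
behind the `Segmenter` interface and the detection-exchange CSV format.

Because phantom boxes are the *tight* bounds of the true mask, the box
interior is mostly lesion; Otsu then bisects the lesion's own intensity
distribution rather than separating lesion from parenchyma, which caps the
reference segmenter's Dice well below what a looser detector box would
allow. The evaluation direction (chronic easier than hyper-acute) is
unaffected.

## The phantom generator

Each phantom is an elliptical bright skull ring (intensity ~230), noisy
parenchyma (mean 100, additive Gaussian noise, sd 8), a symmetric pair of
dark ventricles (~40), and — for the four stroke stages — one hypodense
elliptical lesion. Stage difficulty is controlled by two parameters:

| stage       | mean contrast (δ) | boundary blur σ (px) |
|-------------|------------------:|---------------------:|
| hyper-acute | −6                | 4                    |
| acute       | −15               | 3                    |
| sub-acute   | −25               | 2                    |
| chronic     | −40               | 1                    |

matching the clinical conspicuity gradient (hyper-acute subtlest, chronic
best demarcated). Lesion semi-axes are drawn from 11–17% of the slice size.
Three design points matter:

* `lesion_delta` is realized as the **mean contrast over the lesion mask**:
  the blurred indicator field is rescaled so that its average over the
  half-peak region equals δ. Without this, boundary blur dilutes the
  achieved contrast by roughly 8–25% depending on σ, and the configured
  numbers would not be recoverable from the images.
* The ground-truth mask is the half-peak contour of the **pre-noise**
  lesion field, so ground truth is independent of the noise draw.
* The lesion placement margin uses the **maximum** boundary σ across all
  stages, so every stage draws lesion centers from the same spatial
  distribution. (A σ-dependent margin would let sharp chronic lesions sit
  more peripherally than blurred ones, confounding placement with
  conspicuity.)

The base geometry (skull, parenchyma, ventricle pair) is symmetric under
180° rotation about the image center; the rotated copy of a lesion mask is
therefore an exactly matched lesion-free control region, which is how the
contrast-recovery test measures achieved δ.

The default slice size is 128 px (desk scale); 640 px mirrors the
standardized clinical input size. Phantoms claim *no* anatomical realism:
no gyral/sulcal structure, no beam-hardening, no partial-volume effects,
and — importantly — pixelwise independent noise rather than the spatially
correlated noise of real CT reconstruction.

## Classification protocol

The primary protocol is stratified k-fold cross-validation (default 25
folds; the desk-scale benchmarks use 5) over four binary tasks — normal vs
one stroke stage, the stroke stage being the positive class, so recall
reads as stroke sensitivity. The fixed 70/20/10 split exists as an
alternative mode; when both protocols appear in a study description, CV is
the one that determines headline numbers here. An all-five multiclass mode
with one-vs-rest macro averaging is provided as a clearly-labeled
extension. Metrics are accuracy, precision, recall, F1 and AUC (rank-sum /
Mann–Whitney formulation with midranks for ties); ratios with zero
denominators report 0 with a `degenerate` flag instead of aborting a fold.

Augmentation quadruples a training set (original, horizontal flip, random
rotation in ±15° with reflective padding, random 85–100%-area crop resized
back). Reflective padding avoids introducing black corners that would
distort EME blocks. When augmentation is enabled inside cross-validation it
is applied to the **training rows of each fold only** — augmenting before
the split would leak variants of one image across folds. Enhancement, when
enabled, runs after augmentation (the order is a config decision, exposed,
not dictated by the source protocol).

The desk-scale feature stand-in (`BlockStatExtractor`) computes per-block
mean and population standard deviation on an 8×8 grid plus a 16-bin global
normalized histogram (144 features). Externally computed CNN embeddings
(e.g. a DenseNet121 transfer-learning stage run elsewhere) drop in through
`EmbeddingFileExtractor` without bundling any pretrained weights.

Metric CSVs are part of the byte-identical determinism contract and
therefore contain no timings; wall times (hardware-dependent, reported
informationally only) go to separate `timing_*.csv` files.

## What the phantom benchmark shows — and does not

With the defaults above (100 phantoms per class, 128 px, 5-fold CV), the
raw pipeline recovers the intended difficulty gradient: mean accuracy
increases monotonically from the hyper-acute to the chronic task, and the
normal-vs-chronic task exceeds 0.95. The reference segmenter's mean Dice is
likewise higher for chronic than hyper-acute lesions. CLAHE at clip limit 4
raises EME on essentially all low-contrast phantom interiors.

One directional claim does **not** reproduce at desk scale: running the
full SPEM chain before feature extraction *lowers* phantom classification
accuracy on the subtlest (hyper-acute) task relative to raw images, even
though CLAHE alone raises it slightly. The mechanism is straightforward:
under pixelwise-independent noise of sd 8 against a lesion contrast of 6,
the sharpening stages (erosion residue, LoG subtraction, unsharp masking)
amplify high-frequency noise faster than lesion signal, and block-statistic
features integrate that noise directly. The setting in which enhancement
helps a real pipeline — edge/texture conspicuity for a CNN on relatively
low-noise clinical CT — is precisely what this stand-in extractor and noise
model do not represent. The package keeps the enhancement defaults faithful
to the described method rather than de-tuning the sharpening stages until
the comparison flips; the corresponding acceptance test is expected to fail
on phantoms and documents this limitation.

## Problem sizes

The bundled benchmarks use 128-px phantoms, 100 samples per class, 5-fold
CV, and 5–10 random seeds per comparison — sizes chosen so the whole suite
runs in minutes on one CPU while keeping the Monte-Carlo error of each
reported mean near or below one accuracy point. The clinical-scale
configuration (640-px inputs, 25-fold CV, thousands of images) is reachable
through the same interfaces.
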