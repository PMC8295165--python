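# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic experiments do and do
not demonstrate.

## Tensor backend

All networks run on `ivuscaps.autodiff`, a small reverse-mode automatic
differentiation engine over dense numpy arrays written for this package.
The iterative routing procedure is *unrolled*: every routing iteration's
softmax, weighted sums and nonlinearities are ordinary nodes in the
backward graph, so gradients flow through the routing exactly (verified
against central finite differences to 1e-3 relative error).  Float32 is
the working precision for training; the primitives preserve the input
dtype, so the oracle and gradient tests run in float64.  Coupling logits
are re-initialized to zero on every forward pass — routing is inference-
time iteration, not learned state.  Because softmax of zero logits is
exactly uniform, the first routing iteration is computed as a window sum
over the compact (pre-windowed) child tensor; the windowed tensor is only
materialized when a later iteration needs child-specific coefficients.
This is an algebraic identity, not an approximation, and layers with one
routing iteration never materialize windows at all.  For the later
iterations, the three windowed-routing contractions (coefficient-weighted
sums, child–parent agreements, and their shared adjoint scatter) and the
per-capsule matrix transforms run as fused numba kernels that index the
compact padded child tensor in place — the k²-times-larger windowed
tensor is never built.  The kernels are plain multiply–accumulate loops
without fast-math, so they match the explicit-loop oracle references to
float roundoff.

## Capsule primitives

* `squash` bounds the Euclidean/Frobenius norm below 1 and preserves
  direction; it is implemented as `x · n/(1+n²)` with `n² = Σx²` and a
  1e-16 floor inside the square root so the zero capsule maps to zero
  with a finite gradient.
* `Psquash` divides a pose matrix by its maximum absolute entry, floored
  at 1e-12 so the zero matrix maps to itself (the printed formula would
  divide by zero there).
* Dual routing couples the pose and appearance streams with one
  coefficient set per (child, parent) pair; the agreement update is the
  sum of the two Frobenius inner products feeding one shared logit.  The
  softmax runs over parent types for each child (a part chooses its
  whole).  The "dynamic" routing variant on matrix capsules flattens each
  pose+appearance pair into a single vector, routes with dot-product
  agreement, and applies the vector `squash` to the whole concatenated
  capsule — the matrix-specific nonlinearities are what the dual
  algorithm adds.
* Pose treatment: the best-performing variant normalizes every column of
  the *transformed* pose matrix to unit length and then adds scaled
  coordinates; alternatives (normalizing the transformation matrix
  instead, skipping coordinates, doing nothing) are selectable via
  `PoseTreatment`.  Coordinates are the child capsule's own grid position
  normalized to [0, 1] (row and col added to the first two entries of the
  last pose column), at scale 1.0 by default.  Applying them at the
  child's position, before window extraction, keeps zero-padding capsules
  exactly zero so they cannot influence routing at the image border.
* The appearance bias `b_ij` is a scalar added entrywise before the
  appearance transform; a full-matrix bias variant is exposed via
  `matrix_bias=True` since the notation admits either reading.

## Architecture

The capsule U-Net: an ordinary 5×5 convolution produces
`shape[0] · pA²` rectified feature maps that are reshaped into the first
level's appearance matrices (then squashed into the sub-unit Frobenius
ball so they enter on the same scale as later layers); initial poses are
the identity.  Each encoder level applies `layers_per_level` convolutional
capsule layers; a stride-2 routing window moves between levels; the
decoder mirrors the encoder with transposed (input-dilated) routing
windows and merges skip connections by *type concatenation* — addition
would average capsules of different types before routing could arbitrate
between them.  The final layer routes onto `classes` capsule types and
scores each class as the product of the pose and appearance Frobenius
norms; prediction is the per-pixel argmax.  Same-padding everywhere, so
spatial sizes halve/double exactly and a 256×256 input works with five
levels.

Transform banks are shared across all spatial positions and window
offsets (one `(Ti, To)` bank per layer), which keeps the largest preset
around half a million parameters.  Parameter budget tiers: the presets
`{3,4,5,6}`, `{3,5,7,9}` and `{3,6,12,24,48}` define three sizes; the
baseline residual U-Net is matched to each by bisecting a fractional
channel base (channels per level are `round(base · 2^level)`, preserving
the doubling rule while allowing <1% budget error).  The baseline uses
residual blocks of two 3×3 convolutions with per-channel spatial
normalization and a projected shortcut, stride-2 convolutions to
downsample, and nearest-neighbour upsampling followed by a 3×3
convolution.

## Losses

The spread loss penalizes, per pixel, every wrong-class activation within
a margin of the true-class activation:
`Σ_{c≠t} max(0, m − (a_t − a_c))²`, averaged over pixels.  Activations
enter raw (the Frobenius-product output layer has no normalization
attached).  The margin ramps linearly 0.2 → 0.9 over the first 20% of the
epoch budget and stays at 0.9 — starting small keeps early gradients
alive when all activations are similar.  The generalized Dice loss for
the baseline weights each class by the squared reciprocal of its volume;
a class absent from the target would get infinite weight, so its weight
is capped at the largest finite class weight.

## Metrics

Dice is reported in percent with the both-empty convention (100 when a
class is absent from both masks).  Hausdorff and average Hausdorff
distances are computed between class *boundary* pixels (4-connectivity;
the image border counts as outside), since they measure edge alignment; a
flag switches to filled-region mode for sensitivity checks.  Nearest-
neighbour queries use a k-d tree; the test suite checks them against a
brute-force all-pairs implementation to 1e-9.  A class missing from one
mask yields flagged-missing distances rather than infinities.  With a
mm-per-pixel spacing, physical distances are pixel distances scaled
linearly.

## Synthetic phantoms

The generator emulates the features that make IVUS segmentation hard:
dark elliptical lumen inside a brighter wall annulus (deformed ellipses
expressed as smooth periodic radial functions, which guarantees a single
closed wall ring strictly containing the lumen), a bright central
catheter disc with a ring-down halo, multiplicative gamma speckle
(mean 1, shape 3–8, lightly blurred to mimic correlated ultrasound
texture), and randomly placed angular shadow wedges with raised-cosine
edges.  Frames are grouped into synthetic "patients" sharing morphology
statistics so grouped cross-validation is meaningful.  Default frame size
is 256 (the training resolution); experiments here run at 64.  Not
modeled: physically accurate wave propagation, plaque and calcification
echogenicity, transducer-frequency-specific texture — so passing the
synthetic recovery experiment shows the architecture, losses, routing and
pipeline work end-to-end, not that real-IVUS accuracy numbers transfer.

Augmentation is a uniform random rotation about the frame center
(bilinear for the image, nearest-neighbour for the mask so labels stay
integral) plus random horizontal/vertical flips, applied on the fly to
training frames only.  Arbitrary angles (not only 90° multiples) are
appropriate because IVUS frames are rotationally unconstrained about the
catheter.

## Cross-validation schemes

On a ten-patient manifest: `s250` holds out all frames of one training
patient per fold (five folds over five training patients) with the
remaining five patients as a fixed common test set; `s150` is the same
scheme with a 60% per-patient frame subsample; `s50` splits a single
training patient's frames into five folds of ten — deliberately
correlated validation.  Test identity across scenarios and zero train/
validation/test leakage are asserted at construction.  Model selection is
the best epoch by mean foreground (wall + lumen)/2 validation Dice,
earliest epoch on ties.  Fold aggregates report mean ± standard deviation
across folds; per-image values are also emitted.  Batch size defaults to
4 (unspecified upstream; config-exposed); learning rates default to 1e-3
(capsule, spread loss) and 2e-4 (baseline, generalized Dice loss), with
200 epochs as the full-scale default.

## Desk-scale experiment sizes

Training the five-level, 5×5-window network on hundreds of 256×256 frames
is a GPU-scale computation; this package's experiments are sized for a
single CPU core.  The end-to-end recovery experiment uses a toy network
(shape {2,4}, one layer per level, 3×3 windows, two routing iterations,
2×2 pose and 3×3 appearance matrices) trained for 30 epochs at batch
size 1 on 32 phantoms at 64×64 from eight synthetic patients, with
separate validation and test patients.  Under these conditions held-out
lumen Dice ≥ 85% and wall Dice ≥ 70% are expected in at least two of
three seeds; the thin wall ring is the harder target since a one-pixel
boundary error costs proportionally more of its area.  The full-size
presets are still constructed and parameter-counted exactly; they are
simply not trained in the test suite.

## Known limitations

* No batching across images inside a forward pass; gradients accumulate
  over a batch by summation.  Throughput, not correctness, is the cost.
* The routing window at image borders includes zero capsules (same
  padding).  They contribute nothing to weighted sums or agreements but
  do receive (uniform) coefficients.
* `Psquash`'s gradient at a tied maximum splits evenly among ties — a
  measure-zero event in float arithmetic.
* The dynamic-routing variant on matrix capsules is one reasonable
  reading of "dynamic routing applied to the same network"; the dual
  algorithm is the primary, fully specified path.
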