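# Methods

## Problem and model

The package classifies one eye as healthy or early-stage glaucoma from
two modalities: a color fundus photograph and eleven OCT sector
thicknesses (four macular quadrant sectors UO/UI/LO/LI and seven
peripapillary RNFL sectors G/T/TS/TI/N/NS/NI, all in µm).  Severity
staging follows the vision-mean-defect convention (early: V-MD in
(−6, 0] dB); only the binary label enters the classifier.

Three models are defined.  Model 1 (CNN branch) maps the preprocessed
78×116×3 image tensor through four Convolution–BatchNorm–ReLU–MaxPool
stages and one final valid 3×5 convolution to a 32-value feature
vector.  Model 2 (ANN branch) maps the two structural features
(WA_MT, WA_RNFL) through a fully connected ReLU stack (default 4
layers × 16 nodes).  Model 3 concatenates the CNN feature vector with
the ANN's final hidden layer (width 32+16) and applies a dense head
(default 2 layers × 16 nodes) ending in a single sigmoid unit p̂.  The
decision rule is ŷ = 1 iff p̂ > 0.5, strictly, so p̂ = 0.5 maps to
healthy.  Each branch is also buildable standalone with its own sigmoid
head, which is how the branch-vs-fusion comparison is run.

### CNN stage geometry

Only the feature-map sizes of the reference architecture are fixed a
priori; the kernel/stride/padding combination realizing them is a
package design choice:

| stage | conv | pool | map after conv | after pool |
|---|---|---|---|---|
| 1 | 3×3, pad 1, stride 1 | 2×2, stride 2 | 32@78×116 | 32@39×58 |
| 2 | 5×4, valid, stride 2 | 3×3, stride 1 | 32@18×28 | 32@16×26 |
| 3 | 2×2, valid, stride 2 | 3×3, stride 1 | 32@8×13 | 32@6×11 |
| 4 | 3×3, pad 1, stride 1 | 2×2, stride 2 (floor) | 32@6×11 | 32@3×5 |

followed by a valid 3×5 convolution to 32@1×1.  Construction validates
the induced trace against this table and raises, naming the first
mismatching stage, if a custom configuration breaks it.  Normalization
is per-channel batch normalization (the conventional reading of a
C-N-R-P block); initialization is seeded He-uniform, appropriate for
ReLU stacks and reproducible.

### Loss

L = −y·(1−p̂)^α·β·ln p̂ − (1−y)·p̂^α·β·ln(1−p̂), with α ≥ 0, β > 0,
defaults α=1, β=1.5.  The logarithm is natural; the exponent β inside
log p̂^β is applied as the gain β·ln p̂ in both terms symmetrically.
Probabilities are clamped to [ε, 1−ε], ε = 10⁻⁷ (configurable), and
batch reduction is the mean, making the objective invariant to batch
size.  At α=0, β=1 the loss is exactly binary cross-entropy, which the
suite checks to machine precision, along with analytic-vs-numerical
gradient agreement at 10⁻⁵.

## Preprocessing

Five stages, composed in order; every output is 78×116×3 regardless of
input size.

1. *Text blackout.* Clinical fundus exports carry burned-in patient
   text; the configured band is set to exactly 0 in all channels.
2. *Single-scale Retinex*, per channel: log(I+ε) − log(G_σ∗I+ε) with a
   Gaussian surround (σ default 30 px at 500×750, scaled with image
   height), rescaled min–max to [0, 255] (a fixed-gain clip mode is
   also available).  A multiplicative illumination field varying slower
   than σ cancels in the log ratio; the suite verifies invariance on
   constructed gain fields and gradient flattening on the phantom's
   illumination model.
3. *Elliptical ROI* covering cup, disc and macula; outside pixels are
   zeroed.  The two treatments of the outside region produce genuinely
   different tensors: `black_fill` keeps the full frame, `delete`
   additionally crops to the ellipse's bounding box.  The default is
   `delete`.  The ellipse is a global configuration (center/semi-axes),
   defaulting to a region spanning the phantom's disc and macula
   centers; per-image ROIs are possible but not default.
4. *Rotation augmentation*: each image becomes two — the original plus
   one rotation drawn uniformly from {30, 60, 90, 120, 180}° counter-
   clockwise about the center.  Multiples of 90° are exact grid moves;
   other angles use bilinear interpolation with out-of-canvas = 0.
5. *Resize* to 78 rows × 116 columns by exact area interpolation
   computed from the integral image (each output pixel is the mean of
   its fractional source box), so constant images and global means are
   preserved to float precision.

## Training schedule

Training runs `l` blocks (default 5) of up to `h` epochs (default 200),
each epoch `b` batches (default 100) of size `m` (default 40) drawn at
random from the training set.  Design choices where the procedure was
genuinely open:

* *Blocks are independent restarts*: each block re-initializes weights
  (block-derived seed) and re-seeds the batch sampler while keeping the
  same split.  The alternative — one continued run checkpointed per
  block — produces strongly correlated block-models; independent
  restarts make the mean ± s.e. over blocks an honest variability
  estimate against a fixed test set.
* *Checkpoint rule*: every 40 batches (configurable) the current
  weights are scored on the validation set, as is the end of every
  epoch; the best-scoring candidate becomes the block-model.
* *Termination rule*: early stopping when the per-epoch validation
  loss has not improved for `patience` epochs (default 10).
* *Optimizer*: Adam, learning rate 10⁻³, seeded.

The split is stratified by class at fractions (0.50, 0.20, 0.30) with
largest-remainder rounding (204 healthy → 102/41/61; 130 early →
65/26/39), performed on subjects *before* augmentation so both views of
an eye stay in one set.  Validation and test predictions use only the
unrotated view — one decision per eye.  Thickness features are z-scored
with training-set statistics stored alongside the model.

## Factorial hyperparameter optimization

Four two-level factors are tuned for the fused model: ANN layers
(2 / 4), ANN nodes (4 / 16), head layers (2 / 3), head nodes (4 / 16).
The engine generates the 2^k design in standard order (first factor
alternating fastest), runs each combination with independent
replicates (default 2) of multi-block trainings (default 5 blocks per
run), and estimates effects by OLS of all block accuracies on the coded
±1 factors: effect = 2·coefficient, with t and p values from the fit.
The response unit is one block accuracy; the error degrees of freedom
therefore pool replicates and blocks, a choice documented rather than
claimed canonical.  Two-way interactions are estimable on demand, but
only main effects drive the recommended setting: +1 for positive
coefficients, −1 otherwise, ties toward −1 (the cheaper level).
Combinations are ranked by mean accuracy with ties broken by lower SD.

## Phantom generator

The generator emulates the statistical structure the classifier
assumes, not retinal appearance.  Healthy sector means are set in
physiological ranges (macular ~283–310 µm with inner sectors thicker;
RNFL following an ISNT-like profile, 70–140 µm) with Gaussian noise
(default SD 10 µm, truncated at 0).  Glaucomatous eyes thin
multiplicatively: early by `thinning_fraction_early` (default 0.15, a
mid-range early-glaucoma RNFL loss), moderate and severe by 1.75× and
2.5× that fraction.  Images carry a bright disc with a brighter cup
(cup-to-disc ratio ~N(0.35, 0.05) healthy vs ~N(0.60, 0.05) glaucoma),
a darker macula, parabolic vessel arcs, a smooth multiplicative
illumination field, and a bright glyph band at a fixed top-left
position.  Identical spec + seed reproduces the cohort bit-exactly.

What the phantom does *not* model: real fundus texture, vessel
branching anatomy, stage-specific image phenotypes beyond the
cup-to-disc shift, inter-eye correlation within a patient (each record
is one independent eye), instrument segmentation artifacts, or
covariate shift between clinics.  Passing tests therefore demonstrate
that the pipeline recovers planted signal under its own assumptions —
not clinical performance.

## Scaled-down end-to-end experiment

The acceptance suite's end-to-end comparison uses a 120-eye cohort
(60 healthy / 60 early, thinning 0.30 — a strongly separable setting),
3 blocks × ≤10 epochs × 10 batches of m=8, three training seeds; these
problem sizes are the package's chosen desk-scale configuration.  Under
it the thickness branch is near-ceiling, the image branch is weakly
above chance (the cup-to-disc cue survives preprocessing but 60
training eyes and 300 gradient steps give the CNN little room), and the
fused model matches or exceeds the best branch in every seed — the
qualitative fusion claim, at desk scale.

## Numerical notes and limitations

* All layer gradients (convolution via im2col/col2im, batch norm in
  train and eval mode, overlapping max pooling) are verified against
  central differences at 10⁻⁵–10⁻⁴.
* Batch norm keeps running statistics (momentum 0.9) so evaluation is
  deterministic for fixed weights.
* Metrics with zero denominators are reported as undefined (`None`)
  and excluded from block aggregation instead of being coerced to 0.
* The CSV round trip writes floats with `%.17g` and reads with
  pandas' round-trip parser; cohorts survive write→read bit-exactly.
* The harmonic/geometric/arithmetic mean ordering H ≤ G ≤ A (equality
  iff precision = recall) is exact algebra and tested on a grid.
* The NumPy network core is single-threaded-friendly and sized for
  78×116 inputs; it is not a general deep-learning framework (no GPU,
  no autograd graph, no transfer learning).
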