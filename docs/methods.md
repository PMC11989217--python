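# Methods

## Model

The estimator is a classification-then-expectation model. Withering is
discretised into time-point classes `i = 0…n` with strictly decreasing
wet-basis moisture labels `Y_i ∈ (0,1)`; a CNN maps an RGB image to a
softmax confidence vector `N` over those classes; the moisture estimate is
`Y = Σ Y_i N_i`. Two assumptions matter:

1. **Monotone appearance.** Leaf appearance (colour, outline, texture) must
   change monotonically with moisture, so that an intermediate stage is
   classified as a mixture of its temporal neighbours. Under that
   assumption the convexity of the expectation turns a categorical
   classifier into an interpolating regressor — including for whole stages
   absent from training.
2. **Calibration in the ordinal sense.** The estimate only needs confidence
   mass concentrated on classes with labels near the truth; it does not need
   calibrated probabilities in the proper-scoring sense. Mass placed
   entirely on one *adjacent* class bounds the error by the label gap.

Confidence vectors reported at fixed precision are used as-is: values are
rounded to `decimals` places (8 by default) and the weighted sum is taken
without renormalizing, so a printed vector summing to 0.99999997 reproduces
the printed estimate bit for bit. Full precision is available with
`decimals=None`.

The withering verdict compares the estimate with the industry moderate band,
inclusive at both ends: moderate for 0.58 ≤ Y ≤ 0.66, insufficient above,
excessive below.

## Backbone

Nine backbone stages mirror the cross-stage-partial classification layout —
alternating downsampling convolutions and fusion blocks with nominal widths
64, 128, 128, 256, 256, 512, 512, 1024, 1024 and fusion repeats 3, 6, 6, 3 —
followed by a classify head (1×1 expansion, global average pooling, linear
logits, softmax). Two substitutions:

* **RFAConv** replaces each plain downsampling convolution. The attention
  branch average-pools each k×k field (stride s, same padding), passes the
  summary through a grouped 1×1 convolution to k² logits per channel, and
  softmax-normalizes over the k² positions. The feature branch is a
  depthwise k×k expansion (one group per input channel, k² maps each) gated
  by ReLU(BatchNorm(·)). The normalization inside the gate is batch
  normalization — the conventional choice in receptive-field attention
  designs; the weighted features are laid out as non-overlapping k×k tiles
  and reduced by a stride-k convolution, so output spatial dims equal those
  of a same-padded stride-s convolution.
* **C2f_CA** applies coordinate attention to the fused output of the C2f
  block (after the post-concatenation 1×1 fusion). Placing the gate on the
  fused map — rather than inside each bottleneck — keeps the gate count at
  one per block and conditions it on the richest representation. The gate
  uses the standard coordinate-attention form: height- and width-pooled
  descriptors, shared 1×1 reduction (÷32, floor 1 channel) with hard-swish,
  then two sigmoid branches multiplied back onto the input.

`ArchitecturePlan.width_multiplier` scales every channel count (rounded,
floored at 2, forced even so the C2f split is exact). Two profiles are
predefined: **full** (multiplier 1, 224×224-scale inputs) and **mini**
(multiplier 1/16, 64×64 inputs), the latter small enough to train on one
CPU in minutes. Argmax class ties break toward the lowest index.

## Training

Adam with lr 0.01, batch size 16, beta1 0.937 (the "momentum" slot),
beta2 0.999, L2 weight decay 5·10⁻⁴; cross-entropy on softmax logits;
He-normal initialization; one seeded generator drives initialization and
batch shuffling, so runs are bit-reproducible. The full profile defaults to
200 epochs; the mini profile to 30. Single-sample batches are skipped
(batch norm needs ≥ 2). Inputs are uint8 images scaled to [0,1].

The network layers run on the package's own numpy reverse-mode autodiff
(float32). The engine provides exactly the primitives the backbone needs;
grouped convolution is the one heavy primitive (strided-window einsum
forward, k² scatter-add backward), and batch norm, SiLU, hard-swish and
softmax are fused nodes with closed-form gradients. All gradients are
finite-difference tested.

## Synthetic withering series

The generator emulates the *structure* of an hourly withering image series,
not leaf optics. Each image is a ragged-edged superellipse leaf over a dark
neutral background with a central vein, low-frequency blotch texture and
additive Gaussian pixel noise. Dryness `d = (0.80 − m)/0.35` (clipped to
[0,1]) drives, linearly:

* interior colour from fresh green (74, 148, 58) toward dark olive
  (96, 84, 38), scaled by `darkening_gain` (default 1.0);
* leaf axis scale `1 − 0.25·shrink_gain·d` (default gain 1.0);
* blotch amplitude `0.04 + 0.10·d` (texture coarsens as leaves dry).

Per-image randomness: colour jitter (SD 1 intensity unit), edge raggedness
(three angular harmonics, SD 0.02), pixel noise (`noise_sd`, default 8).
The background is darker than any leaf colour so both darkening and
shrinkage move first-order grayscale statistics the same way, making
class-mean colour and area strictly monotone in moisture — the contracts the
tests assert. The gains are free parameters: no published data quantifies
appearance change per hour, so defaults were chosen once to give adjacent
classes visibly overlapping but separable appearance.

The default 13-class label trajectory interleaves the ten reference training
labels (0.7843 … 0.4863) with the three externally measured hold-out stages
(0.7799, 0.7231, 0.597) at indices 1, 5 and 9; each held-out label lies
between its neighbours, so the 10-train / 3-external protocol tests pure
interpolation. What passing tests on this generator shows: the pipeline's
plumbing, the interpolation mechanism, and the monotone-feature reasoning
are correct. What it does not show: performance on real leaves, where
appearance change is not guaranteed monotone, lighting varies, and
between-leaf variation within a time point is far richer.

## Data handling

Datasets are class-per-directory PNG/JPEG trees plus `labels.csv`
(class_index, moisture). The train/validation split takes
`floor((1 − ratio)·N)` validation items from the shuffled pool — the floor
rule is the only one consistent with a 556-image pool splitting 9:1 into
501/55 — unstratified by default, with a stratified option. Augmentation
(crop, rotate, flip, brightness) never alters labels, resizes back to the
working resolution, and clips to [0,255]; right-angle rotations use exact
index permutation, other angles bilinear interpolation; brightness is
multiplicative.

## Colour/texture descriptors

The 15 first-order descriptors use textbook definitions (ITU-R BT.601 luma;
smoothness `1 − 1/(1+σ²)` on [0,1] gray; third moment on normalized gray;
uniformity and entropy over a 256-bin histogram; HSV means; colour angle =
hue of the mean RGB vector; super-green `2G − R − B`; red/green ratio, NaN
on an all-black image). The exact formulations behind the historical
feature names are not published, so the canonical forms were adopted and
unit-tested against hand-computable images.

## Evaluation

RMSEP = √(Σ(y−ŷ)²/n). SD is the N−1 standard deviation of the *reference
labels* (the ten training moistures by default), not of the evaluation
truths. RPD = SD/RMSEP, reported as infinite (not an error) when RMSEP = 0,
with the conventional reading: > 2 good, 1–2 average, < 1 unusable. Rp
defaults to `1 − Σ(ŷ−y)²/Σ(ŷ−ȳ)²` with ȳ the reference-label mean — the
printed-form convention — and offers the textbook denominator Σ(y−ȳ)² via
`denominator="true"`; which of the two the original formulation intended is
not decidable from its typography, so both ship and the choice is explicit.

## Numerical notes and limitations

* Problem sizes: the end-to-end acceptance run trains on 400 images
  (10 classes × 40) at 64×64 for 30 epochs — the mini profile's intended
  scale — and evaluates 120 held-out images.
* The confidence-weighted estimate cannot extrapolate outside
  [min Y_i, max Y_i]; stages wetter or drier than the trained range are
  clamped to the nearest label by construction.
* Eight-decimal reporting introduces up to ~5·10⁻⁹ rounding error per
  confidence; published worked examples can therefore differ from exact
  arithmetic on their own printed inputs by one unit in the eighth decimal.
* Batch norm makes training-mode forward passes batch-dependent; inference
  always uses running statistics (estimators call `eval()` after fit).
* The autodiff engine is single-device float32 without in-place ops or
  higher-order gradients; it is a training engine for small models, not a
  general framework.
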