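# Methods

`thermonet` re-implements, as desk-scale, fully tested components, a
breast-thermography classification framework built on the inception
family of convolutional networks: explicit graph builders for inception
V3, V4 and the modified variant MV4; the twelve-metric diagnostic
evaluation suite; the thermal-image preprocessing and augmentation
pipeline; a synthetic thermogram generator; and a training/evaluation
harness that reproduces the mechanics of optimizer x learning-rate x
epoch experiment grids on CPU.

## Architecture graphs

Networks are explicit DAGs of typed layer nodes (`conv`, `batchnorm`,
`activation`, pooling, `concat`, `dropout`, `global_avg_pool`, `dense`,
`softmax`, `classification`). Spatial geometry follows the convolution
output-size rule

    out = floor((W - F + 2P) / S) + 1

per axis (W input size, F filter size, P symmetric padding, S stride);
`"same"` padding is supported at stride 1. A non-integer quotient is
permitted with floor semantics and a warning, matching common framework
practice; the rule itself gives no rounding prescription. Every
convolution is followed by batch normalization and ReLU.

**Inception V4** is built to the canonical published configuration: stem
to 35x35x384, four inception-A blocks (384 ch), reduction-A
(k,l,m,n = 192,224,256,384 -> 1024 ch), seven inception-B blocks
(branch widths 128+384+256+256 = 1024 ch), reduction-B (-> 1536 ch),
three inception-C blocks (1536 ch), then the classifier head
(global average pooling, dropout 0.8, dense 1536->2, softmax).

**Inception V3** keeps that family's canonical per-block filter geometry
(factorized 5x5/7x7 convolutions) with the composition used in the
thermography experiments: three inception-A, reduction-A, four
inception-B, reduction-B, two inception-C, ending at 2048 features into
a dropout-free head (global average pooling, dense 2048->2, softmax).
Published block descriptions for V3 are partly contradictory (a claim
that all filters are 3x3 conflicts with the factorized geometry the
model family is defined by); the builder follows block counts from the
experimental description and canonical filter geometry, and this choice
is recorded here as an interpretation.

**Inception MV4** replaces each of the seven inception-B blocks with a
shallower multi-branch block that preserves the 1024 concatenated output
features, so reduction-B and all downstream stages are reused unchanged.
The default block (`MV4BlockConfig`) has three branches, all stride 1:

* average pool -> 1x1 conv (128) -> 3x3 conv (256). Keeping the 1x1
  projection before the added 3x3 is deliberate: a 3x3 convolution
  applied directly to the 1024-channel block input would cost
  9*1024*256 = 2.36 M parameters in this branch alone and make the
  modified block *heavier* than the canonical one, inverting the whole
  point of the redesign. With the projection the branch costs 0.43 M and
  its output width still rises from 128 to 256 features.
* direct 1x1 conv (384);
* 1x1 conv (192) feeding two parallel 3x3 convs (192 each).

Concatenated output: 256 + 384 + 192 + 192 = 1024. A literal variant
with two parallel 256-filter convs (total 1152) is available via
`MV4BlockConfig.literal_text()`; it is geometrically valid but breaks
the feature-preservation rule, so strict configs reject it. Under the
default configuration MV4 has strictly fewer nodes, edges, parameters
and multiply-accumulates than V4 at the same input and head, and the
node/edge difference is exactly 7x the per-block reduction.

Layer counting convention: every node of every kind is one layer; edges
are connections. Counts published by other toolboxes use undocumented
conventions and are stored as descriptive metadata only, never asserted.

Parameter counting: conv Fh*Fw*Cin*Cout (+Cout bias when requested;
the executor itself allocates no conv bias since batchnorm follows every
conv), dense Cin*Cout+Cout, batchnorm 2C trainable + 2C running
statistics. FLOPs (multiply-accumulates): conv Hout*Wout*Fh*Fw*Cin*Cout,
dense Cin*Cout.

Transfer-learning freezes mark nodes non-trainable: either the first
n conv layers in topological order or a named region (the stem).
"Stem weights fixed during fine-tuning" is implemented as freezing, not
zero-initialization — zeroing would destroy pretrained features, and a
frozen random stem is the honest from-scratch analogue.

## Diagnostic metrics

From confusion counts (TP, TN, FP, FN): accuracy (percent), sensitivity
TP/(TP+FN), specificity TN/(FP+TN), precision TP/(TP+FP), NPV
TN/(TN+FN), FPR = 1-specificity, FNR = 1-sensitivity, LRP =
Sen/(1-Spe), LRN = (1-Sen)/Spe, AUC = (Sen+Spe)/2 (balanced accuracy,
*not* the ROC area), EER = 1-AUC, and F1 = 2*Sen*P/(Sen+P). Any zero
denominator produces an explicit undefined value rendered `NA` — never 0
or infinity. Computation is full double precision; rounding happens only
at formatting (accuracy 2 decimals, others 3). One published equation
carries the LRP label on the LRN formula; the implementation follows the
symbol table (an evident typo).

## Thermal I/O and augmentation

Inputs are 8/16-bit PNG/TIFF/JPEG frames or whitespace-delimited
plain-text temperature matrices (min-max scaled onto the 16-bit range on
load). Grayscale conversion uses the standard luminance weights
0.299/0.587/0.114 (the source pipeline never specifies its conversion).
Resizing to the 299x299 (or 75x75 tiny) network geometry is bilinear and
range-preserving; single-channel frames are replicated to three channels
for ingestion.

Augmentation draws — mirror across the vertical axis with probability
0.5, integer translation up to +-30 px per axis with edge-replication
fill, per-axis upscaling up to 10% with center crop — all come from one
seeded generator, so a (seed, policy) pair reproduces the augmented
stream bit-for-bit. "Flip along the vertical axis" is read as mirroring
left<->right, the anatomically meaningful operation for bilaterally
symmetric anatomy; a flag selects the up-down reading.

Stratified splitting assigns floor(fraction * n) records per class to
training after a seeded per-class shuffle; the 1019 + 862 cohort at 70%
training leaves 306 + 259 held-out records.

## Synthetic thermograms

The generator emulates the statistical structure the classifier relies
on, not tissue biophysics (no Pennes bioheat modelling, single frontal
view). A frame is a 480x640 16-bit field: ambient background (18-25 °C),
an elliptical torso at 33 °C baseline plus a smooth low-frequency
physiological field that is exactly mirror-symmetric about the midline
(a coarse Gaussian grid upsampled over one half and mirrored), plus
i.i.d. sensor noise. Sick frames add one (configurably more) Gaussian
hot spot centered inside a breast disc with peak elevation delta_t,
truncated at three standard deviations; placement keeps the truncation
disc away from its mirrored position, so with zero noise the maximum
mirror-difference statistic equals delta_t exactly and is zero for every
healthy frame — the label-faithfulness invariant the tests assert.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| frame | 480x640, 16-bit | thermal-camera-native geometry |
| baseline | 33 °C | skin surface temperature |
| ambient | 20 °C (valid 18-25) | controlled acquisition-room protocol |
| smooth field amplitude | 0.5 °C | normal smooth skin-temperature variation is well under 1 °C |
| sensor noise sd | 0.2 °C | a few times the 0.04 °C camera sensitivity, covering physiological jitter |
| lesion delta_t | 1-3 °C | reported tumour-associated local hyperthermia |
| lesion radius | 0.10-0.16 of frame height | hyperthermia covers a broad vascularized region, not just the tumour; also keeps the lesion resolvable after the tiny network's 10.7x stem downsampling |
| rendering window | 22-38 °C | physiological contrast; the camera's full -40..500 °C span would waste nearly all code values |

Rendering quantizes to 16 bits over the window (implied temperature
error at most window/65535) either directly (grayscale) or through a
fixed, analytically defined rainbow palette (color), so "color" runs are
reproducible. Per-record seeds derive from the master seed, making any
single frame reproducible in isolation.

What the simulator does **not** model — and hence what passing tests do
not show about real data: real anatomy and pose variation, vascular
patterns, multi-view (90° lateral) geometry, dynamic cold-stress
protocols, camera fixed-pattern noise, and the label noise of clinical
screening. The end-to-end property below is a smoke test of the whole
pipeline's mechanics, not evidence of clinical performance.

## Training harness

No GPU framework is assumed: training runs on a NumPy executor that
walks the layer DAG (im2col convolutions, exact batchnorm forward/
backward, pooling with argmax routing, concat splitting, inverted
dropout, softmax/cross-entropy), with SGDM (momentum 0.9, the toolbox
default the source setup relies on), Adam and RMSProp at standard
defaults. Analytic gradients are verified against numeric
differentiation in the test suite. Runs are bit-deterministic given the
seed: one generator drives label shuffling (negative control only), the
stratified split, weight initialization, batch order, dropout and
augmentation.

Full-size 299x299 networks build and execute but are not a practical
CPU training path. The desk-scale **tiny variants** keep the stage
sequence and the exact block internals but reduce the block repeats to
1 inception-A / 2 inception-B / 1 inception-C at width scale 0.375 and a
75x75 input. Depth had to be reduced along with width: piloting showed a
~55-convolution width-scaled network trained from random initialization
simply does not leave chance level within the 84 minibatch-10 steps that
three epochs on 280 training frames provide, regardless of learning
rate — the published 100%-by-epoch-3 results rest on ImageNet-pretrained
weights, which have no desk-scale equivalent.

The tiny from-scratch protocol (defaults of `easy_smoke_config`):

* SGDM at lr 0.0125 — the from-scratch analogue of the 1e-4 fine-tuning
  rate used with pretrained weights;
* linear warmup over the first 20 steps (a freshly initialized deep
  network produces very large early gradients through batchnorm layers
  whose batch-of-10 variance estimates are tiny);
* left-right mirror augmentation (the cheap, anatomically meaningful
  slice of the full flip/translate/scale policy);
* Polyak-Ruppert tail averaging: the weights evaluated after the final
  epoch are the running average of that epoch's iterates, removing most
  minibatch jitter from a short run;
* a precise-BN recalibration pass (momentum-0 full-training-set forward)
  before each evaluation, because 84 small-batch updates leave the
  running statistics lagging the final weights.

Dropout 0.8 is kept in the full-size V4/MV4 head but omitted from the
tiny head: with a ~576-entry pooled feature vector and 84 training
steps, dropping 80% of features is starvation, not regularization.

The "easy setting" for the end-to-end property fixes every lesion at
delta_t = 3 °C over 0.05 °C sensor noise, 200 + 200 frames, 70/30 split,
minibatch 10, 3 epochs. Under this protocol tiny-MV4 reaches >= 95%
held-out accuracy in at least 9 of 10 seeded repeats, while the
label-shuffled negative control stays inside the 99.9% binomial band
around the 50% class prior. Tiny-MV4 also executes strictly fewer
multiply-accumulates per frame than tiny-V4 — the desk-scale analogue of
the "faster with minimal accuracy loss" claim.

"Marginal error" of a repeat summary is the half-width of a t-based 95%
confidence interval for the mean accuracy; identical runs give zero
margin. Grid runs derive per-cell seeds from the base seed, write
long-format and pivoted (epochs x optimizer x learning-rate) CSVs, and
resume cell-by-cell from cached JSON results.

## Numerical and degenerate-input choices

* Batchnorm variance floor 1e-5; inference uses running statistics.
* Weight init: He-normal scaled by fan-in; dense biases zero.
* Non-finite training loss flags the run failed instead of raising.
* Constant text matrices scale to all-zero 16-bit frames.
* A lesion that cannot be placed within bounded attempts raises rather
  than silently producing an unlabeled-consistent frame.
* Ties in maxpool route gradient to the first maximum.

## Problem sizes used

Tests and the acceptance checks run the generator at reduced frames
(120x160) where frame content is irrelevant to the property under test,
and at 480x640 with 200 + 200 frames for the end-to-end training
property; the experiment grids in the tests use 24 + 24-frame micro
datasets. These sizes are the package's chosen desk-scale study
conditions; the full 1019 + 862 cohort remains the generator's CLI
default.

## Known limitations

* Absolute layer/connection/parameter counts of other toolboxes are not
  reproduced (undocumented conventions); they are carried as metadata.
* The executor is CPU-bound NumPy: full-size training is supported in
  principle but impractically slow, and no multi-GPU path exists.
* The simulator's simplicity means synthetic accuracy says nothing
  quantitative about clinical data (see above).
* ROC-curve analysis is out of scope; "AUC" throughout is balanced
  accuracy by definition.
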