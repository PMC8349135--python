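# thermonet

Early breast-cancer screening by infrared thermography rests on a simple
physiological fact: tumour-associated vascularization locally elevates
skin temperature, so a sick breast shows a warm, *asymmetric* spot where
a healthy torso is bilaterally symmetric and smooth. Deep convolutional
classifiers of the inception family — inception V3, inception V4, and a
modified V4 ("MV4") that removes layers from every inception-B block
while preserving its 1,024 output features — have been applied to
classify such thermograms as healthy or sick.

`thermonet` provides that framework as a tested, desk-scale package for
researchers who want to study the architectures and the evaluation
methodology without a GPU or access to a clinical thermal-image
database:

* **`thermonet.graph` / `thermonet.builders`** — inception V3, V4 and
  MV4 as explicit layer DAGs with shape inference by the output-size
  rule `floor((W − F + 2P)/S) + 1`, analytic parameter counts, FLOP
  estimates, transfer-learning freezes and canonical JSON serialization.
  The MV4 block replaces the canonical inception-B (branch widths
  128 + 384 + 256 + 256) with a shallower three-branch block
  (256 + 384 + 192 + 192 = 1,024), keeping every downstream stage
  geometry-compatible.
* **`thermonet.metrics`** — the twelve-metric diagnostic suite from
  confusion counts: accuracy, sensitivity Sen = TP/(TP+FN), specificity
  Spe = TN/(FP+TN), precision, NPV, FPR, FNR, likelihood ratios
  LRP = Sen/(1−Spe) and LRN = (1−Sen)/Spe, balanced-accuracy
  AUC = (Sen+Spe)/2, EER = 1−AUC, and F1 — with explicit `NA` semantics
  for zero denominators.
* **`thermonet.thermal_io`** — 8/16-bit image and plain-text
  temperature-matrix input, grayscale conversion, resizing to network
  geometry, seeded flip/translate/scale augmentation, stratified
  splitting.
* **`thermonet.synthgen`** — a synthetic thermogram generator (symmetric
  smooth healthy fields vs localized hot-spot pathology on a 480×640
  16-bit frame) so every downstream stage is testable with no download.
* **`thermonet.experiment` / `thermonet.nn`** — a NumPy training
  executor (SGDM/Adam/RMSProp, cross-entropy) and a harness for
  optimizer × learning-rate × epoch grids, repeat statistics and
  negative controls, using width/depth-scaled "tiny" variants that train
  on one CPU in under a minute.

## Worked example

Evaluate a classifier run that produced 257 true positives, 303 true
negatives, 1 false positive and 1 false negative on a 562-image held-out
set:

```sh
$ thermonet metrics eval --tp 257 --tn 303 --fp 1 --fn 1
accuracy 99.64
sensitivity 0.996
specificity 0.997
precision 0.996
npv 0.997
fpr 0.003
fnr 0.004
lrp 302.822
lrn 0.004
auc 0.996
eer 0.004
f1 0.996
```

Reading: the model misses 0.4% of sick patients (sensitivity 0.996) and
raises false alarms on 0.3% of healthy ones; a positive call multiplies
the odds of disease roughly 300-fold (LRP); balanced accuracy (the AUC
column in this suite) is 0.996. A perfect run (FP = FN = 0) renders LRP
as `NA` — the ratio is undefined at specificity 1 — rather than
infinity.

Compare the V4 and MV4 architectures at the standard 299×299×3 input:

```sh
$ thermonet build --model v4  --out v4.json
$ thermonet build --model mv4 --out mv4.json
$ thermonet diff v4.json mv4.json
{
 "a": "inception_v4",
 "b": "inception_mv4",
 "layer_count": [490, 406, -84],
 "connection_count": [544, 460, -84],
 "parameter_count": [41240642, 32441698, -8798944],
 "flops_estimate": [12252441696, 9718933600, -2533508096]
}
```

Replacing the seven inception-B blocks removes 84 nodes and 84 edges
(12 per block), 8.8 M parameters and 2.5 G multiply-accumulates — about
21% of the compute — while every modified block still emits exactly
1,024 feature channels, which is the design's feature-preservation rule.

Generate a synthetic cohort and train the tiny MV4 variant end-to-end:

```python
from thermonet import experiment, synthgen

config = experiment.easy_simulation_config()      # 3 °C lesions, low noise
records = [r for r, _ in synthgen.generate_records(
    200, 200, config, "grayscale", master_seed=123)]
result = experiment.train_and_evaluate(
    experiment.easy_smoke_config(seed=0), records)
print(result.val_accuracy)    # (77.5, 90.0, 99.16666666666667) — % per epoch
print(result.counts)          # ConfusionCounts(tp=59, tn=60, fp=0, fn=1)
```

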