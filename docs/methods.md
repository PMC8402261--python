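# Methods

`blanketpose` studies a practical obstacle in camera-based sleep
monitoring: a blanket hides most of the postural detail an overhead
depth camera relies on. The package implements the full experimental
loop — synthetic depth-scene generation, blanket-fusion augmentation, a
jointly trained dual-head classifier, and stratified evaluation — so
that every claim it makes is recomputable from a seed.

## The scene model

A rig places an orthographic depth camera 1.6 m above a 196 × 90 cm bed;
each pixel stores the camera-to-surface distance in millimetres, row 0
at the head end. The default frame is 128 × 96 pixels (the full-sensor
848 × 480 geometry is configurable but unnecessary for the questions the
package answers, and the small frame trains on one CPU core).

**Bodies.** A participant is a vector of morphometric parameters —
stature, shoulder width, trunk (chest) thickness, limb radius, habitual
knee flexion, head yaw, plus a random bed offset and rotation — drawn
from truncated normal population distributions (stature 167 ± 18 cm,
bounds 145–190 cm; the remaining defaults are ordinary adult
anthropometry). A posed body is the pointwise maximum of capsule height
fields (head, chest, pelvis, arms, thighs, shanks, feet) arranged by one
of seven templates:

- *supine*: wide footprint, height = trunk thickness, arms at the
  sides, toes up;
- *prone (head left / right)*: like supine but the head capsule is
  yawed to one side and rendered lower (face down), arms raised beside
  the head, feet flat;
- *log (left / right)*: side-lying, narrow footprint, stack height
  ½(shoulder width + trunk thickness) — always taller than the same
  body supine — legs nearly extended (knee flexion = ¼ of the
  participant's habitual flexion);
- *fetal (left / right)*: side-lying with hips and knees strongly
  flexed (full habitual flexion, drawn from 110 ± 15°), pulling the
  feet toward the pelvis and shortening the footprint.

Right-side templates are the left templates with every lateral
coordinate negated; because the pixel grid is forced to be exactly
antisymmetric about the bed midline, a left/right pair renders to
bit-exact mirror images before the random offset is applied. Offsets
are clamped so the body footprint never leaves the bed rectangle.

**Blankets.** A blanket is (thickness, drape-smoothing scale): thick
80 mm / 60 mm, medium 20 mm / 30 mm, thin 4 mm / 12 mm, none 0 / 0. The
draped surface is a Gaussian-smoothed copy of the body height field
raised by the thickness and clamped to stay at or above the body, with
the head end of the bed left uncovered (feathered edge at ~0.45–0.55 m
from the head end). This reproduces the qualitative behaviour that
matters for the classification problem: a loftier blanket low-passes
body detail over a longer length scale, monotonically reducing the
surface's total variation, while never letting the covered surface read
*farther* from the camera than the bare body.

**Sensor noise** is zero-mean Gaussian with SD 5 mm, truncated at ±3 SD,
added per pixel at render time. Real time-of-flight cameras also show
range-dependent bias, edge artefacts and dropouts; none of these are
modelled, so results on the synthetic cohort certify the pipeline's
correctness and the relative value of its components, not field
accuracy on human data.

**Cohorts.** `generate_dataset(n, seed)` renders every participant in
every posture under every condition, posing each body once per posture
and reusing that pose across all four blankets — the physical premise
that makes intraclass fusion meaningful. 51 participants yield
51 × 7 × 4 = 1428 samples. All randomness flows from the seed;
identical seeds give bit-identical cohorts.

## Augmentation

**Affine.** One random transform per frame per epoch: scale ±5%,
translation ±2% of each frame dimension, rotation ±5.0°, shear ±2.5°,
bilinear interpolation, out-of-frame pixels filled with the bed-plane
depth. The ranges are small enough that a centred body always stays
inside the frame.

**Blanket fusion.** For each (participant, posture) and each of the
C(4,2) = 6 unordered pairs of blanket conditions, a fused frame
`u·img1 + (1−u)·img2` with `u ~ U(0,1)` drawn fresh every epoch —
a hypothetical intermediate blanket with the parents' (identical)
posture label. Fusion acts on raw depth in millimetres, *before*
per-frame normalization, because depth is the scale on which the scene
is approximately a linear combination of body and blanket surfaces.
Affine augmentation is applied after fusion so the parents stay
perfectly aligned.

## Model and training

The classifier is a small strided CNN — three convolutions
(16/32/64 channels, strides 4/2/2, ReLU), global average pooling, a
128-unit dense layer, dropout with drop probability 0.8 — feeding two
parallel softmax heads: 4-class coarse and 7-class fine. Inputs are
standardized per frame (zero mean, unit variance) after any fusion. The
forward/backward pass and the optimizer are implemented in numpy inside
the package (`blanketpose._nn`), keeping the training loop
single-threaded and reproducible; the network is ~45k parameters, sized
for CPU training at desk scale.

The loss is the plain sum of the two categorical cross-entropies, with
predicted probabilities floored at 1e-12 inside the log. Optimization
is Adam at a fixed learning rate 1e-4 with decoupled L2 weight decay
5e-4 on weight tensors (not biases), batch size 16.

Training is two-phase: phase 1 on the synthesized fusion stream
(regenerated every epoch), phase 2 on the original frames, both with
affine augmentation. The desk-scale default is 40 + 10 epochs with
20 training and 8 test participants; epoch counts scale linearly from
the full-scale 400 + 100 schedule and suffice for convergence at this
data size (~1 minute per run on one CPU core).

Prediction takes each head's argmax (ties broken toward the lowest
class code). The two heads can disagree — the coarse head's argmax need
not equal the coarse class implied by the fine head — and the pipeline
reports this disagreement rate rather than reconciling the heads.

## Evaluation

Per-class metrics are one-vs-rest on the confusion matrix: recall
TP/(TP+FN), precision TP/(TP+FP), accuracy (TP+TN)/total, F1
2TP/(2TP+FP+FN); 0/0 ratios return 0, and a class absent from both
truth and predictions is flagged undefined and excluded from macro
averages with a warning. "Overall" values are unweighted (macro) means
across classes; because the term *accuracy* is ambiguous in summary
tables, both macro accuracy (mean of per-class one-vs-rest accuracies)
and micro accuracy (trace/total) are reported. Cohen's kappa is
(p_o − p_e)/(1 − p_e) with p_e from the row/column marginals; it is
undefined (error) when all mass sits in one cell.

The stratified report computes every (posture, blanket) F1 cell from
that stratum's own restricted confusion matrix — never by averaging
other cells, which does not commute with rounding — plus per-blanket
overall columns, a control-minus-thick overall-F1 delta per
granularity, and the coarse-minus-fine overall-F1 delta. Zero-support
cells are marked absent, not zero. Display rounding is one decimal for
percentages and three for kappa; all arithmetic is done at full
precision.

## The fusion ablation

To test whether fusion actually buys robustness to unseen blankets,
`run_ablation` trains with only the thick and no-blanket conditions and
evaluates on all four (medium and thin never seen in training), twice
per seed: a fusion arm (synthesized phase 1 + original phase 2) and a
control arm (original frames only). The arms are matched on *total
sample passes*, not epochs: with two training conditions a fused epoch
holds half as many samples as an original epoch, so equal epoch counts
would hand the control arm twice the gradient steps. The default
ablation cohort is 14 + 8 participants at 64 × 48 with 150 + 40 epochs
(control: 115 original-only epochs), sized so both arms reach
convergence — at much shorter schedules the comparison measures
optimization noise, not the augmentation. The result is reported as
per-seed F1 for both arms with the sign pattern of the differences,
over at least three seeds.

The measured benefit is real but marginal at desk scale: fusion wins a
majority of seeds in some triples and loses in others. This is a
property of the simulator, not a bug — the synthetic medium and thin
conditions sit close to the no-blanket control, so a control model
trained on {thick, none} already generalizes to them reasonably well,
leaving little headroom for the fused frames to add. On real blankets,
whose drape differs more from the no-blanket scene, the same experiment
has more room to separate the arms.

## Numerical and design notes

- **Seed fan-out.** One global seed; each stage's generator is seeded
  with the first 4 bytes of SHA-256 of `"{seed}:{stage}"` (mod 2³¹), so
  stages never share a stream and any stage can be reproduced alone.
- **Determinism.** Byte-identical report JSON across reruns of the same
  config in the same environment (single-threaded numpy arithmetic).
- **Degenerate inputs.** Zero-SD population fields are legal and
  collapse to the mean; zero-epoch phases are legal (phase 1 = 0 is the
  no-fusion mode); empty confusion matrices and single-cell kappa raise
  explicit "no support"/"undefined" errors rather than returning
  numbers.
- **Dropout 0.8** is the drop probability (keep 0.2), implemented as
  inverted dropout; it is aggressive for a 128-unit layer and is the
  main regularizer besides weight decay and augmentation.
- **Limitations.** Rigid mattress (no deformation under load); no cloth
  dynamics, wrinkles or overhang at the bed edges; orthographic rather
  than perspective projection; no temporal information. The simulator
  is a fixture generator with controlled difficulty, not a human-subject
  dataset; absolute scores on it do not transfer to real cohorts,
  though orderings (coarse vs fine, control vs thick) reproduce the
  expected structure.
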