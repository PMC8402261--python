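# blanketpose

Classifying how a person is lying in bed from an overhead depth camera
is easy — until they pull up a blanket. `blanketpose` is a tested,
fully reproducible pipeline for *blanket-accommodative* sleep-posture
classification: it simulates labeled overhead depth scenes of people in
bed under four blanket conditions (8 cm thick, 2 cm medium, 0.4 cm
thin, none), augments training data with intraclass *blanket fusion*,
trains a dual-head convolutional classifier, and evaluates it with
stratified posture × blanket metrics on held-out participants. It is
aimed at researchers prototyping non-contact sleep-monitoring methods
who need a controlled, seedable stand-in for human depth data.

## The method

**Postures.** Seven fine-grained classes — supine, prone (head left /
right), log (left / right), fetal (left / right) — merge into four
coarse classes (supine, prone, left / right side-lying): log and fetal
pool into side-lying, the prone head variants pool into prone.

**Blanket fusion (intraclass mix-up).** Because a participant holds the
same pose across blanket conditions, two depth frames of the same
(participant, posture) under different blankets can be convexly
combined,

    Fusion(img1, img2) = u·img1 + (1−u)·img2,   u ~ U(0, 1),

yielding a plausible frame of a *hypothetical* blanket with an unchanged
label. Four conditions give C(4,2) = 6 such pairs; a fresh `u` is drawn
for every pair in every training epoch.

**Dual-head network.** A shared CNN backbone → dropout (p = 0.8) → two
parallel fully connected softmax heads (4-class and 7-class), trained
jointly with the summed cross-entropy

    L = CE_coarse(y, ŷ) + CE_fine(y, ŷ),   CE(y, ŷ) = −Σᵢ yᵢ log ŷᵢ,

by Adam (lr 1e-4, decoupled L2 5e-4) in two phases: first on the
synthesized fusion stream, then on the original frames.

**Evaluation.** Confusion matrices; one-vs-rest recall, precision,
accuracy and F1 per class; macro overall values; Cohen's kappa
κ = (p_o − p_e)/(1 − p_e); and a stratified posture × blanket F1 table
with control-minus-thick and coarse-minus-fine deltas. Splits are by
participant, so no person appears in both train and test.

See `docs/methods.md` for the scene simulator, the drape model, and all
numerical conventions.

## Worked example

```python
from blanketpose import PipelineConfig
from blanketpose.config import SimulateConfig
from blanketpose.model import ModelConfig, TrainConfig
from blanketpose.pipeline import run_pipeline

config = PipelineConfig(
    seed=1,
    simulate=SimulateConfig(n_train=8, n_test=4, frame_rows=64, frame_cols=48),
    model=ModelConfig(input_shape=(64, 48)),
    train=TrainConfig(epochs_phase1=40, epochs_phase2=10),
)
result = run_pipeline(config)
print(result.fine_report.render_table())
```

which prints (about 30 s on one CPU core):

```
Posture/Blanket           thick   medium     thin     none  Overall
supine                   100.0%    66.7%    40.0%    66.7%    72.0%
prone_head_left           66.7%    57.1%    53.3%    57.1%    58.2%
prone_head_right           0.0%     0.0%     0.0%     0.0%     0.0%
log_left                  85.7%   100.0%   100.0%   100.0%    96.8%
log_right                 85.7%   100.0%   100.0%    85.7%    93.3%
fetal_left                72.7%   100.0%   100.0%   100.0%    91.4%
fetal_right               85.7%   100.0%   100.0%    88.9%    93.8%
Overall                   70.9%    74.8%    70.5%    71.2%    72.2%
Cohen's kappa: 0.719
```

Each cell is the F1 score (%) for one posture under one blanket
condition on the 4 held-out participants, computed from that stratum's
own confusion matrix; the Overall column pools all blankets. The table
shows the structure the method is built around: side-lying postures
survive occlusion well, while at this deliberately tiny training scale
(8 participants) one prone head orientation collapses entirely — the
head-orientation cue is the subtlest feature in the scene. The
desk-scale defaults (`PipelineConfig()`: 20 + 8 participants, 128 × 96
frames, 40 + 10 epochs, ~1 min) reach overall fine F1 around 70–77%
with coarse ≥ fine on average.

The same pipeline is available from the shell:

```sh
blanketpose simulate --participants 5 --seed 0 --out runs/sim
blanketpose train --seed 0 --out runs/exp0
blanketpose ablate --seeds 0,1,2 --out runs/ablation.json
```

`simulate` writes 16-bit grayscale PNGs (depth in mm) plus a manifest
CSV; `train` writes the manifest, checkpoint, stratified reports and a
locked config snapshot under one run directory.

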