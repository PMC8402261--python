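"""End-to-end orchestration: simulate -> split -> two-phase training ->
stratified evaluation, plus the blanket-fusion ablation experiment.

A run is fully determined by its :class:`~blanketpose.config.PipelineConfig`;
every stage draws its seed from the global seed via
:func:`~blanketpose.config.derive_seed`.  Artifacts are written under one
run directory: ``manifest.csv``, ``frames/`` (16-bit PNGs, depth in mm),
``checkpoints/``, ``report.json``, ``config.lock.yaml``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import augmentation, scene_sim
from .config import PipelineConfig, derive_seed
from .dataset import (
    CoarsePosture,
    FinePosture,
    Manifest,
    assign_split,
    coarse_codes_from_fine,
    split_participants,
    write_manifest,
)
from .errors import BlanketPoseError, ConfigurationError
from .evaluation import EvalReport, stratified_report
from .model import PostureClassifier, TrainConfig, build_model, predict_batch, train_two_phase

log = logging.getLogger("blanketpose")

__all__ = ["PipelineResult", "AblationResult", "run_pipeline", "run_ablation"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    manifest: Manifest
    model: PostureClassifier
    history: dict[str, list[float]]
    fine_report: EvalReport
    coarse_report: EvalReport
    #: fraction of test samples where the coarse head disagrees with the
    #: coarse class implied by the fine head's prediction
    head_disagreement_rate: float

    def report_dict(self) -> dict:
        return {
            "seed": self.config.seed,
            "n_test_samples": self.fine_report.overall.support,
            "fine": self.fine_report.to_dict(),
            "coarse": self.coarse_report.to_dict(),
            "granularity_delta_f1": self.coarse_report.overall.f1
            - self.fine_report.overall.f1,
            "head_disagreement_rate": self.head_disagreement_rate,
            "loss_history": self.history,
        }

    def report_json(self) -> str:
        return json.dumps(_round_floats(self.report_dict()), indent=2, sort_keys=True)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Stage helpers


def simulate_cohort(config: PipelineConfig) -> scene_sim.SimulatedDataset:
    """Generate the cohort and assign the participant-level split."""
    sim = config.simulate
    rig = scene_sim.CameraRig(frame_rows=sim.frame_rows, frame_cols=sim.frame_cols)
    data = scene_sim.generate_dataset(
        n_participants=sim.n_train + sim.n_test,
        seed=derive_seed(config.seed, "simulate"),
        rig=rig,
        noise_sd=sim.noise_sd,
    )
    assignment = split_participants(
        data.manifest.participants(), sim.n_train, sim.n_test,
        seed=derive_seed(config.seed, "split"),
    )
    data.manifest = assign_split(data.manifest, assignment)
    return data


def _stack(samples, frames) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([frames[s.sample_id] for s in samples]).astype(np.float32)
    y = np.array([int(s.fine_label) for s in samples], dtype=int)
    return x, y


def build_epoch_fns(data: scene_sim.SimulatedDataset, config: PipelineConfig):
    """(synthesized, original) epoch functions for the two-phase trainer.

    The synthesized function regenerates all fused samples with fresh
    mixing weights each call; both functions apply one random affine
    transform per frame (after fusion, so parent alignment stays exact).
    """
    train_manifest = data.manifest.subset(
        split="train", blankets=set(config.simulate.train_blankets)
    )
    if len(train_manifest) == 0:
        raise ConfigurationError("empty training dataset")
    affine_cfg = config.augment.affine
    bed_depth = data.rig.height_above_bed
    x_orig, y_orig = _stack(train_manifest.samples, data.frames)

    def augment_all(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty_like(x)
        for i in range(len(x)):
            out[i] = augmentation.affine_augment(x[i], affine_cfg, rng, bed_depth)
        return out

    def synthesized(epoch: int, rng: np.random.Generator):
        fused = list(augmentation.synthesized_epoch(train_manifest, data.frames, rng))
        x = np.stack([f.frame for f in fused]).astype(np.float32)
        y = np.array([int(f.fine_label) for f in fused], dtype=int)
        return augment_all(x, rng), y

    def original(epoch: int, rng: np.random.Generator):
        return augment_all(x_orig, rng), y_orig

    return synthesized, original


def evaluate_on_test(
    model: PostureClassifier, data: scene_sim.SimulatedDataset
) -> tuple[EvalReport, EvalReport, float]:
    """Stratified fine and coarse reports on the held-out participants."""
    test = data.manifest.subset(split="test")
    if len(test) == 0:
        raise ConfigurationError("no test samples to evaluate")
    x, y_fine = _stack(test.samples, data.frames)
    blankets = [s.blanket for s in test.samples]
    pred_c, pred_f, _, _ = predict_batch(model, x)
    y_coarse = coarse_codes_from_fine(y_fine)
    fine_report = stratified_report(
        y_fine, pred_f, blankets, tuple(p.name for p in FinePosture)
    )
    coarse_report = stratified_report(
        y_coarse, pred_c, blankets, tuple(p.name for p in CoarsePosture)
    )
    disagreement = float(np.mean(pred_c != coarse_codes_from_fine(pred_f)))
    return fine_report, coarse_report, disagreement


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    force: bool = False,
    write_frames: bool = False,
    checkpoint: str | Path | None = None,
) -> PipelineResult:
    """Run the full experiment.

    With ``checkpoint`` given, training is skipped and the stored model
    is evaluated on the freshly simulated test set (eval-only mode).
    Rerunning with the same config and seed reproduces the report
    byte-for-byte.
    """
    run_id = f"run-seed{config.seed}"
    out = _prepare_run_dir(out_dir, force) if out_dir is not None else None

    log.info("[%s] [simulate] generating %d+%d participants", run_id,
             config.simulate.n_train, config.simulate.n_test)
    data = simulate_cohort(config)

    if checkpoint is not None:
        log.info("[%s] [train] eval-only mode, loading %s", run_id, checkpoint)
        model = PostureClassifier.load(checkpoint)
        history: dict[str, list[float]] = {"phase1": [], "phase2": []}
    else:
        model = build_model(config.model, seed=derive_seed(config.seed, "model"))
        synth, orig = build_epoch_fns(data, config)
        if not config.augment.fusion:
            synth = None
            train_cfg = _no_fusion_schedule(config.train)
        else:
            train_cfg = config.train
        log.info("[%s] [train] two-phase schedule %d+%d epochs", run_id,
                 train_cfg.epochs_phase1, train_cfg.epochs_phase2)
        history = train_two_phase(
            model, synth, orig, train_cfg,
            rng=np.random.default_rng(derive_seed(config.seed, "train")),
        )

    log.info("[%s] [evaluate] scoring held-out participants", run_id)
    fine_report, coarse_report, disagreement = evaluate_on_test(model, data)
    result = PipelineResult(
        config=config, manifest=data.manifest, model=model, history=history,
        fine_report=fine_report, coarse_report=coarse_report,
        head_disagreement_rate=disagreement,
    )
    if out is not None:
        _write_artifacts(result, data, out, write_frames)
        log.info("[%s] [evaluate] artifacts written to %s", run_id, out)
    return result


def _no_fusion_schedule(train: TrainConfig) -> TrainConfig:
    """Fold the fused phase's epoch budget into original-data training so
    the ablation arms see equal numbers of epochs."""
    return TrainConfig(
        learning_rate=train.learning_rate, l2_weight=train.l2_weight,
        epochs_phase1=0, epochs_phase2=train.epochs_phase1 + train.epochs_phase2,
        batch_size=train.batch_size, seed=train.seed,
    )


def _prepare_run_dir(out_dir: str | Path, force: bool) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise BlanketPoseError(
                f"[setup] run directory {out} is not empty; pass force to overwrite"
            )
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_artifacts(
    result: PipelineResult, data: scene_sim.SimulatedDataset, out: Path, write_frames: bool
) -> None:
    import imageio.v3 as iio

    write_manifest(result.manifest, out / "manifest.csv")
    result.config.to_yaml(out / "config.lock.yaml")
    (out / "report.json").write_text(result.report_json())
    ckpt = out / "checkpoints"
    ckpt.mkdir(exist_ok=True)
    result.model.save(ckpt / "model", extra={"seed": result.config.seed})
    np.savetxt(out / "confusion_fine.csv", result.fine_report.confusion.counts,
               fmt="%d", delimiter=",")
    np.savetxt(out / "confusion_coarse.csv", result.coarse_report.confusion.counts,
               fmt="%d", delimiter=",")
    (out / "report.txt").write_text(
        "Fine-grained (7-posture)\n" + result.fine_report.render_table()
        + "\n\nCoarse-grained (4-posture)\n" + result.coarse_report.render_table() + "\n"
    )
    if write_frames:
        frames_dir = out / "frames"
        frames_dir.mkdir(exist_ok=True)
        for sample in result.manifest:
            depth = np.round(data.frames[sample.sample_id]).astype(np.uint16)
            iio.imwrite(frames_dir / f"{sample.sample_id}.png", depth)


# ---------------------------------------------------------------------------
# Ablation


@dataclass
class AblationResult:
    seeds: list[int]
    fine_f1_fusion: list[float]
    fine_f1_control: list[float]

    @property
    def deltas(self) -> list[float]:
        return [a - b for a, b in zip(self.fine_f1_fusion, self.fine_f1_control)]

    @property
    def sign_pattern(self) -> list[int]:
        return [int(np.sign(d)) for d in self.deltas]

    @property
    def n_fusion_wins(self) -> int:
        return sum(d >= 0 for d in self.deltas)

    def to_dict(self) -> dict:
        return {
            "seeds": self.seeds,
            "fine_f1_fusion": self.fine_f1_fusion,
            "fine_f1_control": self.fine_f1_control,
            "deltas": self.deltas,
            "sign_pattern": self.sign_pattern,
            "n_fusion_wins": self.n_fusion_wins,
            "mean_delta": float(np.mean(self.deltas)),
        }


def run_ablation(config: PipelineConfig, seeds: list[int]) -> AblationResult:
    """Does blanket fusion help generalize to unseen blanket conditions?

    For each seed, training is restricted to the thick and no-blanket
    conditions while evaluation covers all four (medium and thin are
    never seen in training).  The fusion arm trains with the synthesized
    phase; the control arm spends the same total epoch budget on the
    original frames only.  Returns per-seed overall fine F1 for both
    arms.
    """
    if len(seeds) < 3:
        raise ConfigurationError("ablation needs at least 3 seeds for evidence")
    from dataclasses import replace

    # match the two arms on total sample passes, not epochs: with k
    # training conditions a fused epoch holds n*7*C(k,2) samples and an
    # original epoch n*7*k, so the control arm's epoch count is scaled
    # to spend the same budget on original frames only.
    train_blankets = ("thick", "none")
    k = len(train_blankets)
    n_fused_per_epoch = k * (k - 1) // 2
    t = config.train
    control_epochs = round(
        (t.epochs_phase1 * n_fused_per_epoch + t.epochs_phase2 * k) / k
    )
    control_train = TrainConfig(
        learning_rate=t.learning_rate, l2_weight=t.l2_weight,
        epochs_phase1=0, epochs_phase2=control_epochs,
        batch_size=t.batch_size, seed=t.seed,
    )

    fusion_scores, control_scores = [], []
    for seed in seeds:
        base = replace(
            config,
            seed=seed,
            simulate=replace(config.simulate, train_blankets=train_blankets),
        )
        log.info("[ablation-seed%d] [train] fusion arm", seed)
        res_fusion = run_pipeline(replace(base, augment=replace(base.augment, fusion=True)))
        log.info("[ablation-seed%d] [train] control arm", seed)
        res_control = run_pipeline(
            replace(base, train=control_train,
                    augment=replace(base.augment, fusion=False))
        )
        fusion_scores.append(res_fusion.fine_report.overall.f1)
        control_scores.append(res_control.fine_report.overall.f1)
    return AblationResult(
        seeds=list(seeds), fine_f1_fusion=fusion_scores, fine_f1_control=control_scores
    )
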