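"""Stratified classification metrics: confusion matrices, one-vs-rest
per-class metrics, macro averages, Cohen's kappa, and posture x blanket
stratified reports.

Per-class metrics come from one-vs-rest counts extracted from the
confusion matrix:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    F1        = 2 TP / (2 TP + FP + FN)

Macro metrics are the unweighted mean of per-class values over classes
with support (a class that never occurs and is never predicted is
flagged undefined and excluded with a warning).  Cohen's kappa is
``(p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed agreement
(trace / total) and ``p_e = sum_i row_i * col_i / total^2`` the chance
agreement.  Every stratified cell is computed from the stratum's own
restricted confusion matrix, never by averaging other cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import BLANKET_ORDER
from .errors import InputError, LabelError

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "EvalReport",
    "confusion",
    "class_metrics",
    "macro_metrics",
    "micro_accuracy",
    "cohen_kappa",
    "stratified_report",
    "granularity_delta",
    "control_thick_delta",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self):
        c = self.counts
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InputError("confusion matrix must be square")
        if np.any(c < 0):
            raise InputError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class ``i``."""
        c = self.counts
        tp = int(c[i, i])
        fp = int(c[:, i].sum() - c[i, i])
        fn = int(c[i, :].sum() - c[i, i])
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn


def confusion(
    true_codes, pred_codes, n_classes: int, class_names: tuple[str, ...] | None = None
) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label-code sequences."""
    t = np.asarray(true_codes, dtype=int)
    p = np.asarray(pred_codes, dtype=int)
    if t.shape != p.shape:
        raise InputError("true and predicted label sequences differ in length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise LabelError(f"label codes out of range for {n_classes} classes")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    names = class_names or tuple(str(i) for i in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=names)


@dataclass(frozen=True)
class ClassMetrics:
    recall: float
    precision: float
    accuracy: float
    f1: float
    support: int
    undefined: bool = False  # 0/0 throughout: class absent from truth and predictions


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def class_metrics(conf: ConfusionMatrix, i: int) -> ClassMetrics:
    """One-vs-rest metrics for class ``i``; 0/0 ratios return 0, and a
    class with no support and no predictions is flagged undefined."""
    if conf.total == 0:
        raise InputError("no support: empty confusion matrix")
    tp, fp, tn, fn = conf.one_vs_rest(i)
    support = tp + fn
    return ClassMetrics(
        recall=_ratio(tp, tp + fn),
        precision=_ratio(tp, tp + fp),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        support=support,
        undefined=(support == 0 and fp == 0),
    )


def macro_metrics(conf: ConfusionMatrix) -> ClassMetrics:
    """Unweighted mean of per-class metrics over defined classes."""
    per_class = [class_metrics(conf, i) for i in range(conf.n_classes)]
    defined = [m for m in per_class if not m.undefined]
    if not defined:
        raise InputError("no support: every class is undefined")
    if len(defined) < len(per_class):
        absent = [conf.class_names[i] for i, m in enumerate(per_class) if m.undefined]
        warnings.warn(
            f"classes excluded from macro average (no support, never predicted): {absent}",
            stacklevel=2,
        )
    return ClassMetrics(
        recall=float(np.mean([m.recall for m in defined])),
        precision=float(np.mean([m.precision for m in defined])),
        accuracy=float(np.mean([m.accuracy for m in defined])),
        f1=float(np.mean([m.f1 for m in defined])),
        support=conf.total,
    )


def micro_accuracy(conf: ConfusionMatrix) -> float:
    """Plain fraction of correctly classified samples (trace / total)."""
    if conf.total == 0:
        raise InputError("no support: empty confusion matrix")
    return float(np.trace(conf.counts) / conf.total)


def cohen_kappa(conf: ConfusionMatrix) -> float:
    """Chance-corrected agreement between truth and prediction."""
    total = conf.total
    if total == 0:
        raise InputError("no support: empty confusion matrix")
    p_o = np.trace(conf.counts) / total
    rows = conf.counts.sum(axis=1)
    cols = conf.counts.sum(axis=0)
    p_e = float(rows @ cols) / (total * total)
    if p_e == 1.0:
        raise InputError("kappa undefined: all mass in a single class (p_e = 1)")
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# Stratified report


@dataclass
class EvalReport:
    """Per-class, per-(class, blanket) and overall metrics for one
    granularity — the shape of a posture x blanket results table."""

    class_names: tuple[str, ...]
    overall: ClassMetrics
    micro_accuracy: float
    kappa: float
    per_class: dict[str, ClassMetrics]
    per_stratum: dict[tuple[str, str], float | None]  # (class, blanket) -> F1
    overall_by_blanket: dict[str, float | None]  # blanket -> macro F1
    delta_control_minus_thick: float | None
    confusion: ConfusionMatrix = field(repr=False, default=None)

    def to_dict(self) -> dict:
        def cm(m: ClassMetrics) -> dict:
            return {
                "recall": m.recall,
                "precision": m.precision,
                "accuracy": m.accuracy,
                "f1": m.f1,
                "support": m.support,
            }

        return {
            "class_names": list(self.class_names),
            "overall": cm(self.overall),
            "micro_accuracy": self.micro_accuracy,
            "kappa": self.kappa,
            "per_class": {k: cm(v) for k, v in self.per_class.items()},
            "per_stratum": {
                f"{cls}|{blk}": f1 for (cls, blk), f1 in self.per_stratum.items()
            },
            "overall_by_blanket": dict(self.overall_by_blanket),
            "delta_control_minus_thick": self.delta_control_minus_thick,
            "confusion": self.confusion.counts.tolist(),
        }

    def render_table(self) -> str:
        """Text table mirroring the posture x blanket layout (F1, %)."""
        blankets = [b for b in BLANKET_ORDER]
        width = max(len(c) for c in self.class_names) + 2
        head = "Posture/Blanket".ljust(width + 4) + "".join(
            b.rjust(9) for b in blankets
        ) + "Overall".rjust(9)
        lines = [head]
        for cls in self.class_names:
            cells = []
            for b in blankets:
                f1 = self.per_stratum.get((cls, b))
                cells.append("   --".rjust(9) if f1 is None else f"{100*f1:8.1f}%")
            overall = self.per_class[cls].f1
            lines.append(cls.ljust(width + 4) + "".join(cells) + f"{100*overall:8.1f}%")
        cells = []
        for b in blankets:
            f1 = self.overall_by_blanket.get(b)
            cells.append("   --".rjust(9) if f1 is None else f"{100*f1:8.1f}%")
        lines.append("Overall".ljust(width + 4) + "".join(cells) + f"{100*self.overall.f1:8.1f}%")
        lines.append(f"Cohen's kappa: {self.kappa:.3f}")
        return "\n".join(lines)


def stratified_report(
    true_codes,
    pred_codes,
    blanket_tags,
    class_names: tuple[str, ...],
) -> EvalReport:
    """Build the full stratified report for one label granularity.

    Every (class, blanket) F1 is computed from the confusion matrix of
    that blanket stratum alone; per-class overall values come from the
    blanket-pooled matrix; the control-minus-thick delta compares macro
    F1 between the no-blanket and thick strata.
    """
    true_codes = np.asarray(true_codes, dtype=int)
    pred_codes = np.asarray(pred_codes, dtype=int)
    blanket_tags = np.asarray(blanket_tags)
    if not (len(true_codes) == len(pred_codes) == len(blanket_tags)):
        raise InputError("truth, predictions and blanket tags differ in length")
    n = len(class_names)
    pooled = confusion(true_codes, pred_codes, n, class_names)
    overall = macro_metrics(pooled)
    per_class = {cls: class_metrics(pooled, i) for i, cls in enumerate(class_names)}

    per_stratum: dict[tuple[str, str], float | None] = {}
    overall_by_blanket: dict[str, float | None] = {}
    for blanket in BLANKET_ORDER:
        mask = blanket_tags == blanket
        if not mask.any():
            for cls in class_names:
                per_stratum[(cls, blanket)] = None
            overall_by_blanket[blanket] = None
            continue
        sub = confusion(true_codes[mask], pred_codes[mask], n, class_names)
        for i, cls in enumerate(class_names):
            m = class_metrics(sub, i)
            per_stratum[(cls, blanket)] = None if m.undefined else m.f1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            overall_by_blanket[blanket] = macro_metrics(sub).f1

    delta = control_thick_delta(overall_by_blanket)
    return EvalReport(
        class_names=tuple(class_names),
        overall=overall,
        micro_accuracy=micro_accuracy(pooled),
        kappa=cohen_kappa(pooled),
        per_class=per_class,
        per_stratum=per_stratum,
        overall_by_blanket=overall_by_blanket,
        delta_control_minus_thick=delta,
        confusion=pooled,
    )


def granularity_delta(coarse_overall_f1: float, fine_overall_f1: float) -> float:
    """Drop in overall F1 when switching from coarse to fine labels."""
    return coarse_overall_f1 - fine_overall_f1


def control_thick_delta(overall_by_blanket: dict[str, float | None]) -> float | None:
    """Drop in overall F1 from the no-blanket control to the thick blanket."""
    control = overall_by_blanket.get("none")
    thick = overall_by_blanket.get("thick")
    if control is None or thick is None:
        return None
    return control - thick
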