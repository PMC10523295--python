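"""Multiclass evaluation: confusion matrix, precision/recall/F1 (per-class,
macro, micro), Cohen's kappa and one-vs-rest ROC/AUC.

Conventions:

* rows of the confusion matrix are true classes, columns predictions, class
  order fixed alphabetical;
* accuracy p0 = trace / total (N_cor / N_all);
* kappa = (p0 - pe) / (1 - pe) with pe = sum_c rowsum(c) * colsum(c) / total^2
  from the matrix marginals;
* micro-averaged F1 sums TP/FP/FN over classes — for single-label multiclass
  data it coincides with accuracy;
* zero-division in precision/recall yields 0.0 with an ``undefined`` flag
  rather than an exception or a dropped class;
* ROC is one-vs-rest per class, AUC by the trapezoidal rule over the
  threshold sweep, which equals the Mann-Whitney concordance probability with
  half credit for ties;
* display rounding is half-up to two decimals; internal values keep full
  precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import CLASS_NAMES


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up rounding for report display (3.5 -> 4, 2.675 @2 -> 2.68)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray                 # (C, C) ints; rows true, cols predicted
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {counts.shape}")
        if counts.shape[0] != len(self.class_names):
            raise ValueError("class_names length must match matrix size")
        if np.any(counts < 0):
            raise ValueError("confusion matrix entries must be >= 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))


def confusion_matrix(true_labels, predicted_labels,
                     class_names: tuple[str, ...] = CLASS_NAMES) -> ConfusionMatrix:
    """Count items of true class i predicted as class j."""
    t = _as_indices(true_labels, class_names)
    p = _as_indices(predicted_labels, class_names)
    if len(t) != len(p):
        raise ValueError(f"label lists differ in length: {len(t)} vs {len(p)}")
    if len(t) == 0:
        raise ValueError("need at least one labeled item")
    c = len(class_names)
    counts = np.zeros((c, c), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def _as_indices(labels, class_names) -> np.ndarray:
    idx = []
    for lab in labels:
        if hasattr(lab, "index") and hasattr(lab, "name") and not isinstance(lab, str):
            idx.append(int(lab.index))
        elif isinstance(lab, str):
            if lab not in class_names:
                raise ValueError(f"unknown label {lab!r}; classes are {list(class_names)}")
            idx.append(class_names.index(lab))
        else:
            i = int(lab)
            if not 0 <= i < len(class_names):
                raise ValueError(f"label index {i} outside [0, {len(class_names)})")
            idx.append(i)
    return np.array(idx, dtype=np.int64)


def accuracy(cm: ConfusionMatrix) -> float:
    """p0 = N_cor / N_all (trace over total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


@dataclass(frozen=True)
class ClassPRF:
    precision: float
    recall: float
    f1: float
    support: int
    precision_undefined: bool = False
    recall_undefined: bool = False


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0.0 when both rates are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def per_class_prf(cm: ConfusionMatrix) -> dict[str, ClassPRF]:
    """Per-class precision (column-wise), recall (row-wise) and F1.

    A class never predicted has undefined precision, a class with no true
    items undefined recall; both are reported as 0.0 with a flag.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    out: dict[str, ClassPRF] = {}
    col_sums = cm.counts.sum(axis=0)
    row_sums = cm.counts.sum(axis=1)
    for i, name in enumerate(cm.class_names):
        tp = int(cm.counts[i, i])
        p_undef = col_sums[i] == 0
        r_undef = row_sums[i] == 0
        precision = 0.0 if p_undef else tp / col_sums[i]
        recall = 0.0 if r_undef else tp / row_sums[i]
        out[name] = ClassPRF(precision=float(precision), recall=float(recall),
                             f1=f1_score(float(precision), float(recall)),
                             support=int(row_sums[i]),
                             precision_undefined=bool(p_undef),
                             recall_undefined=bool(r_undef))
    return out


def macro_scores(per_class: dict[str, ClassPRF]) -> tuple[float, float, float]:
    """Unweighted means of per-class precision, recall and F1."""
    if not per_class:
        raise ValueError("need at least one class")
    ps = [c.precision for c in per_class.values()]
    rs = [c.recall for c in per_class.values()]
    fs = [c.f1 for c in per_class.values()]
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def weighted_scores(per_class: dict[str, ClassPRF]) -> tuple[float, float, float]:
    """Support-weighted means of per-class precision, recall and F1."""
    supports = np.array([c.support for c in per_class.values()], dtype=float)
    if supports.sum() == 0:
        raise ValueError("no support in any class")
    w = supports / supports.sum()
    ps = np.array([c.precision for c in per_class.values()])
    rs = np.array([c.recall for c in per_class.values()])
    fs = np.array([c.f1 for c in per_class.values()])
    return float(w @ ps), float(w @ rs), float(w @ fs)


def micro_f1(cm: ConfusionMatrix) -> float:
    """F1 of TP/FP/FN summed across classes (== accuracy for single-label)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = float(np.trace(cm.counts))
    fp = float(cm.counts.sum() - np.trace(cm.counts))
    fn = fp  # each misclassified item is one FP (for the predicted class) and one FN
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return f1_score(precision, recall)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p0: float
    pe: float
    defined: bool = True


def kappa(cm: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement (p0 - pe) / (1 - pe)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.total
    p0 = accuracy(cm)
    row = cm.counts.sum(axis=1).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    pe = float((row * col).sum() / (n * n))
    if pe == 1.0:
        # degenerate: marginals concentrated on one class
        if p0 == 1.0:
            return KappaResult(kappa=1.0, p0=p0, pe=pe, defined=True)
        return KappaResult(kappa=float("nan"), p0=p0, pe=pe, defined=False)
    return KappaResult(kappa=float((p0 - pe) / (1.0 - pe)), p0=p0, pe=pe)


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    defined: bool = True


def roc_auc(scores: np.ndarray, true_labels,
            class_names: tuple[str, ...] = CLASS_NAMES) -> dict[str, RocCurve]:
    """One-vs-rest ROC per class from class-probability scores.

    AUC is the trapezoidal area under the threshold-swept curve; tied scores
    are grouped, which gives exactly the Mann-Whitney concordance probability
    with half credit for ties. A class with no positives or no negatives is
    flagged undefined (AUC NaN).
    """
    scores = np.asarray(scores, dtype=float)
    t = _as_indices(true_labels, class_names)
    if scores.ndim != 2 or scores.shape[0] != len(t):
        raise ValueError(f"scores must be (n_items, n_classes), got {scores.shape}")
    out: dict[str, RocCurve] = {}
    for i, name in enumerate(class_names):
        pos = t == i
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[name] = RocCurve(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
                                 auc=float("nan"), defined=False)
            continue
        s = scores[:, i]
        order = np.argsort(-s, kind="stable")
        s_sorted = s[order]
        pos_sorted = pos[order].astype(float)
        tp_cum = np.cumsum(pos_sorted)
        fp_cum = np.cumsum(1.0 - pos_sorted)
        # keep only the last index of each tied-score run (threshold points)
        distinct = np.r_[np.diff(s_sorted) != 0, True]
        tpr = np.r_[0.0, tp_cum[distinct] / n_pos]
        fpr = np.r_[0.0, fp_cum[distinct] / n_neg]
        auc = float(np.trapezoid(tpr, fpr))
        out[name] = RocCurve(fpr=fpr, tpr=tpr, auc=auc)
    return out


# -- report assembly --------------------------------------------------------

@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    accuracy: float
    per_class: dict[str, ClassPRF]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_f1: float
    kappa: KappaResult
    roc: dict[str, RocCurve] | None = None

    def to_dict(self) -> dict:
        d = {
            "class_names": list(self.confusion.class_names),
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "per_class": {k: asdict(v) for k, v in self.per_class.items()},
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "kappa": asdict(self.kappa),
        }
        if self.roc is not None:
            d["roc"] = {k: {"fpr": v.fpr.tolist(), "tpr": v.tpr.tolist(),
                            "auc": v.auc, "defined": v.defined}
                        for k, v in self.roc.items()}
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def table_frame(self) -> pd.DataFrame:
        """Classification-report table: per-class rows plus accuracy,
        macro-avg and weighted-avg rows, rounded half-up to 2 decimals."""
        rows = []
        for name, c in self.per_class.items():
            rows.append((name, round_half_up(c.precision), round_half_up(c.recall),
                         round_half_up(c.f1)))
        rows.append(("accuracy", None, None, round_half_up(self.accuracy)))
        rows.append(("macro avg", round_half_up(self.macro_precision),
                     round_half_up(self.macro_recall), round_half_up(self.macro_f1)))
        wp, wr, wf = weighted_scores(self.per_class)
        rows.append(("weighted avg", round_half_up(wp), round_half_up(wr),
                     round_half_up(wf)))
        return pd.DataFrame(rows, columns=["class", "precision", "recall", "f1-score"])


def report_from_counts(cm: ConfusionMatrix,
                       scores: np.ndarray | None = None,
                       true_labels=None) -> EvalReport:
    per_class = per_class_prf(cm)
    mp, mr, mf = macro_scores(per_class)
    roc = None
    if scores is not None and true_labels is not None:
        roc = roc_auc(scores, true_labels, class_names=cm.class_names)
    return EvalReport(confusion=cm, accuracy=accuracy(cm), per_class=per_class,
                      macro_precision=mp, macro_recall=mr, macro_f1=mf,
                      micro_f1=micro_f1(cm), kappa=kappa(cm), roc=roc)


def evaluate(model, items, preprocess=None) -> EvalReport:
    """Run a trained model over labeled items and assemble the full report.

    ``items`` may be SyntheticSamples, (image, label) pairs or LabeledItems
    (paths are loaded on the fly). Images are resized to the model's input
    side; normalization is applied only when the preprocess config asks for
    validation-time normalization (``normalize_train_only`` off).
    """
    from .dense_model import predict_proba
    from .io_preprocess import load_image, normalize_image, resize_image

    side = model.config.input_side
    images, labels = [], []
    for it in items:
        if hasattr(it, "path") and hasattr(it, "label"):
            img = load_image(it.path)
            lab = it.label
        elif hasattr(it, "image") and hasattr(it, "label"):
            img, lab = it.image, it.label
        else:
            img, lab = it
        img = resize_image(np.asarray(img, dtype=float), side)
        if preprocess is not None and not preprocess.normalize_train_only:
            img = normalize_image(img, preprocess)
        images.append(img)
        labels.append(lab.index if hasattr(lab, "index") else int(lab))
    if not images:
        raise ValueError("need at least one item to evaluate")
    scores = predict_proba(model, np.stack(images))
    preds = np.argmax(scores, axis=1)
    cm = confusion_matrix(labels, preds.tolist(),
                          class_names=CLASS_NAMES[:scores.shape[1]]
                          if scores.shape[1] <= len(CLASS_NAMES) else
                          tuple(f"class_{i}" for i in range(scores.shape[1])))
    return report_from_counts(cm, scores=scores, true_labels=labels)
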