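"""Evaluation: confusion matrices, macro metrics, the majority-label
baseline, and the validation/test splitting schemes.

Metrics follow the macro-averaged convention appropriate for the heavily
imbalanced structure-label distributions: per-class precision, recall and
F1 are averaged with equal class weight over the *union* of labels present
in the truth or the predictions (not the full label set), and a per-class
ratio with a zero denominator contributes 0. Accuracy is the multiclass
generalisation trace/total. With these conventions the metrics of a
constant majority-class predictor reduce to closed forms of the majority
fraction a and evaluated class count N: macro precision a/N, macro recall
1/N, macro F1 (2a/(1+a))/N.

Splitting schemes: stratified k-fold at the structure level, leave-one-
center-out cross-validation, and whole-center holdout (no patient or
center ever straddles train and test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datatypes import LabelSet

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "SplitPlan",
    "confusion",
    "compute_metrics",
    "MajorityLabelBaseline",
    "majority_label_baseline",
    "stratified_kfold",
    "center_cross_validation",
    "center_holdout",
    "plot_confusion",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = truth, columns = prediction, in labelset order."""

    counts: np.ndarray
    labelset: LabelSet

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labelset)
        if self.counts.shape != (n, n) or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative |L| x |L| matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    per_class: dict[str, dict[str, float]]
    evaluated_label_count: int
    total: int

    def to_dict(self) -> dict:
        return {
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "evaluated_label_count": self.evaluated_label_count,
            "total": self.total,
            "per_class": self.per_class,
        }

    def rounded(self, ndigits: int = 3) -> dict:
        """Display rounding (half away from zero), matching report tables."""
        def r(x: float) -> float:
            scale = 10 ** ndigits
            return float(np.floor(abs(x) * scale + 0.5) / scale * np.sign(x)) if x else 0.0
        d = self.to_dict()
        return {k: (r(v) if isinstance(v, float) else v)
                for k, v in d.items() if k != "per_class"}


@dataclass
class SplitPlan:
    """Named train/validation(/test) partitions of record ids."""

    scheme: str
    splits: list[dict[str, list]] = field(default_factory=list)


def confusion(truth, pred, labelset: LabelSet) -> ConfusionMatrix:
    truth, pred = list(truth), list(pred)
    if len(truth) != len(pred) or not truth:
        raise ValueError("truth and pred must be equal-length and non-empty")
    n = len(labelset)
    counts = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(truth, pred):
        counts[labelset.index(t), labelset.index(p)] += 1
    return ConfusionMatrix(counts, labelset)


def compute_metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """Macro precision/recall/F1 over labels present in truth or
    predictions, plus trace/total accuracy and a per-class table."""
    counts = cm.counts
    if counts.sum() < 1:
        raise ValueError("empty confusion matrix")
    present = np.flatnonzero((counts.sum(axis=1) + counts.sum(axis=0)) > 0)
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    total = counts.sum()
    tn = total - tp - fp - fn

    def safe(num, den):
        return np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)

    prec = safe(tp, tp + fp)
    rec = safe(tp, tp + fn)
    f1 = safe(2 * prec * rec, prec + rec)

    per_class = {}
    for c in present:
        name = cm.labelset.class_names[c]
        per_class[name] = {
            "precision": float(prec[c]), "recall": float(rec[c]), "f1": float(f1[c]),
            "tp": int(tp[c]), "fp": int(fp[c]), "fn": int(fn[c]), "tn": int(tn[c]),
        }
    return EvaluationReport(
        macro_precision=float(prec[present].mean()),
        macro_recall=float(rec[present].mean()),
        macro_f1=float(f1[present].mean()),
        accuracy=float(tp.sum() / total),
        per_class=per_class,
        evaluated_label_count=len(present),
        total=int(total),
    )


@dataclass
class MajorityLabelBaseline:
    """Constant classifier predicting the most frequent training label."""

    label: str
    labelset: LabelSet

    def predict(self, records) -> list[str]:
        return [self.label] * len(records)

    def predict_proba(self, records) -> np.ndarray:
        p = np.zeros((len(records), len(self.labelset)))
        p[:, self.labelset.index(self.label)] = 1.0
        return p


def majority_label_baseline(train_labels, labelset: LabelSet) -> MajorityLabelBaseline:
    """Ties between equally frequent labels break by labelset order."""
    train_labels = list(train_labels)
    if not train_labels:
        raise ValueError("need at least one training label")
    best = max(labelset, key=lambda name: (train_labels.count(name), -labelset.index(name)))
    return MajorityLabelBaseline(label=best, labelset=labelset)


def stratified_kfold(record_ids, labels, k: int = 5, seed: int = 0) -> SplitPlan:
    """K disjoint folds stratified by standard label; per-fold class counts
    differ by at most one from perfect proportionality."""
    record_ids = np.asarray(record_ids)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(record_ids):
        raise ValueError("k exceeds record count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    plan = SplitPlan(scheme="kfold5" if k == 5 else f"kfold{k}")
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        plan.splits.append({"name": f"fold{fold}",
                            "train": record_ids[tr].tolist(),
                            "validation": record_ids[va].tolist()})
    return plan


def center_cross_validation(record_ids, center_ids) -> SplitPlan:
    """Leave-one-center-out: each center's records form one validation
    fold; all other centers train."""
    record_ids = np.asarray(record_ids)
    center_ids = np.asarray(center_ids)
    centers = sorted(set(center_ids.tolist()))
    if len(centers) < 2:
        raise ValueError("need >= 2 centers")
    plan = SplitPlan(scheme="center_loo")
    for c in centers:
        mask = center_ids == c
        plan.splits.append({"name": str(c),
                            "train": record_ids[~mask].tolist(),
                            "validation": record_ids[mask].tolist()})
    return plan


def center_holdout(record_ids, center_ids, n_test_centers: int, seed: int = 0) -> SplitPlan:
    """Assign whole centers to the test side; no patient straddles the
    boundary because patients belong to exactly one center."""
    record_ids = np.asarray(record_ids)
    center_ids = np.asarray(center_ids)
    centers = sorted(set(center_ids.tolist()))
    if not (0 < n_test_centers < len(centers)):
        raise ValueError("n_test_centers must be in (0, n_centers)")
    rng = np.random.default_rng(seed)
    test_centers = set(rng.choice(centers, size=n_test_centers, replace=False).tolist())
    mask = np.isin(center_ids, sorted(test_centers))
    plan = SplitPlan(scheme="center_holdout")
    plan.splits.append({"name": "holdout",
                        "train": record_ids[~mask].tolist(),
                        "test": record_ids[mask].tolist(),
                        "test_centers": sorted(test_centers)})
    return plan


def plot_confusion(cm: ConfusionMatrix, path=None, title: str = ""):
    """Render the confusion matrix as a heatmap (matplotlib figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(cm.labelset),) * 2)
    ax.imshow(cm.counts, cmap="Blues")
    names = cm.labelset.class_names
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("truth")
    if title:
        ax.set_title(title)
    for i in range(len(names)):
        for j in range(len(names)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center", fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
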