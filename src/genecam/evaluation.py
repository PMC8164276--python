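"""Performance surfaces: confusion matrices, per-class metrics, experiments.

Two experiment designs are supported, mirroring how multi-cancer
classifiers are usually evaluated:

* multiwise - one cross-validation over all classes at once, with a
  pooled confusion matrix and CAM leader genes for a focal class;
* pairwise - the dataset restricted to two classes, the same pipeline on
  the restriction, and the focal class's ranking recorded for later
  intersection across pairs.

`confusability_index` quantifies how strongly a classifier swaps two
classes: the mean of the two row-normalized cross cells of the confusion
matrix (0 for a perfect classifier, 1 for two classes always swapped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_matrix",
    "metric_report",
    "confusability_index",
    "ExperimentResult",
    "run_multiwise_experiment",
    "run_pairwise_experiment",
]


@dataclass
class ConfusionMatrix:
    class_names: list[str]
    counts: np.ndarray  # rows = true class, columns = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized grid; an empty class's row stays all-zero."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / np.where(sums > 0, sums, 1), 0.0)
        return out

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        grid = self.normalized if normalized else self.counts
        return pd.DataFrame(grid, index=self.class_names, columns=self.class_names)


def confusion_matrix(y_true, y_pred, class_names: list[str]) -> ConfusionMatrix:
    """Count grid: cell (i, j) = samples of true class i predicted as class j."""
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    known = set(class_names)
    for label in list(y_true) + list(y_pred):
        if label not in known:
            raise ValueError(f"unknown label {label!r}")
    if len(y_true) == 0:
        counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    else:
        counts = _sk_confusion(y_true, y_pred, labels=class_names).astype(int)
    return ConfusionMatrix(list(class_names), counts)


@dataclass
class MetricReport:
    accuracy: float
    per_class: dict[str, dict[str, float | None]]  # precision/recall/f1, None if undefined
    macro_precision: float
    macro_recall: float
    macro_f1: float
    training_accuracy: float | None = None
    provenance: str = ""

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "training_accuracy": self.training_accuracy,
            "provenance": self.provenance,
        }


def metric_report(
    cm: ConfusionMatrix, training_accuracy: float | None = None, provenance: str = ""
) -> MetricReport:
    """Accuracy plus per-class and macro precision/recall/F1.

    Per-class values that are undefined (a class never predicted, or with
    no true samples) are reported as None and excluded from the macro
    means, with a warning.
    """
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    col_sums = counts.sum(axis=0)
    row_sums = counts.sum(axis=1)
    per_class: dict[str, dict[str, float | None]] = {}
    undefined = []
    for i, name in enumerate(cm.class_names):
        precision = float(diag[i] / col_sums[i]) if col_sums[i] > 0 else None
        recall = float(diag[i] / row_sums[i]) if row_sums[i] > 0 else None
        if precision is not None and recall is not None and precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        elif precision is not None and recall is not None:
            f1 = 0.0
        else:
            f1 = None
        if precision is None or recall is None:
            undefined.append(name)
        per_class[name] = {"precision": precision, "recall": recall, "f1": f1}
    if undefined:
        warnings.warn(
            f"metrics undefined for classes {undefined}; excluded from macro means", stacklevel=2
        )

    def macro(key: str) -> float:
        vals = [v[key] for v in per_class.values() if v[key] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    return MetricReport(
        accuracy=float(diag.sum() / counts.sum()),
        per_class=per_class,
        macro_precision=macro("precision"),
        macro_recall=macro("recall"),
        macro_f1=macro("f1"),
        training_accuracy=training_accuracy,
        provenance=provenance,
    )


def confusability_index(cm: ConfusionMatrix, class_a: str, class_b: str) -> float:
    """Mean of the two row-normalized cross cells between two classes."""
    for c in (class_a, class_b):
        if c not in cm.class_names:
            raise ValueError(f"class {c!r} not in confusion matrix")
    ia, ib = cm.class_names.index(class_a), cm.class_names.index(class_b)
    norm = cm.normalized
    directions = []
    for i, j in ((ia, ib), (ib, ia)):
        if cm.counts[i].sum() > 0:
            directions.append(norm[i, j])
        else:
            warnings.warn(f"class {cm.class_names[i]!r} has no samples; direction excluded",
                          stacklevel=2)
    if not directions:
        raise ValueError("both classes are empty")
    return float(np.mean(directions))


@dataclass
class ExperimentResult:
    cv: "CVResult"
    confusion: ConfusionMatrix
    report: MetricReport
    rankings: dict[str, "GeneRanking"]


def run_multiwise_experiment(
    dataset,
    pconfig,
    cconfig,
    tconfig,
    focal_class: str | None = None,
    top_n: int = 20,
    all_classes: bool = False,
) -> ExperimentResult:
    """One cross-validation over all classes, plus multiwise leader genes."""
    from .attribution import extract_leader_genes_multiwise
    from .classifier import cross_validate

    if len(dataset.class_names) < 3:
        raise ValueError("a multiwise experiment needs >= 3 classes")
    cv = cross_validate(dataset, pconfig, cconfig, tconfig)
    cm = cv.confusion()
    report = metric_report(cm, training_accuracy=cv.mean_training_accuracy,
                           provenance=f"multiwise, {tconfig.folds} folds")
    targets = cv.class_names if all_classes else [focal_class or cv.class_names[0]]
    rankings = {
        c: extract_leader_genes_multiwise(cv, dataset, c, top_n=top_n) for c in targets
    }
    return ExperimentResult(cv, cm, report, rankings)


def run_pairwise_experiment(
    dataset, class_a: str, class_b: str, pconfig, cconfig, tconfig, top_n: int = 20
) -> ExperimentResult:
    """The full pipeline on the dataset restricted to two classes.

    The returned ranking (for class_a, the focal class) is computed the
    same way as the multiwise one but flagged "pairwise" so it can feed
    the cross-pair intersection.
    """
    from .attribution import aggregate_class_scores, GeneRanking, GeneScore, _rank_scores
    from .classifier import cross_validate
    from dataclasses import replace

    for c in (class_a, class_b):
        if c not in dataset.class_names:
            raise ValueError(f"class {c!r} absent from dataset")
    restricted = dataset.restrict([class_a, class_b])
    cconfig2 = replace(cconfig, n_classes=2)
    cv = cross_validate(restricted, pconfig, cconfig2, tconfig)
    cm = cv.confusion()
    report = metric_report(cm, training_accuracy=cv.mean_training_accuracy,
                           provenance=f"pairwise {class_a} vs {class_b}, {tconfig.folds} folds")
    agg = aggregate_class_scores(cv, restricted, class_a)
    scores = _rank_scores(agg, len(agg))  # keep the full ranking for deep pooling
    pixmap = cv.layout.gene_to_pixel
    scores = [GeneScore(s.gene_id, s.score, pixmap.get(s.gene_id, -1)) for s in scores]
    ranking = GeneRanking(class_a, "pairwise", scores,
                          provenance=f"vs {class_b}, {tconfig.folds} folds")
    return ExperimentResult(cv, cm, report, {class_a: ranking})
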