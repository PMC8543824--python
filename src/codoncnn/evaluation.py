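"""One-vs-rest metrics, replicate protocol, and model comparison.

A k-class prediction task is evaluated as k binary problems: for each class
c the labels are binarised to c-vs-rest and TP/FN/FP/TN, precision, recall
and F-measure are computed. Experiments are replicated with consecutive
seeds (fresh split, initialisation, and training each time) and summarised
as mean +/- SE, with SE the sample standard deviation over replicates
divided by sqrt(replicates). Two methods' replicate accuracies are compared
with a two-sided Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import stats


@dataclass
class BinaryConfusion:
    """Per-class one-vs-rest confusion cells (reals: may be replicate means)."""

    cells: dict[str, dict[str, float]]  # class -> {TP, FN, FP, TN}

    def total(self, class_label: str) -> float:
        c = self.cells[class_label]
        return c["TP"] + c["FN"] + c["FP"] + c["TN"]


@dataclass
class ClassificationReport:
    """Per-class precision/recall/F and overall accuracy."""

    per_class: dict[str, dict[str, float]]  # class -> {precision, recall, f_measure}
    accuracy: float


def per_class_metrics(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    class_set: list,
) -> tuple[ClassificationReport, BinaryConfusion]:
    """One-vs-rest metrics for every class plus joint accuracy.

    Zero-denominator precision/recall are defined as 0 (e.g. a class the
    predictor never outputs has precision 0 by convention).
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    known = set(class_set)
    stray = (set(true_labels.tolist()) | set(predicted_labels.tolist())) - known
    if stray:
        raise ValueError(f"labels outside the declared class set: {sorted(stray)}")

    cells: dict[str, dict[str, float]] = {}
    per_class: dict[str, dict[str, float]] = {}
    for c in class_set:
        t = true_labels == c
        p = predicted_labels == c
        tp = float(np.sum(t & p))
        fn = float(np.sum(t & ~p))
        fp = float(np.sum(~t & p))
        tn = float(np.sum(~t & ~p))
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        cells[str(c)] = {"TP": tp, "FN": fn, "FP": fp, "TN": tn}
        per_class[str(c)] = {"precision": precision, "recall": recall, "f_measure": f}
    accuracy = float(np.mean(true_labels == predicted_labels))
    return ClassificationReport(per_class=per_class, accuracy=accuracy), BinaryConfusion(
        cells=cells
    )


def averaged_confusion(per_run: list[BinaryConfusion]) -> BinaryConfusion:
    """Cell-wise arithmetic mean of per-run confusion matrices."""
    if not per_run:
        raise ValueError("need at least one run")
    class_sets = [set(c.cells) for c in per_run]
    if any(cs != class_sets[0] for cs in class_sets):
        raise ValueError("inconsistent class sets across runs")
    out: dict[str, dict[str, float]] = {}
    for cls in per_run[0].cells:
        out[cls] = {
            cell: float(np.mean([run.cells[cls][cell] for run in per_run]))
            for cell in ("TP", "FN", "FP", "TN")
        }
    return BinaryConfusion(cells=out)


@dataclass
class ReplicateSummary:
    """Per-replicate reports plus mean/SE summaries."""

    reports: list[ClassificationReport]
    confusions: list[BinaryConfusion]
    accuracies: np.ndarray
    mean_accuracy: float
    se_accuracy: float
    mean_confusion: BinaryConfusion
    per_class_summary: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )  # class -> metric -> (mean, SE)
    extras: list[dict] = field(default_factory=list)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(values.mean()), se


def replicate_experiment(
    run_one: Callable[[int], tuple[np.ndarray, np.ndarray, dict]],
    class_set: list,
    replicates: int = 10,
    base_seed: int = 0,
) -> ReplicateSummary:
    """Repeat an experiment with seeds base_seed + 0..replicates-1.

    ``run_one(seed)`` must re-split, re-initialise and re-train, returning
    (true_test_labels, predicted_test_labels, extras). Anything raised
    inside a replicate is re-raised with the replicate index attached.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates for an SE")
    reports, confusions, extras = [], [], []
    for i in range(replicates):
        try:
            y_true, y_pred, extra = run_one(base_seed + i)
        except Exception as exc:
            raise RuntimeError(f"replicate {i} (seed {base_seed + i}) failed: {exc}") from exc
        report, confusion = per_class_metrics(y_true, y_pred, class_set)
        reports.append(report)
        confusions.append(confusion)
        extras.append(extra)
    accuracies = np.array([r.accuracy for r in reports])
    mean_acc, se_acc = _mean_se(accuracies)
    per_class_summary: dict[str, dict[str, tuple[float, float]]] = {}
    for c in reports[0].per_class:
        per_class_summary[c] = {
            metric: _mean_se(np.array([r.per_class[c][metric] for r in reports]))
            for metric in ("precision", "recall", "f_measure")
        }
    return ReplicateSummary(
        reports=reports,
        confusions=confusions,
        accuracies=accuracies,
        mean_accuracy=mean_acc,
        se_accuracy=se_acc,
        mean_confusion=averaged_confusion(confusions),
        per_class_summary=per_class_summary,
        extras=extras,
    )


def compare_models(accuracies_a, accuracies_b) -> float:
    """Two-sided Welch t-test p-value on two sets of replicate accuracies."""
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("replicate counts must match")
    if len(a) < 2:
        raise ValueError("need >= 2 replicates per method")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.pvalue)


def write_metrics_report(summary: ReplicateSummary, path: str | Path) -> None:
    """TSV: class, precision+/-SE, recall+/-SE, F+/-SE."""
    with open(path, "w") as fh:
        fh.write(
            "class\tprecision_mean\tprecision_se\trecall_mean\trecall_se\t"
            "f_measure_mean\tf_measure_se\n"
        )
        for c, metrics in summary.per_class_summary.items():
            p, pse = metrics["precision"]
            r, rse = metrics["recall"]
            f, fse = metrics["f_measure"]
            fh.write(f"{c}\t{p:.6f}\t{pse:.6f}\t{r:.6f}\t{rse:.6f}\t{f:.6f}\t{fse:.6f}\n")
        fh.write(
            f"overall_accuracy\t{summary.mean_accuracy:.6f}\t{summary.se_accuracy:.6f}"
            "\t\t\t\t\n"
        )


def write_confusion_report(confusion: BinaryConfusion, path: str | Path) -> None:
    """TSV: class, TP, FN, FP, TN (cells may be replicate means)."""
    with open(path, "w") as fh:
        fh.write("class\tTP\tFN\tFP\tTN\n")
        for c, cells in confusion.cells.items():
            fh.write(
                f"{c}\t{cells['TP']:.4f}\t{cells['FN']:.4f}\t{cells['FP']:.4f}\t"
                f"{cells['TN']:.4f}\n"
            )
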