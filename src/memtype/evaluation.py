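"""Classification metrics: per-class one-vs-rest Se/Sp/ACC/MCC and OSR.

For class *i* with one-vs-rest counts TP, TN, FP, FN:

    Se_i  = TP / (TP + FN)
    Sp_i  = TN / (TN + FP)
    ACC_i = (TP + TN) / N
    MCC_i = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))
    OSR   = sum_i TP_i / N        (overall success rate = accuracy)

All metrics are computed on exact integer counts.  Whenever a ratio's
denominator is zero (a class never present or never predicted) the
metric is defined as 0 - the convention matching how never-predicted
minority classes are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np


@dataclass(frozen=True)
class ClassConfusion:
    """One-vs-rest confusion counts for a single class."""

    class_id: int
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_labels(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("label vectors are empty")
    return y_true, y_pred


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int],
                     class_id: int) -> ClassConfusion:
    """One-vs-rest TP/TN/FP/FN for ``class_id``."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    t = y_true == class_id
    p = y_pred == class_id
    return ClassConfusion(class_id=class_id,
                          tp=int(np.sum(t & p)),
                          tn=int(np.sum(~t & ~p)),
                          fp=int(np.sum(~t & p)),
                          fn=int(np.sum(t & ~p)))


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def class_metrics(counts: ClassConfusion) -> Dict[str, float]:
    """Se, Sp, ACC and MCC from integer counts (zero-denominator -> 0)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    se = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    acc = _safe_div(tp + tn, counts.n)
    denom2 = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, np.sqrt(denom2)) if denom2 else 0.0
    return {"Se": se, "Sp": sp, "ACC": acc, "MCC": float(mcc)}


def overall_success_rate(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Fraction of samples whose predicted class equals the true class."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


@dataclass
class MetricSet:
    """Per-class metrics plus the dataset-level overall success rate."""

    per_class: Dict[int, Dict[str, float]]
    osr: float
    k: int


def evaluate(y_true: Sequence[int], y_pred: Sequence[int],
             classes: Sequence[int] | None = None) -> MetricSet:
    y_true, y_pred = _check_labels(y_true, y_pred)
    if classes is None:
        classes = sorted(set(int(c) for c in np.unique(y_true)))
    per_class = {c: class_metrics(confusion_counts(y_true, y_pred, c))
                 for c in classes}
    return MetricSet(per_class=per_class,
                     osr=overall_success_rate(y_true, y_pred),
                     k=len(classes))


#: display names for the 8 membrane protein types
TYPE_NAMES = {1: "Type I", 2: "Type II", 3: "Type III", 4: "Type IV",
              5: "Multipass", 6: "Lipid-chain-anchored", 7: "GPI-anchored",
              8: "Peripheral"}


def format_report(metrics: MetricSet, names: Dict[int, str] | None = None) -> str:
    """Aligned per-class table (rows = classes, columns = Se/Sp/ACC/MCC)."""
    names = names or TYPE_NAMES
    width = max([len(names.get(c, str(c))) for c in metrics.per_class] + [5])
    lines = [f"{'Class':<{width}}  {'Se':>7} {'Sp':>7} {'ACC':>7} {'MCC':>7}"]
    for c, m in metrics.per_class.items():
        label = names.get(c, str(c))
        lines.append(f"{label:<{width}}  {m['Se']:7.4f} {m['Sp']:7.4f} "
                     f"{m['ACC']:7.4f} {m['MCC']:7.4f}")
    lines.append(f"{'OSR':<{width}}  {metrics.osr:7.4f}")
    return "\n".join(lines)


def write_report_tsv(path: Union[str, Path], metrics: MetricSet,
                     names: Dict[int, str] | None = None) -> None:
    names = names or TYPE_NAMES
    with open(path, "w") as fh:
        fh.write("class\tSe\tSp\tACC\tMCC\n")
        for c, m in metrics.per_class.items():
            fh.write(f"{names.get(c, str(c))}\t{m['Se']:.4f}\t{m['Sp']:.4f}"
                     f"\t{m['ACC']:.4f}\t{m['MCC']:.4f}\n")
        fh.write(f"OSR\t{metrics.osr:.4f}\t\t\t\n")
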