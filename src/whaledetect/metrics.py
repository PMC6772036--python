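"""Evaluation conventions: confusion matrices with an explicit positive
class, water-positive precision/recall/F1, the whale-detection false-positive
rate, per-fold tables, and learning-rate sweep summaries.

Two conventions live side by side and must not be conflated:

* the water-positive convention — precision is the share of model-classified
  water that really is water, recall the share of true water the model
  found; this is the headline precision/recall/F1 reported per model;
* the whale-detection false-positive rate — the share of water tiles flagged
  as whale (i.e. sent to a human reviewer needlessly).

Undefined metrics (zero denominators, e.g. a degenerate all-water fold with
no predicted positives) surface as explicit ``None`` values, rendered as
"undefined" in reports — never silently as 0 or NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "precision_recall",
    "f1",
    "fpr_whale_detection",
    "metric_report",
    "fold_report",
    "lr_sweep_report",
    "UNDEFINED",
]

#: Marker string used when a metric's denominator is zero.
UNDEFINED = "undefined"

_CLASSES = ("water", "whale")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with a declared positive class.

    tp/fp/fn/tn follow the declared ``positive_class``; swapping the
    positive class maps (tp, fp, fn, tn) -> (tn, fn, fp, tp).
    """

    positive_class: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if self.positive_class not in _CLASSES:
            raise ParameterError(f"unknown positive class {self.positive_class!r}")
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swap_positive(self) -> "ConfusionMatrix":
        other = _CLASSES[1 - _CLASSES.index(self.positive_class)]
        return ConfusionMatrix(
            positive_class=other, tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp
        )

    @property
    def n_positive(self) -> int:
        """Tiles whose true class is the positive class."""
        return self.tp + self.fn


def confusion(
    labels: Sequence[str],
    predictions: Sequence[str],
    positive_class: str = "water",
) -> ConfusionMatrix:
    """Exact 2x2 counts of label/prediction pairs."""
    if len(labels) != len(predictions):
        raise ParameterError(
            f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions"
        )
    for sym in set(labels) | set(predictions):
        if sym not in _CLASSES:
            raise ParameterError(f"unknown class symbol {sym!r}")
    tp = fp = fn = tn = 0
    for lab, pred in zip(labels, predictions):
        if lab == positive_class:
            if pred == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if pred == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(positive_class, tp, fp, fn, tn)


def precision_recall(cm: ConfusionMatrix) -> tuple[float | None, float | None]:
    """precision = tp/(tp+fp), recall = tp/(tp+fn); ``None`` when undefined."""
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    return precision, recall


def f1(precision: float | None, recall: float | None) -> float | None:
    """Harmonic mean 2PR/(P+R); ``None`` if either input is undefined or
    both are zero."""
    if precision is None or recall is None:
        return None
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ParameterError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def fpr_whale_detection(cm: ConfusionMatrix) -> float:
    """Share of true water tiles flagged as whale (reviewer burden).

    Requires a water-positive matrix; with that convention the flagged water
    tiles are the false negatives. Distinct from (1 - precision).
    """
    if cm.positive_class != "water":
        cm = cm.swap_positive()
    n_water = cm.tp + cm.fn
    if n_water == 0:
        raise DegenerateInputError("no water tiles in the evaluated set")
    return cm.fn / n_water


@dataclass(frozen=True)
class MetricReport:
    """Water-positive precision/recall/F1 plus the whale-detection FPR."""

    precision: float | None
    recall: float | None
    f1: float | None
    fpr_whale_detection: float | None
    n_water: int
    n_whale: int

    @staticmethod
    def from_confusion(cm: ConfusionMatrix) -> "MetricReport":
        if cm.positive_class != "water":
            cm = cm.swap_positive()
        p, r = precision_recall(cm)
        n_water = cm.tp + cm.fn
        return MetricReport(
            precision=p,
            recall=r,
            f1=f1(p, r),
            fpr_whale_detection=(cm.fn / n_water if n_water else None),
            n_water=n_water,
            n_whale=cm.fp + cm.tn,
        )


def metric_report(cm: ConfusionMatrix) -> MetricReport:
    return MetricReport.from_confusion(cm)


def _cell(value: float | None, digits: int = 3):
    return UNDEFINED if value is None else round(value, digits)


def fold_report(fold_cms: Sequence[ConfusionMatrix]) -> pd.DataFrame:
    """Per-fold table (n water/whale test, precision, recall, F1) with
    min/max/mean summary rows; undefined metrics propagate as markers."""
    if not fold_cms:
        raise ParameterError("need at least one fold")
    rows = []
    for k, cm in enumerate(fold_cms, start=1):
        rep = MetricReport.from_confusion(cm)
        rows.append(
            {
                "fold": str(k),
                "n_water_test": rep.n_water,
                "n_whale_test": rep.n_whale,
                "precision": _cell(rep.precision),
                "recall": _cell(rep.recall),
                "f1": _cell(rep.f1),
            }
        )
    df = pd.DataFrame(rows)
    for stat in ("min", "max", "mean"):
        row = {"fold": stat, "n_water_test": "", "n_whale_test": ""}
        for col in ("precision", "recall", "f1"):
            vals = [v for v in df[col][: len(fold_cms)] if v != UNDEFINED]
            if not vals:
                row[col] = UNDEFINED
            elif stat == "min":
                row[col] = round(min(vals), 3)
            elif stat == "max":
                row[col] = round(max(vals), 3)
            else:
                row[col] = round(sum(vals) / len(vals), 3)
        df.loc[len(df)] = row
    return df


def lr_sweep_report(
    runs: Sequence[tuple[float, MetricReport]]
) -> pd.DataFrame:
    """Learning-rate-sorted precision/recall table with a best-by-F1 marker."""
    if not runs:
        raise ParameterError("need at least one run")
    lrs = [lr for lr, _ in runs]
    if len(set(lrs)) != len(lrs):
        raise ParameterError("duplicate learning-rate entries")
    for _, rep in runs:
        if rep.precision is None:
            raise ParameterError("runs with undefined precision cannot be tabulated")
    runs = sorted(runs, key=lambda t: t[0])
    f1s = [(-1.0 if rep.f1 is None else rep.f1) for _, rep in runs]
    best = max(range(len(runs)), key=lambda i: (f1s[i], -i))
    return pd.DataFrame(
        {
            "learning_rate": [lr for lr, _ in runs],
            "precision": [_cell(rep.precision) for _, rep in runs],
            "recall": [_cell(rep.recall) for _, rep in runs],
            "f1": [_cell(rep.f1) for _, rep in runs],
            "best": [i == best for i in range(len(runs))],
        }
    )
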