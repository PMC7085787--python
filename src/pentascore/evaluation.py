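"""Per-parameter confusion-matrix evaluation against ground truth.

Predicted and true sub-scores are binarized (default: full marks on the
parameter counts as positive) and tallied into TP/FP/FN/TN; sensitivity,
specificity, accuracy and precision are reported as percentages rounded
half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .scoring import MAX_SUBSCORES, ScoreReport
from .synthgen import GroundTruth

PARAMETERS = ("angles", "intersection", "closure", "tremor")


class UndefinedMetricError(ZeroDivisionError):
    """A metric denominator is zero for these counts."""


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metrics:
    """Percentages to two decimals; None where the denominator was zero."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    undefined: tuple[str, ...] = ()


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    frac = Decimal(100 * num) / Decimal(den)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, precision."""
    vals = {
        "sensitivity": _pct(c.tp, c.tp + c.fn),
        "specificity": _pct(c.tn, c.tn + c.fp),
        "accuracy": _pct(c.tp + c.tn, c.total),
        "precision": _pct(c.tp, c.tp + c.fp),
    }
    undefined = tuple(k for k, v in vals.items() if v is None)
    return Metrics(**vals, undefined=undefined)


def evaluate_dataset(
    reports: list[ScoreReport],
    truths: list[GroundTruth],
    positive_rule: str | int = "full",
) -> dict[str, tuple[ConfusionCounts, Metrics]]:
    """Tally per-parameter confusion counts of predictions vs ground truth.

    ``positive_rule``: "full" treats the parameter's maximum sub-score as the
    positive class; an integer level runs one-vs-rest at that score level.
    """
    if len(reports) != len(truths):
        raise ValueError("reports and truths must have equal length")
    out: dict[str, tuple[ConfusionCounts, Metrics]] = {}
    for param in PARAMETERS:
        level = MAX_SUBSCORES[param] if positive_rule == "full" else int(positive_rule)
        tp = fp = fn = tn = 0
        for rep, truth in zip(reports, truths):
            pred = rep.sub_scores[param] == level
            true = truth.sub_scores[param] == level
            if pred and true:
                tp += 1
            elif pred and not true:
                fp += 1
            elif true:
                fn += 1
            else:
                tn += 1
        counts = ConfusionCounts(tp, fp, fn, tn)
        out[param] = (counts, confusion_metrics(counts))
    return out


def evaluation_table(results: dict[str, tuple[ConfusionCounts, Metrics]]) -> pd.DataFrame:
    """One row per parameter: counts and metrics (delimited-friendly)."""
    rows = []
    for param, (c, m) in results.items():
        rows.append(
            {
                "parameter": param,
                "TP": c.tp,
                "FP": c.fp,
                "FN": c.fn,
                "TN": c.tn,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "precision": m.precision,
            }
        )
    return pd.DataFrame(rows)
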