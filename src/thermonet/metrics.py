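"""Diagnostic-test metrics for a binary (sick vs healthy) classifier.

Twelve metrics are computed from raw confusion counts: accuracy (as a
percentage), sensitivity, specificity, precision, negative predictive
value, false-positive and false-negative rates, the positive and negative
likelihood ratios, balanced-accuracy AUC, equal error rate, and F1.  Here
"AUC" denotes the mean of sensitivity and specificity (balanced accuracy),
not the ROC area, and EER is its complement — the convention used in
diagnostic-thermography reporting.

Any metric with a zero denominator is *undefined* and carried as ``None``
(rendered ``NA``), never coerced to zero or infinity.  All arithmetic is
full double precision; rounding happens only at formatting time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "evaluate",
    "confusion_from_predictions",
    "format_report_table",
    "TABLE_COLUMNS",
]

#: Column order of the rendered report table.
TABLE_COLUMNS = [
    "Method", "TP", "TN", "FP", "FN",
    "Accu", "Sen", "Spe", "P", "NPV",
    "FPR", "FNR", "LRP", "LRN", "AUC", "EER", "F1",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts; the sole input to the suite."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Relabel classes: positives become negatives and vice versa."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class MetricReport:
    """The twelve metrics; ``None`` marks an undefined (NA) value.

    ``accuracy`` is a percentage in [0, 100]; ``lrp``/``lrn`` are
    non-negative ratios; every other defined field is a fraction in [0, 1].
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    npv: float | None
    fpr: float | None
    fnr: float | None
    lrp: float | None
    lrn: float | None
    auc: float | None
    eer: float | None
    f1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: float, den: float) -> float | None:
    return num / den if den else None


def evaluate(counts: ConfusionCounts) -> MetricReport:
    """Compute the metric suite from confusion counts.

    Sensitivity = TP/(TP+FN), specificity = TN/(FP+TN), precision =
    TP/(TP+FP), NPV = TN/(TN+FN), FPR = 1 - specificity, FNR = 1 -
    sensitivity, LRP = Sen/(1-Spe), LRN = (1-Sen)/Spe, AUC = (Sen+Spe)/2,
    EER = 1 - AUC, F1 = 2*Sen*P/(Sen+P).  Zero denominators yield ``None``:
    precision is undefined when no positive calls were made, LRP when
    specificity is exactly 1, F1 when precision is undefined or Sen+P = 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, fp + tn)
    prec = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    fpr = None if spe is None else 1.0 - spe
    fnr = None if sen is None else 1.0 - sen
    lrp = None if sen is None or spe is None or spe == 1.0 else sen / (1.0 - spe)
    lrn = None if sen is None or spe is None or spe == 0.0 else (1.0 - sen) / spe
    auc = None if sen is None or spe is None else (sen + spe) / 2.0
    eer = None if auc is None else 1.0 - auc
    f1 = (
        None
        if sen is None or prec is None or (sen + prec) == 0.0
        else 2.0 * sen * prec / (sen + prec)
    )
    return MetricReport(
        accuracy=100.0 * (tp + tn) / counts.total,
        sensitivity=sen,
        specificity=spe,
        precision=prec,
        npv=npv,
        fpr=fpr,
        fnr=fnr,
        lrp=lrp,
        lrn=lrn,
        auc=auc,
        eer=eer,
        f1=f1,
    )


def confusion_from_predictions(
    true_labels: Sequence, predicted_labels: Sequence, positive_label
) -> ConfusionCounts:
    """Tally confusion counts from paired label sequences.

    Every predicted label must appear among the true labels or equal the
    positive label; anything else is treated as an unseen label and
    rejected rather than silently counted.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    if len(true_labels) == 0:
        raise ValueError("label sequences must be non-empty")
    seen = set(true_labels) | {positive_label}
    unseen = set(predicted_labels) - seen
    if unseen:
        raise ValueError(f"predicted labels not seen among true labels: {sorted(map(str, unseen))}")
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _fmt(value: float | None, decimals: int) -> str:
    return "NA" if value is None else f"{value:.{decimals}f}"


def format_report_table(
    reports: Iterable[tuple[str, ConfusionCounts, MetricReport]]
) -> str:
    """Render reports as CSV: accuracy with 2 decimals, other metrics with
    3, undefined cells as ``NA``."""
    rows = []
    for name, counts, report in reports:
        rows.append(
            {
                "Method": name,
                "TP": counts.tp,
                "TN": counts.tn,
                "FP": counts.fp,
                "FN": counts.fn,
                "Accu": _fmt(report.accuracy, 2),
                "Sen": _fmt(report.sensitivity, 3),
                "Spe": _fmt(report.specificity, 3),
                "P": _fmt(report.precision, 3),
                "NPV": _fmt(report.npv, 3),
                "FPR": _fmt(report.fpr, 3),
                "FNR": _fmt(report.fnr, 3),
                "LRP": _fmt(report.lrp, 3),
                "LRN": _fmt(report.lrn, 3),
                "AUC": _fmt(report.auc, 3),
                "EER": _fmt(report.eer, 3),
                "F1": _fmt(report.f1, 3),
            }
        )
    frame = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    return buf.getvalue()


def parse_report_table(csv_text: str) -> pd.DataFrame:
    """Re-read a rendered table, keeping every metric cell as a string so
    the rendering round-trips exactly."""
    return pd.read_csv(io.StringIO(csv_text), dtype=str, keep_default_na=False)
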