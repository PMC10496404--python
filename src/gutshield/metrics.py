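"""Binary-classification performance metrics.

Conventions: the positive class (label 1) is the anti-commensal compound.
TP/TN/FP/FN follow the usual confusion-matrix meaning, so

* SE (sensitivity, recall on positives) = TP / (TP + FN)
* SP (specificity, recall on negatives) = TN / (TN + FP)
* ACC = (TP + TN) / N
* MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
* F1 = 2TP / (2TP + FP + FN)
* AUC = rank-based area under the ROC curve (ties contribute 1/2), i.e. the
  normalized Mann–Whitney U statistic.

Zero-denominator cases yield NaN ("undefined"), never exceptions; NaN always
loses comparisons during model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

METRIC_NAMES = ("SE", "SP", "ACC", "MCC", "F1", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(((yt == 1) & (yp == 1)).sum()),
            TN=int(((yt == 0) & (yp == 0)).sum()),
            FP=int(((yt == 0) & (yp == 1)).sum()),
            FN=int(((yt == 1) & (yp == 0)).sum()),
        )


@dataclass
class MetricsReport:
    """Point values (or fold aggregates) of the six evaluation metrics."""

    SE: float
    SP: float
    ACC: float
    MCC: float
    F1: float
    AUC: float = math.nan
    sd: Optional[dict[str, float]] = None

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Point metrics from a confusion matrix (AUC is left undefined)."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.n == 0:
        raise ValueError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else math.nan
    return MetricsReport(
        SE=_ratio(tp, tp + fn),
        SP=_ratio(tn, tn + fp),
        ACC=_ratio(tp + tn, counts.n),
        MCC=mcc,
        F1=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Tie-aware rank AUC; NaN when only one class is present."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(s)  # average ranks resolve ties as 1/2 credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_predictions(
    y_true: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> MetricsReport:
    """All six metrics from probability scores at a decision threshold."""
    y_pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    report = classification_metrics(ConfusionCounts.from_predictions(y_true, y_pred))
    report.AUC = auc(y_true, scores)
    return report


def aggregate_reports(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Mean ± sd over fold/repeat/split reports (NaN-aware means)."""
    stacked = {m: np.array([r.as_dict()[m] for r in reports], dtype=float) for m in METRIC_NAMES}
    means = {m: float(np.nanmean(v)) if not np.isnan(v).all() else math.nan
             for m, v in stacked.items()}
    sds = {m: float(np.nanstd(v, ddof=1)) if np.isfinite(v).sum() > 1 else 0.0
           for m, v in stacked.items()}
    out = MetricsReport(**{m: means[m] for m in METRIC_NAMES})
    out.sd = sds
    return out


def metric_key(value: float) -> float:
    """Sort key where NaN (undefined) always loses."""
    return -math.inf if math.isnan(value) else value
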