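"""Classification metrics for the toxic / non-toxic task.

Sensitivity (SN) and specificity (SP) are reported as percentages, balanced
accuracy is their mean, and the Matthews correlation coefficient (MCC) is
evaluated from the four confusion cells in closed form:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

Printed values are rounded half-up (2 decimals for percentages, 3 for MCC)
to match how such tables are conventionally typeset; unrounded values are
always carried alongside. :func:`reconstruct_confusion` inverts printed
SN/SP percentages back to the unique integer confusion cells, which lets
published tables be checked arithmetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import math

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricReport:
    """SN/SP/BACC in percent, MCC in [-1, 1], optional AUC in [0, 1].

    `sn`..`mcc` are unrounded; the `rounded` dict carries the half-up
    presentation values. `mcc_degenerate` flags a zero marginal, where MCC
    is reported as 0 by convention.
    """

    sn: float
    sp: float
    bacc: float
    mcc: float
    auc: float | None = None
    mcc_degenerate: bool = False

    @property
    def rounded(self) -> dict[str, float]:
        out = {
            "sn": round_half_up(self.sn, 2),
            "sp": round_half_up(self.sp, 2),
            "bacc": round_half_up(self.bacc, 2),
            "mcc": round_half_up(self.mcc, 3),
        }
        if self.auc is not None:
            out["auc"] = round_half_up(self.auc, 3)
        return out


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count the four confusion cells from binary vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """SN, SP, BACC and MCC from confusion cells."""
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise ValueError("SN/SP undefined: need at least one sample of each class")
    sn = 100.0 * counts.tp / counts.n_pos
    sp = 100.0 * counts.tn / counts.n_neg
    bacc = 0.5 * (sn + sp)
    denom = (
        (counts.tp + counts.fp)
        * (counts.tn + counts.fn)
        * (counts.tp + counts.fn)
        * (counts.tn + counts.fp)
    )
    degenerate = denom == 0
    if degenerate:
        mcc = 0.0
    else:
        mcc = (counts.tp * counts.tn - counts.fp * counts.fn) / math.sqrt(denom)
    return MetricReport(sn=sn, sp=sp, bacc=bacc, mcc=mcc, auc=auc, mcc_degenerate=degenerate)


def evaluate(y_true, y_pred, scores=None) -> MetricReport:
    """Convenience wrapper: confusion cells + metrics (+ AUC when scores given)."""
    area = auc(y_true, scores) if scores is not None else None
    return metrics(confusion_counts(y_true, y_pred), auc=area)


def auc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with mid-ranks for ties."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def roc_points(y_true, scores) -> list[tuple[float, float]]:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(y_true, int), np.asarray(scores, float))
    return list(zip(fpr.tolist(), tpr.tolist()))


def reconstruct_confusion(
    n_pos: int, n_neg: int, sn_pct: float, sp_pct: float
) -> ConfusionCounts:
    """Invert printed SN/SP percentages to the unique integer confusion cells.

    Searches all integer TP in [0, n_pos] (TN in [0, n_neg]) whose percentage
    rounds half-up, at two decimals, to the printed value; errors unless the
    solution is unique.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp_candidates = [
        t for t in range(n_pos + 1) if round_half_up(100.0 * t / n_pos, 2) == sn_pct
    ]
    tn_candidates = [
        t for t in range(n_neg + 1) if round_half_up(100.0 * t / n_neg, 2) == sp_pct
    ]
    if len(tp_candidates) != 1 or len(tn_candidates) != 1:
        raise ValueError(
            f"printed SN/SP do not invert uniquely: TP candidates {tp_candidates}, "
            f"TN candidates {tn_candidates}"
        )
    tp, tn = tp_candidates[0], tn_candidates[0]
    return ConfusionCounts(tp=tp, tn=tn, fp=n_neg - tn, fn=n_pos - tp)
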