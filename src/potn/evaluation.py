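"""Evaluation surfaces: ROC/AUC, partial AUC at a false-positive-rate cap,
confusion metrics, relative improvement, virtual-screening enrichment, and
post-processing of T2 binding-assay fluorescence readouts.

Conventions: the ROC is built by a standard threshold sweep in which tied
scores advance the false- and true-positive rates jointly; the area is
trapezoidal, i.e. the Mann-Whitney concordance probability with half
credit for ties. Partial AUC is reported unnormalized (its maximum equals
the cap); a normalized variant divides by the cap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    """Threshold-sweep ROC: monotone (FPR, TPR) points from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class EvalReport:
    auc: float | None = None
    partial_auc: dict[float, float] | None = None
    accuracy: float | None = None
    precision: float | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    threshold: float | None = None


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skm.roc_curve(labels, np.asarray(scores, dtype=float),
                                drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def partial_auc(curve: RocCurve, fpr_cap: float,
                normalized: bool = False) -> float:
    """Area under the ROC restricted to FPR in [0, cap].

    Linear interpolation of TPR at the cap; the unnormalized maximum is
    the cap itself (a perfect classifier at cap 0.05 scores 0.05).
    """
    if not 0 < fpr_cap <= 1:
        raise ValueError("fpr_cap must be in (0, 1]")
    fpr, tpr = curve.fpr, curve.tpr
    # keep the curve's own points up to the cap (duplicated FPR values
    # mark vertical segments and must not be re-interpolated), then add
    # one linearly interpolated point on the segment crossing the cap
    keep = fpr <= fpr_cap
    f, t = fpr[keep], tpr[keep]
    if f[-1] < fpr_cap:
        t_cap = np.interp(fpr_cap, fpr, tpr)
        f = np.append(f, fpr_cap)
        t = np.append(t, t_cap)
    area = float(np.trapezoid(t, f))
    return area / fpr_cap if normalized else area


def confusion_metrics(scores: Sequence[float], labels: Sequence[int],
                      threshold: float = 0.0) -> EvalReport:
    """Accuracy, precision and the confusion counts at a score threshold.

    Predicted positive iff score > threshold. Precision is undefined
    (NaN, with a warning) when nothing is predicted positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores > threshold
    actual = labels == 1
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    tn = int(np.sum(~pred & ~actual))
    fn = int(np.sum(~pred & actual))
    n = len(labels)
    acc = (tp + tn) / n if n else math.nan
    if tp + fp:
        prec = tp / (tp + fp)
    else:
        logger.warning("no predicted positives; precision undefined")
        prec = math.nan
    return EvalReport(accuracy=acc, precision=prec,
                      tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold)


def evaluate(scores: Sequence[float], labels: Sequence[int],
             threshold: float = 0.0,
             fpr_caps: Sequence[float] = ()) -> EvalReport:
    """Full report: AUC, optional partial AUCs, and threshold metrics."""
    curve = roc_curve(scores, labels)
    report = confusion_metrics(scores, labels, threshold)
    report.auc = auc(curve)
    report.partial_auc = {cap: partial_auc(curve, cap) for cap in fpr_caps}
    return report


def improvement_rate(new_value: float, baseline_value: float,
                     ndigits: int = 2) -> float:
    """Relative improvement over a baseline, as a percentage."""
    if baseline_value <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (new_value - baseline_value) / baseline_value, ndigits)


def enrichment_curve(
    ranked_ids: Sequence[str], active_ids: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Actives recovered as a function of the fraction of the library screened.

    recovery(f) = |actives among the top ceil(f*N)| / |actives|. Returns
    the screened fractions k/N for k = 0..N, the recovery at each, and the
    smallest fraction achieving full recovery.
    """
    ranked = list(ranked_ids)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranking contains duplicates")
    actives = set(active_ids)
    if not actives:
        raise ValueError("active set is empty")
    if not actives.issubset(ranked):
        raise ValueError("every active must appear in the ranking")
    n = len(ranked)
    hits = np.cumsum([pid in actives for pid in ranked])
    recovery = np.concatenate([[0.0], hits / len(actives)])
    fractions = np.arange(n + 1) / n
    full_at = fractions[int(np.argmax(recovery >= 1.0))]
    return fractions, recovery, float(full_at)


def fluorescence_index(a: float, b: float) -> float:
    """FI = (a - b) / b, where a is the mean fluorescence with the peptide
    and b without it (the T2 stabilization readout)."""
    if b <= 0:
        raise ValueError("background fluorescence b must be positive")
    return (a - b) / b


#: FI cut-points for the binding-affinity categories (half-open intervals)
FI_MODERATE = 0.5
FI_HIGH = 1.5


def categorize_binding(fi: float) -> str:
    """weak: FI < 0.5; moderate: 0.5 <= FI < 1.5; high: FI >= 1.5."""
    if not np.isfinite(fi):
        raise ValueError("FI must be finite")
    if fi < FI_MODERATE:
        return "weak"
    if fi < FI_HIGH:
        return "moderate"
    return "high"


def binding_summary(records: pd.DataFrame) -> dict:
    """Categorize a table of binding readouts and summarize the shares.

    Accepts columns ``fi`` or the raw pair ``mfi_with``/``mfi_without``.
    Reports category counts, the share of binders (FI >= 0.5), and the
    high-affinity share among the binders.
    """
    if "fi" in records.columns:
        fi = records["fi"].astype(float)
    else:
        fi = records.apply(
            lambda r: fluorescence_index(r["mfi_with"], r["mfi_without"]),
            axis=1)
    cats = fi.map(categorize_binding)
    counts = {c: int((cats == c).sum()) for c in ("weak", "moderate", "high")}
    n = len(cats)
    binders = counts["moderate"] + counts["high"]
    return {
        "counts": counts,
        "n": n,
        "binder_share": binders / n if n else math.nan,
        "high_share_among_binders":
            counts["high"] / binders if binders else math.nan,
    }
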