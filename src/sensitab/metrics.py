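"""Model evaluation metrics.

Implements the 13-metric evaluation bundle used throughout the pipeline:
accuracy, AUC, average precision, Cohen's kappa, Brier score, F1, Jaccard,
MCC, NPV, precision, sensitivity, specificity and NegLog2RMSL, together
with exact confusion-matrix accounting.

Two scores are bespoke to this pipeline:

* ``neglog2_rmsl`` — the model-selection score: the negative base-2
  logarithm of the root-mean-square loss between predicted probabilities
  and the binary labels.  RMSL of 0.5 (an uninformative constant 0.5
  predictor) scores 1.0; halving the RMSL adds one to the score.
* ``cohen_mcc`` — Cohen's kappa and the Matthews correlation coefficient
  combined into a single chance-corrected agreement score (arithmetic mean
  by default).

The positive class is *sensitive* (label 1).  Probability ties at the
decision threshold classify positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

NEGLOG2_RMSL_EPS = 1e-6

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "metric_suite",
    "neglog2_rmsl",
    "cohen_mcc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with sensitive as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    arr = arr.astype(int)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1")
    return arr


def confusion(labels, predicted_labels) -> ConfusionCounts:
    """Exact confusion counts for binary labels vs binary predictions."""
    y = _as_binary(labels, "labels")
    yhat = _as_binary(predicted_labels, "predicted_labels")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.size} labels vs {yhat.size} predictions")
    return ConfusionCounts(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
    )


def neglog2_rmsl(labels, probabilities, eps: float = NEGLOG2_RMSL_EPS) -> float:
    """Negative log2 of the root-mean-square loss of probabilities vs labels.

    RMSL = sqrt(mean((p - y)^2)) with y in {0, 1}; the score is
    -log2(max(RMSL, eps)), so it is strictly decreasing in RMSL until the
    clamp and higher is better.
    """
    y = _as_binary(labels, "labels")
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    rmsl = float(np.sqrt(np.mean((p - y) ** 2)))
    return float(-np.log2(max(rmsl, eps)))


def _kappa_mcc_from_counts(c: ConfusionCounts):
    """Closed-form kappa and MCC; degenerate marginals give 0 with a flag."""
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    n = tp + fp + tn + fn
    flags = []
    row_pos, row_neg = tp + fn, tn + fp            # actual marginals
    col_pos, col_neg = tp + fp, tn + fn            # predicted marginals
    mcc_denom = row_pos * row_neg * col_pos * col_neg
    if mcc_denom == 0:
        mcc = 0.0
        flags.append("mcc_degenerate")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_denom)
    po = (tp + tn) / n if n else 0.0
    pe = (col_pos * row_pos + col_neg * row_neg) / (n * n) if n else 0.0
    if n == 0 or pe == 1.0:
        kappa = 0.0
        flags.append("kappa_degenerate")
    else:
        kappa = (po - pe) / (1.0 - pe)
    return float(kappa), float(mcc), flags


def cohen_mcc(labels, predicted_labels, combine: str = "mean"):
    """Cohen's kappa, MCC and their combination for binary predictions.

    ``combine`` is ``"mean"`` (arithmetic mean, default) or ``"min"``.
    Degenerate confusion tables (a zero marginal) define the affected
    statistic as 0.
    """
    c = confusion(labels, predicted_labels)
    kappa, mcc, _ = _kappa_mcc_from_counts(c)
    if combine == "mean":
        combined = (kappa + mcc) / 2.0
    elif combine == "min":
        combined = min(kappa, mcc)
    else:
        raise ValueError(f"combine must be 'mean' or 'min', got {combine!r}")
    return kappa, mcc, combined


@dataclass
class MetricReport:
    """The 13-metric evaluation bundle plus confusion counts."""

    accuracy: float
    auc: float
    average_precision: float
    cohen_kappa: float
    brier_score: float
    f1: float
    jaccard: float
    jaccard_macro: float
    mcc: float
    cohen_mcc_combined: float
    npv: float
    precision: float
    sensitivity: float
    specificity: float
    neglog2rmsl: float
    confusion: ConfusionCounts
    decision_threshold: float
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "accuracy", "auc", "average_precision", "cohen_kappa",
                "brier_score", "f1", "jaccard", "jaccard_macro", "mcc",
                "cohen_mcc_combined", "npv", "precision", "sensitivity",
                "specificity", "neglog2rmsl", "decision_threshold",
            )
        }
        d["confusion"] = self.confusion.to_dict()
        d["flags"] = list(self.flags)
        return d

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _safe_div(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(f"{name}_undefined")
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts):
    """Thresholded metrics derived by closed form from confusion counts."""
    flags: list = []
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    n = c.total
    out = {
        "accuracy": _safe_div(tp + tn, n, flags, "accuracy"),
        "precision": _safe_div(tp, tp + fp, flags, "precision"),
        "sensitivity": _safe_div(tp, tp + fn, flags, "sensitivity"),
        "specificity": _safe_div(tn, tn + fp, flags, "specificity"),
        "npv": _safe_div(tn, tn + fn, flags, "npv"),
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn, flags, "f1"),
        "jaccard": _safe_div(tp, tp + fp + fn, flags, "jaccard"),
    }
    jac_neg = _safe_div(tn, tn + fn + fp, flags, "jaccard_negative")
    out["jaccard_macro"] = (out["jaccard"] + jac_neg) / 2.0
    kappa, mcc, km_flags = _kappa_mcc_from_counts(c)
    out["cohen_kappa"] = kappa
    out["mcc"] = mcc
    out["cohen_mcc_combined"] = (kappa + mcc) / 2.0
    flags.extend(km_flags)
    return out, flags


def metric_suite(labels, probabilities, threshold: float = 0.5) -> MetricReport:
    """Full evaluation of probabilistic predictions against binary labels.

    Thresholded metrics come from confusion counts at ``threshold``
    (probability ties classify positive); AUC and average precision use the
    probability ranking; the Brier score is the mean squared difference
    between the probability and the 0/1 label.  On a single-class label
    vector AUC and average precision are undefined and flagged, with the
    remainder still computed.
    """
    y = _as_binary(labels, "labels")
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(p).all():
        raise ValueError("probabilities must be finite")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    predicted = (p >= threshold).astype(int)
    c = confusion(y, predicted)
    thresholded, flags = metrics_from_counts(c)
    if len(np.unique(y)) < 2:
        auc, ap = 0.0, 0.0
        flags.extend(["auc_undefined", "average_precision_undefined"])
    else:
        auc = float(roc_auc_score(y, p))
        ap = float(average_precision_score(y, p))
    return MetricReport(
        auc=auc,
        average_precision=ap,
        brier_score=float(np.mean((p - y) ** 2)),
        neglog2rmsl=neglog2_rmsl(y, p),
        confusion=c,
        decision_threshold=float(threshold),
        flags=flags,
        **thresholded,
    )
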