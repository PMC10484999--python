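"""Held-out evaluation, repeated cross-validation and cohort prediction.

``repeated_kfold`` runs the full training recipe (resampling, optional
hyperparameter search, model fitting) inside each fold's training portion
and scores the untouched fold test portion, for ``repeats`` independent
stratified k-fold partitions.  Each fold's train/test sample ids are kept
in an audit trail so leakage is checkable after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import LabeledDataset, ExpressionMatrix, SamplingPlan, resample
from .metrics import MetricReport, metric_suite
from .model import EncoderState, FittedModel, HyperParams, fit, predict_proba
from .search import SearchSpec, optimize

__all__ = [
    "CVResult",
    "CohortPrediction",
    "repeated_kfold",
    "evaluate_holdout",
    "predict_cohort",
]

_SUMMARY_METRICS = ("auc", "accuracy", "f1", "mcc", "cohen_kappa",
                    "neglog2rmsl", "sensitivity", "specificity")


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    report: MetricReport
    train_ids: list
    test_ids: list


@dataclass
class CVResult:
    """Per-fold metric reports plus distribution summaries."""

    records: list            # list[FoldRecord]
    k: int
    repeats: int
    seed: int
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            frame = self.to_frame()
            self.summary = {
                m: {"mean": float(frame[m].mean()), "sd": float(frame[m].std(ddof=1)),
                    "min": float(frame[m].min()), "max": float(frame[m].max())}
                for m in _SUMMARY_METRICS
            }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"repeat": r.repeat, "fold": r.fold}
            row.update({k: v for k, v in r.report.to_dict().items()
                        if isinstance(v, (int, float))})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def audit(self) -> list:
        """(repeat, fold, train_ids, test_ids) tuples for leakage checks."""
        return [(r.repeat, r.fold, list(r.train_ids), list(r.test_ids))
                for r in self.records]


@dataclass
class CohortPrediction:
    """Per-sample sensitivity calls over a prediction cohort."""

    sample_ids: list
    probabilities: np.ndarray
    calls: list                      # "sensitive" / "resistant"
    decision_threshold: float

    @property
    def counts(self) -> dict:
        return {
            "sensitive": sum(c == "sensitive" for c in self.calls),
            "resistant": sum(c == "resistant" for c in self.calls),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "probability": self.probabilities,
            "call": self.calls,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def class_lists(self) -> dict:
        """Sample-id lists per call, ranked by probability (enrichment-ready)."""
        frame = self.to_frame()
        return {
            "sensitive": frame[frame["call"] == "sensitive"]
            .sort_values("probability", ascending=False)["sample_id"].tolist(),
            "resistant": frame[frame["call"] == "resistant"]
            .sort_values("probability")["sample_id"].tolist(),
        }


def _fit_fold(train: LabeledDataset, val: LabeledDataset,
              sampling: SamplingPlan, search_spec: SearchSpec | None,
              hp: HyperParams, encoder: EncoderState | None,
              fold_seed: int):
    """Training recipe applied inside one fold's training portion."""
    plan = SamplingPlan(sampling.strategy, seed=fold_seed)
    resampled = resample(train, plan)
    if search_spec is not None and search_spec.method != "hardcoded":
        result = optimize(resampled, search_spec, encoder)
        chosen = result.best_hyperparams
    else:
        chosen = hp
    chosen = HyperParams.from_dict({**chosen.to_dict(), "seed": fold_seed})
    return fit(resampled, chosen, encoder=encoder, validation=val)


def repeated_kfold(
    d: LabeledDataset,
    k: int = 5,
    repeats: int = 20,
    hp: HyperParams | None = None,
    sampling: SamplingPlan | None = None,
    search_spec: SearchSpec | None = None,
    encoder: EncoderState | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the full recipe.

    For every repeat a fresh stratified partition is drawn; within each
    fold, resampling and (optional) hyperparameter search run on the
    training portion only and the fold's test portion is scored untouched.
    Returns exactly ``k * repeats`` records.
    """
    hp = hp or HyperParams()
    sampling = sampling or SamplingPlan("none")
    counts = d.class_counts()
    if min(counts.values()) < k:
        raise ValueError(
            f"every class needs >= k={k} samples for stratified folds; have {counts}")
    rng = np.random.default_rng(seed)
    records = []
    for repeat in range(repeats):
        repeat_seed = int(rng.integers(2**31))
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=repeat_seed)
        for fold, (tr_idx, te_idx) in enumerate(splitter.split(d.features, d.labels)):
            train = d.subset(tr_idx)
            test = d.subset(te_idx)
            fold_seed = int(np.random.default_rng(repeat_seed + fold).integers(2**31))
            # early-stopping validation is carved from the fold's training
            # portion; the fold test set stays untouched until scoring
            model = _fit_fold_with_internal_val(
                train, sampling, search_spec, hp, encoder, fold_seed)
            p = predict_proba(model, test)
            report = metric_suite(test.labels, p, threshold=threshold)
            records.append(FoldRecord(repeat, fold, report,
                                      model.metadata["training_sample_ids"],
                                      list(test.sample_ids)))
    return CVResult(records=records, k=k, repeats=repeats, seed=seed)


def _fit_fold_with_internal_val(train, sampling, search_spec, hp, encoder, fold_seed):
    from sklearn.model_selection import train_test_split

    counts = train.class_counts()
    if min(counts.values()) >= 4:
        tr_idx, va_idx = train_test_split(
            np.arange(train.n_samples), test_size=0.2,
            random_state=fold_seed % (2**31), stratify=train.labels)
        inner_train, inner_val = train.subset(tr_idx), train.subset(va_idx)
    else:
        inner_train, inner_val = train, None
    model = _fit_fold(inner_train, inner_val, sampling or SamplingPlan("none"),
                      search_spec, hp or HyperParams(), encoder, fold_seed)
    # the audit must cover everything the fold's training phase saw
    seen = set(model.metadata["training_sample_ids"]) | set(train.sample_ids)
    model.metadata["training_sample_ids"] = sorted(seen)
    return model


def evaluate_holdout(m: FittedModel, test: LabeledDataset,
                     threshold: float | None = None) -> MetricReport:
    """Score a fitted model on an untouched test set (13 metrics + counts).

    Rejects evaluation if any test id appears in the model's recorded
    training ids (leakage guard).
    """
    trained_on = set(m.metadata.get("training_sample_ids", []))
    overlap = trained_on & set(test.sample_ids)
    if overlap:
        raise ValueError(f"test ids overlap the model's training ids: {sorted(overlap)}")
    p = predict_proba(m, test)
    return metric_suite(test.labels, p,
                        threshold=m.decision_threshold if threshold is None else threshold)


def predict_cohort(m: FittedModel, cohort: ExpressionMatrix,
                   threshold: float = 0.5) -> CohortPrediction:
    """Call each cohort sample sensitive/resistant at the given threshold.

    The cohort must already be normalized with the model's training stats.
    Samples at exactly the threshold are called sensitive.
    """
    p = predict_proba(m, cohort)
    calls = ["sensitive" if pi >= threshold else "resistant" for pi in p]
    return CohortPrediction(
        sample_ids=list(cohort.sample_ids),
        probabilities=p,
        calls=calls,
        decision_threshold=threshold,
    )
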