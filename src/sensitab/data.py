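"""Expression-matrix and drug-response handling.

Loading, high-variance gene selection, min-max normalization, IC50
binarization into sensitive/resistant labels, train/test splitting and the
tripartite (none/over/under) training-set resampling strategy.

Conventions
-----------
* Matrices are samples x genes internally; loaders normalize orientation.
* The positive class is *sensitive* (label 1); resistant is 0.
* Sensitivity rule: IC50 strictly below the threshold (default 500 nM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

SENSITIVE = 1
RESISTANT = 0
DEFAULT_IC50_THRESHOLD_NM = 500.0

__all__ = [
    "ExpressionMatrix",
    "DrugResponseTable",
    "LabeledDataset",
    "SamplingPlan",
    "NormalizationStats",
    "load_expression",
    "load_responses",
    "select_top_variance_genes",
    "minmax_normalize",
    "binarize_response",
    "split_train_test",
    "resample",
]


def _check_unique(ids, what: str) -> None:
    seen: dict = {}
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen[i] = True


@dataclass
class ExpressionMatrix:
    """A samples x genes matrix of finite expression values."""

    sample_ids: list
    gene_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(list(self.sample_ids), list(genes), self.values[:, cols].copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        rows = [index[s] for s in samples]
        return ExpressionMatrix(list(samples), list(self.gene_ids), self.values[rows].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def to_csv(self, path, orientation: str = "samples_as_rows", sep: str = ",") -> None:
        df = self.to_dataframe()
        if orientation == "genes_as_rows":
            df = df.T
        elif orientation != "samples_as_rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        df.to_csv(path, sep=sep)


@dataclass
class DrugResponseTable:
    """Per-(sample, drug) IC50 values in nM."""

    table: pd.DataFrame  # columns: sample_id, drug, ic50_nM

    def __post_init__(self) -> None:
        required = {"sample_id", "drug", "ic50_nM"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"response table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["ic50_nM"] = pd.to_numeric(t["ic50_nM"], errors="raise").astype(float)
        if (t["ic50_nM"] <= 0).any() or not np.isfinite(t["ic50_nM"]).all():
            bad = t.loc[~(t["ic50_nM"] > 0) | ~np.isfinite(t["ic50_nM"]), "sample_id"].tolist()
            raise ValueError(f"IC50 must be positive and finite; offending samples: {bad}")
        dup = t.duplicated(subset=["sample_id", "drug"])
        if dup.any():
            pairs = t.loc[dup, ["sample_id", "drug"]].itertuples(index=False)
            raise ValueError(f"duplicate (sample, drug) pairs: {[tuple(p) for p in pairs]}")
        self.table = t.reset_index(drop=True)

    def ic50_for(self, drug: str, sample_ids) -> pd.Series:
        sub = self.table[self.table["drug"] == drug].set_index("sample_id")["ic50_nM"]
        missing = [s for s in sample_ids if s not in sub.index]
        if missing:
            raise KeyError(f"samples without an IC50 for drug {drug!r}: {missing}")
        return sub.loc[list(sample_ids)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class LabeledDataset:
    """Normalized features in [0, 1] paired with binary sensitivity labels."""

    sample_ids: list
    gene_ids: list
    features: np.ndarray
    labels: np.ndarray  # 1 = sensitive, 0 = resistant

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        _check_unique(self.gene_ids, "gene")
        if self.features.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("feature matrix shape does not match id lists")
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("label vector length does not match sample count")
        if self.features.size and (self.features.min() < -1e-12 or self.features.max() > 1 + 1e-12):
            raise ValueError("features must lie within [0, 1]; normalize first")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = resistant, 1 = sensitive)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def class_counts(self) -> dict:
        return {
            "sensitive": int((self.labels == SENSITIVE).sum()),
            "resistant": int((self.labels == RESISTANT).sum()),
        }

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        ids = [self.sample_ids[i] for i in indices]
        # Resampling may duplicate ids; suffix clones so ids stay unique.
        seen: dict = {}
        out_ids = []
        for s in ids:
            if s in seen:
                seen[s] += 1
                out_ids.append(f"{s}__dup{seen[s]}")
            else:
                seen[s] = 0
                out_ids.append(s)
        return LabeledDataset(out_ids, list(self.gene_ids), self.features[indices].copy(), self.labels[indices].copy())


@dataclass(frozen=True)
class SamplingPlan:
    """One leg of the tripartite sampling strategy: none, over or under."""

    strategy: str = "none"
    seed: int = 0

    STRATEGIES = ("none", "over", "under")

    def __post_init__(self) -> None:
        if self.strategy not in self.STRATEGIES:
            raise ValueError(f"strategy must be one of {self.STRATEGIES}, got {self.strategy!r}")


@dataclass
class NormalizationStats:
    """Per-gene min/max fitted on one matrix, applicable to another."""

    gene_ids: list
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if len(self.gene_ids) != self.mins.size or self.mins.size != self.maxs.size:
            raise ValueError("stats arrays must match gene list length")

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(list(d["gene_ids"]), np.asarray(d["mins"]), np.asarray(d["maxs"]))


def load_expression(path, orientation: str = "samples_as_rows", sep=None) -> ExpressionMatrix:
    """Read a delimited expression table into samples x genes orientation.

    The first column holds row identifiers and the header row column
    identifiers.  ``orientation`` declares what the file's rows mean;
    gzip-compressed files are accepted transparently.
    """
    if orientation not in ("samples_as_rows", "genes_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    # pandas silently renames duplicate header entries; check the raw header
    raw_header = pd.read_csv(path, sep=sep, engine="python", header=None,
                             nrows=1).iloc[0, 1:].astype(str)
    what_cols = "gene" if orientation == "samples_as_rows" else "sample"
    dupes = raw_header[raw_header.duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate {what_cols} identifier: {dupes.iloc[0]!r}")
    if df.index.duplicated().any():
        first = df.index[df.index.duplicated()][0]
        what_rows = "sample" if orientation == "samples_as_rows" else "gene"
        raise ValueError(f"duplicate {what_rows} identifier: {first!r}")
    if orientation == "genes_as_rows":
        df = df.T
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError):
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}: "
                        f"{df.iat[i, j]!r}"
                    ) from None
        raise
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def load_responses(path) -> DrugResponseTable:
    """Read a CSV with columns sample_id, drug, ic50_nM."""
    return DrugResponseTable(pd.read_csv(path))


def select_top_variance_genes(x: ExpressionMatrix, k: int):
    """Rank genes by per-gene variance (descending) and return the top ``k``.

    Ties are broken lexicographically on gene id so the selection is
    deterministic.  Asking for more genes than exist returns all of them
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    variances = x.values.var(axis=0, ddof=0)
    order = sorted(range(x.n_genes), key=lambda j: (-variances[j], x.gene_ids[j]))
    if k > x.n_genes:
        warnings.warn(
            f"requested {k} genes but matrix has only {x.n_genes}; returning all",
            stacklevel=2,
        )
        k = x.n_genes
    return [x.gene_ids[j] for j in order[:k]]


def minmax_normalize(x: ExpressionMatrix, fitted_stats: NormalizationStats | None = None):
    """Scale each gene to [0, 1] via (v - min) / (max - min).

    With ``fitted_stats`` (e.g. from training data) the supplied min/max are
    applied and out-of-range results are clipped into [0, 1]; genes that are
    constant in the fitting data map to 0 everywhere.  Returns the
    normalized matrix and the stats used.
    """
    if fitted_stats is None:
        stats = NormalizationStats(
            list(x.gene_ids), x.values.min(axis=0), x.values.max(axis=0)
        )
    else:
        index = {g: j for j, g in enumerate(fitted_stats.gene_ids)}
        missing = [g for g in x.gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from supplied normalization stats: {missing}")
        cols = [index[g] for g in x.gene_ids]
        stats = NormalizationStats(list(x.gene_ids), fitted_stats.mins[cols], fitted_stats.maxs[cols])
    span = stats.maxs - stats.mins
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = (x.values - stats.mins) / span
    normalized[:, span == 0] = 0.0
    normalized = np.clip(normalized, 0.0, 1.0)
    return ExpressionMatrix(list(x.sample_ids), list(x.gene_ids), normalized), stats


def binarize_response(
    responses: DrugResponseTable,
    drug: str,
    sample_ids,
    threshold_nM: float = DEFAULT_IC50_THRESHOLD_NM,
) -> np.ndarray:
    """Label samples sensitive (1) iff IC50 < threshold, else resistant (0).

    The inequality is strict: a sample sitting exactly at the threshold is
    resistant.
    """
    if threshold_nM <= 0:
        raise ValueError("threshold must be positive")
    ic50 = responses.ic50_for(drug, sample_ids)
    return (ic50.to_numpy() < threshold_nM).astype(int)


def make_labeled(
    x: ExpressionMatrix,
    responses: DrugResponseTable,
    drug: str,
    threshold_nM: float = DEFAULT_IC50_THRESHOLD_NM,
) -> LabeledDataset:
    """Pair a normalized matrix with IC50-derived labels."""
    labels = binarize_response(responses, drug, x.sample_ids, threshold_nM)
    return LabeledDataset(list(x.sample_ids), list(x.gene_ids), x.values, labels)


def split_train_test(
    d: LabeledDataset,
    test_fraction: float,
    seed: int,
    stratified: bool = True,
):
    """Deterministically partition samples into disjoint train and test sets."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = d.class_counts()
    if min(counts.values()) < 1:
        raise ValueError("both classes must be present before splitting")
    if stratified and min(counts.values()) < 2:
        raise ValueError(
            f"stratified split needs >= 2 samples per class, have {counts}"
        )
    idx = np.arange(d.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=d.labels if stratified else None,
        shuffle=True,
    )
    return d.subset(np.sort(train_idx)), d.subset(np.sort(test_idx))


def resample(train: LabeledDataset, plan: SamplingPlan) -> LabeledDataset:
    """Apply one tripartite sampling strategy to a *training* split.

    ``none`` is the identity; ``over`` grows the minority class to the
    majority count by duplication with replacement (duplicates get suffixed
    ids so they are identifiable); ``under`` randomly discards majority
    samples down to the minority count.  Test data must never pass through
    this function — that contract is the caller's.
    """
    counts = train.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"resampling requires both classes; have {counts}")
    if plan.strategy == "none":
        return train
    rng = np.random.default_rng(plan.seed)
    idx_pos = np.flatnonzero(train.labels == SENSITIVE)
    idx_neg = np.flatnonzero(train.labels == RESISTANT)
    minority, majority = (idx_pos, idx_neg) if len(idx_pos) <= len(idx_neg) else (idx_neg, idx_pos)
    if plan.strategy == "over":
        extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
        keep = np.concatenate([np.arange(train.n_samples), extra])
    else:  # under
        kept_majority = rng.choice(majority, size=len(minority), replace=False)
        keep = np.sort(np.concatenate([minority, kept_majority]))
    return train.subset(keep)
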