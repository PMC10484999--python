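"""Hyperparameter-search orchestration.

Four strategies share one surface: ``hardcoded`` (score the pre-defined
configuration once), ``grid`` (exhaustive enumeration of an enumerable
space), ``bayes`` (Gaussian-process surrogate with expected-improvement
acquisition) and ``tpe`` (tree-structured Parzen estimator: kernel-density
models of good vs bad trials).  The ``superior`` mode runs all four with
independently derived seeds and keeps the winner.

Candidates are scored by inner-validation NegLog2RMSL computed entirely
inside the training split (stratified k-fold by default), so held-out test
data can never leak into model selection; every sample id seen during a
search is recorded in an audit log.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import LabeledDataset
from .metrics import neglog2_rmsl
from .model import EncoderState, HyperParams, fit, predict_proba

SEARCH_METHODS = ("bayes", "grid", "tpe", "hardcoded", "superior")
# Tie-break preference order: simplest machinery first.
_TIE_ORDER = ("hardcoded", "grid", "bayes", "tpe")

_INT_FIELDS = {"decision_width", "attention_width", "n_decision_steps",
               "batch_size", "max_epochs", "early_stop_patience"}

DEFAULT_SPACE = {
    "decision_width": [8, 16, 32],
    "attention_width": [8, 16, 32],
    "n_decision_steps": [3, 5],
    "learning_rate": ("log", 1e-3, 2e-2),
}

__all__ = [
    "SearchSpec",
    "SearchResult",
    "optimize",
    "superior_search",
    "DEFAULT_SPACE",
]


@dataclass
class SearchSpec:
    """What to search, how, and with what budget.

    ``space`` maps HyperParams field names to either a list of grid values
    or a range tuple ``("log"|"linear", low, high)``.  ``budget`` is the
    number of candidate evaluations per method.
    """

    method: str = "hardcoded"
    space: dict = field(default_factory=dict)
    budget: int = 20
    inner_validation: str = "k_fold"
    inner_k: int = 3
    inner_holdout_fraction: float = 0.25
    hardcoded: HyperParams = field(default_factory=HyperParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in SEARCH_METHODS:
            raise ValueError(f"method must be one of {SEARCH_METHODS}")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.inner_validation not in ("k_fold", "holdout"):
            raise ValueError("inner_validation must be 'k_fold' or 'holdout'")
        valid = set(HyperParams().to_dict())
        unknown = set(self.space) - valid
        if unknown:
            raise ValueError(f"space keys are not HyperParams fields: {sorted(unknown)}")


@dataclass
class MethodRow:
    """One executed (or failed) search strategy."""

    method: str
    best_params: HyperParams | None
    score: float
    evaluations: int
    wall_time_s: float
    error: str | None = None


@dataclass
class SearchResult:
    best_hyperparams: HyperParams
    winning_method: str
    table: list = field(default_factory=list)          # list[MethodRow]
    trace: list = field(default_factory=list)          # per-candidate records
    audit_sample_ids: set = field(default_factory=set)

    def table_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"method": r.method, "score": r.score, "evaluations": r.evaluations,
              "wall_time_s": r.wall_time_s, "error": r.error,
              **({f"param_{k}": v for k, v in r.best_params.to_dict().items()}
                 if r.best_params else {})}
             for r in self.table]
        )

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


class _InnerScorer:
    """Scores a candidate configuration inside the training split only."""

    def __init__(self, train: LabeledDataset, spec: SearchSpec,
                 encoder: EncoderState | None):
        self.train = train
        self.spec = spec
        self.encoder = encoder
        self.audit: set = set(train.sample_ids)

    def __call__(self, hp: HyperParams) -> float:
        d, spec = self.train, self.spec
        scores = []
        if spec.inner_validation == "k_fold":
            k = min(spec.inner_k, min(d.class_counts().values()))
            if k < 2:
                raise ValueError("inner k-fold needs >= 2 samples per class")
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
            folds = splitter.split(d.features, d.labels)
        else:
            tr, va = train_test_split(
                np.arange(d.n_samples), test_size=spec.inner_holdout_fraction,
                random_state=spec.seed, stratify=d.labels)
            folds = [(tr, va)]
        for tr_idx, va_idx in folds:
            inner_train = d.subset(tr_idx)
            inner_val = d.subset(va_idx)
            model = fit(inner_train, hp, encoder=self.encoder, validation=inner_val)
            p = predict_proba(model, inner_val)
            scores.append(neglog2_rmsl(inner_val.labels, p))
        return float(np.mean(scores))


def _is_range(entry) -> bool:
    return isinstance(entry, tuple) and len(entry) == 3 and entry[0] in ("log", "linear")


def _resolve(spec: SearchSpec, assignment: dict) -> HyperParams:
    base = spec.hardcoded.to_dict()
    for k, v in assignment.items():
        if k in _INT_FIELDS or k == "seed":
            base[k] = int(round(v))
        else:
            base[k] = float(v)
    return HyperParams.from_dict(base)


def _sample_assignment(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for key, entry in space.items():
        if _is_range(entry):
            kind, lo, hi = entry
            if kind == "log":
                out[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                out[key] = float(rng.uniform(lo, hi))
        else:
            out[key] = entry[rng.integers(len(entry))]
    return out


def _encode(space: dict, assignment: dict) -> np.ndarray:
    """Map an assignment into [0, 1]^D for the GP surrogate."""
    coords = []
    for key in sorted(space):
        entry = space[key]
        v = assignment[key]
        if _is_range(entry):
            kind, lo, hi = entry
            if kind == "log":
                coords.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
            else:
                coords.append((v - lo) / (hi - lo))
        else:
            coords.append(list(entry).index(v) / max(len(entry) - 1, 1))
    return np.asarray(coords)


def _run_hardcoded(scorer, spec, rng, trace, method="hardcoded"):
    hp = spec.hardcoded
    score = scorer(hp)
    trace.append({"method": method, "candidate": 0, "score": score, **hp.to_dict()})
    return hp, score, 1


def _run_grid(scorer, spec, rng, trace):
    enumerable = {k: v for k, v in spec.space.items() if not _is_range(v)}
    if spec.method == "grid" and enumerable.keys() != spec.space.keys():
        ranges = sorted(set(spec.space) - set(enumerable))
        raise ValueError(f"grid search needs an enumerable space; ranges: {ranges}")
    # under "superior", continuous dimensions stay at their hardcoded values
    keys = sorted(enumerable)
    points = list(itertools.product(*(enumerable[k] for k in keys)))
    if not points and spec.method == "superior":
        points = [()]
    if not points:
        raise ValueError("grid search over an empty space")
    points = points[: spec.budget] if spec.budget < len(points) else points
    best_hp, best_score = None, -np.inf
    for i, values in enumerate(points):
        hp = _resolve(spec, dict(zip(keys, values)))
        score = scorer(hp)
        trace.append({"method": "grid", "candidate": i, "score": score, **hp.to_dict()})
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp, best_score, len(points)


def _run_random_seeded(scorer, spec, rng, trace, method, n, observed):
    """Shared random-exploration phase for the surrogate strategies."""
    best_hp, best_score = None, -np.inf
    for i in range(n):
        assignment = _sample_assignment(spec.space, rng)
        hp = _resolve(spec, assignment)
        score = scorer(hp)
        observed.append((assignment, score))
        trace.append({"method": method, "candidate": i, "score": score, **hp.to_dict()})
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp, best_score


def _run_bayes(scorer, spec, rng, trace):
    """GP-surrogate search with expected-improvement acquisition."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm

    if not spec.space:
        raise ValueError("bayes search over an empty space")
    observed: list = []
    n_init = min(max(3, spec.budget // 3), spec.budget)
    best_hp, best_score = _run_random_seeded(
        scorer, spec, rng, trace, "bayes", n_init, observed)
    for i in range(n_init, spec.budget):
        X = np.array([_encode(spec.space, a) for a, _ in observed])
        y = np.array([s for _, s in observed])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), alpha=1e-6, normalize_y=True,
            random_state=int(rng.integers(2**31)))
        gp.fit(X, y)
        candidates = [_sample_assignment(spec.space, rng) for _ in range(64)]
        Xc = np.array([_encode(spec.space, a) for a in candidates])
        mu, sd = gp.predict(Xc, return_std=True)
        improve = mu - y.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, improve / sd, 0.0)
        ei = np.where(sd > 0, improve * norm.cdf(z) + sd * norm.pdf(z),
                      np.maximum(improve, 0.0))
        assignment = candidates[int(np.argmax(ei))]
        hp = _resolve(spec, assignment)
        score = scorer(hp)
        observed.append((assignment, score))
        trace.append({"method": "bayes", "candidate": i, "score": score, **hp.to_dict()})
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp, best_score, spec.budget


def _tpe_density(values, entry, at):
    """Per-dimension density of observed values evaluated at candidates."""
    if _is_range(entry):
        kind, lo, hi = entry
        tf = np.log if kind == "log" else np.asarray
        pts = np.asarray([tf(v) for v in values], dtype=float)
        at = np.asarray([tf(v) for v in at], dtype=float)
        if pts.size < 2 or np.ptp(pts) == 0:
            return np.ones_like(at)
        return gaussian_kde(pts)(at)
    # categorical: Laplace-smoothed frequencies
    choices = list(entry)
    counts = np.array([sum(v == c for v in values) for c in choices], float) + 1.0
    freq = counts / counts.sum()
    return np.array([freq[choices.index(v)] for v in at])


def _run_tpe(scorer, spec, rng, trace):
    """Tree-structured Parzen estimator over the search space."""
    if not spec.space:
        raise ValueError("tpe search over an empty space")
    observed: list = []
    n_init = min(max(3, spec.budget // 3), spec.budget)
    best_hp, best_score = _run_random_seeded(
        scorer, spec, rng, trace, "tpe", n_init, observed)
    for i in range(n_init, spec.budget):
        scores = np.array([s for _, s in observed])
        n_good = max(1, int(np.ceil(0.25 * len(observed))))
        good_idx = np.argsort(scores)[::-1][:n_good]
        good = [observed[j][0] for j in good_idx]
        bad = [observed[j][0] for j in range(len(observed)) if j not in set(good_idx)]
        candidates = [_sample_assignment(spec.space, rng) for _ in range(24)]
        ratio = np.ones(len(candidates))
        for key, entry in spec.space.items():
            at = [c[key] for c in candidates]
            lg = _tpe_density([g[key] for g in good], entry, at)
            lb = (_tpe_density([b[key] for b in bad], entry, at)
                  if bad else np.ones(len(candidates)))
            ratio *= (lg + 1e-12) / (lb + 1e-12)
        assignment = candidates[int(np.argmax(ratio))]
        hp = _resolve(spec, assignment)
        score = scorer(hp)
        observed.append((assignment, score))
        trace.append({"method": "tpe", "candidate": i, "score": score, **hp.to_dict()})
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp, best_score, spec.budget


_RUNNERS = {
    "hardcoded": _run_hardcoded,
    "grid": _run_grid,
    "bayes": _run_bayes,
    "tpe": _run_tpe,
}


def _pick_winner(rows: list, n_features: int) -> MethodRow:
    scored = [r for r in rows if r.error is None]
    if not scored:
        raise RuntimeError("every search strategy failed: "
                           + "; ".join(f"{r.method}: {r.error}" for r in rows))
    best_score = max(r.score for r in scored)
    tied = [r for r in scored if r.score == best_score]
    tied.sort(key=lambda r: (r.best_params.n_parameters(n_features),
                             _TIE_ORDER.index(r.method)))
    return tied[0]


def optimize(train: LabeledDataset, spec: SearchSpec,
             encoder: EncoderState | None = None) -> SearchResult:
    """Run one search strategy (or all four for ``superior``) on training data.

    Only the training split is visible here; candidate scores are inner-
    validation NegLog2RMSL.  The result's audit log lists every sample id
    the search touched.
    """
    if min(train.class_counts().values()) == 0:
        raise ValueError("search requires both classes in the training data")
    if spec.method != "hardcoded" and spec.method != "superior" and not spec.space:
        raise ValueError(f"method {spec.method!r} requires a non-empty space")
    methods = list(_TIE_ORDER) if spec.method == "superior" else [spec.method]
    if spec.method == "superior" and not spec.space:
        raise ValueError("superior search requires a non-empty space")
    scorer = _InnerScorer(train, spec, encoder)
    rows, trace = [], []
    seed_rng = np.random.default_rng(spec.seed)
    for method in methods:
        method_seed = int(seed_rng.integers(2**31))
        rng = np.random.default_rng(method_seed)
        t0 = time.perf_counter()
        try:
            best_hp, best_score, n_evals = _RUNNERS[method](scorer, spec, rng, trace)
            rows.append(MethodRow(method, best_hp, best_score, n_evals,
                                  time.perf_counter() - t0))
        except Exception as exc:
            if spec.method != "superior":
                raise
            rows.append(MethodRow(method, None, -np.inf, 0,
                                  time.perf_counter() - t0, error=str(exc)))
    winner = _pick_winner(rows, train.n_genes)
    return SearchResult(
        best_hyperparams=winner.best_params,
        winning_method=winner.method,
        table=rows,
        trace=trace,
        audit_sample_ids=set(scorer.audit),
    )


def superior_search(train: LabeledDataset, spec: SearchSpec,
                    encoder: EncoderState | None = None) -> SearchResult:
    """Run hardcoded, grid, bayes and tpe and keep the NegLog2RMSL winner."""
    if spec.method != "superior":
        raise ValueError("superior_search requires spec.method == 'superior'")
    return optimize(train, spec, encoder)
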