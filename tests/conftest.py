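import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from sensitab.data import (
    LabeledDataset,
    make_labeled,
    minmax_normalize,
    split_train_test,
)
from sensitab.model import HyperParams, fit, predict_proba
from sensitab.simdata import make_pharmacogenomic


@pytest.fixture(scope="session")
def small_cohort():
    """A compact separable cohort shared by the cheaper tests."""
    return make_pharmacogenomic(
        n_sensitive=60, n_resistant=60, n_genes=50, n_informative=5,
        effect_size=3.0, n_unlabeled=40, seed=7,
    )


@pytest.fixture(scope="session")
def small_labeled(small_cohort) -> LabeledDataset:
    annotated, responses, _, _ = small_cohort
    norm, _ = minmax_normalize(annotated)
    return make_labeled(norm, responses, "venetoclax")


@pytest.fixture(scope="session")
def imbalanced_labeled() -> LabeledDataset:
    """10 resistant / 3 sensitive, for resampling-count arithmetic."""
    rng = np.random.default_rng(0)
    features = rng.random((13, 4))
    labels = np.array([1, 1, 1] + [0] * 10)
    return LabeledDataset([f"s{i}" for i in range(13)],
                          [f"g{j}" for j in range(4)], features, labels)


def benchmark_holdout_auc(
    seed: int,
    effect_size: float = 3.0,
    n_per_class: int = 150,
    n_genes: int = 200,
    n_informative: int = 10,
    shuffle_labels: bool = False,
    drop_informative: bool = False,
    max_epochs: int = 40,
) -> float:
    """Held-out AUC of the standard synthetic benchmark for one seed.

    Generates a cohort, splits off a held-out test set, trains the gated
    tabular network with an internal early-stopping split, and scores the
    untouched test set.
    """
    annotated, responses, _, truth = make_pharmacogenomic(
        n_sensitive=n_per_class, n_resistant=n_per_class, n_genes=n_genes,
        n_informative=n_informative, effect_size=effect_size,
        n_unlabeled=2, seed=seed,
    )
    norm, _ = minmax_normalize(annotated)
    d = make_labeled(norm, responses, "venetoclax")
    if drop_informative:
        keep = [j for j, g in enumerate(d.gene_ids)
                if g not in truth.informative_gene_ids]
        d = LabeledDataset(d.sample_ids, [d.gene_ids[j] for j in keep],
                           d.features[:, keep], d.labels)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1)
        d = LabeledDataset(d.sample_ids, d.gene_ids, d.features,
                           rng.permutation(d.labels))
    train, test = split_train_test(d, 0.25, seed)
    inner_train, inner_val = split_train_test(train, 0.2, seed + 1)
    model = fit(inner_train, HyperParams(max_epochs=max_epochs, seed=seed),
                validation=inner_val)
    return float(roc_auc_score(test.labels, predict_proba(model, test)))
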