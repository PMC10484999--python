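import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from sensitab.data import (
    ExpressionMatrix,
    LabeledDataset,
    make_labeled,
    minmax_normalize,
    split_train_test,
)
from sensitab.model import (
    BASELINE_PANEL,
    HyperParams,
    _init_params,
    _recon_loss_grads,
    _supervised_loss_grads,
    fit,
    fit_baselines,
    load_model,
    predict_proba,
    pretrain,
    save_model,
)
from sensitab.simdata import make_pharmacogenomic

from conftest import benchmark_holdout_auc


def _separable_dataset(n=200, n_genes=20, effect=5.0, seed=0):
    annotated, responses, _, _ = make_pharmacogenomic(
        n_sensitive=n // 2, n_resistant=n // 2, n_genes=n_genes,
        n_informative=1, effect_size=effect, n_unlabeled=2, seed=seed)
    norm, _ = minmax_normalize(annotated)
    return make_labeled(norm, responses, "venetoclax")


class TestHyperParams:
    @pytest.mark.parametrize("bad", [
        {"decision_width": 0}, {"relaxation_gamma": 0.5},
        {"sparsity_coefficient": -1}, {"learning_rate": 0},
        {"early_stop_patience": -1}, {"max_epochs": 0},
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            HyperParams(**bad)

    def test_round_trips_flat_map(self):
        hp = HyperParams(decision_width=8, learning_rate=0.005)
        assert HyperParams.from_dict(hp.to_dict()) == hp


class TestGradients:
    """Analytic gradients agree with central finite differences."""

    @staticmethod
    def _check(loss_fn, params, tol=1e-4):
        _, grads = loss_fn(params)
        for key, g in grads.items():
            arr = params[key]
            flat = np.atleast_1d(arr).ravel()
            gflat = np.atleast_1d(np.asarray(g)).ravel()
            for idx in range(flat.size):
                eps = 1e-6
                old = flat[idx]
                flat[idx] = old + eps
                lp, _ = loss_fn(params)
                flat[idx] = old - eps
                lm, _ = loss_fn(params)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                # absolute floor guards against FD noise on tiny gradients
                denom = abs(num) + abs(gflat[idx]) + 1e-6
                assert abs(num - gflat[idx]) / denom < tol, key

    def test_supervised_gradients(self):
        rng = np.random.default_rng(0)
        hp = HyperParams(decision_width=4, attention_width=3,
                         n_decision_steps=2, sparsity_coefficient=1e-3)
        x = rng.random((6, 5))
        y = rng.integers(0, 2, 6).astype(float)
        params = _init_params(hp, 5, rng)
        self._check(lambda p: _supervised_loss_grads(p, hp, x, y), params)

    def test_reconstruction_gradients(self):
        rng = np.random.default_rng(1)
        hp = HyperParams(decision_width=4, attention_width=3,
                         n_decision_steps=1, sparsity_coefficient=1e-3)
        x = rng.random((6, 5))
        mask = (rng.random((6, 5)) < 0.5).astype(float)
        params = _init_params(hp, 5, rng)
        params["recon_D"] = rng.normal(0, 0.1, (4, 5))
        params["recon_e"] = np.zeros(5)
        self._check(lambda p: _recon_loss_grads(p, hp, x, mask), params)


class TestPretrain:
    def test_same_seed_same_fingerprint(self, small_cohort):
        _, _, unlabeled, _ = small_cohort
        norm, _ = minmax_normalize(unlabeled)
        hp = HyperParams(max_epochs=5, seed=3)
        assert pretrain(norm, hp).fingerprint == pretrain(norm, hp).fingerprint

    def test_reconstruction_loss_improves(self):
        rng = np.random.default_rng(0)
        x = ExpressionMatrix([f"s{i}" for i in range(200)],
                             [f"g{j}" for j in range(50)],
                             rng.random((200, 50)))
        enc = pretrain(x, HyperParams(max_epochs=20, seed=0))
        assert enc.loss_history[-1] <= enc.loss_history[0]

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_masking_fraction_validated(self, frac, small_cohort):
        _, _, unlabeled, _ = small_cohort
        norm, _ = minmax_normalize(unlabeled)
        with pytest.raises(ValueError):
            pretrain(norm, HyperParams(max_epochs=2), masking_fraction=frac)

    def test_requires_normalized_input(self, small_cohort):
        _, _, unlabeled, _ = small_cohort
        with pytest.raises(ValueError, match="normalized"):
            pretrain(unlabeled, HyperParams(max_epochs=2))


class TestFit:
    def test_separable_data_learned_within_50_epochs(self):
        d = _separable_dataset()
        model = fit(d, HyperParams(max_epochs=50, seed=0))
        p = predict_proba(model, d)
        assert np.mean((p >= 0.5).astype(int) == d.labels) == 1.0

    def test_single_class_rejected(self):
        d = LabeledDataset(["a", "b"], ["g"], np.zeros((2, 1)), np.array([1, 1]))
        with pytest.raises(ValueError):
            fit(d, HyperParams(max_epochs=2))

    def test_encoder_feature_mismatch_rejected(self, small_cohort, small_labeled):
        _, _, unlabeled, _ = small_cohort
        norm, _ = minmax_normalize(unlabeled.subset_genes(unlabeled.gene_ids[:10]))
        enc = pretrain(norm, HyperParams(max_epochs=2, seed=0))
        with pytest.raises(ValueError, match="features"):
            fit(small_labeled, HyperParams(max_epochs=2), encoder=enc)

    def test_seed_determinism_end_to_end(self, small_labeled):
        train, test = split_train_test(small_labeled, 0.25, seed=0)
        hp = HyperParams(max_epochs=10, seed=42)
        p1 = predict_proba(fit(train, hp), test)
        p2 = predict_proba(fit(train, hp), test)
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_valid(self, small_labeled):
        model = fit(small_labeled, HyperParams(max_epochs=5, seed=1))
        p = predict_proba(model, small_labeled)
        assert np.isfinite(p).all() and p.min() >= 0 and p.max() <= 1

    def test_pretraining_does_not_hurt(self):
        """Median paired held-out AUC: pretrained >= cold start - 0.05."""
        deltas = []
        for seed in range(10):
            annotated, responses, unlabeled, _ = make_pharmacogenomic(
                n_sensitive=60, n_resistant=60, n_genes=50, n_informative=5,
                effect_size=2.0, n_unlabeled=120, seed=seed)
            norm, stats = minmax_normalize(annotated)
            d = make_labeled(norm, responses, "venetoclax")
            train, test = split_train_test(d, 0.25, seed)
            unlab_norm, _ = minmax_normalize(unlabeled, stats)
            hp = HyperParams(max_epochs=25, seed=seed)
            enc = pretrain(unlab_norm, hp)
            auc_warm = roc_auc_score(test.labels,
                                     predict_proba(fit(train, hp, encoder=enc), test))
            auc_cold = roc_auc_score(test.labels,
                                     predict_proba(fit(train, hp), test))
            deltas.append(auc_warm - auc_cold)
        assert np.median(deltas) >= -0.05

    def test_label_shuffled_auc_near_chance(self):
        aucs = [benchmark_holdout_auc(seed, shuffle_labels=True,
                                      n_per_class=75, n_genes=60, max_epochs=25)
                for seed in range(10)]
        assert 0.4 <= np.median(aucs) <= 0.6

    def test_uninformative_features_guardrail(self):
        aucs = [benchmark_holdout_auc(seed, drop_informative=True,
                                      n_per_class=75, n_genes=60, max_epochs=25)
                for seed in range(10)]
        assert np.median(aucs) < 0.65


class TestPredict:
    def test_gene_permutation_invariance(self, small_labeled):
        model = fit(small_labeled, HyperParams(max_epochs=5, seed=2))
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_labeled.n_genes)
        shuffled = ExpressionMatrix(
            small_labeled.sample_ids,
            [small_labeled.gene_ids[j] for j in perm],
            small_labeled.features[:, perm])
        np.testing.assert_allclose(predict_proba(model, shuffled),
                                   predict_proba(model, small_labeled))

    def test_extra_gene_rejected(self, small_labeled):
        model = fit(small_labeled, HyperParams(max_epochs=2, seed=2))
        extra = ExpressionMatrix(
            small_labeled.sample_ids,
            small_labeled.gene_ids + ["novel"],
            np.hstack([small_labeled.features,
                       np.zeros((small_labeled.n_samples, 1))]))
        with pytest.raises(ValueError, match="novel"):
            predict_proba(model, extra)

    def test_save_load_round_trip(self, small_labeled, tmp_path):
        model = fit(small_labeled, HyperParams(max_epochs=3, seed=4))
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        np.testing.assert_array_equal(predict_proba(loaded, small_labeled),
                                      predict_proba(model, small_labeled))


class TestBaselines:
    def test_singleton_panel(self, small_labeled):
        train, val = split_train_test(small_labeled, 0.3, seed=0)
        reports = fit_baselines(train, val, ["logistic_regression"])
        assert set(reports) == {"logistic_regression"}

    def test_duplicates_deduplicated_with_warning(self, small_labeled):
        train, val = split_train_test(small_labeled, 0.3, seed=0)
        with pytest.warns(UserWarning):
            reports = fit_baselines(train, val, ["knn", "knn"])
        assert set(reports) == {"knn"}

    def test_unknown_identifier_rejected(self, small_labeled):
        train, val = split_train_test(small_labeled, 0.3, seed=0)
        with pytest.raises(ValueError):
            fit_baselines(train, val, ["perceptron_9000"])

    def test_all_baselines_learn_separable_benchmark(self):
        annotated, responses, _, _ = make_pharmacogenomic(
            n_sensitive=200, n_resistant=200, n_genes=30, n_informative=10,
            effect_size=3.0, n_unlabeled=2, seed=7)
        norm, _ = minmax_normalize(annotated)
        d = make_labeled(norm, responses, "venetoclax")
        train, val = split_train_test(d, 0.25, seed=7)
        reports = fit_baselines(train, val, BASELINE_PANEL, seed=7)
        for name, report in reports.items():
            assert report.auc >= 0.95, name
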