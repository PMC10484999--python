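import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sensitab.data import (
    ExpressionMatrix,
    DrugResponseTable,
    LabeledDataset,
    NormalizationStats,
    SamplingPlan,
    binarize_response,
    load_expression,
    minmax_normalize,
    resample,
    select_top_variance_genes,
    split_train_test,
)


def _write(tmp_path, text, name="m.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadExpression:
    def test_round_trip_samples_as_rows(self, tmp_path):
        p = _write(tmp_path, "id,gA,gB\ns1,1,2\ns2,3,4\n")
        x = load_expression(p, "samples_as_rows")
        assert x.sample_ids == ["s1", "s2"]
        assert x.gene_ids == ["gA", "gB"]
        np.testing.assert_array_equal(x.values, [[1, 2], [3, 4]])

    def test_genes_as_rows_is_transpose(self, tmp_path):
        p = _write(tmp_path, "id,gA,gB\ns1,1,2\ns2,3,4\n")
        direct = load_expression(p, "samples_as_rows")
        transposed = load_expression(_write(tmp_path, "id,s1,s2\ngA,1,3\ngB,2,4\n", "t.csv"),
                                     "genes_as_rows")
        np.testing.assert_array_equal(direct.values, transposed.values)
        assert direct.gene_ids == transposed.gene_ids

    def test_duplicate_gene_named_in_error(self, tmp_path):
        p = _write(tmp_path, "id,gA,gA\ns1,1,2\n")
        with pytest.raises(ValueError, match="gA"):
            load_expression(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = _write(tmp_path, "id,gA,gB\ns1,1,oops\n")
        with pytest.raises(ValueError, match="gB"):
            load_expression(p)

    def test_gzip_accepted(self, tmp_path):
        import gzip
        p = tmp_path / "m.csv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("id,gA\ns1,1\ns2,2\n")
        assert load_expression(p).n_samples == 2

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix(["s1"], ["g1", "g2"], [[1.0, np.nan]])


class TestVarianceSelection:
    def test_constant_gene_ranked_last(self):
        x = ExpressionMatrix(["a", "b", "c"], ["g1", "g2", "g3"],
                             [[5, 1, 0], [5, 2, 4], [5, 9, 8]])
        assert select_top_variance_genes(x, 3)[-1] == "g1"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.random((6, 4)) * [1, 10, 0.1, 5]
        x = ExpressionMatrix([f"s{i}" for i in range(6)],
                             ["g1", "g2", "g3", "g4"], values)
        oracle = sorted(range(4), key=lambda j: -values[:, j].var())[:2]
        assert select_top_variance_genes(x, 2) == [x.gene_ids[j] for j in oracle]

    def test_k_equal_to_n_genes_returns_all(self):
        x = ExpressionMatrix(["a", "b"], ["g1", "g2"], [[0, 1], [1, 3]])
        assert set(select_top_variance_genes(x, 2)) == {"g1", "g2"}

    def test_k_too_large_warns_and_returns_all(self):
        x = ExpressionMatrix(["a", "b"], ["g1", "g2"], [[0, 1], [1, 3]])
        with pytest.warns(UserWarning):
            assert len(select_top_variance_genes(x, 5)) == 2

    def test_tie_break_lexicographic(self):
        x = ExpressionMatrix(["a", "b"], ["gB", "gA"], [[0, 0], [2, 2]])
        assert select_top_variance_genes(x, 2) == ["gA", "gB"]


class TestMinMax:
    def test_endpoints_map_to_zero_and_one(self):
        x = ExpressionMatrix(["a", "b", "c"], ["g"], [[0], [5], [10]])
        norm, _ = minmax_normalize(x)
        np.testing.assert_allclose(norm.values[:, 0], [0, 0.5, 1])

    def test_constant_gene_maps_to_zero(self):
        x = ExpressionMatrix(["a", "b", "c"], ["g"], [[7], [7], [7]])
        norm, _ = minmax_normalize(x)
        np.testing.assert_array_equal(norm.values[:, 0], [0, 0, 0])

    def test_external_stats_clip(self):
        stats = NormalizationStats(["g"], np.array([0.0]), np.array([10.0]))
        x = ExpressionMatrix(["a"], ["g"], [[12.0]])
        norm, _ = minmax_normalize(x, stats)
        assert norm.values[0, 0] == 1.0

    def test_missing_gene_in_stats_rejected(self):
        stats = NormalizationStats(["other"], np.array([0.0]), np.array([1.0]))
        with pytest.raises(KeyError, match="g"):
            minmax_normalize(ExpressionMatrix(["a"], ["g"], [[1.0]]), stats)

    def test_idempotent_with_own_stats(self):
        rng = np.random.default_rng(0)
        x = ExpressionMatrix([f"s{i}" for i in range(5)],
                             [f"g{j}" for j in range(3)], rng.random((5, 3)))
        norm, stats = minmax_normalize(x)
        again, _ = minmax_normalize(norm, NormalizationStats(
            norm.gene_ids, norm.values.min(axis=0), norm.values.max(axis=0)))
        np.testing.assert_allclose(again.values, norm.values, atol=1e-12)


class TestBinarize:
    @pytest.mark.parametrize("ic50,expected", [(300.0, 1), (500.0, 0), (499.9, 1)])
    def test_threshold_rule_is_strict(self, ic50, expected):
        t = DrugResponseTable(pd.DataFrame(
            {"sample_id": ["s1"], "drug": ["venetoclax"], "ic50_nM": [ic50]}))
        assert binarize_response(t, "venetoclax", ["s1"])[0] == expected

    def test_missing_sample_listed(self):
        t = DrugResponseTable(pd.DataFrame(
            {"sample_id": ["s1"], "drug": ["venetoclax"], "ic50_nM": [100.0]}))
        with pytest.raises(KeyError, match="s2"):
            binarize_response(t, "venetoclax", ["s1", "s2"])

    @given(ic50=st.floats(min_value=1e-3, max_value=1e9,
                          allow_nan=False, allow_infinity=False))
    @settings(deadline=None, derandomize=True)
    def test_every_positive_ic50_maps_to_one_label(self, ic50):
        t = DrugResponseTable(pd.DataFrame(
            {"sample_id": ["s"], "drug": ["d"], "ic50_nM": [ic50]}))
        assert binarize_response(t, "d", ["s"])[0] in (0, 1)

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(ValueError):
            DrugResponseTable(pd.DataFrame(
                {"sample_id": ["s"], "drug": ["d"], "ic50_nM": [-1.0]}))


class TestSplit:
    def test_partition(self, small_labeled):
        train, test = split_train_test(small_labeled, 0.2, seed=0)
        assert set(train.sample_ids) | set(test.sample_ids) == set(small_labeled.sample_ids)
        assert not set(train.sample_ids) & set(test.sample_ids)
        assert test.n_samples == round(0.2 * small_labeled.n_samples)

    def test_deterministic_under_seed(self, small_labeled):
        a = split_train_test(small_labeled, 0.2, seed=5)
        b = split_train_test(small_labeled, 0.2, seed=5)
        assert a[1].sample_ids == b[1].sample_ids

    def test_stratified_allocation_balanced_20(self):
        d = LabeledDataset([f"s{i}" for i in range(20)], ["g"],
                           np.zeros((20, 1)), np.array([1] * 10 + [0] * 10))
        _, test = split_train_test(d, 0.2, seed=1, stratified=True)
        assert (test.labels == 1).sum() == 2 and (test.labels == 0).sum() == 2

    def test_tiny_class_rejected_under_stratification(self):
        d = LabeledDataset(["a", "b", "c"], ["g"], np.zeros((3, 1)),
                           np.array([1, 0, 0]))
        with pytest.raises(ValueError):
            split_train_test(d, 0.34, seed=0, stratified=True)

    @given(seed=st.integers(min_value=0, max_value=2**20))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_disjointness_for_all_seeds(self, seed):
        d = LabeledDataset([f"s{i}" for i in range(12)], ["g"],
                           np.zeros((12, 1)), np.array([1, 0] * 6))
        train, test = split_train_test(d, 0.25, seed=seed)
        assert not set(train.sample_ids) & set(test.sample_ids)
        assert len(train.sample_ids) + len(test.sample_ids) == 12


class TestResample:
    def test_none_is_identity(self, imbalanced_labeled):
        out = resample(imbalanced_labeled, SamplingPlan("none"))
        assert out.sample_ids == imbalanced_labeled.sample_ids
        np.testing.assert_array_equal(out.features, imbalanced_labeled.features)

    def test_over_equalizes_up(self, imbalanced_labeled):
        out = resample(imbalanced_labeled, SamplingPlan("over", seed=1))
        assert out.class_counts() == {"sensitive": 10, "resistant": 10}

    def test_under_equalizes_down(self, imbalanced_labeled):
        out = resample(imbalanced_labeled, SamplingPlan("under", seed=1))
        assert out.class_counts() == {"sensitive": 3, "resistant": 3}

    def test_duplicates_flagged_in_ids(self, imbalanced_labeled):
        out = resample(imbalanced_labeled, SamplingPlan("over", seed=1))
        assert any("__dup" in s for s in out.sample_ids)

    def test_deterministic(self, imbalanced_labeled):
        a = resample(imbalanced_labeled, SamplingPlan("under", seed=9))
        b = resample(imbalanced_labeled, SamplingPlan("under", seed=9))
        assert a.sample_ids == b.sample_ids

    def test_single_class_rejected(self):
        d = LabeledDataset(["a", "b"], ["g"], np.zeros((2, 1)), np.array([1, 1]))
        with pytest.raises(ValueError):
            resample(d, SamplingPlan("over"))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            SamplingPlan("smote")
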