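import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafpheno.cohort import (
    agreement_stats,
    hierarchical_cluster,
    pc_correlation,
    pca_top10,
    positive_back_difference,
    tree_feature_importance,
)


class TestAgreement:
    def test_identical_vectors(self):
        s = agreement_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.r2 == pytest.approx(1.0)
        assert s.mae == 0.0
        assert s.mape == 0.0

    def test_constant_offset(self):
        s = agreement_stats([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert s.mae == pytest.approx(3.0)

    def test_zero_variance_manual_leaves_r2_undefined(self):
        s = agreement_stats([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert s.r2 is None

    def test_zero_manual_value_leaves_mape_undefined(self):
        s = agreement_stats([0.0, 2.0], [1.0, 2.0])
        assert s.mape is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(10, 3, 10)
        c = m + rng.normal(0, 1, 10)
        s = agreement_stats(m, c)
        # independent elementwise evaluation
        r2 = 1 - sum((ci - mi) ** 2 for mi, ci in zip(m, c)) / \
            sum((mi - np.mean(m)) ** 2 for mi in m)
        mae = sum(abs(ci - mi) for mi, ci in zip(m, c)) / 10
        mape = 100 * sum(abs((ci - mi) / mi) for mi, ci in zip(m, c)) / 10
        assert s.r2 == pytest.approx(r2)
        assert s.mae == pytest.approx(mae)
        assert s.mape == pytest.approx(mape)


class TestPositiveBack:
    def test_identical_gives_zero(self):
        pb = positive_back_difference({"a": 5.0}, {"a": 5.0})
        assert pb["a"] == 0.0

    def test_definition(self):
        pb = positive_back_difference({"x": 100.0}, {"x": 50.0})
        assert pb["x"] == pytest.approx(50.0)

    def test_back_larger_is_negative(self):
        pb = positive_back_difference({"x": 50.0}, {"x": 100.0})
        assert pb["x"] == pytest.approx(-100.0)

    def test_antisymmetry_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, b = rng.uniform(1, 100, 2)
            fwd = positive_back_difference({"x": p}, {"x": b})["x"]
            rev = positive_back_difference({"x": b}, {"x": p})["x"]
            assert fwd == pytest.approx(-rev * b / p)

    def test_zero_positive_is_undefined(self):
        pb = positive_back_difference({"x": 0.0}, {"x": 1.0})
        assert pb["x"] is None


class TestTreeImportance:
    def test_perfect_feature_dominates(self):
        rng = np.random.default_rng(1)
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        X["sep"] = y * 10.0 + rng.normal(0, 0.1, n)
        imp = tree_feature_importance(X, y, seed=0)
        assert imp["sep"] >= 95.0
        assert imp.sum() == pytest.approx(100.0)

    def test_duplicated_feature_splits_importance(self):
        rng = np.random.default_rng(2)
        n = 200
        y = np.repeat([0, 1], n // 2)
        base = pd.DataFrame({
            "sep": y * 10.0 + rng.normal(0, 0.1, n),
            "noise": rng.normal(size=n),
        })
        dup = base.copy()
        dup["sep2"] = base["sep"]
        i1 = tree_feature_importance(base, y, seed=0)
        i2 = tree_feature_importance(dup, y, seed=0)
        assert i2["sep"] + i2["sep2"] == pytest.approx(i1["sep"], abs=1.0)

    def test_pure_noise_has_no_dominant_feature(self):
        n = 120
        y = np.repeat([0, 1], n // 2)
        tops = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.normal(size=(n, 10)))
            X.columns = [f"f{i}" for i in range(10)]
            tops.append(tree_feature_importance(X, y, seed=seed).iloc[0])
        assert max(tops) <= 60.0

    def test_single_class_raises(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            tree_feature_importance(X, [1, 1, 1], seed=0)


class TestPCA:
    def test_planar_data_needs_two_components(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(50, 2))
        X = pd.DataFrame(coords @ basis)
        res = pca_top10(X)
        assert res.explained_variance[:2].sum() == pytest.approx(1.0)

    def test_explained_variance_non_increasing_and_bounded(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(40, 15)))
        res = pca_top10(X)
        ev = res.explained_variance
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1.0 + 1e-9

    def test_matches_eigendecomposition_oracle(self):
        """Scores agree (up to sign) with a direct eigendecomposition of
        the z-scored covariance on a 20x6 table."""
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        res = pca_top10(X, n_components=6)
        Z = (X - X.mean()) / X.std(ddof=0)
        cov = Z.to_numpy().T @ Z.to_numpy() / 20
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        oracle = Z.to_numpy() @ v[:, order]
        got = res.scores.to_numpy()
        for j in range(got.shape[1]):
            assert (np.allclose(got[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(got[:, j], -oracle[:, j], atol=1e-8))

    def test_scores_are_orthogonal(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(30, 8)))
        S = pca_top10(X).scores.to_numpy()
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_constant_columns_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(20, 4)))
        X["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = pca_top10(X)
        assert res.dropped == ["const"]


class TestClustering:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.3, size=(20, 3))
        b = rng.normal(5, 0.3, size=(20, 3))
        X = pd.DataFrame(np.vstack([a, b]))
        labels = hierarchical_cluster(X, k=2)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_four_blobs_perfect_agreement(self):
        rng = np.random.default_rng(9)
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], float)
        pts = np.vstack([c + rng.normal(0, 0.4, size=(15, 2))
                         for c in centers])
        labels = hierarchical_cluster(pd.DataFrame(pts), k=4)
        truth = np.repeat(np.arange(4), 15)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_k_equals_n_gives_singletons(self):
        X = pd.DataFrame(np.arange(10.0).reshape(5, 2))
        labels = hierarchical_cluster(X, k=5)
        assert len(set(labels)) == 5

    def test_invalid_k_raises(self):
        X = pd.DataFrame(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            hierarchical_cluster(X, k=0)
        with pytest.raises(ValueError):
            hierarchical_cluster(X, k=10)


def test_pc_correlation_shape():
    rng = np.random.default_rng(10)
    tables = {name: pd.DataFrame(
        rng.normal(size=(25, 10)),
        columns=[f"PC{i + 1}" for i in range(10)])
        for name in ("GEO", "VEN", "CLR", "COM")}
    corr = pc_correlation(tables)
    assert corr.shape == (40, 40)
    assert np.allclose(np.diag(corr), 1.0)
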