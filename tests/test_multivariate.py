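"""PCA, replicate averaging, NIPALS PLSR, loading dot-product ranking."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from ocproteo.errors import InputError, JoinError
from ocproteo.matrix import SCALE_LOG2_SCALED
from ocproteo.multivariate import (
    PLSModel,
    average_replicates,
    loading_dot_rank,
    pca,
    plsr_nipals,
)


class TestPca:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 6)
        vals = np.vstack([2 * t, -3 * t])  # 2 features, samples on a line
        m = make_matrix(vals, scale=SCALE_LOG2_SCALED)
        res = pca(m)
        assert res.pct_variance.iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(10, 6)), scale=SCALE_LOG2_SCALED)
        assert pca(m).pct_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(10, 6)), scale=SCALE_LOG2_SCALED)
        res = pca(m)
        X = m.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(res.scores.shape[1]):
            oracle = Xc @ evecs[:, j]
            got = res.scores.iloc[:, j].to_numpy()
            agree = min(
                np.abs(got - oracle).max(), np.abs(got + oracle).max()
            )
            assert agree < 1e-8

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(8, 5)), scale=SCALE_LOG2_SCALED)
        res = pca(m)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(InputError):
            pca(make_matrix([[1.0]], scale=SCALE_LOG2_SCALED))


class TestAverageReplicates:
    def _matrix(self):
        vals = np.array([[2.0, 4.0, 6.0, 10.0]])
        return make_matrix(
            vals,
            donors=["d1", "d1", "d1", "d2"],
            treatments=["N", "N", "N", "IC"],
        )

    def test_replicate_mean(self):
        X, _ = average_replicates(self._matrix())
        assert X.loc[("d1", "N"), "f1"] == pytest.approx(4.0)

    def test_single_replicate_passthrough(self):
        X, _ = average_replicates(self._matrix())
        assert X.loc[("d2", "IC"), "f1"] == pytest.approx(10.0)

    def test_response_aligned(self):
        resp = pd.Series({("d1", "N"): 20.0, ("d2", "IC"): 54.0})
        X, y = average_replicates(self._matrix(), resp)
        assert list(y.index) == list(X.index)
        assert y.tolist() == [20.0, 54.0]

    def test_missing_response_raises_join_error(self):
        resp = pd.Series({("d1", "N"): 20.0})
        with pytest.raises(JoinError):
            average_replicates(self._matrix(), resp)

    def test_balanced_group_count(self, small_experiment):
        exp = small_experiment
        media = exp.matrix.select_compartment("media")
        X, _ = average_replicates(media)
        assert len(X) == exp.config.n_donors * len(exp.config.treatments)


def _random_problem(rng, n=10, p=3):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    y = pd.Series(rng.normal(size=n))
    return X, y


class TestPlsrNipals:
    def test_orthonormal_columns_weight_closed_form(self):
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 3)))
        X = pd.DataFrame(Q, columns=["a", "b", "c"])
        X = X - X.mean()  # keep columns orthogonal after internal centering
        y = pd.Series(rng.normal(size=12))
        model = plsr_nipals(X, y, n_components=1)
        expected = X.to_numpy().T @ (y - y.mean()).to_numpy()
        expected = expected / np.linalg.norm(expected)
        np.testing.assert_allclose(
            model.weights.iloc[:, 0], expected, atol=1e-10
        )

    def test_full_rank_fit_equals_ols(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            X, y = _random_problem(rng)
            model = plsr_nipals(X, y, n_components=3)
            Z = np.column_stack([np.ones(len(y)), X.to_numpy()])
            ols_fit = Z @ np.linalg.lstsq(Z, y.to_numpy(), rcond=None)[0]
            np.testing.assert_allclose(model.fitted(), ols_fit, atol=1e-8)

    def test_matches_sklearn_pls(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(5)
        X, y = _random_problem(rng, n=20, p=6)
        model = plsr_nipals(X, y, n_components=2)
        ref = sklearn.PLSRegression(n_components=2, scale=False).fit(
            X.to_numpy(), y.to_numpy()
        )
        # loadings agree up to per-component sign
        for j in range(2):
            ours = model.x_loadings.iloc[:, j].to_numpy()
            theirs = ref.x_loadings_[:, j]
            assert min(
                np.abs(ours - theirs).max(), np.abs(ours + theirs).max()
            ) < 1e-8

    def test_response_equal_to_feature_dominates_loading(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(15, 5)),
                         columns=[f"x{j}" for j in range(5)])
        X = (X - X.mean()) / X.std(ddof=1)
        y = X["x2"].copy()
        model = plsr_nipals(X, y, n_components=2)
        xl1 = model.x_loadings.iloc[:, 0].abs()
        assert xl1.idxmax() == "x2"

    def test_deflation_exhausts_x(self):
        rng = np.random.default_rng(7)
        X, y = _random_problem(rng, n=8, p=4)
        model = plsr_nipals(X, y, n_components=4)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        recon = model.x_scores.to_numpy() @ model.x_loadings.to_numpy().T
        assert np.linalg.norm(Xc - recon) < 1e-8 * np.linalg.norm(Xc)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(8)
        X, y = _random_problem(rng, n=12, p=5)
        T = plsr_nipals(X, y, n_components=3).x_scores.to_numpy()
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_zero_variance_response_rejected(self):
        rng = np.random.default_rng(9)
        X, _ = _random_problem(rng)
        with pytest.raises(InputError):
            plsr_nipals(X, pd.Series(np.ones(10)), 2)

    def test_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(10)
        X, y = _random_problem(rng, n=4, p=6)  # rank <= 3 after centering
        with pytest.raises(InputError):
            plsr_nipals(X, y, n_components=5)


def _model_from_loadings(xl_rows, yl, ids=None):
    xl = np.asarray(xl_rows, dtype=float)
    ids = ids or [f"f{i}" for i in range(len(xl))]
    n = len(ids)
    return PLSModel(
        x_loadings=pd.DataFrame(xl, index=ids, columns=["LV1", "LV2"]),
        y_loadings=np.asarray(yl, dtype=float),
        x_scores=pd.DataFrame(np.zeros((3, 2)), columns=["LV1", "LV2"]),
        weights=pd.DataFrame(xl, index=ids, columns=["LV1", "LV2"]),
        x_mean=pd.Series(np.zeros(n), index=ids),
        y_mean=0.0,
        n_components=2,
    )


class TestLoadingDotRank:
    def test_arithmetic_example(self):
        model = _model_from_loadings([(2, 0), (0, 1), (-2, 0)], (1.0, 0.5))
        ranked = loading_dot_rank(model, top_n=3)
        assert ranked["dot_score"].tolist() == [2.0, 0.5, -2.0]
        assert ranked.loc[0, "feature_id"] == "f0"
        assert ranked["rank"].tolist() == [1, 2, 3]

    def test_degenerate_y_loadings_rank_lexicographically(self):
        model = _model_from_loadings(
            [(1, 1), (2, 2), (3, 3)], (0.0, 0.0), ids=["c", "a", "b"]
        )
        ranked = loading_dot_rank(model, top_n=3)
        assert ranked["feature_id"].tolist() == ["a", "b", "c"]
        assert (ranked["dot_score"] == 0).all()

    def test_sign_equivariance_under_response_negation(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(12, 6)),
                         columns=[f"x{j}" for j in range(6)])
        y = pd.Series(rng.normal(size=12))
        s1 = loading_dot_rank(plsr_nipals(X, y, 2), top_n=6)
        s2 = loading_dot_rank(plsr_nipals(X, -y, 2), top_n=6)
        merged = s1.merge(s2, on="feature_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["dot_score_a"], -merged["dot_score_b"], atol=1e-10
        )

    def test_rank_invariant_to_feature_order(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(10, 5)),
                         columns=["e", "d", "c", "b", "a"])
        y = pd.Series(rng.normal(size=10))
        r1 = loading_dot_rank(plsr_nipals(X, y, 2), top_n=5)
        r2 = loading_dot_rank(
            plsr_nipals(X[sorted(X.columns)], y, 2), top_n=5
        )
        assert r1["feature_id"].tolist() == r2["feature_id"].tolist()

    def test_top_n_overflow_warns_and_returns_all(self):
        model = _model_from_loadings([(1, 0), (0, 1)], (1.0, 1.0))
        with pytest.warns(UserWarning):
            ranked = loading_dot_rank(model, top_n=10)
        assert len(ranked) == 2

    def test_xl1_xl2_variant(self):
        model = _model_from_loadings([(2, 3), (-1, 4)], (1.0, 1.0))
        ranked = loading_dot_rank(model, top_n=2, variant="xl1_xl2")
        assert ranked["dot_score"].tolist() == [6.0, -4.0]
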