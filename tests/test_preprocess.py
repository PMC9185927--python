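"""Filtering, imputation, normalization, scaling and batch correction."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_knn_impute, make_matrix
from ocproteo.errors import ConfigurationError, ConfoundingError, InputError
from ocproteo.matrix import SCALE_LOG2
from ocproteo.preprocess import (
    filter_features,
    knn_impute,
    log2_scale,
    log2_transform,
    normalize_dna,
    remove_batch,
    scale_features,
)


class TestFilter:
    def _matrix_with_presence(self, counts, n_samples=10):
        vals = np.full((len(counts), n_samples), np.nan)
        for i, c in enumerate(counts):
            vals[i, :c] = 10.0
        return make_matrix(vals)

    def test_seventy_percent_rule(self):
        m = self._matrix_with_presence([7, 6, 10])
        kept = filter_features(m, 0.70).feature_ids
        assert kept == ["f1", "f3"]

    def test_zero_min_frac_keeps_everything_but_exogenous(self):
        m = self._matrix_with_presence([1, 0, 10])
        kept = filter_features(m, 0.0, exogenous={"f3"}).feature_ids
        assert kept == ["f1", "f2"]

    def test_exogenous_removed_despite_full_presence(self):
        m = self._matrix_with_presence([10, 10])
        assert filter_features(m, 0.7, exogenous={"f1"}).feature_ids == ["f2"]

    def test_bad_min_frac(self):
        with pytest.raises(ConfigurationError):
            filter_features(self._matrix_with_presence([5]), 1.2)


class TestKnnImpute:
    def test_single_neighbour_example(self):
        m = make_matrix([[1, 2, 3], [1, 2, np.nan]], scale=SCALE_LOG2)
        out = knn_impute(m, k=1)
        assert out.values.loc["f2", "s3"] == pytest.approx(3.0)

    def test_complete_matrix_unchanged(self):
        m = make_matrix(np.arange(6.0).reshape(2, 3) + 1, scale=SCALE_LOG2)
        out = knn_impute(m, k=2)
        assert out.values.equals(m.values)

    def test_large_k_uses_all_observed_features(self):
        vals = np.array([[1, 2, np.nan], [0, 1, 5.0], [2, 3, 7.0], [9, 9, 9.0]])
        m = make_matrix(vals, scale=SCALE_LOG2)
        out = knn_impute(m, k=50)
        assert out.values.loc["f1", "s3"] == pytest.approx(np.mean([5, 7, 9]))

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(15, 8))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        m = make_matrix(vals, scale=SCALE_LOG2)
        out = knn_impute(m, k=3)
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])
        assert not np.isnan(out.values.to_numpy()).any()

    @pytest.mark.parametrize("k", [1, 3, 10])
    def test_matches_brute_force_oracle(self, k):
        rng = np.random.default_rng(k)
        for _ in range(5):
            vals = rng.normal(size=(20, 12))
            vals[rng.random(vals.shape) < 0.1] = np.nan
            vals[0, :] = rng.normal(size=12)  # keep at least one full row
            m = make_matrix(vals, scale=SCALE_LOG2)
            expected = brute_force_knn_impute(vals, k)
            out = knn_impute(m, k=k).values.to_numpy()
            np.testing.assert_allclose(out, expected, rtol=0, atol=1e-12)

    def test_feature_with_no_observations_errors(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(InputError):
            knn_impute(make_matrix(vals, scale=SCALE_LOG2), k=1)


class TestLog2Scale:
    def test_hand_example(self):
        m = make_matrix([[1.0, 2.0, 4.0]])
        out = log2_scale(m)
        np.testing.assert_allclose(out.values.to_numpy()[0], [-1, 0, 1], atol=1e-12)
        assert out.scale_tag == "log2_scaled"

    def test_mean_zero_unit_variance(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.uniform(1, 50, size=(10, 6)))
        out = log2_scale(m)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(out.values.var(axis=1, ddof=1), 1, atol=1e-9)

    def test_constant_feature_errors_by_default(self):
        with pytest.raises(InputError):
            log2_scale(make_matrix([[5.0, 5.0, 5.0]]))

    def test_constant_feature_zero_mode(self):
        out = log2_scale(make_matrix([[5.0, 5.0, 5.0]]), on_constant="zero")
        np.testing.assert_allclose(out.values.to_numpy(), 0.0)

    def test_nonpositive_value_names_cell(self):
        with pytest.raises(InputError, match="f1.*s2"):
            log2_transform(make_matrix([[1.0, -2.0]]))


class TestNormalizeDna:
    def _setup(self, dna=2.0, ww=1.0):
        m = make_matrix(
            [[100.0]], donors=["d1"], treatments=["N"], compartment="tissue"
        )
        biochem = pd.DataFrame(
            {
                "donor": ["d1"],
                "treatment": ["N"],
                "replicate": [1],
                "dna_ng": [dna],
                "wet_weight_mg": [ww],
            }
        )
        return m, biochem

    def test_divides_by_dna_per_wet_weight(self):
        m, b = self._setup(dna=2.0, ww=1.0)
        assert normalize_dna(m, b).values.iloc[0, 0] == pytest.approx(50.0)

    def test_media_samples_pass_through(self):
        m = make_matrix([[100.0]], compartment="media")
        out = normalize_dna(m, pd.DataFrame(columns=["donor", "treatment",
                                                     "replicate", "dna_ng",
                                                     "wet_weight_mg"]))
        assert out.values.iloc[0, 0] == 100.0

    def test_orphan_sample_raises_join_error(self):
        from ocproteo.errors import JoinError

        m, b = self._setup()
        b = b.assign(donor="other")
        with pytest.raises(JoinError):
            normalize_dna(m, b)

    def test_nonpositive_dna_raises(self):
        m, b = self._setup(dna=-1.0)
        with pytest.raises(InputError):
            normalize_dna(m, b)

    def test_constant_scaling_preserves_t_statistics(self):
        # dividing every sample by one constant shifts log2 values uniformly,
        # leaving within-design contrast t statistics identical
        from ocproteo.differential import fit_feature_models, moderated_contrasts

        rng = np.random.default_rng(2)
        vals = rng.uniform(10, 100, size=(12, 8))
        treatments = ["N"] * 4 + ["IC"] * 4
        m1 = make_matrix(vals, treatments=treatments)
        m2 = make_matrix(vals / 2.0, treatments=treatments)
        t1 = moderated_contrasts(
            fit_feature_models(log2_transform(m1), include_batch=False),
            contrasts=[("IC", "N")],
        )
        t2 = moderated_contrasts(
            fit_feature_models(log2_transform(m2), include_batch=False),
            contrasts=[("IC", "N")],
        )
        np.testing.assert_allclose(
            t1["moderated_t"], t2["moderated_t"], rtol=1e-10
        )


class TestRemoveBatch:
    def _batched(self, vals, batches, treatments=None):
        return make_matrix(
            vals, batches=batches, treatments=treatments, scale=SCALE_LOG2
        )

    def test_pure_offset_removed_exactly(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 10))
        vals = base.copy()
        vals[:, 5:] += 2.5
        m = self._batched(vals, ["b1"] * 5 + ["b2"] * 5)
        out = remove_batch(m).values.to_numpy()
        means1, means2 = out[:, :5].mean(axis=1), out[:, 5:].mean(axis=1)
        np.testing.assert_allclose(means1, means2, atol=1e-9)

    def test_zero_batch_effect_identity(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(4, 8))
        m = self._batched(base, ["b1"] * 4 + ["b2"] * 4)
        # data constructed with no batch term; correction must be ~no-op up to
        # the estimated (noise-level) batch coefficient — here use balanced
        # identical halves so the estimate is exactly zero
        sym = np.concatenate([base[:, :4], base[:, :4]], axis=1)
        m = self._batched(sym, ["b1"] * 4 + ["b2"] * 4)
        out = remove_batch(m).values.to_numpy()
        np.testing.assert_allclose(out, sym, atol=1e-9)

    def test_refitted_batch_coefficient_near_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(8, 12)) + np.repeat([[0.0, 1.7]], 6, axis=0).T.reshape(1, -1)
        batches = ["b1", "b2"] * 6
        treatments = ["N", "N", "IC", "IC"] * 3
        m = self._batched(vals, batches, treatments)
        corrected = remove_batch(m)
        # refit: per feature, regress corrected values on design + batch again
        meta = corrected.sample_meta
        X = np.column_stack(
            [
                np.ones(12),
                (meta["treatment"] == "IC").to_numpy(float),
                np.where(meta["batch"] == "b1", 1.0, -1.0),
            ]
        )
        Y = corrected.values.to_numpy().T
        coefs = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.abs(coefs[2]).max() < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(5, 10))
        vals[:, ::2] += rng.normal(size=(5, 1))
        m = self._batched(vals, ["b1"] * 5 + ["b2"] * 5, ["N", "IC"] * 5)
        once = remove_batch(m)
        twice = remove_batch(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-8
        )

    def test_confounded_batch_raises(self):
        vals = np.ones((3, 6)) + np.random.default_rng(7).normal(size=(3, 6))
        m = self._batched(vals, ["b1"] * 3 + ["b2"] * 3,
                          ["N"] * 3 + ["IC"] * 3)
        with pytest.raises(ConfoundingError):
            remove_batch(m)

    def test_single_batch_raises(self):
        m = self._batched(np.ones((2, 4)), ["b1"] * 4)
        with pytest.raises(ConfoundingError):
            remove_batch(m)
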