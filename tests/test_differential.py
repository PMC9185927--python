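"""Per-feature models, empirical-Bayes moderation, FDR, presence classes."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from ocproteo.differential import (
    PriorEstimate,
    adjust_bh,
    condition_unique,
    estimate_prior,
    fit_feature_models,
    moderated_contrasts,
    posterior_s2,
    trigamma_inverse,
)
from ocproteo.errors import ConfigurationError, InputError
from ocproteo.matrix import SCALE_LOG2, AbundanceMatrix


def _two_group(vals, n_per=3):
    treatments = ["N"] * n_per + ["IC"] * n_per
    return make_matrix(vals, treatments=treatments, scale=SCALE_LOG2)


class TestFeatureModels:
    def test_contrast_is_difference_of_group_means(self):
        m = _two_group([[5, 5, 5, 7, 7, 7.0]])
        fit = fit_feature_models(m, include_batch=False)
        res = moderated_contrasts(fit, [("IC", "N")],
                                  prior=PriorEstimate(0.0, 1.0))
        assert res["log2_fc"].iloc[0] == pytest.approx(2.0)

    def test_duplicating_samples_doubles_df(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 6))
        m1 = _two_group(vals)
        doubled = np.concatenate(
            [vals[:, :3], vals[:, :3], vals[:, 3:], vals[:, 3:]], axis=1
        )
        m2 = _two_group(doubled, n_per=6)
        f1 = fit_feature_models(m1, include_batch=False)
        f2 = fit_feature_models(m2, include_batch=False)
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-10)
        assert f2.df == 2 * f1.df + 2  # 12-2 vs 6-2 residual df

    def test_residual_variance_matches_formula(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 6))
        m = _two_group(vals)
        fit = fit_feature_models(m, include_batch=False)
        for i in range(5):
            g1, g2 = vals[i, :3], vals[i, 3:]
            rss = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
            assert fit.s2.iloc[i] == pytest.approx(rss / 4, rel=1e-10)

    def test_rank_deficient_design_names_columns(self):
        m = make_matrix(
            np.ones((2, 4)) + np.random.default_rng(2).normal(size=(2, 4)),
            treatments=["N", "N", "IC", "IC"],
            batches=["b1", "b1", "b2", "b2"],
            scale=SCALE_LOG2,
        )
        with pytest.raises(InputError, match="batch"):
            fit_feature_models(m, include_batch=True)

    def test_incomplete_matrix_rejected(self):
        m = _two_group([[1, 2, np.nan, 4, 5, 6.0]])
        with pytest.raises(InputError):
            fit_feature_models(m, include_batch=False)


class TestEmpiricalBayes:
    def test_identical_variances_degenerate(self):
        prior = estimate_prior([1.0, 1.0, 1.0, 1.0], df=4)
        assert np.isinf(prior.d0)
        assert prior.s02 == pytest.approx(1.0)
        np.testing.assert_allclose(
            posterior_s2(np.array([1.0, 1, 1, 1]), 4, prior), 1.0
        )

    def test_d0_zero_limit_equals_ordinary_t(self):
        rng = np.random.default_rng(3)
        m = _two_group(rng.normal(size=(20, 6)))
        fit = fit_feature_models(m, include_batch=False)
        res = moderated_contrasts(fit, [("IC", "N")],
                                  prior=PriorEstimate(0.0, 123.0))
        # ordinary t from first principles
        beta = fit.coef["treatment[IC]"] - fit.coef["treatment[N]"]
        se = np.sqrt(fit.s2 * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(
            res["moderated_t"], (beta / se), atol=1e-6
        )

    def test_d0_infinite_pools_all_variances(self):
        rng = np.random.default_rng(4)
        m = _two_group(rng.normal(size=(10, 6)))
        fit = fit_feature_models(m, include_batch=False)
        res = moderated_contrasts(fit, [("IC", "N")],
                                  prior=PriorEstimate(np.inf, 2.0))
        beta = fit.coef["treatment[IC]"] - fit.coef["treatment[N]"]
        np.testing.assert_allclose(
            res["moderated_t"], beta / np.sqrt(2.0 * (2 / 3)), atol=1e-6
        )

    def test_hyperparameter_recovery(self):
        # s^2 ~ s0^2 * chi^2_d / d scaled by inverse-chi^2 prior draws
        rng = np.random.default_rng(5)
        d0, s02, d, n = 4.0, 2.0, 4, 2000
        sg2 = s02 * d0 / rng.chisquare(d0, n)
        s2 = sg2 * rng.chisquare(d, n) / d
        prior = estimate_prior(s2, d)
        assert 2.5 <= prior.d0 <= 6.0
        assert 1.6 <= prior.s02 <= 2.5

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in (0.1, 1.0, 5.0, 50.0):
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_moderated_t_monotone_in_effect(self):
        fit_df, s2 = 4, np.array([1.0, 1.0, 1.0])
        prior = PriorEstimate(4.0, 1.0)
        post = posterior_s2(s2, fit_df, prior)
        betas = np.array([0.5, 1.0, 2.0])
        t = betas / np.sqrt(post)
        assert np.all(np.diff(t) > 0)


class TestAdjustBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_passthrough(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            adjust_bh([0.5, 1.5])

    def test_null_calibration(self):
        # under a global null, the fraction of q < 0.05 stays near zero
        rng = np.random.default_rng(6)
        frac = []
        for _ in range(50):
            m = _two_group(rng.normal(size=(100, 6)))
            fit = fit_feature_models(m, include_batch=False)
            res = moderated_contrasts(fit, [("IC", "N")])
            frac.append((res["fdr_q"] < 0.05).mean())
        mc_err = np.std(frac) / np.sqrt(len(frac))
        assert np.mean(frac) <= 0.05 + 2 * mc_err + 0.01


class TestConditionUnique:
    def _matrix(self, presence):
        """presence: feature -> dict treatment -> donors with signal."""
        donors = [f"d{i}" for i in range(1, 8)]
        treatments = ["N", "D", "IC", "ICD"]
        cols, meta = [], []
        for t in treatments:
            for d in donors:
                cols.append(f"{d}_{t}")
                meta.append((d, t))
        vals = np.full((len(presence), len(cols)), np.nan)
        for i, per_trt in enumerate(presence.values()):
            for j, (d, t) in enumerate(meta):
                if d in per_trt.get(t, ()):
                    vals[i, j] = 10.0
        m = make_matrix(
            vals,
            donors=[d for d, _ in meta],
            treatments=[t for _, t in meta],
        )
        return m

    def test_unique_to_ic(self):
        donors6 = [f"d{i}" for i in range(1, 7)]
        m = self._matrix({"f": {"IC": donors6}})
        out = condition_unique(m)
        assert out["conditions"].tolist() == ["IC"]

    def test_everywhere_not_flagged(self):
        alld = [f"d{i}" for i in range(1, 8)]
        m = self._matrix({"f": {t: alld for t in ("N", "D", "IC", "ICD")}})
        assert condition_unique(m).empty

    def test_two_condition_case(self):
        alld = [f"d{i}" for i in range(1, 8)]
        m = self._matrix({"f": {"IC": alld, "ICD": alld[:6]}})
        out = condition_unique(m)
        assert out["conditions"].tolist() == ["IC,ICD"]

    def test_weak_detection_elsewhere_disqualifies(self):
        donors6 = [f"d{i}" for i in range(1, 7)]
        m = self._matrix({"f": {"IC": donors6, "N": ["d1"]}})
        assert condition_unique(m).empty

    def test_threshold_above_donor_count_rejected(self):
        m = self._matrix({"f": {"IC": ["d1"]}})
        with pytest.raises(ConfigurationError):
            condition_unique(m, donor_threshold=20)
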