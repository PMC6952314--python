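"""Censored lognormal regression: closed-form and brute-force oracles,
invariances, and the medication-indicator machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from hrmwas.censored_regression import (
    MEDICATION_TARGETS,
    ModelSpec,
    censored_lognormal_mle,
    detect_medication_indicators,
    fit_censored_lognormal,
    fit_with_medication_adjustment,
)
from hrmwas.feature_table import ValidationError

from conftest import make_table


def _simulate(rng, n_per=30, beta=0.4, sigma=0.5, censor_q=None):
    dx = np.r_[np.zeros(n_per), np.ones(n_per)]
    sex = rng.integers(0, 2, 2 * n_per).astype(float)
    age = rng.uniform(55, 85, 2 * n_per)
    X = np.column_stack([np.ones(2 * n_per), dx, sex, age])
    y = 14.0 + beta * dx + 0.1 * sex + 0.01 * age + rng.normal(0, sigma, 2 * n_per)
    det = np.ones(y.size, dtype=bool)
    if censor_q is not None:
        det = y >= np.quantile(y, censor_q)
    return X, y, det


class TestAgainstOracles:
    def test_no_censoring_matches_ols_closed_form(self):
        """With zero censored observations the MLE equals OLS, and sigma the
        1/n residual SD."""
        rng = np.random.default_rng(1)
        X, y, det = _simulate(rng)
        beta, sigma, cov, ll, conv, _ = censored_lognormal_mle(y, det, X, y.min() - 1.0)
        bo, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert conv
        np.testing.assert_allclose(beta, bo, atol=1e-6)
        assert sigma == pytest.approx(np.sqrt(np.mean((y - X @ bo) ** 2)), abs=1e-6)

    def test_matches_generic_optimizer_on_tiny_instance(self):
        """Independent likelihood written from scratch, maximized with a
        different method, agrees within 1e-4 on an n<=12 instance."""
        rng = np.random.default_rng(7)
        n = 12
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y = 2.0 + 0.5 * X[:, 1] + rng.normal(0, 0.6, n)
        c = np.quantile(y, 0.3)
        det = y >= c

        def nll(theta):
            b, s = theta[:2], abs(theta[2]) + 1e-12
            out = -np.sum(stats.norm.logpdf(y[det], X[det] @ b, s))
            out -= np.sum(stats.norm.logcdf(c, X[~det] @ b, s))
            return out

        ref = optimize.minimize(nll, [y[det].mean(), 0.0, y[det].std()],
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        beta, sigma, *_ = censored_lognormal_mle(y, det, X, c)
        np.testing.assert_allclose(beta, ref.x[:2], atol=1e-4)
        assert sigma == pytest.approx(abs(ref.x[2]), abs=1e-4)

    def test_matches_lifelines_aft(self):
        """Cross-check the diagnosis coefficient against an independent
        left-censored lognormal AFT implementation."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        X, y, det = _simulate(rng, n_per=60, beta=0.5, censor_q=0.2)
        lod = y[det].min()
        beta, sigma, *_ = censored_lognormal_mle(y, det, X, lod)
        df = pd.DataFrame({
            "T": np.exp(np.where(det, y, lod)),
            "E": det.astype(int),
            "dx": X[:, 1], "sex": X[:, 2], "age": X[:, 3],
        })
        aft = lifelines.LogNormalAFTFitter()
        aft.fit_left_censoring(df, "T", "E")
        ref = aft.params_.loc[("mu_", "dx")]
        assert beta[1] == pytest.approx(ref, abs=1e-3)

    def test_loglik_not_below_ols_start(self):
        rng = np.random.default_rng(11)
        X, y, det = _simulate(rng, censor_q=0.25)
        lod = y[det].min()
        beta, sigma, cov, ll, conv, _ = censored_lognormal_mle(y, det, X, lod)
        # log-likelihood at the OLS-based starting point
        y0 = np.where(det, y, lod)
        b0, *_ = np.linalg.lstsq(X, y0, rcond=None)
        s0 = max(np.sqrt(np.mean((y0 - X @ b0) ** 2)), 1e-2)
        u = (lod - X[~det] @ b0) / s0
        ll0 = np.sum(stats.norm.logpdf(y[det], X[det] @ b0, s0)) + np.sum(special.log_ndtr(u))
        assert ll >= ll0 - 1e-9


class TestInvariances:
    def test_scale_invariance(self):
        """Multiplying intensities and LOD by c shifts mu by log c and
        leaves beta and sigma unchanged."""
        rng = np.random.default_rng(5)
        X, y, det = _simulate(rng, censor_q=0.25)
        lod = y[det].min()
        b1, s1, *_ = censored_lognormal_mle(y, det, X, lod)
        c = 7.3
        b2, s2, *_ = censored_lognormal_mle(y + np.log(c), det, X, lod + np.log(c))
        assert b2[0] - b1[0] == pytest.approx(np.log(c), abs=1e-5)
        np.testing.assert_allclose(b2[1:], b1[1:], atol=1e-5)
        assert s2 == pytest.approx(s1, abs=1e-5)

    def test_rank_deficiency_raises(self, sample_info_small):
        vals = pd.Series(np.exp(np.random.default_rng(0).normal(14, 0.5, 24)),
                         index=sample_info_small.index)
        solo = sample_info_small.copy()
        solo["diagnosis"] = "AD"  # single group: diagnosis column constant
        with pytest.raises(ValidationError, match="rank"):
            fit_censored_lognormal(vals, solo, ModelSpec("f"))

    def test_censoring_separation_flagged(self, sample_info_small):
        rng = np.random.default_rng(2)
        vals = pd.Series(np.exp(rng.normal(14, 0.3, 24)), index=sample_info_small.index)
        vals[sample_info_small["diagnosis"] == "NC"] = np.nan  # whole group censored
        fit = fit_censored_lognormal(vals, sample_info_small, ModelSpec("f"))
        assert any("separation" in n for n in fit.notes)


class TestMedicationAdjustment:
    def test_all_zero_indicators_equal_unadjusted(self, sample_info_small):
        rng = np.random.default_rng(4)
        vals = pd.Series(np.exp(rng.normal(14, 0.5, 24)), index=sample_info_small.index)
        med = pd.DataFrame(0, index=["m1", "m2"], columns=sample_info_small.index)
        spec = ModelSpec("f")
        plain = fit_censored_lognormal(vals, sample_info_small, spec)
        adj = fit_with_medication_adjustment(vals, sample_info_small, spec, med)
        assert adj.params["diagnosis"] == pytest.approx(plain.params["diagnosis"], abs=1e-8)
        assert len(adj.notes) == 2  # both constant indicators dropped

    def test_indicator_equal_to_diagnosis_collinear(self, sample_info_small):
        rng = np.random.default_rng(4)
        vals = pd.Series(np.exp(rng.normal(14, 0.5, 24)), index=sample_info_small.index)
        med = pd.DataFrame(
            [(sample_info_small["diagnosis"] == "AD").astype(int)], index=["m1"]
        )
        with pytest.raises(ValidationError, match="rank"):
            fit_with_medication_adjustment(vals, sample_info_small, ModelSpec("f"), med)

    def test_independent_indicator_leaves_beta_stable(self):
        """An indicator independent of outcome and diagnosis changes beta1
        by < 10% relative at large n."""
        rng = np.random.default_rng(9)
        n = 1000
        info = pd.DataFrame({
            "study_id": "s", "diagnosis": ["NC", "AD"] * (n // 2),
            "sex": rng.integers(0, 2, n), "age": rng.uniform(55, 85, n), "batch": "b",
        }, index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"))
        dx = (info["diagnosis"] == "AD").to_numpy(float)
        y = 14.0 + 0.4 * dx + rng.normal(0, 0.5, n)
        vals = pd.Series(np.exp(y), index=info.index)
        med = pd.DataFrame([rng.integers(0, 2, n)], index=["m1"], columns=info.index)
        spec = ModelSpec("f")
        plain = fit_censored_lognormal(vals, info, spec)
        adj = fit_with_medication_adjustment(vals, info, spec, med)
        rel = abs(adj.params["diagnosis"] - plain.params["diagnosis"]) / abs(plain.params["diagnosis"])
        assert rel < 0.10


class TestMedicationDetection:
    def test_exact_mz_feature_returned(self):
        nan = np.nan
        t = make_table(
            mz=[251.1753, 400.0], rt=[100.0, 120.0],
            intensities=[[5e4, nan, 6e4, nan], [1e4, 1e4, 1e4, 1e4]],
        )
        flags = detect_medication_indicators(t)
        assert list(flags.loc["rivastigmine"]) == [1, 0, 1, 0]

    def test_absent_target_gives_zero_row(self):
        t = make_table(mz=[500.0], rt=[100.0], intensities=[[1.0, 2.0]])
        flags = detect_medication_indicators(t)
        assert (flags.loc["memantine"] == 0).all()

    def test_nearest_ppm_wins(self):
        target = MEDICATION_TARGETS["memantine"]
        nan = np.nan
        t = make_table(
            mz=[target * (1 + 1e-6), target * (1 + 3e-6)], rt=[100.0, 100.0],
            intensities=[[10.0, nan], [nan, 10.0]],
        )
        flags = detect_medication_indicators(t)
        assert list(flags.loc["memantine"]) == [1, 0]  # the 1 ppm candidate


class TestParameterRecovery:
    def test_beta_recovery_moderate_replicates(self):
        """Mean estimate near truth and near-nominal Wald coverage over 120
        simulated censored features (a fast version of the full study-scale
        check in the acceptance suite)."""
        from hrmwas.synthetic_data import SimConfig, generate_two_studies

        cfg = SimConfig(seed=13, n_features=120, frac_shared=1.0, frac_affected=1.0,
                        effect_size=0.4, censor_frac_target=0.25, n_batches=1,
                        batch_shift_sd=0.0, batch_scale_sd=0.0, n_adduct_clusters=0,
                        include_mci_in_study1=False)
        t1, _, info, _ = generate_two_studies(cfg)
        s1 = info[info["study_id"] == "study1"]
        ests, cover = [], 0
        for fid in t1.feature_ids:
            fit = fit_censored_lognormal(t1.intensities.loc[fid], s1, ModelSpec(fid))
            e, se = fit.params["diagnosis"], fit.ses["diagnosis"]
            ests.append(e)
            cover += abs(e - 0.4) <= 1.96 * se
        assert np.mean(ests) == pytest.approx(0.4, abs=0.06)
        assert 0.88 <= cover / len(ests) <= 1.0
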