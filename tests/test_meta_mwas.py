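"""Fixed-effects meta-analysis, BH FDR and the replication/selection rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrmwas.meta_mwas import (
    bh_fdr,
    combine_studies,
    fixed_effects_meta,
    heterogeneity,
    medication_sensitivity_check,
    select_features,
)


def brute_force_bh(p):
    """Independent step-up implementation, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestFixedEffects:
    def test_published_combined_estimates(self):
        """Worked combinations from the two-study plasma MWAS: the piperine
        and unknown-halogenated features and the glutamine combined SE."""
        piperine = fixed_effects_meta([-0.59, -0.89], [0.31, 0.49])
        assert round(piperine.estimate, 2) == -0.68
        unknown = fixed_effects_meta([0.41, 0.38], [0.17, 0.21])
        assert round(unknown.estimate, 2) == 0.40
        glutamine = fixed_effects_meta([0.22, 0.31], [0.11, 0.13])
        assert round(glutamine.se, 2) == 0.08

    def test_identical_studies_symmetry(self):
        res = fixed_effects_meta([0.3, 0.3], [0.1, 0.1])
        assert res.estimate == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(0)
        e = rng.normal(0, 1, 5)
        s = rng.uniform(0.05, 0.5, 5)
        ref = combine_effects(e, s**2)
        mine = fixed_effects_meta(e, s)
        assert mine.estimate == pytest.approx(ref.mean_effect_fe, abs=1e-10)
        assert mine.se == pytest.approx(ref.sd_eff_w_fe, abs=1e-10)

    @given(
        st.lists(st.floats(-2, 2), min_size=2, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_estimate_within_study_range_and_se_smaller(self, est, ses):
        ses = ses[: len(est)]
        res = fixed_effects_meta(est, ses)
        assert min(est) - 1e-12 <= res.estimate <= max(est) + 1e-12
        assert res.se < min(ses) + 1e-12

    def test_single_study_passthrough_warns(self, caplog):
        res = fixed_effects_meta([0.5], [0.2])
        assert (res.estimate, res.se) == (0.5, 0.2)

    def test_invalid_se_excluded(self):
        res = fixed_effects_meta([0.5, 0.7, 0.9], [0.2, np.nan, 0.0])
        assert (res.estimate, res.se) == (0.5, 0.2)

    def test_heterogeneity_zero_for_identical(self):
        q, i2 = heterogeneity([0.4, 0.4], [0.1, 0.1])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0


class TestBhFdr:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.3] * 5), [0.3] * 5)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=60))
    @settings(max_examples=250, deadline=None)
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=30), st.randoms())
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_fdr(p)
        q_perm = bh_fdr([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


def _records(rows):
    df = pd.DataFrame(rows).set_index("feature_id")
    return df


class TestSelection:
    def test_replicated_positive_feature_selected(self):
        rec = _records([
            dict(feature_id="gln", est_study1=0.22, est_study2=0.31,
                 p_study1=0.04, p_study2=0.02, fdr_q=0.07),
        ])
        out = select_features(rec)
        assert bool(out.loc["gln", "selected"])

    def test_per_study_p_rule(self):
        rec = _records([
            dict(feature_id="a", est_study1=0.4, est_study2=0.4,
                 p_study1=0.04, p_study2=0.12, fdr_q=0.001),
        ])
        assert not select_features(rec)["selected"].any()

    def test_sign_discordance_rejected(self):
        rec = _records([
            dict(feature_id="a", est_study1=0.3, est_study2=-0.3,
                 p_study1=1e-6, p_study2=1e-6, fdr_q=1e-6),
        ])
        assert not select_features(rec)["selected"].any()

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        rows = [dict(feature_id=f"f{i}",
                     est_study1=rng.normal(), est_study2=rng.normal(),
                     p_study1=rng.uniform(0, 0.3), p_study2=rng.uniform(0, 0.3),
                     fdr_q=rng.uniform(0, 0.4)) for i in range(80)]
        rec = _records(rows)
        tight = select_features(rec, fdr_thresh=0.20, per_study_p=0.10)
        loose = select_features(rec, fdr_thresh=0.30, per_study_p=0.20)
        assert set(tight.index[tight["selected"]]) <= set(loose.index[loose["selected"]])

    def test_combine_studies_restricts_to_common_features(self):
        long = pd.DataFrame({
            "study_id": ["s1", "s1", "s2"],
            "feature_id": ["a", "b", "a"],
            "estimate": [0.2, 0.3, 0.4], "se": [0.1, 0.1, 0.2], "p": [0.05, 0.01, 0.04],
        })
        rec = combine_studies(long)
        assert list(rec.index) == ["a"]
        assert rec.loc["a", "meta_se"] <= min(0.1, 0.2)


class TestMedicationSensitivity:
    def test_unchanged_betas_kept(self):
        out = medication_sensitivity_check({"s1": 0.4, "s2": 0.3}, {"s1": 0.4, "s2": 0.3})
        assert out["verdict"] == "keep"

    def test_strong_attenuation_excluded(self):
        out = medication_sensitivity_check({"s1": 0.40, "s2": 0.30}, {"s1": 0.10, "s2": 0.30})
        assert out["verdict"] == "exclude"

    def test_sign_flip_excluded(self):
        out = medication_sensitivity_check({"s1": 0.2, "s2": 0.2}, {"s1": -0.25, "s2": 0.2})
        assert out["verdict"] == "exclude"

    def test_nonconvergent_adjusted_is_indeterminate(self):
        out = medication_sensitivity_check({"s1": 0.4, "s2": 0.3}, {"s1": None, "s2": 0.3})
        assert out["verdict"] == "indeterminate"

    def test_medication_driven_feature_excluded_on_simulation(self):
        """A feature causally driven by a medication given to cases is
        excluded; diagnosis-driven features are kept."""
        from hrmwas.censored_regression import (
            ModelSpec, detect_medication_indicators,
            fit_censored_lognormal, fit_with_medication_adjustment)
        from hrmwas.synthetic_data import (
            SimConfig, generate_two_studies, spike_dependent_feature,
            spike_medication_features)

        cfg = SimConfig(seed=21, n_features=40, n_per_group=40, frac_shared=1.0,
                        frac_affected=0.1, effect_size=0.8, censor_frac_target=0.0,
                        n_batches=1, batch_shift_sd=0.0, batch_scale_sd=0.0,
                        n_adduct_clusters=0, include_mci_in_study1=False)
        t1, t2, info, truth = generate_two_studies(cfg)
        verdicts = {}
        for study, t in (("study1", t1), ("study2", t2)):
            sub = info[info["study_id"] == study]
            cases = sub.index[sub["diagnosis"] == "AD"]
            t = spike_medication_features(t, {"memantine": 180.1748}, 0.5, cases, seed=5)
            med = detect_medication_indicators(t, {"memantine": 180.1748})
            t = spike_dependent_feature(t, med.loc["memantine"], mz=700.1234, effect=1.5, seed=6)
            for fid in ["DEP_700.1234", truth.affected_feature_ids[0]]:
                spec = ModelSpec(fid)
                plain = fit_censored_lognormal(t.intensities.loc[fid], sub, spec)
                adj = fit_with_medication_adjustment(t.intensities.loc[fid], sub, spec, med)
                verdicts.setdefault(fid, [{}, {}])
                verdicts[fid][0][study] = float(plain.params["diagnosis"])
                verdicts[fid][1][study] = float(adj.params["diagnosis"])
        dep = medication_sensitivity_check(*verdicts["DEP_700.1234"])
        real = medication_sensitivity_check(*verdicts[truth.affected_feature_ids[0]])
        assert dep["verdict"] == "exclude"
        assert real["verdict"] == "keep"
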