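"""Feature-table model: I/O, LOD rule, filters, batch correction, CSF rule."""

import numpy as np
import pandas as pd
import pytest

from hrmwas.feature_table import (
    BIOMARKER_NEGATIVE,
    BIOMARKER_POSITIVE,
    UNCLASSIFIABLE,
    ValidationError,
    classify_csf,
    correct_batches,
    filter_presence,
    filter_rt,
    read_feature_table,
    validate_sample_info,
    write_feature_table,
    write_sample_info,
)

from conftest import make_table


@pytest.fixture()
def toy_table():
    nan = np.nan
    return make_table(
        mz=[100.05, 200.10, 300.15],
        rt=[25.0, 30.0, 120.0],
        intensities=[
            [1200.0, 5000.0, nan, 3000.0],
            [nan, nan, nan, 900.0],
            [10.0, 20.0, 30.0, 40.0],
        ],
    )


class TestModelAndIO:
    def test_lod_is_lowest_detected(self, toy_table):
        assert toy_table.lod["f0"] == 1200.0
        assert toy_table.lod["f1"] == 900.0

    def test_round_trip(self, toy_table, tmp_path):
        p = tmp_path / "t.csv"
        write_feature_table(toy_table, p)
        back = read_feature_table(p)
        pd.testing.assert_frame_equal(back.features, toy_table.features)
        pd.testing.assert_frame_equal(back.intensities, toy_table.intensities)

    def test_missing_sample_metadata_named(self, toy_table, tmp_path, sample_info_small):
        write_feature_table(toy_table, tmp_path / "t.csv")
        write_sample_info(sample_info_small.iloc[:2], tmp_path / "m.csv")
        with pytest.raises(ValidationError, match="s2"):
            read_feature_table(tmp_path / "t.csv", tmp_path / "m.csv")

    def test_non_numeric_intensity_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "feature_id,mz,rt,s0,s1\nf0,100.0,60.0,12.0,oops\n"
        )
        with pytest.raises(ValidationError, match="non-numeric"):
            read_feature_table(tmp_path / "bad.csv")

    def test_duplicate_feature_ids_rejected(self, tmp_path):
        (tmp_path / "dup.csv").write_text(
            "feature_id,mz,rt,s0\nf0,100.0,60.0,1.0\nf0,101.0,61.0,2.0\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_feature_table(tmp_path / "dup.csv")

    def test_sample_info_validation(self, sample_info_small):
        validate_sample_info(sample_info_small)
        bad = sample_info_small.copy()
        bad.loc[bad.index[0], "diagnosis"] = "ALS"
        with pytest.raises(ValidationError, match="diagnosis"):
            validate_sample_info(bad)


class TestFilters:
    def test_rt_threshold_is_strict_below(self, toy_table):
        out = filter_rt(toy_table, 30.0)
        assert list(out.features.index) == ["f1", "f2"]  # 25 s removed, 30 s kept

    def test_rt_zero_is_identity(self, toy_table):
        assert list(filter_rt(toy_table, 0.0).features.index) == list(toy_table.features.index)

    def test_rt_all_removed_gives_empty(self, toy_table):
        assert len(filter_rt(toy_table, 1000.0).features) == 0

    def test_presence_is_strict_greater(self):
        # 80/100 detected at min_frac=0.8 -> removed; 81/100 -> retained
        nan = np.nan
        row80 = [1.0] * 80 + [nan] * 20
        row81 = [1.0] * 81 + [nan] * 19
        t = make_table([100.0, 200.0], [60.0, 60.0], [row80, row81])
        out = filter_presence(t, 0.8)
        assert list(out.features.index) == ["f1"]

    def test_presence_zero_identity_when_all_detected_once(self, toy_table):
        out = filter_presence(toy_table, 0.0)
        assert list(out.features.index) == list(toy_table.features.index)

    def test_filters_idempotent_and_commute(self, small_sim):
        _, t1, _, _, _ = small_sim
        a = filter_presence(filter_rt(t1, 30), 0.8)
        b = filter_rt(filter_presence(t1, 0.8), 30)
        assert list(a.features.index) == list(b.features.index)
        again = filter_presence(filter_rt(a, 30), 0.8)
        pd.testing.assert_frame_equal(a.intensities, again.intensities)


class TestBatchCorrection:
    def test_single_batch_identity(self, small_sim):
        _, t1, _, _, _ = small_sim
        t = t1.copy()
        t.batches = pd.Series("b0", index=t.sample_ids)
        out = correct_batches(t)
        np.testing.assert_allclose(
            out.intensities.to_numpy(), t.intensities.to_numpy(), rtol=1e-10
        )

    def test_pure_additive_shift_removed(self):
        """Two batches differing by a pure log-scale shift delta: the
        post-correction between-batch mean difference is < 0.05 * delta."""
        rng = np.random.default_rng(3)
        n_feat, n_per = 150, 60
        delta = 1.0  # log2 units
        base = rng.normal(14, 0.3, size=(n_feat, 2 * n_per))
        base[:, n_per:] += delta
        t = make_table(
            mz=np.linspace(100, 900, n_feat),
            rt=np.full(n_feat, 100.0),
            intensities=np.power(2.0, base),
            batches=["b1"] * n_per + ["b2"] * n_per,
        )
        out = correct_batches(t)
        L = np.log2(out.intensities.to_numpy())
        diff = L[:, n_per:].mean(axis=1) - L[:, :n_per].mean(axis=1)
        assert np.abs(diff).mean() < 0.05 * delta
        # grand mean per feature preserved
        np.testing.assert_allclose(
            L.mean(axis=1), base.mean(axis=1), atol=0.02
        )

    def test_nondetects_untouched_and_positive(self, small_sim):
        _, t1, _, _, _ = small_sim
        out = correct_batches(t1)
        pd.testing.assert_frame_equal(out.detected, t1.detected)
        assert (out.intensities.fillna(1.0) > 0).all().all()

    def test_tiny_batch_rejected(self, toy_table):
        toy_table.batches = pd.Series(["a", "a", "a", "b"], index=toy_table.sample_ids)
        with pytest.raises(ValidationError, match="<2 samples"):
            correct_batches(toy_table)

    def test_all_nondetect_batch_rejected(self):
        nan = np.nan
        t = make_table(
            [100.0, 200.0], [60.0, 60.0],
            [[1.0, 2.0, nan, nan], [3.0, 4.0, nan, nan]],
            batches=["a", "a", "b", "b"],
        )
        with pytest.raises(ValidationError, match="batch 'b'"):
            correct_batches(t)


class TestCsfClassification:
    def test_ad_group_means_positive(self):
        assert classify_csf(117, 203) == BIOMARKER_POSITIVE  # ratio 0.576

    def test_control_group_means_negative(self):
        assert classify_csf(44, 340) == BIOMARKER_NEGATIVE  # ratio 0.129

    def test_threshold_inclusive(self):
        assert classify_csf(39.0, 100.0) == BIOMARKER_POSITIVE  # exactly 0.39

    def test_missing_biomarkers_unclassifiable(self):
        assert classify_csf(None, 200) == UNCLASSIFIABLE
        assert classify_csf(np.nan, 200) == UNCLASSIFIABLE
        assert classify_csf(50, 0) == UNCLASSIFIABLE
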