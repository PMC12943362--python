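"""Drift correction, QC metrics, feature filters, sample outliers."""

import numpy as np
import pytest

from pfasmet.qc import (compute_qc_metrics,
                        detect_sample_outliers, drift_correct, filter_features)
from pfasmet.simulate import SynthConfig, generate_feature_study

from .conftest import make_study


def _drifting_study(grouped_cohort, n_features=100, amplitude=1.0, seed=33):
    _, cohort = grouped_cohort
    cfg = SynthConfig(n_subjects_total=200, n_per_group=41, n_features=n_features,
                      n_planted=0, drift_amplitude=amplitude, drift_shape="linear",
                      qc_rsd_target=0.05, detection_quantile=0.0,
                      missing_rate_random=0.0, seed=seed)
    return generate_feature_study(cfg, cohort)


class TestDriftCorrect:
    def test_flat_features_pass_through_nearly_unchanged(self, grouped_cohort):
        study, _ = _drifting_study(grouped_cohort, n_features=60, amplitude=0.0)
        corrected, report = drift_correct(study)
        # without drift the spline has no predictive signal: most features
        # are left untouched, and any accepted correction is nearly null
        assert len(report.rejected) >= 0.7 * study.intensities.shape[0]
        a = study.intensities.to_numpy()
        b = corrected.intensities.to_numpy()
        rel = np.abs(b - a) / a
        assert np.nanmedian(np.nanmax(rel, axis=1)) < 0.01

    def test_monotone_twofold_drift_is_removed(self, grouped_cohort):
        study, _ = _drifting_study(grouped_cohort, n_features=100, amplitude=1.0)
        pre = compute_qc_metrics(study).table["rsd_qc"]
        corrected, report = drift_correct(study)
        post = compute_qc_metrics(corrected).table["rsd_qc"]
        improved = (post < pre).mean()
        assert improved >= 0.95
        assert len(report.corrected) >= 95

    def test_feature_with_three_qcs_passes_through(self):
        rng = np.random.default_rng(0)
        roles = ["qc", "sample", "sample", "qc", "sample", "sample", "qc",
                 "sample", "sample", "qc"]
        m = np.exp(rng.normal(10, 0.3, (2, 10)))
        m[0, 9] = np.nan  # only 3 observed QCs for feature 0
        study = make_study(m, roles, groups=["", "low", "high", "", "low", "high",
                                             "", "low", "high", ""])
        corrected, report = drift_correct(study)
        assert "F001" in report.too_few_qc
        keep = np.isfinite(m[0])
        assert np.allclose(corrected.intensities.to_numpy()[0, keep], m[0, keep])

    def test_missingness_is_never_altered(self, small_study):
        _, _, study, _ = small_study
        corrected, _ = drift_correct(study)
        assert np.array_equal(np.isfinite(study.intensities.to_numpy()),
                              np.isfinite(corrected.intensities.to_numpy()))

    def test_accepted_corrections_reduce_qc_rsd(self, small_study):
        _, _, study, _ = small_study
        pre = compute_qc_metrics(study).table["rsd_qc"]
        corrected, report = drift_correct(study)
        post = compute_qc_metrics(corrected).table["rsd_qc"]
        assert (post[report.corrected] < pre[report.corrected] + 1e-9).all()


class TestQCMetrics:
    def test_hand_computed_rsd_and_dratio(self):
        roles = ["qc", "qc", "qc", "sample", "sample", "sample", "blank"]
        groups = ["", "", "", "low", "low", "high", ""]
        # feature 1: QC {8,10,12} -> sd 2, mean 10, RSD 20%
        # feature 2: QC {90,100,110}, samples with identical sd -> D-ratio 100%
        m = np.array([[8, 10, 12, 50, 60, 70, 1.0],
                      [90, 100, 110, 90, 100, 110, 1.0],
                      [5, 5, 5, 5, 5, 5, 1.0]], dtype=float)
        study = make_study(m, roles, groups=groups)
        tab = compute_qc_metrics(study).table
        assert tab.loc["F001", "rsd_qc"] == pytest.approx(20.0)
        assert tab.loc["F002", "dratio"] == pytest.approx(100.0)
        assert tab.loc["F003", "rsd_qc"] == pytest.approx(0.0)
        assert tab.loc["F003", "dratio"] == pytest.approx(0.0)

    def test_feature_absent_from_all_qcs_flagged_undefined(self):
        roles = ["qc", "qc", "sample", "sample", "sample", "sample"]
        groups = ["", "", "low", "low", "high", "high"]
        m = np.array([[np.nan, np.nan, 5, 6, 7, 8.0]])
        study = make_study(m, roles, groups=groups)
        tab = compute_qc_metrics(study).table
        assert np.isnan(tab.loc["F001", "rsd_qc"])
        assert tab.loc["F001", "detect_qc"] == 0.0


class TestFilterFeatures:
    def _toy_study(self):
        """Six features each violating one criterion, one clean."""
        roles = (["blank"] * 2 + ["qc"] * 10
                 + ["sample"] * 8)
        groups = [""] * 12 + ["low"] * 4 + ["high"] * 4
        n = len(roles)
        rng = np.random.default_rng(1)

        def clean_row():
            row = np.empty(n)
            row[:2] = 1.0                      # blanks
            row[2:12] = 1000 * (1 + 0.01 * rng.normal(size=10))   # tight QCs
            row[12:] = 1000 * (1 + 0.5 * rng.normal(size=8))      # spread samples
            return np.abs(row) + 1
        rows = []
        r = clean_row(); rows.append(r)                       # clean
        r = clean_row(); r[12:] = 5.0; r[2:12] = 5.0; rows.append(r)   # blank rule
        r = clean_row(); r[12:18] = np.nan; rows.append(r)    # group detection
        r = clean_row(); r[2:8] = np.nan; rows.append(r)      # qc detection < 70%
        r = clean_row(); r[2:12] = np.abs(1000 * (1 + 0.8 * rng.normal(size=10))) + 1
        rows.append(r)                                        # QC RSD > 30%
        r = clean_row(); r[12:] = 1000 * (1 + 0.001 * rng.normal(size=8))
        rows.append(r)                                        # D-ratio > 40%
        return make_study(np.array(rows), roles, groups=groups)

    def test_per_criterion_counts_match_hand_construction(self):
        study = self._toy_study()
        metrics = compute_qc_metrics(study)
        filtered, report = filter_features(study, metrics)
        assert report.retained == ["F001"]
        assert report.removed_by == {"blank": 1, "detection": 2, "rsd": 1,
                                     "dratio": 1}
        assert filtered.intensities.shape[0] == 1

    def test_idempotent(self):
        study = self._toy_study()
        metrics = compute_qc_metrics(study)
        once, r1 = filter_features(study, metrics)
        twice, r2 = filter_features(once, compute_qc_metrics(once))
        assert r2.retained == r1.retained
        assert sum(r2.removed_by.values()) == 0

    def test_clean_synthetic_study_passes_untouched(self, grouped_cohort):
        study, _ = _drifting_study(grouped_cohort, n_features=50, amplitude=0.0)
        metrics = compute_qc_metrics(study)
        _, report = filter_features(study, metrics)
        assert sum(report.removed_by.values()) == 0

    def test_no_blanks_skips_blank_rule_with_warning(self):
        roles = ["qc"] * 4 + ["sample"] * 8
        groups = [""] * 4 + ["low"] * 4 + ["high"] * 4
        rng = np.random.default_rng(2)
        m = np.abs(rng.normal(100, 5, (3, 12))) + 1
        study = make_study(m, roles, groups=groups)
        with pytest.warns(UserWarning, match="blank"):
            _, report = filter_features(study, compute_qc_metrics(study))
        assert "blank" in report.skipped


class TestSampleOutliers:
    def _study_with_counts(self, counts_low, counts_high, n_features=50):
        rng = np.random.default_rng(0)
        n = len(counts_low) + len(counts_high) + 2
        roles = ["qc", "qc"] + ["sample"] * (n - 2)
        groups = ["", ""] + ["low"] * len(counts_low) + ["high"] * len(counts_high)
        m = np.abs(rng.normal(100, 10, (n_features, n))) + 1
        for i, c in enumerate(list(counts_low) + list(counts_high)):
            col = 2 + i
            m[c:, col] = np.nan
        return make_study(m, roles, groups=groups)

    def test_low_count_sample_flagged(self):
        study = self._study_with_counts([50] * 19 + [20], [50] * 20)
        report = detect_sample_outliers(study)
        flagged = list(report.flags.index[report.flags])
        assert len(flagged) == 1

    def test_uniform_counts_give_no_outliers(self):
        study = self._study_with_counts([40] * 10, [40] * 10)
        report = detect_sample_outliers(study)
        assert not report.flags.any()

    def test_flags_invariant_to_sample_order(self):
        study = self._study_with_counts([50] * 9 + [10], [50] * 10)
        report1 = detect_sample_outliers(study)
        perm = list(np.random.default_rng(1).permutation(study.intensities.columns))
        shuffled = make_study(study.intensities[perm].to_numpy(),
                              list(study.injections.loc[perm, "role"]),
                              orders=list(study.injections.loc[perm, "order"]),
                              groups=list(study.injections.loc[perm, "group"]))
        mapping = dict(zip(shuffled.intensities.columns, perm))
        report2 = detect_sample_outliers(shuffled)
        for new_id, old_id in mapping.items():
            if new_id in report2.flags.index:
                assert report2.flags[new_id] == report1.flags[old_id]

    def test_small_group_not_evaluable(self):
        study = self._study_with_counts([40, 40, 30], [40] * 6)
        report = detect_sample_outliers(study)
        assert "low" in report.not_evaluable
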