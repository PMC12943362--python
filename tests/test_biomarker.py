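"""Associations, ROC, clustering, MCCV ranking, panel construction and SVM."""

import numpy as np
import pandas as pd
import pytest

from pfasmet.biomarker import (build_panel, cluster_features,
                               correlation_category, evaluate_panel_svm,
                               rank_features_mccv, sensitivity_regression,
                               spearman_assoc, univariate_roc)

from .oracles import auc_pair_counting


class TestSpearmanAssociation:
    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, 40)
        t = v + rng.normal(0, 1, 40)
        a = spearman_assoc(v, t)
        b = spearman_assoc(v, np.exp(t * 3.0))
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_perfect_concordance_is_strong(self):
        res = spearman_assoc(np.arange(10.0), np.arange(10.0) * 2 + 1)
        assert res.r == pytest.approx(1.0)
        assert res.category == "strong"

    def test_category_bins_reproduce_reported_labels(self):
        # the eight reported exposure-associated metabolites: r = 0.61 is the
        # single strong case; the remainder are weak
        assert correlation_category(0.61) == "strong"
        for r in (0.34, 0.25, 0.23, -0.25, -0.27, -0.31, -0.33):
            assert correlation_category(r) == "weak"
        assert correlation_category(0.151) == "very weak"
        assert correlation_category(0.45) == "moderate"

    def test_constant_input_flagged(self):
        res = spearman_assoc(np.full(6, 2.0), np.arange(6.0))
        assert res.category == "undefined"


class TestSensitivityRegression:
    def test_orthogonal_covariates_have_unit_vif(self):
        n = 64
        # orthogonal contrast-coded covariates
        c1 = np.tile([1, -1], n // 2).astype(float)
        c2 = np.tile([1, 1, -1, -1], n // 4).astype(float)
        cov = pd.DataFrame({"c1": c1, "c2": c2})
        rng = np.random.default_rng(3)
        t = np.tile([1, 1, 1, 1, -1, -1, -1, -1], n // 8).astype(float)
        y = 0.5 * t + rng.normal(0, 0.1, n)
        res = sensitivity_regression(y, t, cov)
        assert res.vif["c1"] == pytest.approx(1.0, abs=1e-9)
        assert res.vif["c2"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(4)
        t = rng.normal(0, 1, 30)
        cov = pd.DataFrame({"a": rng.normal(0, 1, 30)})
        cov["b"] = cov["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            sensitivity_regression(rng.normal(0, 1, 30), t, cov)

    def test_adjusted_beta_recovers_generative_slope(self):
        rng = np.random.default_rng(5)
        n = 300
        t = rng.uniform(0, 300, n)
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n).astype(float),
                            "age": rng.uniform(20, 60, n)})
        y = 0.002 * t + 0.1 * cov["sex"] + rng.normal(0, 0.1, n)
        res = sensitivity_regression(y.to_numpy(), t, cov)
        assert res.beta_adjusted == pytest.approx(0.002, abs=3e-4)
        assert res.beta_unadjusted == pytest.approx(0.002, abs=3e-4)


class TestUnivariateROC:
    def test_perfect_separation(self):
        v = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        res = univariate_roc(v, y, n_boot=100, seed=0)
        assert res.auc == 1.0

    def test_hand_computed_three_quarters(self):
        v = np.array([1.0, 3.0, 2.0, 4.0])
        y = np.array([0, 0, 1, 1])
        res = univariate_roc(v, y, n_boot=100, seed=0)
        assert res.auc == pytest.approx(0.75)

    def test_auc_equals_u_statistic_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            pos = rng.integers(0, 5, rng.integers(3, 10)).astype(float)
            neg = rng.integers(0, 5, rng.integers(3, 10)).astype(float)
            v = np.concatenate([neg, pos])
            y = np.array([0] * neg.size + [1] * pos.size)
            res = univariate_roc(v, y, n_boot=10, seed=0)
            assert res.auc == pytest.approx(auc_pair_counting(pos, neg), abs=1e-12)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(0, 1, 41), rng.normal(0.8, 1, 41)])
        y = np.array([0] * 41 + [1] * 41)
        res = univariate_roc(v, y, n_boot=500, seed=1)
        assert res.ci[0] <= res.auc <= res.ci[1]


class TestClustering:
    def test_correlated_blocks_recovered(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0, 1, 60)
        X = pd.DataFrame({
            "a1": a, "a2": 2 * a + 1, "a3": -a,        # |rho| = 1 block
            "b1": b, "b2": 3 * b - 2,
        })
        labels = cluster_features(X, k=2)
        assert labels["a1"] == labels["a2"] == labels["a3"]
        assert labels["b1"] == labels["b2"]
        assert labels["a1"] != labels["b1"]

    def test_k_equals_p_gives_singletons(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("wxyz"))
        labels = cluster_features(X, k=4)
        assert labels.nunique() == 4

    def test_invariant_to_feature_order_up_to_relabeling(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(0, 1, (50, 6)),
                         columns=[f"f{i}" for i in range(6)])
        l1 = cluster_features(X, k=3)
        perm = ["f3", "f0", "f5", "f1", "f4", "f2"]
        l2 = cluster_features(X[perm], k=3)
        # same partition: co-membership must agree
        for f in perm:
            for g in perm:
                assert (l1[f] == l1[g]) == (l2[f] == l2[g])

    def test_k_above_candidates_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            cluster_features(X, k=5)


class TestRankingMCCV:
    def test_dominant_feature_always_selected(self):
        rng = np.random.default_rng(11)
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame(rng.normal(0, 1, (40, 31)),
                         columns=[f"f{i}" for i in range(31)])
        X["f0"] += 3.0 * y
        freqs = rank_features_mccv(X, y, n_iter=40, seed=0)
        assert freqs["f0"] == 1.0
        assert ((freqs >= 0) & (freqs <= 1)).all()

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(12)
        y = np.array([0] * 15 + [1] * 15)
        X = pd.DataFrame(rng.normal(0, 1, (30, 20)))
        a = rank_features_mccv(X, y, n_iter=25, seed=5)
        b = rank_features_mccv(X, y, n_iter=25, seed=5)
        assert a.equals(b)


class TestBuildPanel:
    def test_exhaustive_argmax_per_cluster(self):
        ids = [f"m{i}" for i in range(10)]
        clusters = pd.Series([1, 1, 2, 2, 3, 3, 4, 4, 5, 5], index=ids)
        rng = np.random.default_rng(13)
        freqs = pd.Series(rng.uniform(0.3, 1.0, 10).round(2), index=ids)
        aucs = pd.Series(rng.uniform(0.5, 0.9, 10).round(3), index=ids)
        panel = build_panel(clusters, freqs, aucs, top_n=12, panel_size=5)
        # oracle: brute-force best AUC per cluster (all in top set, top_n=12)
        for c in range(1, 6):
            members = [f for f in ids if clusters[f] == c]
            best = max(members, key=lambda f: (aucs[f], freqs[f]))
            assert best in panel
        assert len(panel) == 5

    def test_one_candidate_per_cluster_returns_all(self):
        ids = ["a", "b", "c"]
        clusters = pd.Series([1, 2, 3], index=ids)
        freqs = pd.Series([0.5, 0.6, 0.7], index=ids)
        aucs = pd.Series([0.6, 0.7, 0.8], index=ids)
        assert sorted(build_panel(clusters, freqs, aucs, panel_size=3)) == ids

    def test_auc_tie_broken_by_frequency(self):
        ids = ["a", "b"]
        clusters = pd.Series([1, 1], index=ids)
        freqs = pd.Series({"a": 0.4, "b": 0.9})
        aucs = pd.Series({"a": 0.7, "b": 0.7})
        assert build_panel(clusters, freqs, aucs, panel_size=1) == ["b"]

    def test_cluster_outside_top_set_falls_back_with_warning(self):
        ids = [f"m{i}" for i in range(4)]
        clusters = pd.Series([1, 1, 2, 2], index=ids)
        freqs = pd.Series([0.9, 0.8, 0.1, 0.05], index=ids)
        aucs = pd.Series([0.6, 0.7, 0.8, 0.9], index=ids)
        with pytest.warns(UserWarning, match="falling back"):
            panel = build_panel(clusters, freqs, aucs, top_n=2, panel_size=2)
        assert "m3" in panel        # best AUC of the excluded cluster


class TestPanelSVM:
    def test_perfect_panel_saturates(self):
        rng = np.random.default_rng(14)
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame({"f1": y * 10.0 + rng.normal(0, 0.01, 40),
                          "f2": rng.normal(0, 1, 40)})
        res = evaluate_panel_svm(X, y, n_iter=20, n_perm=99, seed=0,
                                 null_n_iter=5)
        assert res.auc == pytest.approx(1.0)
        assert res.perm_p == pytest.approx(1 / 100)

    def test_null_panel_not_significant_on_average(self):
        rng = np.random.default_rng(15)
        y = np.array([0] * 20 + [1] * 20)
        ps = []
        for seed in range(10):
            X = pd.DataFrame(rng.normal(0, 1, (40, 5)))
            res = evaluate_panel_svm(X, y, n_iter=10, n_perm=39, seed=seed,
                                     null_n_iter=10)
            ps.append(res.perm_p)
        assert np.mean(ps) > 0.2

    def test_rejects_tiny_classes(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            evaluate_panel_svm(X, y, n_iter=5, n_perm=0, seed=0)
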