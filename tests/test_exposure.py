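"""Censored imputation, totals, group assignment, cohort comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pfasmet.containers import CohortTable
from pfasmet.exposure import (assign_extreme_groups, cliffs_delta,
                              compare_groups, fit_and_impute_censored,
                              phi_coefficient, total_pfas)

from .conftest import make_cohort
from .oracles import cliffs_delta_enumeration, phi_from_indicators


def _simulate_censored(n, mu, sigma, censored_frac, seed):
    rng = np.random.default_rng(seed)
    conc = np.exp(rng.normal(mu, sigma, n))
    lod = float(np.exp(mu + sigma * sps.norm.ppf(censored_frac)))
    flags = np.where(conc < lod, "below_lod", "quantified")
    values = np.where(flags == "quantified", conc, np.nan)
    return values, flags, lod


class TestCensoredImputation:
    def test_uncensored_sample_equals_plain_lognormal_mle(self):
        rng = np.random.default_rng(1)
        conc = np.exp(rng.normal(0.5, 0.4, 200))
        flags = np.array(["quantified"] * 200, dtype=object)
        _, fit = fit_and_impute_censored(conc, flags, lod=1e-6, loq=1e-6)
        log_c = np.log(conc)
        assert fit.mu == pytest.approx(log_c.mean(), abs=1e-3)
        assert fit.sigma == pytest.approx(log_c.std(ddof=0), abs=1e-3)

    def test_mostly_censored_compound_left_unimputed(self):
        values = np.array([np.nan, np.nan, np.nan, 1.0])
        flags = np.array(["below_lod"] * 3 + ["quantified"], dtype=object)
        out, fit = fit_and_impute_censored(values, flags, lod=0.5, loq=0.6)
        assert not fit.imputed
        assert np.isnan(out[:3]).all() and out[3] == 1.0

    def test_recovers_parameters_under_30pct_censoring(self):
        for seed in range(5):
            values, flags, lod = _simulate_censored(500, 1.0, 0.5, 0.30, seed)
            _, fit = fit_and_impute_censored(values, flags, lod=lod, loq=lod)
            assert abs(fit.mu - 1.0) < 0.1
            assert abs(fit.sigma - 0.5) < 0.1

    def test_draws_stay_inside_truncation_intervals(self):
        rng = np.random.default_rng(4)
        conc = np.exp(rng.normal(0.0, 1.0, 300))
        lod, loq = 0.4, 0.9
        flags = np.where(conc < lod, "below_lod",
                         np.where(conc < loq, "between_lod_loq", "quantified"))
        values = np.where(flags == "quantified", conc, np.nan)
        out, fit = fit_and_impute_censored(values, flags.astype(object),
                                           lod=lod, loq=loq, seed=8)
        assert fit.imputed
        below = out[flags == "below_lod"]
        between = out[flags == "between_lod_loq"]
        assert np.all((below > 0) & (below < lod))
        assert np.all((between >= lod) & (between < loq))

    def test_loq_rule_counts_only_quantified(self):
        conc = np.array([1.0, 2.0] + [np.nan] * 8)
        flags = np.array(["quantified"] * 2 + ["between_lod_loq"] * 8, dtype=object)
        _, fit_lod = fit_and_impute_censored(conc, flags, lod=0.2, loq=0.9, rule="lod")
        _, fit_loq = fit_and_impute_censored(conc, flags, lod=0.2, loq=0.9, rule="loq")
        assert fit_lod.imputed and fit_lod.fraction_above == 1.0
        assert not fit_loq.imputed and fit_loq.fraction_above == 0.2

    def test_rejects_nonpositive_lod(self):
        with pytest.raises(ValueError):
            fit_and_impute_censored([1.0], ["quantified"], lod=0.0, loq=0.1)


def _cohort_with_compounds(rows, lods_loqs):
    subj = {}
    for name, (vals, flags) in rows.items():
        subj[f"{name}_value"] = vals
        subj[f"{name}_flag"] = flags
    n = len(next(iter(rows.values()))[0])
    subjects = pd.DataFrame(subj, index=pd.Index([f"S{i}" for i in range(n)],
                                                 name="subject_id"))
    compounds = pd.DataFrame(lods_loqs, index=pd.Index(list(rows), name="compound"),
                             columns=["lod", "loq"])
    return CohortTable(subjects, compounds)


class TestTotalPFAS:
    def test_loq_half_substitution(self):
        cohort = _cohort_with_compounds(
            {"A": ([1.0], ["quantified"]), "B": ([np.nan], ["below_lod"])},
            [[0.05, 0.1], [0.1, 0.2]])
        assert total_pfas(cohort).iloc[0] == pytest.approx(1.1)

    def test_all_censored_sums_half_loqs(self):
        cohort = _cohort_with_compounds(
            {"A": ([np.nan], ["below_lod"]), "B": ([np.nan], ["between_lod_loq"])},
            [[0.1, 0.2], [0.2, 0.4]])
        assert total_pfas(cohort).iloc[0] == pytest.approx(0.3)

    def test_fully_quantified_equals_plain_sum(self):
        vals = np.arange(1.0, 14.0)
        rows = {f"C{i}": ([v], ["quantified"]) for i, v in enumerate(vals)}
        cohort = _cohort_with_compounds(rows, [[0.1, 0.2]] * 13)
        assert total_pfas(cohort).iloc[0] == pytest.approx(vals.sum())

    def test_monotone_in_quantified_values(self):
        base = _cohort_with_compounds(
            {"A": ([2.0], ["quantified"]), "B": ([np.nan], ["below_lod"])},
            [[0.1, 0.2], [0.1, 0.2]])
        bumped = base.copy()
        bumped.subjects["A_value"] = 3.0
        assert total_pfas(bumped).iloc[0] > total_pfas(base).iloc[0]


class TestGroupAssignment:
    def test_rank_tails(self):
        totals = pd.Series(np.arange(1.0, 101.0),
                           index=[f"S{i:03d}" for i in range(100)])
        labels = assign_extreme_groups(totals, 10)
        assert (labels.iloc[:10] == "low").all()
        assert (labels.iloc[90:] == "high").all()
        assert (labels.iloc[10:90] == "unassigned").all()

    def test_cohort_sized_split_counts(self):
        rng = np.random.default_rng(0)
        totals = pd.Series(rng.lognormal(2, 1, 517),
                           index=[f"S{i:04d}" for i in range(517)])
        labels = assign_extreme_groups(totals, 41)
        counts = labels.value_counts()
        assert counts["low"] == 41 and counts["high"] == 41
        assert counts["unassigned"] == 435

    def test_invariant_to_input_permutation(self):
        rng = np.random.default_rng(3)
        totals = pd.Series(rng.integers(0, 20, 30).astype(float),
                           index=[f"S{i:02d}" for i in range(30)])
        with pytest.warns(UserWarning):
            a = assign_extreme_groups(totals, 5)
        perm = totals.sample(frac=1, random_state=1)
        with pytest.warns(UserWarning):
            b = assign_extreme_groups(perm, 5)
        assert (a.sort_index() == b.sort_index()).all()

    def test_all_ties_resolved_by_id_and_flagged(self):
        totals = pd.Series(1.0, index=[f"S{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="tied"):
            labels = assign_extreme_groups(totals, 2)
        assert list(labels[labels == "low"].index) == ["S0", "S1"]
        assert list(labels[labels == "high"].index) == ["S4", "S5"]

    def test_duplicate_ids_rejected(self):
        totals = pd.Series([1.0, 2.0, 3.0, 4.0], index=["a", "a", "b", "c"])
        with pytest.raises(ValueError, match="duplicate"):
            assign_extreme_groups(totals, 1)


class TestEffectSizes:
    def test_cliffs_delta_forced_cases(self):
        d, _ = cliffs_delta([1, 2], [3, 4])
        assert d == -1.0
        d, _ = cliffs_delta([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_cliffs_delta_matches_pair_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x = rng.integers(0, 8, rng.integers(2, 7)).astype(float)
            y = rng.integers(0, 8, rng.integers(2, 7)).astype(float)
            d, (lo, hi) = cliffs_delta(x, y)
            assert d == pytest.approx(cliffs_delta_enumeration(x, y), abs=1e-12)
            assert -1 <= lo <= hi <= 1

    def test_phi_matches_indicator_correlation(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            table = [[int(((x == 1) & (y == 1)).sum()), int(((x == 1) & (y == 0)).sum())],
                     [int(((x == 0) & (y == 1)).sum()), int(((x == 0) & (y == 0)).sum())]]
            phi = phi_coefficient(table)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                assert np.isnan(phi)
            else:
                assert phi == pytest.approx(phi_from_indicators(x, y), abs=1e-12)


class TestCompareGroups:
    def test_balanced_synthetic_groups_show_no_covariate_imbalance(self, grouped_cohort):
        _, cohort = grouped_cohort
        comp = compare_groups(cohort)
        assert abs(comp.phi) <= 1
        assert comp.mwu_p["total_pfas"] < 1e-6     # groups defined by totals
        # covariates are generated independently of exposure
        assert comp.mwu_p["age"] > 0.001 and comp.mwu_p["bmi"] > 0.001
        d, lo, hi = comp.cliffs_delta["age"]
        assert lo <= d <= hi

    def test_rejects_tiny_groups(self):
        cohort = make_cohort(["male", "female", "male"], ["low", "high", "high"])
        with pytest.raises(ValueError):
            compare_groups(cohort)
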