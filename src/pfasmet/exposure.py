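"""Censored PFAS imputation, subject totals, extreme-group assignment,
and between-group cohort comparison.

Serum PFAS concentrations are left-censored at a per-compound limit of
detection (LOD) and limit of quantification (LOQ).  When enough of a
compound's measurements are observed (>= 30% by default), a censored
lognormal distribution is fitted by maximum likelihood — observed values
contribute the lognormal density, censored values the CDF mass of their
interval — and single random draws from the fitted distribution, truncated
to the censoring interval, replace the censored entries.  Compounds mostly
below the limits are left unimputed and their censored entries treated as
missing.

For totals, censored values are replaced by LOQ/2 per compound before
summation; exposure groups are the lowest and highest `n_per_group`
subjects by total (rank-based tails, mirroring a <=10th / >=90th percentile
selection from a larger source population).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .containers import CohortTable
from .stats import cohens_d

ELIGIBILITY_THRESHOLD = 0.30


@dataclass
class CensoredFit:
    """Fitted censored-lognormal parameters for one compound."""

    compound: str
    mu: float
    sigma: float
    fraction_above: float
    imputed: bool
    bounds: tuple = (0.0, float("inf"))
    converged: bool = True


@dataclass
class CohortComparison:
    """Between-group comparison of cohort characteristics."""

    chi2: float
    chi2_p: float
    phi: float
    mwu_p: dict = field(default_factory=dict)            # variable -> p
    cliffs_delta: dict = field(default_factory=dict)     # variable -> (delta, lo, hi)
    welch_t_p_time: float = float("nan")
    cohens_d_time: float = float("nan")


# ---------------------------------------------------------------------------
# censored lognormal MLE and single random imputation
# ---------------------------------------------------------------------------

def _censored_loglik(params, log_obs, n_below, log_lod, n_between, log_loq):
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    ll = 0.0
    if log_obs.size:
        z = (log_obs - mu) / sigma
        ll += -log_obs.size * np.log(sigma) - 0.5 * np.sum(z ** 2)
    if n_below:
        ll += n_below * sps.norm.logcdf((log_lod - mu) / sigma)
    if n_between:
        mass = (sps.norm.cdf((log_loq - mu) / sigma)
                - sps.norm.cdf((log_lod - mu) / sigma))
        ll += n_between * np.log(max(mass, 1e-300))
    return -ll


def _truncated_lognormal_draw(rng, mu, sigma, lower, upper):
    """Inverse-CDF draw from lognormal(mu, sigma) truncated to (lower, upper)."""
    a = sps.norm.cdf((np.log(lower) - mu) / sigma) if lower > 0 else 0.0
    b = sps.norm.cdf((np.log(upper) - mu) / sigma) if np.isfinite(upper) else 1.0
    if b <= a:  # numerically empty interval: fall back to midpoint
        return float(np.sqrt(max(lower, 1e-12) * (upper if np.isfinite(upper) else lower)))
    u = rng.uniform(a, b)
    u = min(max(u, 1e-12), 1 - 1e-12)
    return float(np.exp(mu + sigma * sps.norm.ppf(u)))


def fit_and_impute_censored(values, flags, lod: float, loq: float, *,
                            compound: str = "", seed: int = 0,
                            rule: str = "lod",
                            threshold: float = ELIGIBILITY_THRESHOLD):
    """Fit a censored lognormal per compound and impute censored entries.

    Parameters
    ----------
    values, flags : array-likes of concentration (NaN where censored) and
        censor status in {quantified, between_lod_loq, below_lod}.
    rule : "lod" counts between-LOD-LOQ values toward the eligibility
        fraction (default); "loq" counts only fully quantified values.

    Returns
    -------
    (imputed values ndarray, CensoredFit).  When the eligibility fraction is
    below `threshold`, no imputation is performed and censored entries stay
    NaN with ``fit.imputed`` False.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=object)
    if lod <= 0:
        raise ValueError("LOD must be positive")
    if loq < lod:
        raise ValueError("LOQ must be >= LOD")
    if rule not in ("lod", "loq"):
        raise ValueError("rule must be 'lod' or 'loq'")
    n = values.size
    quantified = flags == "quantified"
    between = flags == "between_lod_loq"
    below = flags == "below_lod"
    obs = values[quantified]
    obs = obs[np.isfinite(obs)]
    frac_above = float((quantified.sum() + (between.sum() if rule == "lod" else 0)) / n)

    out = values.copy()
    out[~quantified] = np.nan
    if frac_above < threshold:
        fit = CensoredFit(compound=compound, mu=float("nan"), sigma=float("nan"),
                          fraction_above=frac_above, imputed=False)
        return out, fit
    if obs.size < 2:
        raise ValueError("at least 2 quantified values required for imputation")

    log_obs = np.log(obs)
    mu0, sig0 = float(log_obs.mean()), float(max(log_obs.std(ddof=0), 1e-3))
    upper_bound = 10.0 * float(obs.max())
    res = optimize.minimize(
        _censored_loglik, x0=[mu0, np.log(sig0)],
        args=(log_obs, int(below.sum()), np.log(lod), int(between.sum()), np.log(loq)),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    converged = bool(res.success) and np.all(np.isfinite(res.x))
    if converged:
        mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
        sigma = min(max(sigma, 1e-6), 10.0)
    else:
        warnings.warn(f"censored MLE did not converge for {compound or 'compound'}; "
                      "falling back to log-moment estimates")
        mu, sigma = mu0, sig0

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), hash(compound) % (2 ** 31)]))
    for i in range(n):
        if below[i]:
            out[i] = _truncated_lognormal_draw(rng, mu, sigma, 0.0, min(lod, upper_bound))
        elif between[i]:
            out[i] = _truncated_lognormal_draw(rng, mu, sigma, lod, min(loq, upper_bound))
    fit = CensoredFit(compound=compound, mu=mu, sigma=sigma,
                      fraction_above=frac_above, imputed=True,
                      bounds=(0.0, upper_bound), converged=converged)
    return out, fit


def impute_cohort(cohort: CohortTable, seed: int = 0,
                  rule: str = "lod") -> tuple[CohortTable, list]:
    """Run censored imputation for every compound of a cohort table."""
    out = cohort.copy()
    fits = []
    for name in cohort.compound_names:
        lod = float(cohort.compounds.loc[name, "lod"])
        loq = float(cohort.compounds.loc[name, "loq"])
        vals, flags = cohort.values_flags(name)
        imputed, fit = fit_and_impute_censored(
            vals.to_numpy(), flags.to_numpy(), lod, loq,
            compound=name, seed=seed, rule=rule)
        out.subjects[f"{name}_value"] = imputed
        fits.append(fit)
    return out, fits


# ---------------------------------------------------------------------------
# totals and extreme-group assignment
# ---------------------------------------------------------------------------

def total_pfas(cohort: CohortTable) -> pd.Series:
    """Per-subject total PFAS with LOQ/2 substitution.

    total = sum over compounds of (value if quantified and >= LOQ, else LOQ/2).
    """
    if not len(cohort.compounds):
        raise ValueError("cohort carries no compound LOQ information")
    if cohort.compounds["loq"].isna().any():
        raise ValueError("missing LOQ for at least one compound")
    total = pd.Series(0.0, index=cohort.subjects.index)
    for name in cohort.compound_names:
        loq = float(cohort.compounds.loc[name, "loq"])
        vals, flags = cohort.values_flags(name)
        v = vals.to_numpy(dtype=float)
        use = (flags.to_numpy() == "quantified") & np.isfinite(v) & (v >= loq)
        total += np.where(use, np.nan_to_num(v), loq / 2.0)
    return total


def assign_extreme_groups(totals: pd.Series, n_per_group: int) -> pd.Series:
    """Label the lowest/highest `n_per_group` subjects by total PFAS.

    Ties are broken by stable subject-id order, so a permuted input yields
    identical labels.  Emits a warning when ties straddle a cut (degenerate).
    """
    if totals.index.duplicated().any():
        raise ValueError("duplicate subject ids")
    if 2 * n_per_group > len(totals):
        raise ValueError("2 * n_per_group exceeds the number of subjects")
    s = totals.sort_index(kind="stable").sort_values(kind="stable")
    labels = pd.Series("unassigned", index=s.index)
    labels.iloc[:n_per_group] = "low"
    labels.iloc[-n_per_group:] = "high"
    vals = s.to_numpy()
    if (n_per_group < len(s) and vals[n_per_group - 1] == vals[n_per_group]) or \
       (vals[-n_per_group] == vals[-n_per_group - 1]):
        warnings.warn("tied totals straddle a group boundary; "
                      "assignment resolved by subject-id order")
    return labels.reindex(totals.index)


# ---------------------------------------------------------------------------
# group comparison statistics
# ---------------------------------------------------------------------------

def phi_coefficient(table) -> float:
    """Phi for a 2x2 table [[a, b], [c, d]]: (ad - bc)/sqrt(marginal product)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return float("nan")
    return float((a * d - b * c) / np.sqrt(denom))


def cliffs_delta(x, y, alpha: float = 0.05):
    """Cliff's delta of x versus y with an asymmetric normal-theory CI.

    delta = (#(x > y) - #(x < y)) / (n1 n2).  The variance is Cliff's
    consistent (unbiased) estimator from the row/column dominance means; the
    confidence interval uses Cliff's asymmetric transformation, which keeps
    the bounds inside [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    dij = np.sign(x[:, None] - y[None, :])
    d = float(dij.mean())
    if n1 < 2 or n2 < 2:
        return d, (float("nan"), float("nan"))
    di = dij.mean(axis=1)
    dj = dij.mean(axis=0)
    s2 = (n2 ** 2 * np.sum((di - d) ** 2) + n1 ** 2 * np.sum((dj - d) ** 2)
          - np.sum((dij - d) ** 2)) / (n1 * n2 * (n1 - 1) * (n2 - 1))
    s2 = max(s2, (1 - d ** 2) / (n1 * n2 - 1))
    z = sps.norm.ppf(1 - alpha / 2)
    if abs(d) >= 1.0:
        return d, (d, d)
    num_term = z * np.sqrt(s2) * np.sqrt((1 - d ** 2) ** 2 + z ** 2 * s2)
    denom = 1 - d ** 2 + z ** 2 * s2
    lo = (d - d ** 3 - num_term) / denom
    hi = (d - d ** 3 + num_term) / denom
    return d, (float(max(lo, -1.0)), float(min(hi, 1.0)))


def compare_groups(cohort: CohortTable) -> CohortComparison:
    """Compare low vs high exposure groups on cohort characteristics.

    Sex: Yates-corrected chi-square on the 2x2 table plus the phi effect
    size.  Age, BMI, total PFAS: two-sided Mann-Whitney U; age and BMI also
    get Cliff's delta with 95% CI (low minus high orientation).  Blood
    collection time: Welch t-test and Cohen's d.
    """
    subj = cohort.subjects
    low = subj[subj["group"] == "low"]
    high = subj[subj["group"] == "high"]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("each group needs at least 2 subjects")

    table = [[int((low["sex"] == "male").sum()), int((high["sex"] == "male").sum())],
             [int((low["sex"] == "female").sum()), int((high["sex"] == "female").sum())]]
    chi2_res = sps.chi2_contingency(table, correction=True)
    phi = phi_coefficient(table)

    mwu_p, cliffs = {}, {}
    for var in ("age", "bmi", "total_pfas"):
        lo_v = low[var].to_numpy(dtype=float)
        hi_v = high[var].to_numpy(dtype=float)
        mwu_p[var] = float(sps.mannwhitneyu(lo_v, hi_v, alternative="two-sided").pvalue)
        if var != "total_pfas":
            delta, (ci_lo, ci_hi) = cliffs_delta(lo_v, hi_v)
            cliffs[var] = (delta, ci_lo, ci_hi)

    t_lo = low["collection_time"].to_numpy(dtype=float)
    t_hi = high["collection_time"].to_numpy(dtype=float)
    welch = sps.ttest_ind(t_hi, t_lo, equal_var=False)

    return CohortComparison(
        chi2=float(chi2_res.statistic), chi2_p=float(chi2_res.pvalue), phi=phi,
        mwu_p=mwu_p, cliffs_delta=cliffs,
        welch_t_p_time=float(welch.pvalue),
        cohens_d_time=cohens_d(t_hi, t_lo),
    )
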