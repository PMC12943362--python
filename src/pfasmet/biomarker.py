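"""Exposure-metabolite association and discriminatory panel construction.

Covers Spearman association of altered metabolites with total PFAS (with
the conventional |r| strength categories), covariate sensitivity
regressions with variance inflation factors, univariate ROC with bootstrap
confidence intervals, panel construction (hierarchical clustering of
candidates -> PLS-DA VIP ranking over Monte-Carlo subsamples -> highest-AUC
champion per cluster), linear-SVM Monte-Carlo cross-validation of the panel
with class-label permutation significance, and Cohen's d / noncentral-t
power analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC

from .differential import _encode_y
from .stats import auc_mann_whitney, cohens_d, power_t  # noqa: F401  (re-export)

CATEGORY_BINS = (
    ("very weak", 0.0, 0.2),
    ("weak", 0.2, 0.4),
    ("moderate", 0.4, 0.6),
    ("strong", 0.6, np.inf),
)


def correlation_category(r: float) -> str:
    """Strength label from |r|: <0.2 very weak, 0.2-0.39 weak, 0.40-0.59
    moderate, >=0.60 strong."""
    if not np.isfinite(r):
        return "undefined"
    a = abs(r)
    for name, lo, hi in CATEGORY_BINS:
        if lo <= a < hi:
            return name
    return "strong"


@dataclass
class AssociationResult:
    metabolite: str
    r: float
    p: float
    category: str
    beta_unadjusted: float = float("nan")
    beta_adjusted: float = float("nan")
    vif: dict = field(default_factory=dict)


def spearman_assoc(values, totals, metabolite: str = "") -> AssociationResult:
    """Spearman rank correlation (mid-ranks, tie-corrected) with category."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(totals, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(v) == 0 or np.ptp(t) == 0:
        return AssociationResult(metabolite, float("nan"), float("nan"), "undefined")
    res = sps.spearmanr(v, t)
    r = float(res.statistic)
    return AssociationResult(metabolite, r, float(res.pvalue), correlation_category(r))


def sensitivity_regression(values, totals, covariates: pd.DataFrame,
                           metabolite: str = "") -> AssociationResult:
    """OLS of log intensity on total PFAS, unadjusted and covariate-adjusted.

    `covariates` holds numeric columns (sex already encoded).  VIF_j =
    1/(1 - R2_j) from regressing covariate j on the other regressors (with
    intercept).  A rank-deficient design is rejected with the offending
    column named.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(totals, dtype=float)
    X_unadj = sm.add_constant(pd.DataFrame({"total_pfas": t}))
    beta_unadj = float(sm.OLS(y, X_unadj).fit().params["total_pfas"])

    design = pd.DataFrame({"total_pfas": t}).join(covariates.reset_index(drop=True))
    X = sm.add_constant(design)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        for col in design.columns:
            reduced = X.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy(dtype=float)) == rank:
                raise ValueError(f"design matrix is rank deficient; column '{col}' "
                                 "is collinear with the others")
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    vif = {}
    cols = list(design.columns)
    for col in cols:
        others = sm.add_constant(design.drop(columns=[col]))
        r2 = sm.OLS(design[col].to_numpy(dtype=float), others).fit().rsquared
        vif[col] = float(1.0 / (1.0 - r2)) if r2 < 1 else float("inf")
    res = spearman_assoc(y, t, metabolite)
    return AssociationResult(metabolite, res.r, res.p, res.category,
                             beta_unadjusted=beta_unadj,
                             beta_adjusted=float(fit.params["total_pfas"]),
                             vif=vif)


# ---------------------------------------------------------------------------
# univariate ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    metabolite: str
    auc: float
    ci: tuple
    p: float


def univariate_roc(values, labels, n_boot: int = 500, seed: int = 0,
                   metabolite: str = "") -> RocResult:
    """Empirical AUC with stratified percentile-bootstrap 95% CI.

    The AUC equals U/(n1*n2) with ties counted one half; the p-value tests
    AUC != 0.5 through the tie-corrected normal approximation of U.  The
    positive class is 'high' exposure; the AUC is reported as computed, not
    folded to >= 0.5.
    """
    v = np.asarray(values, dtype=float)
    yv = _encode_y(labels)
    pos, neg = v[yv == 1], v[yv == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    auc = auc_mann_whitney(pos, neg)
    p = float(sps.mannwhitneyu(pos, neg, alternative="two-sided",
                               method="asymptotic").pvalue)
    rng = np.random.default_rng(int(seed))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        boots[b] = auc_mann_whitney(bp, bn)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, auc), max(hi, auc)
    return RocResult(metabolite, float(auc), (float(lo), float(hi)), p)


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def cluster_features(X: pd.DataFrame, k: int = 5) -> pd.Series:
    """Agglomerative clustering of candidate features into k clusters.

    Distance 1 - |Spearman correlation across samples| with average linkage:
    strongly co-regulated features cluster together regardless of the sign
    of their correlation.  `X` is samples x features.
    """
    p = X.shape[1]
    if k > p:
        raise ValueError("k must not exceed the number of candidate features")
    if k == p:
        return pd.Series(np.arange(1, p + 1), index=X.columns, name="cluster")
    rho = sps.spearmanr(X.to_numpy(dtype=float)).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=X.columns, name="cluster")


def rank_features_mccv(X: pd.DataFrame, y, n_iter: int = 100, *, top_n: int = 12,
                       n_components: int = 2, seed: int = 0) -> pd.Series:
    """PLS-DA VIP ranking over balanced Monte-Carlo subsamples.

    Per iteration a balanced two-thirds subsample trains a PLS-DA; a feature
    counts as selected when its VIP ranks in the top `top_n`.  Returns the
    selection frequency per feature.
    """
    from .differential import _vip_scores
    if n_iter < 10:
        warnings.warn("fewer than 10 ranking iterations gives noisy frequencies")
    Xa = X.to_numpy(dtype=float)
    yv = _encode_y(y)
    rng = np.random.default_rng(int(seed))
    a = int(min(n_components, Xa.shape[1]))
    counts = pd.Series(0.0, index=X.columns)
    for _ in range(n_iter):
        train = _balanced_split(yv, rng)[0]
        pls = PLSRegression(n_components=a, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(Xa[train], yv[train])
        vip = _vip_scores(pls)
        top = np.argsort(-vip, kind="stable")[:top_n]
        counts.iloc[top] += 1
    return counts / n_iter


def build_panel(clusters: pd.Series, frequencies: pd.Series, aucs: pd.Series,
                *, top_n: int = 12, panel_size: int = 5) -> list:
    """One champion metabolite per cluster from the top-ranked candidates.

    Take the `top_n` candidates by selection frequency; within each cluster
    pick the member of that top set with the highest univariate AUC (ties:
    higher frequency, then lexical id).  A cluster with no member in the top
    set falls back to its overall highest-AUC member, with a warning.
    """
    n_clusters = clusters.nunique()
    if panel_size != n_clusters:
        raise ValueError(f"panel_size ({panel_size}) must equal the number of "
                         f"clusters ({n_clusters})")
    ordered = sorted(frequencies.index, key=lambda f: (-frequencies[f], str(f)))
    top_set = set(ordered[:top_n])
    panel = []
    for c in sorted(clusters.unique()):
        members = list(clusters.index[clusters == c])
        in_top = [m for m in members if m in top_set]
        pool = in_top
        if not pool:
            warnings.warn(f"cluster {c} has no member among the top {top_n} "
                          "ranked candidates; falling back to its best AUC")
            pool = members
        best = sorted(pool, key=lambda m: (-aucs[m], -frequencies[m], str(m)))[0]
        panel.append(best)
    return panel


# ---------------------------------------------------------------------------
# panel evaluation: linear SVM with Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PanelEvaluation:
    members: list
    auc: float
    ci: tuple
    accuracy: float
    perm_p: float
    iteration_aucs: np.ndarray = field(default_factory=lambda: np.array([]))
    n_iter: int = 0
    n_perm: int = 0


def _balanced_split(yv: np.ndarray, rng: np.random.Generator,
                    train_frac: float = 2.0 / 3.0):
    """Class-balanced train indices (same count per class); rest is test."""
    idx0 = np.flatnonzero(yv == 0)
    idx1 = np.flatnonzero(yv == 1)
    n_train = int(np.floor(train_frac * min(idx0.size, idx1.size)))
    if n_train < 2:
        raise ValueError("classes too small for a balanced train/test split")
    tr0 = rng.choice(idx0, size=n_train, replace=False)
    tr1 = rng.choice(idx1, size=n_train, replace=False)
    train = np.concatenate([tr0, tr1])
    test = np.setdiff1d(np.arange(yv.size), train)
    return train, test


def _mccv_mean_auc(Xa: np.ndarray, yv: np.ndarray, n_iter: int,
                   rng: np.random.Generator, C: float = 1.0):
    aucs = np.empty(n_iter)
    accs = np.empty(n_iter)
    for i in range(n_iter):
        train, test = _balanced_split(yv, rng)
        svm = SVC(kernel="linear", C=C)
        svm.fit(Xa[train], yv[train])
        dec = svm.decision_function(Xa[test])
        y_test = yv[test]
        if np.unique(y_test).size < 2:
            aucs[i] = np.nan
        else:
            aucs[i] = auc_mann_whitney(dec[y_test == 1], dec[y_test == 0])
        accs[i] = float(np.mean(svm.predict(Xa[test]) == y_test))
    return aucs, accs


def evaluate_panel_svm(X_panel: pd.DataFrame, y, n_iter: int = 100,
                       n_perm: int = 1000, seed: int = 0, *,
                       null_n_iter: int = 20, C: float = 1.0) -> PanelEvaluation:
    """Monte-Carlo cross-validated linear-SVM evaluation of a panel.

    Per iteration a balanced 2/3-train / 1/3-test split is drawn, a linear
    SVM (C = 1) fitted, and the test decision values scored as an ROC AUC.
    The panel AUC is the mean over iterations with a percentile 95% CI of
    the iteration AUC distribution; accuracy is the mean test accuracy.
    Significance comes from class-label permutation: each of `n_perm`
    permutations reruns the MCCV (at `null_n_iter` iterations for
    tractability) and p = (#{null mean AUC >= observed} + 1)/(n_perm + 1).
    """
    Xa = X_panel.to_numpy(dtype=float)
    yv = _encode_y(y)
    rng = np.random.default_rng(int(seed))
    aucs, accs = _mccv_mean_auc(Xa, yv, n_iter, rng, C=C)
    valid = aucs[np.isfinite(aucs)]
    observed = float(valid.mean())
    lo, hi = np.percentile(valid, [2.5, 97.5])
    if n_perm > 0:
        perm_exceed = 0
        for _ in range(n_perm):
            y_perm = rng.permutation(yv)
            null_aucs, _ = _mccv_mean_auc(Xa, y_perm, null_n_iter, rng, C=C)
            if np.nanmean(null_aucs) >= observed:
                perm_exceed += 1
        perm_p = (perm_exceed + 1) / (n_perm + 1)
    else:
        perm_p = float("nan")
    return PanelEvaluation(members=list(X_panel.columns), auc=observed,
                           ci=(float(lo), float(hi)), accuracy=float(accs.mean()),
                           perm_p=perm_p, iteration_aucs=aucs,
                           n_iter=n_iter, n_perm=n_perm)
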