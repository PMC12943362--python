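"""Differential analysis between exposure groups.

Univariate screen: per-feature Shapiro-Wilk normality routing into either a
two-sample t-test (both groups normal) or a Mann-Whitney U (exact for small
groups, tie-corrected normal approximation otherwise), Benjamini-Hochberg
correction across features, and a fold-change rule — run on raw (post-QC,
pre-treatment) intensities.

Multivariate: PLS-DA on the pretreated matrix fitted by NIPALS (via
scikit-learn's PLSRegression) with the component count chosen by stratified
10-fold cross-validated Q2, per-feature VIP scores, a response-permutation
test on training accuracy, and a bagged decision-tree (random forest)
classifier scored by out-of-bag AUC with out-of-bag permutation importance
(mean decrease in accuracy).

Feature selection is the union of the univariate rule and the multivariate
rule (VIP > 1 from models whose permutation test is significant, combined
with the RF top importances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .stats import auc_mann_whitney, benjamini_hochberg

# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------


def _mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p: exact for n <= 8 per group without ties,
    tie-corrected normal approximation otherwise."""
    use_exact = (x.size <= 8 and y.size <= 8
                 and np.unique(np.concatenate([x, y])).size == x.size + y.size)
    method = "exact" if use_exact else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def univariate_screen(intensities: pd.DataFrame, groups: pd.Series, *,
                      alpha_normality: float = 0.05, fdr: float = 0.05,
                      fc_limits: tuple = (0.8, 1.2)) -> pd.DataFrame:
    """Normality-routed univariate tests with BH correction and FC rule.

    Parameters
    ----------
    intensities : raw intensity matrix, features x samples (NaN = missing).
    groups : Series mapping sample id -> 'low'/'high'.

    Returns a DataFrame indexed by feature with columns shapiro_p_low,
    shapiro_p_high, test, p, q, fc (mean(high)/mean(low)), log2fc, selected.
    A feature is selected iff q < `fdr` and fc > 1.2 or fc < 0.8.
    """
    low_ids = list(groups.index[groups == "low"])
    high_ids = list(groups.index[groups == "high"])
    if len(low_ids) < 3 or len(high_ids) < 3:
        raise ValueError("both groups need at least 3 samples")
    lowX = intensities[low_ids].to_numpy(dtype=float)
    highX = intensities[high_ids].to_numpy(dtype=float)

    rows = []
    for r in range(intensities.shape[0]):
        x = highX[r][np.isfinite(highX[r])]
        y = lowX[r][np.isfinite(lowX[r])]
        fc = float(x.mean() / y.mean()) if x.size and y.size and y.mean() > 0 else np.nan
        if x.size < 3 or y.size < 3:
            rows.append((np.nan, np.nan, "none", 1.0, fc))
            continue
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # degenerate: constant in both groups
            rows.append((np.nan, np.nan, "none", 1.0, 1.0))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_hi = float(sps.shapiro(x).pvalue) if np.ptp(x) > 0 else 0.0
            sw_lo = float(sps.shapiro(y).pvalue) if np.ptp(y) > 0 else 0.0
            if sw_hi >= alpha_normality and sw_lo >= alpha_normality:
                p = float(sps.ttest_ind(x, y, equal_var=True).pvalue)
                test = "t"
            else:
                p = _mann_whitney_p(x, y)
                test = "mann_whitney"
        rows.append((sw_lo, sw_hi, test, p, fc))

    out = pd.DataFrame(rows, index=intensities.index,
                       columns=["shapiro_p_low", "shapiro_p_high", "test", "p", "fc"])
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["log2fc"] = np.log2(out["fc"])
    lo_lim, hi_lim = fc_limits
    out["selected"] = (out["q"] < fdr) & ((out["fc"] > hi_lim) | (out["fc"] < lo_lim))
    return out


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    """Fitted PLS-DA state with VIP scores and cross-validated metrics."""

    n_components: int
    vip: pd.Series
    r2: float
    q2: float
    auc: float
    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    perm_p: float = float("nan")
    platform: str = ""


def _vip_scores(pls: PLSRegression) -> np.ndarray:
    """Variable importance in projection from a fitted PLS model.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), where
    SSY_a is the response variance explained by component a; the mean of
    VIP^2 across features is exactly 1.
    """
    W = pls.x_weights_                       # (p, A), columns unit norm
    T = pls.x_scores_                        # (n, A)
    Q = pls.y_loadings_                      # (1, A)
    p, A = W.shape
    ssy = (Q[0] ** 2) * np.sum(T ** 2, axis=0)
    wnorm2 = np.sum(W ** 2, axis=0)
    contrib = (W ** 2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


def _encode_y(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("y must be binary")
        # 'high' (or the lexically later class) is coded 1
        y = (y == classes[-1]).astype(float)
    y = y.astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary")
    return y


def fit_plsda(X, y, max_components: int = 5, seed: int = 0, *,
              n_folds: int = 10) -> PLSDAModel:
    """PLS-DA with component count chosen by stratified CV Q2.

    X is the pretreated matrix (samples x features, DataFrame or ndarray);
    y binary labels.  Q2 = 1 - PRESS/TSS over stratified `n_folds` folds;
    the cross-validated predicted scores also give the reported AUC.
    """
    feature_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    yv = _encode_y(y)
    n, p = Xa.shape
    max_a = int(min(max_components, p, n - 2))
    counts = np.bincount(yv.astype(int))
    folds = int(min(n_folds, counts.min()))
    if folds < n_folds:
        warnings.warn(f"reduced CV folds to {folds} (small class)")
    if folds < 2:
        raise ValueError("need at least 2 samples per class for CV")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    splits = list(skf.split(Xa, yv))
    press = np.zeros(max_a)
    tss = 0.0
    cv_pred = np.zeros((max_a, n))
    for train, test in splits:
        ybar = yv[train].mean()
        tss += float(np.sum((yv[test] - ybar) ** 2))
        for a in range(1, max_a + 1):
            pls = PLSRegression(n_components=a, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls.fit(Xa[train], yv[train])
            pred = pls.predict(Xa[test]).ravel()
            press[a - 1] += float(np.sum((yv[test] - pred) ** 2))
            cv_pred[a - 1, test] = pred
    q2_by_a = 1.0 - press / tss
    best_a = int(np.argmax(q2_by_a)) + 1
    q2 = float(q2_by_a[best_a - 1])

    pls = PLSRegression(n_components=best_a, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xa, yv)
    fitted = pls.predict(Xa).ravel()
    r2 = float(1.0 - np.sum((yv - fitted) ** 2) / np.sum((yv - yv.mean()) ** 2))
    scores_cv = cv_pred[best_a - 1]
    auc = auc_mann_whitney(scores_cv[yv == 1], scores_cv[yv == 0])
    vip = _vip_scores(pls)
    index = feature_ids if feature_ids is not None else pd.RangeIndex(p)
    return PLSDAModel(n_components=best_a, vip=pd.Series(vip, index=index, name="vip"),
                      r2=r2, q2=q2, auc=auc, weights=pls.x_weights_,
                      scores=pls.x_scores_, loadings=pls.x_loadings_)


def permutation_test(X, y, n_components: int, n_perm: int = 1000,
                     seed: int = 0, *, n_folds: int = 10) -> float:
    """Response-permutation test of a PLS-DA model.

    The statistic is the prediction accuracy observed during training —
    i.e. the stratified cross-validated class accuracy of the model refitted
    (same component count) on each label permutation.  The resubstitution
    accuracy cannot serve here: with far more features than samples every
    refit classifies its own training set perfectly, observed and permuted
    alike, so only the accuracy measured through the training CV loop
    discriminates signal from chance.
    p = (#{perm >= observed} + 1)/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    Xa = np.asarray(X, dtype=float)
    yv = _encode_y(y)
    if np.unique(yv).size < 2:
        raise ValueError("y must contain both classes")
    rng = np.random.default_rng(int(seed))
    folds = int(min(n_folds, np.bincount(yv.astype(int)).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))

    def cv_acc(labels: np.ndarray) -> float:
        correct = 0
        for train, test in skf.split(Xa, labels):
            pls = PLSRegression(n_components=n_components, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls.fit(Xa[train], labels[train])
            pred = (pls.predict(Xa[test]).ravel() > 0.5).astype(float)
            correct += int(np.sum(pred == labels[test]))
        return correct / labels.size

    observed = cv_acc(yv)
    exceed = 0
    for _ in range(n_perm):
        if cv_acc(rng.permutation(yv)) >= observed:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# bagged decision-tree classifier with OOB importance
# ---------------------------------------------------------------------------

@dataclass
class RFResult:
    """Out-of-bag evaluation of the bagged-tree classifier."""

    auc_oob: float
    importance: pd.Series      # mean decrease in OOB accuracy per feature
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


def rf_classify(X, y, n_trees: int = 500, seed: int = 0) -> RFResult:
    """Bootstrap-aggregated decision trees with OOB AUC and OOB permutation
    importance (mean decrease in accuracy).

    Importance of feature j averages, over all trees, the drop in that
    tree's out-of-bag accuracy when feature j is permuted among the OOB
    samples; trees that never split on j contribute zero.
    """
    if n_trees < 50:
        warnings.warn("fewer than 50 trees gives unstable importances")
    feature_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    yv = _encode_y(y).astype(int)
    n, p = Xa.shape
    rng = np.random.default_rng(int(seed))

    vote_sum = np.zeros(n)
    vote_cnt = np.zeros(n)
    mda_sum = np.zeros(p)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        tree = DecisionTreeClassifier(max_features="sqrt",
                                      random_state=int(rng.integers(2 ** 31)))
        tree.fit(Xa[idx], yv[idx])
        if oob.size == 0:
            continue
        X_oob = Xa[oob]
        pred = tree.predict(X_oob)
        vote_sum[oob] += pred
        vote_cnt[oob] += 1
        acc = float(np.mean(pred == yv[oob]))
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        for j in used:
            Xp = X_oob.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            acc_perm = float(np.mean(tree.predict(Xp) == yv[oob]))
            mda_sum[j] += acc - acc_perm
    covered = vote_cnt > 0
    oob_score = np.divide(vote_sum, vote_cnt, out=np.full(n, 0.5), where=covered)
    auc = auc_mann_whitney(oob_score[covered & (yv == 1)],
                           oob_score[covered & (yv == 0)])
    mda = mda_sum / n_trees
    index = feature_ids if feature_ids is not None else pd.RangeIndex(p)
    return RFResult(auc_oob=auc, importance=pd.Series(mda, index=index, name="mda"),
                    hyperparameters={"n_trees": n_trees, "max_features": "sqrt"},
                    seed=int(seed))


def rf_importance_cutoff(X, y, n_trees: int = 500, seed: int = 0,
                         n_label_perm: int = 1, quantile: float = 0.95) -> float:
    """Importance threshold: the 95th percentile of MDA under permuted labels."""
    rng = np.random.default_rng(int(seed))
    yv = _encode_y(y)
    null_imp = []
    for _ in range(n_label_perm):
        y_perm = rng.permutation(yv)
        res = rf_classify(X, y_perm, n_trees=n_trees, seed=int(rng.integers(2 ** 31)))
        null_imp.append(res.importance.to_numpy())
    return float(np.quantile(np.concatenate(null_imp), quantile))


# ---------------------------------------------------------------------------
# union selection
# ---------------------------------------------------------------------------

def select_features(uni: pd.DataFrame, plsda_models: list, rf: RFResult | None,
                    rf_cutoff: float | None = None, *,
                    vip_threshold: float = 1.0, perm_alpha: float = 0.05,
                    rule: str = "vip_and_rf") -> pd.DataFrame:
    """Union of the univariate and multivariate feature selections.

    Multivariate candidates are features with VIP > `vip_threshold` in any
    PLS-DA model whose permutation p < `perm_alpha` (non-significant models
    contribute nothing), combined with the RF top importances by
    intersection (``vip_and_rf``, default) or union (``vip_or_rf``).
    Returns a DataFrame with per-feature route provenance.
    """
    if rule not in ("vip_and_rf", "vip_or_rf"):
        raise ValueError("rule must be 'vip_and_rf' or 'vip_or_rf'")
    features = uni.index
    uni_set = set(features[uni["selected"].astype(bool)])

    vip_set: set = set()
    for model in plsda_models:
        if np.isfinite(model.perm_p) and model.perm_p < perm_alpha:
            vip_set |= set(model.vip.index[model.vip > vip_threshold])
    if rf is not None and rf_cutoff is not None:
        rf_set = set(rf.importance.index[rf.importance > rf_cutoff])
        multi = (vip_set & rf_set) if rule == "vip_and_rf" else (vip_set | rf_set)
    else:
        multi = vip_set

    selected = uni_set | multi
    if not selected:
        warnings.warn("no feature selected by either route")
    route = []
    for f in features:
        in_u, in_m = f in uni_set, f in multi
        route.append("both" if in_u and in_m else
                     "univariate" if in_u else
                     "multivariate" if in_m else "")
    return pd.DataFrame({"selected": [f in selected for f in features],
                         "route": route}, index=features)
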