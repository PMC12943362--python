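"""Pretreatment: imputation, log transform, PQN normalization, Pareto scaling.

Biological samples are imputed with an iterative nonparametric
(random-forest) scheme in the style of missForest: every incomplete feature
is regressed on the others with an ensemble of regression trees and the
cycle repeats until the total change in the imputed values rises or an
iteration cap is reached.  Pooled-QC injections are imputed separately with
the per-feature median of the observed QC values, so technical replicates
never leak into the biological imputation model.

Normalization follows log transform -> probabilistic quotient normalization
(PQN) against the pooled-QC median spectrum -> Pareto scaling.  PQN is
applied on the log scale by subtracting the per-sample median log-quotient,
which is exactly equivalent to dividing natural intensities by the median
natural-scale quotient (the median commutes with the monotone exp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .containers import FeatureStudy


@dataclass
class PretreatedMatrix:
    """Transformed intensities (feature x biological sample) with provenance."""

    data: pd.DataFrame
    pqn_factors: pd.Series          # natural-scale per-sample dilution factor
    provenance: dict = field(default_factory=dict)
    zero_variance_features: list = field(default_factory=list)
    imputed_mask: pd.DataFrame | None = None


def impute_missing(study: FeatureStudy, seed: int = 0, *, n_trees: int = 100,
                   max_iter: int = 10) -> tuple[FeatureStudy, pd.DataFrame]:
    """missForest-style imputation of biological samples; QC by median.

    Features must not be entirely missing across samples (such features are
    expected to have been removed by the QC filters).  Imputed biological
    values are bounded below by half the feature's observed minimum, so a
    feature censored near its detection limit cannot be imputed above it
    from correlated features alone.

    Returns the imputed study and a boolean mask of imputed entries.
    """
    out = study.copy()
    X = out.intensities
    sample_ids = study.sample_ids
    qc_ids = study.qc_ids

    S = X[sample_ids].to_numpy(dtype=float).T      # samples x features
    miss = ~np.isfinite(S)
    if miss.all(axis=0).any():
        raise ValueError("a feature is entirely missing across samples; "
                         "filter such features before imputation")
    overall = miss.mean()
    if overall > 0.5:
        warnings.warn(f"{overall:.0%} of sample entries are missing; "
                      "imputation quality will be poor")

    if miss.any():
        S_imp = _miss_forest(S, miss, seed=seed, n_trees=n_trees, max_iter=max_iter)
    else:
        S_imp = S
    X.loc[:, sample_ids] = S_imp.T

    if qc_ids:
        qc = X[qc_ids].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(qc, axis=1)
        fill = np.where(np.isfinite(qc), qc, med[:, None])
        X.loc[:, qc_ids] = fill

    mask = pd.DataFrame(False, index=X.index, columns=X.columns)
    mask.loc[:, sample_ids] = miss.T
    if qc_ids:
        mask.loc[:, qc_ids] = ~np.isfinite(study.intensities[qc_ids].to_numpy(dtype=float))
    return out, mask


def _miss_forest(S: np.ndarray, miss: np.ndarray, *, seed: int,
                 n_trees: int, max_iter: int) -> np.ndarray:
    """Iterative per-feature random-forest regression imputation."""
    n, p = S.shape
    filled = S.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_med = np.nanmedian(S, axis=0)
        col_min = np.nanmin(np.where(miss, np.nan, S), axis=0)
    for j in range(p):
        filled[miss[:, j], j] = col_med[j]

    # visit features with the fewest missing entries first
    order = [j for j in np.argsort(miss.sum(axis=0), kind="stable") if miss[:, j].any()]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    prev_change = np.inf
    for _ in range(max_iter):
        previous = filled.copy()
        for j in order:
            obs = ~miss[:, j]
            predictors = np.delete(filled, j, axis=1)
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_features="sqrt", bootstrap=True,
                random_state=int(rng.integers(2 ** 31)), n_jobs=1)
            rf.fit(predictors[obs], filled[obs, j])
            pred = rf.predict(predictors[~obs])
            filled[~obs, j] = np.maximum(pred, col_min[j] / 2.0)
        num = float(np.sum((filled[miss] - previous[miss]) ** 2))
        den = float(np.sum(filled[miss] ** 2))
        change = num / den if den > 0 else 0.0
        if change >= prev_change:    # stopping rule: change starts rising
            filled = previous
            break
        prev_change = change
    return filled


def pqn_normalize(matrix: pd.DataFrame, reference: pd.Series, *,
                  log_scale: bool = False) -> tuple[pd.DataFrame, pd.Series]:
    """Probabilistic quotient normalization against a reference spectrum.

    On the natural scale the per-sample dilution factor is the median of the
    feature-wise quotients sample/reference, and each sample is divided by
    its factor.  With ``log_scale=True`` the matrix and reference are log
    intensities and the equivalent subtraction is used.  Returns the
    normalized matrix and the natural-scale factors.

    The reference must be strictly positive (finite on the log scale) for
    every feature used.
    """
    ref = reference.reindex(matrix.index)
    if log_scale:
        if not np.all(np.isfinite(ref.to_numpy(dtype=float))):
            raise ValueError("reference spectrum must be finite for all features")
        log_q = matrix.sub(ref, axis=0)
        log_f = log_q.median(axis=0)
        out = matrix.sub(log_f, axis=1)
        factors = np.exp(log_f)
    else:
        if np.any(ref.to_numpy(dtype=float) <= 0) or ref.isna().any():
            raise ValueError("reference spectrum must be strictly positive")
        q = matrix.div(ref, axis=0)
        factors = q.median(axis=0)
        bad = factors[~(factors > 0)]
        if len(bad):
            raise ValueError(f"non-positive PQN factor for sample(s) {list(bad.index)}")
        out = matrix.div(factors, axis=1)
    factors.name = "pqn_factor"
    return out, factors


def pareto_scale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-feature Pareto scaling: (x - mean) / sqrt(sd), sd with n-1.

    Down-weights high-variance features less aggressively than unit-variance
    scaling, preserving some of the original intensity structure.  Constant
    features map to all-zeros and are returned as flagged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    zero_var = list(matrix.index[sd == 0])
    denom = np.sqrt(sd.replace(0.0, np.nan))
    out = matrix.sub(mean, axis=0).div(denom, axis=0)
    out.loc[zero_var] = 0.0
    return out, zero_var


def pretreat(study: FeatureStudy, seed: int = 0, *, n_trees: int = 100,
             max_iter: int = 10, pqn_reference: str = "qc_median") -> PretreatedMatrix:
    """Full pretreatment: impute -> log -> PQN -> Pareto, with provenance.

    The PQN reference is the pooled-QC median spectrum; the returned matrix
    contains biological samples only.
    """
    imputed, mask = impute_missing(study, seed=seed, n_trees=n_trees,
                                   max_iter=max_iter)
    sample_ids = study.sample_ids
    logX = np.log(imputed.intensities[sample_ids])

    if pqn_reference == "qc_median":
        if not study.qc_ids:
            raise ValueError("qc_median PQN reference requires QC injections")
        ref = np.log(imputed.intensities[study.qc_ids]).median(axis=1)
    elif pqn_reference == "sample_median":
        ref = logX.median(axis=1)
    else:
        raise ValueError(f"unknown PQN reference '{pqn_reference}'")

    normalized, factors = pqn_normalize(logX, ref, log_scale=True)
    scaled, zero_var = pareto_scale(normalized)
    provenance = {
        "steps": ["impute_missing", "log", "pqn", "pareto"],
        "imputer": {"kind": "random_forest", "n_trees": n_trees,
                    "max_iter": max_iter, "seed": seed},
        "pqn_reference": pqn_reference,
    }
    return PretreatedMatrix(data=scaled, pqn_factors=factors,
                            provenance=provenance,
                            zero_variance_features=zero_var,
                            imputed_mask=mask[sample_ids])
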