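"""Pooled-QC drift correction and feature/sample quality control.

Instrument response drifts smoothly with injection order.  The pooled-QC
injections — technical replicates of one pooled extract — trace that drift,
so for every feature a smoothing cubic spline is fitted to QC log-intensity
versus injection order and subtracted from all injections (re-anchored at
the median QC order).  A correction is kept only when it actually lowers
that feature's QC RSD, so flat features cannot be harmed.

Feature filters follow the usual untargeted-metabolomics battery: blank
ratio, detection rates, QC RSD, and D-ratio.  Sample outliers are flagged
from the per-sample detected-feature count via Tukey fences within group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .containers import FeatureStudy


@dataclass
class DriftReport:
    """Per-feature outcome of the drift correction."""

    corrected: list = field(default_factory=list)
    rejected: list = field(default_factory=list)       # fit worsened QC RSD
    too_few_qc: list = field(default_factory=list)     # < 4 observed QC points

    def as_dict(self) -> dict:
        return {"corrected": self.corrected, "rejected": self.rejected,
                "too_few_qc": self.too_few_qc}


@dataclass
class FilterThresholds:
    blank_fold: float = 10.0
    group_rate: float = 0.75
    qc_rate: float = 0.70
    rsd_max: float = 30.0       # percent
    dratio_max: float = 40.0    # percent


@dataclass
class FilterReport:
    removed_by: dict = field(default_factory=dict)   # criterion -> count
    retained: list = field(default_factory=list)
    skipped: list = field(default_factory=list)
    outlier_flags: dict = field(default_factory=dict)
    fences: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps({
            "removed_by": self.removed_by, "retained": self.retained,
            "skipped": self.skipped, "outlier_flags": self.outlier_flags,
            "fences": self.fences}, indent=1))


def _rsd(values: np.ndarray) -> float:
    v = values[np.isfinite(values)]
    if v.size < 2 or v.mean() == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / v.mean())


def _loo_spline_s(x: np.ndarray, y: np.ndarray, s_grid):
    """Pick the smoothing factor by leave-one-out CV over the QC points.

    Returns (best_s, best_err, const_err) where const_err is the LOO error
    of the constant (no-drift) model; a spline that cannot beat the constant
    model is interpolating through noise and should be rejected.
    """
    best_s, best_err = None, np.inf
    n = x.size
    const_err = float(np.mean([(y[i] - np.delete(y, i).mean()) ** 2
                               for i in range(n)]))
    for s in s_grid:
        errs = []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if mask.sum() < 4:
                continue
            try:
                sp = UnivariateSpline(x[mask], y[mask], k=3, s=s * (n - 1) / n)
            except Exception:
                continue
            errs.append((float(sp(x[i])) - y[i]) ** 2)
        if errs:
            err = float(np.mean(errs))
            if err < best_err:
                best_err, best_s = err, s
    return best_s, best_err, const_err


def drift_correct(study: FeatureStudy) -> tuple[FeatureStudy, DriftReport]:
    """Remove injection-order drift per feature using the QC spline.

    For each feature with >= 4 observed QC injections, a smoothing cubic
    spline (smoothing factor chosen by leave-one-out CV with a lower bound
    that prevents interpolating through the noise) is fitted to QC
    log-intensity versus injection order; every present value is corrected
    on the log scale by subtracting the spline prediction and adding its
    value at the median QC order.  Corrections that do not reduce the QC RSD
    are discarded.  Missingness is never altered.
    """
    inj = study.injections
    orders = inj["order"].to_numpy(dtype=float)
    is_qc = (inj["role"] == "qc").to_numpy()
    out = study.intensities.to_numpy(dtype=float).copy()
    report = DriftReport()

    qc_orders_all = orders[is_qc]
    lo_order, hi_order = (qc_orders_all.min(), qc_orders_all.max()) if is_qc.any() else (0, 0)

    for r, fid in enumerate(study.intensities.index):
        row = out[r]
        qc_mask = is_qc & np.isfinite(row)
        n_qc = int(qc_mask.sum())
        if n_qc < 4:
            report.too_few_qc.append(fid)
            continue
        x = orders[qc_mask]
        y = np.log(row[qc_mask])
        sort = np.argsort(x)
        x, y = x[sort], y[sort]
        var_y = float(y.var(ddof=1))
        if var_y == 0:
            report.rejected.append(fid)
            continue
        # candidate smoothing factors around scipy's heuristic m*var; the
        # smallest candidate keeps a floor well above pure interpolation
        s_grid = [n_qc * var_y * f for f in (0.25, 0.5, 1.0, 2.0, 5.0, 50.0)]
        if n_qc >= 5:
            s_best, cv_err, const_err = _loo_spline_s(x, y, s_grid)
            # no predictive drift signal beyond a flat baseline: leave alone
            if s_best is None or cv_err >= const_err:
                report.rejected.append(fid)
                continue
        else:
            s_best = s_grid[2]
        spline = UnivariateSpline(x, y, k=3, s=s_best)
        anchor = float(spline(np.median(x)))
        eval_orders = np.clip(orders, lo_order, hi_order)  # no wild extrapolation
        shift = np.asarray(spline(eval_orders), dtype=float) - anchor

        present = np.isfinite(row)
        candidate = row.copy()
        candidate[present] = np.exp(np.log(row[present]) - shift[present])
        if _rsd(candidate[is_qc]) < _rsd(row[is_qc]):
            out[r] = candidate
            report.corrected.append(fid)
        else:
            report.rejected.append(fid)

    corrected = study.copy()
    corrected.intensities = pd.DataFrame(out, index=study.intensities.index,
                                         columns=study.intensities.columns)
    return corrected, report


@dataclass
class FeatureQCMetrics:
    """Per-feature QC metrics plus the platform-level median QC RSD."""

    table: pd.DataFrame        # indexed by feature id
    mrsd: dict = field(default_factory=dict)   # platform -> median QC RSD (%)


def compute_qc_metrics(study: FeatureStudy) -> FeatureQCMetrics:
    """RSD per group and in QC, D-ratio, detection rates, blank ratio.

    RSD = 100*sd/mean on raw intensities; D-ratio = 100*sd(QC)/sd(biological
    samples); detection = fraction of injections with a present value.
    Features absent from all QCs get NaN QC metrics (they then fail the
    QC-dependent filters).
    """
    if not study.qc_ids:
        raise ValueError("study has no QC injections")
    X = study.intensities
    qc = X[study.qc_ids].to_numpy(dtype=float)
    samples = X[study.sample_ids].to_numpy(dtype=float)
    groups = study.groups

    tab = pd.DataFrame(index=X.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab["rsd_qc"] = [_rsd(row) for row in qc]
        sd_qc = np.array([np.nanstd(row, ddof=1) if np.isfinite(row).sum() > 1
                          else np.nan for row in qc])
        sd_samp = np.array([np.nanstd(row, ddof=1) if np.isfinite(row).sum() > 1
                            else np.nan for row in samples])
        tab["dratio"] = 100.0 * sd_qc / np.where(sd_samp > 0, sd_samp, np.nan)
        tab.loc[(sd_qc == 0), "dratio"] = 0.0
        tab["detect_qc"] = np.isfinite(qc).mean(axis=1)
        for g in groups:
            gx = X[study.sample_ids_in_group(g)].to_numpy(dtype=float)
            tab[f"rsd_{g}"] = [_rsd(row) for row in gx]
            tab[f"detect_{g}"] = np.isfinite(gx).mean(axis=1)
        if study.blank_ids:
            blanks = X[study.blank_ids].to_numpy(dtype=float)
            mean_blank = np.nanmean(np.where(np.isfinite(blanks), blanks, np.nan), axis=1)
            max_sample = np.nanmax(np.where(np.isfinite(samples), samples, np.nan), axis=1)
            tab["blank_ratio"] = max_sample / mean_blank
        else:
            tab["blank_ratio"] = np.nan

    mrsd = {}
    for plat, feats in study.features.groupby("platform").groups.items():
        vals = tab.loc[feats, "rsd_qc"].dropna()
        mrsd[str(plat)] = float(vals.median()) if len(vals) else float("nan")
    return FeatureQCMetrics(table=tab, mrsd=mrsd)


def filter_features(study: FeatureStudy, metrics: FeatureQCMetrics,
                    thresholds: FilterThresholds | None = None
                    ) -> tuple[FeatureStudy, FilterReport]:
    """Apply the quality filters in order blank -> detection -> RSD -> D-ratio.

    A feature is retained iff its maximum sample intensity is at least
    ``blank_fold`` times the mean blank intensity, it is detected in >= 75%
    of at least one sample group and >= 70% of QCs, its QC RSD is < 30%, and
    its D-ratio is < 40%.  The retained set is a conjunction, so it does not
    depend on the order; the per-criterion counts do and are reported in the
    declared order.
    """
    thr = thresholds or FilterThresholds()
    tab = metrics.table
    report = FilterReport()
    alive = pd.Series(True, index=tab.index)

    if study.blank_ids:
        # blank_ratio is NaN when the feature is absent from every blank:
        # there is no blank background to speak of, so the feature passes
        ok_blank = tab["blank_ratio"].fillna(np.inf) >= thr.blank_fold
    else:
        warnings.warn("no blank injections; blank filter skipped")
        report.skipped.append("blank")
        ok_blank = pd.Series(True, index=tab.index)
    report.removed_by["blank"] = int((alive & ~ok_blank).sum())
    alive &= ok_blank

    detect_cols = [c for c in tab.columns if c.startswith("detect_") and c != "detect_qc"]
    group_ok = (tab[detect_cols] >= thr.group_rate).any(axis=1) if detect_cols else True
    ok_detect = group_ok & (tab["detect_qc"] >= thr.qc_rate)
    report.removed_by["detection"] = int((alive & ~ok_detect).sum())
    alive &= ok_detect

    ok_rsd = tab["rsd_qc"].fillna(np.inf) < thr.rsd_max
    report.removed_by["rsd"] = int((alive & ~ok_rsd).sum())
    alive &= ok_rsd

    ok_dratio = tab["dratio"].fillna(np.inf) < thr.dratio_max
    report.removed_by["dratio"] = int((alive & ~ok_dratio).sum())
    alive &= ok_dratio

    report.retained = list(tab.index[alive])
    return study.subset_features(report.retained), report


@dataclass
class OutlierReport:
    flags: pd.Series = None            # sample id -> bool
    fences: dict = field(default_factory=dict)   # group -> (q1, q3, iqr)
    not_evaluable: list = field(default_factory=list)


def detect_sample_outliers(study: FeatureStudy) -> OutlierReport:
    """Flag samples whose detected-feature count falls outside Tukey fences.

    Counts are compared within each exposure group; groups smaller than 4
    are flagged not evaluable and produce no outlier calls.
    """
    report = OutlierReport(flags=pd.Series(False, index=study.sample_ids))
    X = study.intensities
    for g in study.groups:
        ids = study.sample_ids_in_group(g)
        if len(ids) < 4:
            report.not_evaluable.append(g)
            continue
        counts = np.isfinite(X[ids].to_numpy(dtype=float)).sum(axis=0)
        q1, q3 = np.percentile(counts, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        report.fences[g] = (float(q1), float(q3), float(iqr))
        for sid, c in zip(ids, counts):
            report.flags[sid] = bool(c < lo or c > hi)
    return report


def mask_outlier_samples(study: FeatureStudy, report: OutlierReport) -> FeatureStudy:
    """Set all values of flagged samples to missing (downstream exclusion)."""
    out = study.copy()
    for sid, flagged in report.flags.items():
        if flagged:
            out.intensities[sid] = np.nan
    return out
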