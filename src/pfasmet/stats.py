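"""Shared statistical primitives used across pipeline stages.

These are the small, exactly-specified statistics that several stages rely
on (multiple-testing correction, effect sizes, rank-based AUC).  They are
kept in one module so that, e.g., the feature screen and the pathway
over-representation stage share a single Benjamini-Hochberg code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "benjamini_hochberg",
    "cohens_d",
    "auc_mann_whitney",
    "PowerResult",
    "power_t",
]


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, returned in the input
    order.  Controls the FDR at level alpha when features with q < alpha are
    called significant.

    Parameters
    ----------
    pvals : array-like of float in [0, 1]

    Raises
    ------
    ValueError
        If any p-value lies outside [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cohens_d(x_high, x_low) -> float:
    """Cohen's d with the pooled standard deviation (n1 + n2 - 2 denominator).

    d = (mean(x_high) - mean(x_low)) / s_pooled.  Returns NaN when the pooled
    standard deviation is zero (degenerate, both samples constant).
    """
    x = np.asarray(x_high, dtype=float)
    y = np.asarray(x_low, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def auc_mann_whitney(pos, neg) -> float:
    """Empirical ROC AUC of `pos` (positive class) versus `neg`.

    Computed through the rank-sum identity AUC = U / (n1 * n2), with tied
    pairs counted as one half; identical to the trapezoidal area under the
    empirical ROC curve.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").statistic
    return float(u / (pos.size * neg.size))


@dataclass(frozen=True)
class PowerResult:
    """Power of the two-sided two-sample t-test from the noncentral t.

    delta = d * sqrt(n1*n2/(n1+n2)) is the noncentrality parameter and
    df = n1 + n2 - 2; power = P(|T'| > t_{1-alpha/2, df}) with T' noncentral t.
    """

    d: float
    n1: int
    n2: int
    delta: float
    df: int
    alpha: float
    power: float


def power_t(d: float, n1: int, n2: int, alpha: float = 0.05) -> PowerResult:
    """Two-sided independent t-test power for standardized difference `d`."""
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must both be >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    delta = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    if delta == 0.0:
        power = alpha  # central case, exactly the size of the test
    else:
        power = float(sps.nct.sf(tcrit, df, delta) + sps.nct.cdf(-tcrit, df, delta))
    return PowerResult(d=float(d), n1=int(n1), n2=int(n2), delta=float(delta),
                       df=int(df), alpha=float(alpha), power=float(power))
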