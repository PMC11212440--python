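"""Agreement and diagnostic statistics.

Spearman rank correlation, Fisher-Z comparison of correlations from
independent samples, Bland-Altman analysis of measured vs estimated daily
sodium excretion, the ±30% precision (P30) accuracy metric, and
threshold-based classification metrics (sensitivity, specificity, PPV,
NPV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ZComparison",
    "BlandAltman",
    "ClassificationResult",
    "spearman_rho",
    "fisher_z_compare",
    "bland_altman",
    "p30_precision",
    "classification_metrics",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p: float


@dataclass(frozen=True)
class ZComparison:
    """Fisher-Z comparison of two correlation coefficients.

    ``p`` is the one-sided tail probability Φ(−|z|); ``p_two_sided`` doubles
    it.  ``ordering`` records which correlation was first (z > 0 means the
    first was the stronger).
    """

    z: float
    p: float
    p_two_sided: float
    ordering: Tuple[str, str]


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman agreement summary; differences are measured − estimated."""

    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_p: float
    n: int
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class ClassificationResult:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def _paired(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    return x, y


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties).

    The p-value uses the t-approximation with n − 2 degrees of freedom.
    A constant input vector leaves the correlation undefined, signalled as
    NaN rather than an exception.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(math.nan, n, math.nan)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), n, float(p))


def fisher_z_compare(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    labels: Tuple[str, str] = ("r1", "r2"),
) -> ZComparison:
    """Compare two correlations from independent samples via Fisher's z.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)).  Swapping the
    two correlations negates z exactly.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p_one = float(sps.norm.cdf(-abs(z)))
    return ZComparison(z=z, p=p_one, p_two_sided=2.0 * p_one, ordering=labels)


def bland_altman(measured: Sequence[float], estimated: Sequence[float]) -> BlandAltman:
    """Bland-Altman analysis of agreement between measured and estimated.

    Differences are taken as measured − estimated, so a positive bias means
    the formula underestimates.  Limits of agreement are bias ± 1.96 times
    the sample SD of the differences; ``bias_p`` is a one-sample t-test of
    the differences against zero.
    """
    m, e = _paired(measured, estimated)
    if m.size < 2:
        raise ValueError("need at least 2 pairs")
    d = m - e
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.all(d == d[0]):
        bias_p = math.nan if d[0] == 0 else 0.0
    else:
        bias_p = float(sps.ttest_1samp(d, 0.0).pvalue)
    return BlandAltman(
        mean_bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        bias_p=bias_p,
        n=int(m.size),
        means=(m + e) / 2.0,
        diffs=d,
    )


def p30_precision(measured: Sequence[float], estimated: Sequence[float]) -> float:
    """Percentage of estimates within ±30% of the measured value (inclusive)."""
    m, e = _paired(measured, estimated)
    if np.any(m <= 0):
        raise ValueError("measured values must be positive for P30")
    inside = np.abs(e - m) <= 0.30 * m
    return 100.0 * float(inside.mean())


def _pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def classification_metrics(
    measured_g_d: Sequence[float],
    estimated_g_d: Sequence[float],
    threshold: float,
) -> ClassificationResult:
    """Diagnostic performance of an estimate at a sodium-excretion threshold.

    A participant is positive when strictly above the threshold (g/d of
    sodium; 2 g/d and 4 g/d correspond to salt intakes of ~5 and ~10 g/d).
    Metrics with an empty denominator are reported as None, not 0.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    m, e = _paired(measured_g_d, estimated_g_d)
    mp = m > threshold
    ep = e > threshold
    tp = int(np.sum(mp & ep))
    fp = int(np.sum(~mp & ep))
    tn = int(np.sum(~mp & ~ep))
    fn = int(np.sum(mp & ~ep))
    return ClassificationResult(
        threshold=threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
        ppv=_pct(tp, tp + fp),
        npv=_pct(tn, tn + fn),
    )
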