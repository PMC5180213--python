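"""Shared 2x2-table statistics: allelic odds ratios, Woolf intervals, Fisher tests.

Conventions used throughout the package
---------------------------------------
A 2x2 allele table is ordered ``(a, b, c, d)`` =
(case minor alleles, case major alleles, control minor alleles, control major
alleles), so the allelic odds ratio is ``OR = a*d / (b*c)``; OR > 1 means the
minor allele is enriched in cases (risk), OR < 1 protective.

* The Haldane–Anscombe correction (+0.5 to every cell) is applied to the OR and
  its Woolf confidence interval **iff** at least one cell is zero; the Fisher
  P-value is always computed on the uncorrected integer table.
* A table monomorphic in both arms (no minor allele anywhere, or no major
  allele anywhere) has no estimable OR: the OR and CI are NaN and P = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TableTest",
    "haldane_correct",
    "odds_ratio",
    "woolf_ci",
    "fisher_p",
    "test_table",
    "expected_false_positives",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TableTest:
    """Result of an exact test on a 2x2 allele table."""

    a: int
    b: int
    c: int
    d: int
    oratio: float
    ci_lo: float
    ci_hi: float
    p: float

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def haldane_correct(a: float, b: float, c: float, d: float) -> tuple[float, ...]:
    """Add 0.5 to every cell iff any cell is zero, else return unchanged."""
    if min(a, b, c, d) == 0:
        return (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    return (a, b, c, d)


def _monomorphic(a, b, c, d) -> bool:
    return (a == 0 and c == 0) or (b == 0 and d == 0)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Allelic OR = ad/bc, Haldane-corrected iff a zero cell is present.

    Returns NaN when the table is monomorphic in both arms.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")
    if _monomorphic(a, b, c, d):
        return float("nan")
    a, b, c, d = haldane_correct(a, b, c, d)
    return (a * d) / (b * c)


def woolf_ci(a: int, b: int, c: int, d: int, z: float = Z_95) -> tuple[float, float]:
    """Woolf (log-OR) confidence interval on the (possibly corrected) table."""
    if _monomorphic(a, b, c, d):
        return (float("nan"), float("nan"))
    a, b, c, d = haldane_correct(a, b, c, d)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P on the uncorrected integer table."""
    if _monomorphic(a, b, c, d):
        return 1.0
    p = _sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return float(min(p, 1.0))


def test_table(a: int, b: int, c: int, d: int) -> TableTest:
    """OR, Woolf 95% CI and two-sided Fisher P for one allele table."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("2x2 cells must be non-negative integers")
    lo, hi = woolf_ci(a, b, c, d)
    return TableTest(int(a), int(b), int(c), int(d),
                     odds_ratio(a, b, c, d), lo, hi, fisher_p(a, b, c, d))


def expected_false_positives(m: int, alpha: float = 0.05) -> float:
    """Expected false-positive count among m independent null tests at level alpha.

    For the validation panel of 83 SNPs at alpha = 0.05 this is 83 x 0.05 = 4.15,
    i.e. roughly four of the nominally significant hits are expected by chance
    alone — the arithmetic motivating a multiple-test correction.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return m * alpha


def weighted_welch_test(
    case_f: np.ndarray,
    case_w: np.ndarray,
    ctrl_f: np.ndarray,
    ctrl_w: np.ndarray,
) -> tuple[float, float]:
    """Pool-size-weighted Welch t-test on two sets of frequency estimates.

    Returns ``(t, p)`` with a Satterthwaite df. Identical weighted means give
    (0.0, 1.0) exactly. Used by :mod:`ibdarch.screen`; exposed here because it
    is a plain two-sample statistic, not pooled-GWAS-specific.
    """
    case_f = np.asarray(case_f, float)
    ctrl_f = np.asarray(ctrl_f, float)
    case_w = np.asarray(case_w, float)
    ctrl_w = np.asarray(ctrl_w, float)
    if case_f.size < 2 or ctrl_f.size < 2:
        raise ValueError("need >= 2 observations per arm")
    m1, v1, g1 = _weighted_mean_var(case_f, case_w)
    m2, v2, g2 = _weighted_mean_var(ctrl_f, ctrl_w)
    delta = m1 - m2
    if delta == 0.0:
        return 0.0, 1.0
    denom = v1 + v2
    if denom <= 0.0:
        # zero sampling variance but a real difference: P underflows to the
        # smallest representable positive value so it stays in (0, 1]
        return math.copysign(math.inf, delta), float(np.nextafter(0.0, 1.0))
    t = delta / math.sqrt(denom)
    df = denom**2 / (v1**2 / (g1 - 1) + v2**2 / (g2 - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return t, float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def _weighted_mean_var(f: np.ndarray, w: np.ndarray) -> tuple[float, float, int]:
    """Weighted mean and estimated variance of the weighted mean."""
    g = f.size
    sw = w.sum()
    m = float((w * f).sum() / sw)
    # ratio-estimator variance with a small-sample g/(g-1) correction;
    # reduces to the usual s^2/g for equal weights
    v = float((w**2 * (f - m) ** 2).sum() / sw**2 * g / (g - 1))
    return m, v, g
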