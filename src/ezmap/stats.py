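"""Statistical tests and scales used by the cohort analysis.

Thin, explicitly-guarded wrappers around scipy: paired t-tests for the
longitudinal metric comparisons, Welch two-sample t-tests for flagged vs
unflagged group comparisons, chi-square with a Fisher's-exact fallback for
categorical covariates, Cohen's kappa for inter-reader agreement, and the
logMAR -> Snellen conversion used when reporting visual acuity.

Degenerate inputs are handled explicitly rather than propagating NaNs:
zero-variance differences yield p = 1 when the mean difference is zero
(no evidence of change) and p = 0 when it is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def paired_ttest(x1, x2) -> TestResult:
    """Two-sided paired t-test on per-eye differences x2 - x1."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1-D samples")
    if len(x1) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x2 - x1
    if np.allclose(d.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(d.mean(), 0.0) else 0.0
        return TestResult(float("nan"), p, "paired t (zero-variance)")
    t, p = sps.ttest_rel(x2, x1)
    return TestResult(float(t), float(p), "paired t")


def welch_ttest(x, y) -> TestResult:
    """Two-sided Welch two-sample t-test (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t-test needs at least 2 observations per group")
    if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(x.mean(), y.mean()) else 0.0
        return TestResult(float("nan"), p, "Welch t (zero-variance)")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p), "Welch t")


def categorical_test(table: np.ndarray) -> TestResult:
    """Chi-square test of independence, Fisher's exact when cells are sparse.

    Fisher's exact test is used for 2x2 tables with any expected cell
    count of 5 or less (Cochran's validity rule for chi-square, applied
    inclusively).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if table.sum() == 0:
        return TestResult(float("nan"), 1.0, "none (empty table)")
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        # a degenerate margin carries no information about association
        return TestResult(float("nan"), 1.0, "none (degenerate margin)")
    chi2, p, _, expected = sps.chi2_contingency(table)
    if table.shape == (2, 2) and (expected <= 5).any():
        odds, p = sps.fisher_exact(table)
        return TestResult(float(odds), float(p), "Fisher exact")
    return TestResult(float(chi2), float(p), "chi-square")


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa between two raters: (p_o - p_e) / (1 - p_e).

    Works for any label alphabet; the degenerate case of both raters
    constant returns 1.0 when they agree everywhere and 0.0 otherwise.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("kappa needs two equal-length non-empty label vectors")
    n = len(a)
    cats = np.union1d(np.unique(a), np.unique(b))
    p_o = float(np.mean(a == b))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if math.isclose(p_e, 1.0):
        return 1.0 if math.isclose(p_o, 1.0) else 0.0
    return (p_o - p_e) / (1.0 - p_e)


#: Standard Snellen-chart denominators (20-foot notation).
SNELLEN_LINES = (10, 12.5, 16, 20, 25, 32, 40, 50, 63, 80, 100, 125,
                 160, 200, 250, 320, 400, 500, 630, 800, 1000, 2000)


def logmar_to_snellen(logmar: float) -> str:
    """Convert a logMAR acuity to the nearest standard Snellen line.

    The exact denominator is 20 x 10^logMAR; it is snapped to the nearest
    standard chart line in log space (logMAR 0.2 -> 20/32).
    """
    if not math.isfinite(logmar):
        raise ValueError("logMAR must be finite")
    target = math.log10(20.0) + logmar
    best = min(SNELLEN_LINES, key=lambda d: abs(math.log10(d) - target))
    denom = int(best) if float(best).is_integer() else best
    return f"20/{denom}"
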