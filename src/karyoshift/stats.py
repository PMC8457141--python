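"""Statistical tests used throughout the pipeline.

Every test the pipeline relies on is implemented here from its defining
formula so that each one can be checked against a closed-form or
brute-force oracle: Pearson chi-squared on a 2x2 table and on a k x 2
homogeneity table, the Mann-Whitney U test (exact by enumeration for
small samples, normal approximation with tie correction otherwise), the
one-sample t test, Pearson correlation, Holm step-down adjustment and
ordinary least squares.  Only distribution functions (``scipy.stats``
survival functions) are delegated.

All tests are two-sided by default; ``alternative`` switches sidedness
where the analysis calls for it.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _dist

Method = Literal[
    "chi2_pearson",
    "chi2_homogeneity",
    "mann_whitney_u",
    "one_sample_t",
    "pearson_r",
    "linear_regression",
]

Alternative = Literal["two-sided", "less", "greater"]


class DegenerateTableError(ValueError):
    """A contingency table has a zero marginal, making the test undefined."""


class ZeroVarianceError(ValueError):
    """A sample has zero variance where a scale estimate is required."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` is ``None`` for tests whose null distribution carries no
    degrees of freedom (exact Mann-Whitney).
    """

    statistic: float
    p_value: float
    method: Method
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def results_to_table(results: Sequence[TestResult], labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Serialize test results to a tidy table (test, statistic, df, p, method)."""
    labels = list(labels) if labels is not None else [str(i) for i in range(len(results))]
    return pd.DataFrame(
        {
            "test": labels,
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "method": [r.method for r in results],
        }
    )


def _as_count_table(table, shape_hint: str) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D {shape_hint} table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return arr


def chi2_2x2(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-squared test on a 2x2 count table, df = 1.

    The statistic is sum((O - E)^2 / E) over the four cells with
    expected counts from the marginals; with Yates correction each
    |O - E| is reduced by 0.5 (not below zero) before squaring.
    """
    arr = _as_count_table(table, "2x2")
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {arr.shape}")
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    for name, marg in (("row", rows), ("column", cols)):
        if np.any(marg == 0):
            idx = int(np.argmin(marg))
            raise DegenerateTableError(f"{name} marginal {idx} is zero; chi-squared undefined")
    n = arr.sum()
    expected = np.outer(rows, cols) / n
    dev = np.abs(arr - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    p = float(_dist.chi2.sf(stat, df=1))
    return TestResult(statistic=stat, p_value=p, method="chi2_pearson", df=1.0)


def chi2_homogeneity(table) -> TestResult:
    """Chi-squared homogeneity test of k (ref, alt)-style rows, df = k - 1.

    Rows with zero total are excluded with a warning and the degrees of
    freedom reduced accordingly (a silent replicate carries no evidence
    either way).
    """
    arr = _as_count_table(table, "k x 2")
    if arr.shape[1] != 2:
        raise ValueError(f"expected a k x 2 table, got {arr.shape}")
    row_totals = arr.sum(axis=1)
    if np.any(row_totals == 0):
        n_dropped = int(np.sum(row_totals == 0))
        warnings.warn(
            f"excluding {n_dropped} zero-total row(s) from homogeneity test",
            stacklevel=2,
        )
        arr = arr[row_totals > 0]
    k = arr.shape[0]
    if k < 2:
        raise ValueError("homogeneity test needs at least two non-empty rows")
    cols = arr.sum(axis=0)
    if np.any(cols == 0):
        raise DegenerateTableError("a column marginal is zero; homogeneity test undefined")
    expected = np.outer(arr.sum(axis=1), cols) / arr.sum()
    stat = float(np.sum((arr - expected) ** 2 / expected))
    df = float(k - 1)
    p = float(_dist.chi2.sf(stat, df=df))
    return TestResult(statistic=stat, p_value=p, method="chi2_homogeneity", df=df)


def _exact_mw_p(x: np.ndarray, y: np.ndarray, u_x: float, alternative: Alternative) -> float:
    """Exact Mann-Whitney p by enumerating all C(n+m, n) group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = _dist.rankdata(pooled)  # no ties in exact mode, but rankdata is safe
    total = math.comb(n + m, n)
    count_le = 0
    count_ge = 0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        if u <= u_x:
            count_le += 1
        if u >= u_x:
            count_ge += 1
    p_less = count_le / total
    p_greater = count_ge / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def mann_whitney_u(
    x,
    y,
    alternative: Alternative = "two-sided",
    exact_limit: int = 16,
) -> TestResult:
    """Mann-Whitney U test; U is reported for the first sample.

    The exact null distribution is enumerated when the combined sample
    size is at most ``exact_limit`` and there are no ties; otherwise a
    normal approximation with tie correction and continuity correction
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _dist.rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2)
    has_ties = len(np.unique(pooled)) < n + m

    if n + m <= exact_limit and not has_ties:
        p = _exact_mw_p(x, y, u_x, alternative)
        return TestResult(statistic=u_x, p_value=p, method="mann_whitney_u", df=None)

    mean_u = n * m / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n + m) * (n + m - 1))
    var_u = n * m / 12 * ((n + m + 1) - tie_term)
    if var_u <= 0:
        # all observations identical: no evidence of a shift
        return TestResult(statistic=u_x, p_value=1.0, method="mann_whitney_u", df=None)
    sd = math.sqrt(var_u)
    if alternative == "two-sided":
        z = (abs(u_x - mean_u) - 0.5) / sd
        p = 2 * float(_dist.norm.sf(z))
    elif alternative == "greater":
        z = (u_x - mean_u - 0.5) / sd
        p = float(_dist.norm.sf(z))
    else:
        z = (u_x - mean_u + 0.5) / sd
        p = float(_dist.norm.cdf(z))
    return TestResult(statistic=u_x, p_value=min(1.0, p), method="mann_whitney_u", df=None)


def one_sample_t(x, mu0: float, alternative: Alternative = "two-sided") -> TestResult:
    """One-sample t test of mean(x) against mu0, df = n - 1."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t test needs at least two observations")
    n = x.size
    if np.ptp(x) == 0.0:  # exact-constancy check; robust to summation dust in sd
        raise ZeroVarianceError("sample has zero variance; t statistic undefined")
    sd = float(np.std(x, ddof=1))
    t = float((x.mean() - mu0) / (sd / math.sqrt(n)))
    df = float(n - 1)
    if alternative == "two-sided":
        p = 2 * float(_dist.t.sf(abs(t), df))
    elif alternative == "greater":
        p = float(_dist.t.sf(t, df))
    else:
        p = float(_dist.t.cdf(t, df))
    return TestResult(statistic=t, p_value=min(1.0, p), method="one_sample_t", df=df)


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with a t-transform p-value, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs at least three pairs")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.sum(xd**2)))
    sy = float(np.sqrt(np.sum(yd**2)))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("a constant vector has no defined correlation")
    r = float(np.sum(xd * yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = float(n - 2)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r**2))
        p = 2 * float(_dist.t.sf(abs(t), df))
    return TestResult(statistic=r, p_value=min(1.0, p), method="pearson_r", df=df)


def holm_adjust(p) -> np.ndarray:
    """Holm step-down multiple-testing adjustment, order-preserving.

    Sorted p-values are multiplied by (k - i), a running maximum
    enforces monotonicity, results are capped at 1 and returned in the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * (k - np.arange(k))
    adjusted = np.minimum(np.maximum.accumulate(adjusted), 1.0)
    out = np.empty(k)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line fit with the slope's significance."""

    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int


def linear_fit(x, y) -> LinearFit:
    """Simple OLS of y on x via the normal equations.

    Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2); the p-value tests
    slope != 0 with a t statistic on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least three points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ZeroVarianceError("x is constant; slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    df = n - 2
    se2 = ss_res / df / sxx
    if se2 == 0.0:
        p = 0.0 if slope != 0.0 else 1.0
    else:
        t = slope / math.sqrt(se2)
        p = 2 * float(_dist.t.sf(abs(t), df))
    return LinearFit(
        slope=float(slope),
        intercept=intercept,
        r_squared=r2,
        adjusted_r_squared=adj_r2,
        p_value=min(1.0, p),
        n=int(n),
    )
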