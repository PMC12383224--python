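"""Covariate-adjusted correlation, effect-size conversion, and power.

Conventions
-----------
* Partial correlation residualizes both variables on an intercept plus the
  covariates by least squares and correlates the residuals; inference uses
  t = r·sqrt(df) / sqrt(1 - r²) with df = n - 2 - k.
* t-test powers use the noncentral t distribution, two-tailed by default
  (the convention that reproduces the printed group-contrast powers).
* Correlation powers use the Fisher-z approximation with SE = 1/sqrt(n-k-3),
  one-tailed by default (the convention that reproduces the printed
  covariate-adjusted correlation powers); both tails are available via the
  ``tails`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AssociationResult",
    "partial_correlation",
    "r_to_d",
    "one_sample_t",
    "one_sample_t_from_stats",
    "pooled_d",
    "power_two_sample_t",
    "power_one_sample_t",
    "power_correlation",
]


@dataclass
class AssociationResult:
    """A (partial) correlation with its test and effect-size conversions."""

    r: float
    n: int
    k: int
    df: int
    p: float
    d_equiv: float
    power: float


def r_to_d(r: float) -> float:
    """Convert a correlation to the equivalent Cohen's d: d = 2r / sqrt(1 - r²)."""
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1:
        return math.copysign(math.inf, r)
    return 2.0 * r / math.sqrt(1.0 - r * r)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x,
    y,
    covariates=None,
    alpha: float = 0.05,
    power_tails: str = "one",
) -> AssociationResult:
    """Pearson correlation of x and y after removing covariate effects.

    With no covariates this reduces to the plain Pearson correlation.  The
    returned result carries the equivalent Cohen's d and the Fisher-z power
    of the observed |r| at the given sample size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance residuals")
    r = float(np.dot(rx, ry) / (sx * sy))
    r = min(max(r, -1.0), 1.0)
    df = n - 2 - k
    if abs(r) < 1.0:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = 0.0
    power = power_correlation(abs(r), n, k=k, alpha=alpha, tails=power_tails) if abs(r) < 1 else 1.0
    return AssociationResult(r=r, n=n, k=k, df=df, p=p, d_equiv=r_to_d(r), power=power)


def one_sample_t(values, mu0: float) -> tuple[float, int, float, float]:
    """One-sample t-test against mu0; returns (t, df, p, Cohen's d)."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = v.mean()
    sd = v.std(ddof=1)
    return one_sample_t_from_stats(m, sd, n, mu0)


def one_sample_t_from_stats(mean: float, sd: float, n: int, mu0: float):
    """One-sample t-test from summary statistics (M, SD, n)."""
    if sd <= 0:
        raise ValueError("zero variance")
    d = (mean - mu0) / sd
    t = d * math.sqrt(n)
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p, d


def pooled_d(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> float:
    """Two-group Cohen's d with the pooled standard deviation."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    s2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("zero pooled variance")
    return (m1 - m2) / math.sqrt(s2)


def _nct_power(ncp: float, df: int, alpha: float, tails: str) -> float:
    if tails == "two":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    if tails == "one":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tcrit, df, abs(ncp)))
    raise ValueError("tails must be 'one' or 'two'")


def power_two_sample_t(
    d: float, n1: int, n2: int, alpha: float = 0.05, tails: str = "two"
) -> float:
    """Noncentral-t power of an independent-groups t-test at effect size d."""
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    return _nct_power(ncp, n1 + n2 - 2, alpha, tails)


def power_one_sample_t(d: float, n: int, alpha: float = 0.05, tails: str = "two") -> float:
    """Noncentral-t power of a one-sample t-test at effect size d."""
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return _nct_power(d * math.sqrt(n), n - 1, alpha, tails)


def power_correlation(
    r: float, n: int, k: int = 0, alpha: float = 0.05, tails: str = "one"
) -> float:
    """Fisher-z power of a (partial) correlation test.

    ``k`` covariates reduce the effective sample: SE = 1/sqrt(n - k - 3).
    Default one-tailed; two-tailed available.
    """
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (n={n}, k={k})")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = math.atanh(abs(r))
    se = 1.0 / math.sqrt(n - k - 3)
    if tails == "one":
        return float(stats.norm.cdf(z / se - stats.norm.ppf(1 - alpha)))
    if tails == "two":
        zc = stats.norm.ppf(1 - alpha / 2)
        return float(stats.norm.cdf(z / se - zc) + stats.norm.cdf(-z / se - zc))
    raise ValueError("tails must be 'one' or 'two'")
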