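"""Inferential toolkit for cohort results.

Classical one-sample and paired t-tests and Pearson correlations (thin,
typed wrappers over scipy), plus a Bayes factor for correlations computed
under a uniform prior on the population correlation rho in (-1, 1):

    BF01 = f(r | rho = 0, n) / integral_{-1}^{1} f(r | rho, n) * (1/2) drho,

where ``f`` is the exact sampling density of the observed Pearson
coefficient for a bivariate-normal sample of size ``n`` (Hotelling's form,
evaluated through the Gaussian hypergeometric function).  BF01 > 1 means
the data favour the null of no correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "one_sample_t",
    "paired_t",
    "pearson",
    "correlation_coefficient_density",
    "bf01_correlation",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float
    n: int
    bf01: float | None = None


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``.

    Zero-variance samples are handled explicitly: the statistic is +-inf
    (p = 0) when the common value differs from ``mu0``, and 0 (p = 1) when
    it equals it.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    n = len(values)
    mean_diff = float(np.mean(values) - mu0)
    if np.std(values, ddof=1) == 0:
        if mean_diff == 0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0, n=n)
        return TTestResult(t=float(np.sign(mean_diff)) * float("inf"),
                           df=n - 1, p=0.0, mean_diff=mean_diff, n=n)
    res = sps.ttest_1samp(values, mu0)
    return TTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue),
                       mean_diff=mean_diff, n=n)


def paired_t(a, b) -> TTestResult:
    """Paired t-test: one-sample test of the differences against zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def pearson(x, y, bayes_factor: bool = False) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    With ``bayes_factor=True`` the flat-prior BF01 is attached (requires
    n >= 4 and |r| < 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    bf = bf01_correlation(r, n) if bayes_factor else None
    return CorrelationResult(r=r, df=n - 2, p=float(res.pvalue), n=n, bf01=bf)


def correlation_coefficient_density(r, rho, n: int):
    """Exact sampling density f(r | rho, n) of the Pearson coefficient.

    Hotelling's expression for a bivariate-normal sample of size n >= 4:

        f(r) = (n-2) Gamma(n-1) / (sqrt(2 pi) Gamma(n-1/2))
               * (1-rho^2)^((n-1)/2) (1-r^2)^((n-4)/2) (1-rho r)^(3/2-n)
               * 2F1(1/2, 1/2; n-1/2; (1+rho r)/2).

    Vectorised over ``r`` and ``rho``.
    """
    r = np.asarray(r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if n < 4:
        raise ValueError("density implemented for n >= 4")
    if np.any(np.abs(r) >= 1) or np.any(np.abs(rho) >= 1):
        raise ValueError("r and rho must lie strictly inside (-1, 1)")
    log_const = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
    )
    log_density = (
        log_const
        + (n - 1) / 2.0 * np.log1p(-(rho**2))
        + (n - 4) / 2.0 * np.log1p(-(r**2))
        + (1.5 - n) * np.log1p(-rho * r)
    )
    return np.exp(log_density) * special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)


def bf01_correlation(r: float, n: int, epsrel: float = 1e-10) -> float:
    """Bayes factor for the null rho = 0 with a uniform prior on (-1, 1).

    The marginal likelihood under the alternative is the flat-prior average
    of the exact sampling density over rho, computed by adaptive
    quadrature.  Values above 1 favour the null.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be strictly below 1")
    null = float(correlation_coefficient_density(r, 0.0, n))

    def integrand(rho: float) -> float:
        return float(correlation_coefficient_density(r, rho, n))

    marginal, _ = integrate.quad(integrand, -1.0, 1.0, epsrel=epsrel,
                                 epsabs=0.0, limit=200)
    return null / (0.5 * marginal)
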