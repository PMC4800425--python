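"""Hypothesis tests used by the sleep-regulation analysis.

Two tests appear in the pipeline:

* the D'Agostino & Pearson omnibus K2 normality test, applied to the pooled
  y-residuals of a power-law fit (least squares assumes Gaussian residuals)
  or to a raw sample of sleep measurements; and
* Welch's two-tailed two-sample t test (heteroscedastic; no equal-variance
  assumption), used for genotype comparisons of total sleep, bout length
  and bout count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateSampleError, SampleSizeError
from .powerlaw import PowerLawFit


@dataclass
class TestResult:
    """Statistic + p-value container for a hypothesis test."""

    name: str
    statistic: float
    p_value: float
    df: float | tuple
    n: int | tuple

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


#: Smallest sample for which the kurtosis normalizing transform is trusted.
MIN_K2_SAMPLE = 20


def dagostino_pearson_k2(sample) -> TestResult:
    """D'Agostino & Pearson omnibus K2 test of normality.

    Combines the normalizing transforms of sample skewness and kurtosis,
    ``K2 = Z(sqrt(b1))**2 + Z(b2)**2``, referred to chi-squared with 2
    degrees of freedom.  Transform constants follow D'Agostino, Belanger &
    D'Agostino (1990), the canonical published formulas.

    Requires n >= 20 (validity of the kurtosis transform) and a
    non-degenerate sample.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < MIN_K2_SAMPLE:
        raise SampleSizeError(f"K2 test requires n >= {MIN_K2_SAMPLE}, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("K2 test undefined for a zero-variance sample")

    xc = x - x.mean()
    m2 = np.mean(xc**2)
    m3 = np.mean(xc**3)
    m4 = np.mean(xc**4)
    b1 = m3 / m2**1.5  # sample skewness (biased moments)
    b2 = m4 / m2**2  # sample kurtosis

    # skewness transform (Johnson SU approximation)
    y = b1 * np.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(np.log(np.sqrt(w2)))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    z1 = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis transform (Anscombe & Glynn)
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - e_b2) / np.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7.0) * (n + 9))
        * np.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3)))
    )
    a_const = 6.0 + 8.0 / sqrt_beta1 * (
        2.0 / sqrt_beta1 + np.sqrt(1.0 + 4.0 / sqrt_beta1**2)
    )
    z2 = (
        (1.0 - 2.0 / (9.0 * a_const))
        - np.cbrt((1.0 - 2.0 / a_const) / (1.0 + xk * np.sqrt(2.0 / (a_const - 4.0))))
    ) / np.sqrt(2.0 / (9.0 * a_const))

    k2 = float(z1**2 + z2**2)
    p = float(sps.chi2.sf(k2, df=2))
    return TestResult(name="dagostino-pearson-k2", statistic=k2, p_value=p, df=2, n=n)


def residual_normality(x, y, fit: PowerLawFit) -> TestResult:
    """K2 test on the pooled y-residuals of a power-law fit."""
    resid = np.asarray(y, dtype=float) - fit.predict(np.asarray(x, dtype=float))
    return dagostino_pearson_k2(resid)


def welch_t_test(sample_a, sample_b) -> TestResult:
    """Two-tailed two-sample heteroscedastic (Welch) t test.

    Degrees of freedom follow Welch-Satterthwaite.  Both samples need
    n >= 2; samples that are jointly constant have no defined statistic.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise SampleSizeError(f"Welch test requires n >= 2 in both samples, got {na}, {nb}")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult("welch-t", 0.0, 1.0, df=float(na + nb - 2), n=(na, nb))
        raise DegenerateSampleError("both samples constant with unequal means")
    se2 = va / na + vb / nb
    t = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(name="welch-t", statistic=t, p_value=p, df=df, n=(na, nb))
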