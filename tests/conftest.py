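"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check:

* ``oracle_powerlaw`` minimizes the (weighted) sum of squares by a dense
  grid over the exponent with the closed-form scale at each grid point,
  then Brent refinement — no Levenberg-Marquardt.
* ``brute_force_sleep_runs`` scans a trace minute by minute for maximal
  zero runs — no vectorized run-length machinery.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from flysleep.dam import ActivityTrace


def oracle_powerlaw(x, y, w=None, b_range=(-5.0, 3.0), n_grid=4001):
    """Grid-search + Brent oracle for min_w sum w*(y - a*x^b)^2.

    For fixed b the optimal scale is closed-form:
    a(b) = sum(w*x^b*y) / sum(w*x^(2b)).
    Returns (a, b, ss) where ss is the weighted residual sum of squares.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(y) if w is None else np.asarray(w, float)

    def a_of_b(b):
        xb = x**b
        return float(np.sum(w * xb * y) / np.sum(w * xb**2))

    def ss(b):
        a = a_of_b(b)
        return float(np.sum(w * (y - a * x**b) ** 2))

    grid = np.linspace(*b_range, n_grid)
    losses = np.array([ss(b) for b in grid])
    b0 = grid[int(np.argmin(losses))]
    step = (b_range[1] - b_range[0]) / (n_grid - 1)
    res = minimize_scalar(
        ss, bracket=(b0 - step, b0, b0 + step), method="brent",
        options={"xtol": 1e-13},
    )
    b = float(res.x)
    return a_of_b(b), b, ss(b)


def brute_force_sleep_runs(counts, min_sleep=5):
    """All maximal zero runs of length >= min_sleep, as (start, length)."""
    runs = []
    i, n = 0, len(counts)
    while i < n:
        if counts[i] == 0:
            j = i
            while j < n and counts[j] == 0:
                j += 1
            if j - i >= min_sleep:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def reference_k2(sample):
    """Published-formula K2 oracle, written independently of the package.

    Normalizing transforms of skewness (Johnson SU) and kurtosis
    (Anscombe-Glynn), combined as a chi-squared(2) statistic.
    """
    from math import log, sqrt

    from scipy.stats import chi2

    x = np.asarray(sample, float)
    n = len(x)
    d = x - x.mean()
    m2, m3, m4 = (np.mean(d**k) for k in (2, 3, 4))
    g1 = m3 / m2**1.5
    g2 = m4 / m2**2

    Y = g1 * sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    B2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9))
    W2 = -1.0 + sqrt(2.0 * (B2 - 1.0))
    Z1 = (1.0 / sqrt(0.5 * log(W2))) * np.arcsinh(Y * sqrt((W2 - 1.0) / 2.0))

    Eb2 = 3.0 * (n - 1) / (n + 1)
    Vb2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xs = (g2 - Eb2) / sqrt(Vb2)
    sb1 = 6.0 * (n**2 - 5 * n + 2) / ((n + 7.0) * (n + 9)) * sqrt(
        6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3)))
    A = 6.0 + 8.0 / sb1 * (2.0 / sb1 + sqrt(1.0 + 4.0 / sb1**2))
    Z2 = ((1.0 - 2.0 / (9.0 * A))
          - np.cbrt((1.0 - 2.0 / A) / (1.0 + xs * sqrt(2.0 / (A - 4.0))))
          ) / sqrt(2.0 / (9.0 * A))

    k2 = float(Z1**2 + Z2**2)
    return k2, float(chi2.sf(k2, 2))


@pytest.fixture
def rng():
    return np.random.default_rng(20160104)


def make_trace(counts, animal_id="test#01", start_day=1, start_zt=0):
    return ActivityTrace(animal_id=animal_id, counts=np.asarray(counts, dtype=np.int64),
                         start_day=start_day, start_zt=start_zt)
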