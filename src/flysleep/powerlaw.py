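"""Power-law regression of mean sleep bout length on sleep bout count.

The model is ``y = a * x**b`` fitted by (optionally weighted) nonlinear
least squares, where ``x`` is an animal-period's sleep bout count and
``y`` its mean sleep bout length.  Because every animal-period satisfies
``total sleep = x * y`` exactly, a fit with exponent ``b`` near -1 has a
scale parameter ``a`` that estimates the cohort's typical total sleep
(``y * x = a`` when ``b = -1``), and the coefficient of determination R²
measures how tightly total sleep is held to that value across animals —
high R² indicates tightly regulated sleep, low R² dysregulated sleep.

:class:`PowerLawRegressor` follows the scikit-learn estimator contract
(``fit``/``predict``, ``get_params``/``set_params``, trailing-underscore
fitted attributes) so it composes with sklearn pipelines and model
selection; module-level functions are thin wrappers returning the
:class:`PowerLawFit` result record.

Numerical contract: parameters are initialized from the ordinary linear
regression of ln y on ln x, then refined by Levenberg-Marquardt with
analytic Jacobian; the parameter covariance is ``s^2 (J^T W J)^{-1}`` with
``s^2 = SS_res / (n - 2)``, and 95% intervals and delta-method confidence
bands use the t distribution on n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InsufficientDataError, UnidentifiableModelError

from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class PowerLawFit:
    """Result record of a single power-law fit."""

    a: float
    b: float
    covariance: np.ndarray  # 2x2 for (a, b)
    r_squared: float
    ss_res: float
    ss_tot: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    dependency: float
    n: int
    dof: int
    converged: bool
    label: str | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**self.b

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "a": self.a,
            "b": self.b,
            "ci_a_low": self.ci_a[0],
            "ci_a_high": self.ci_a[1],
            "ci_b_low": self.ci_b[0],
            "ci_b_high": self.ci_b[1],
            "r_squared": self.r_squared,
            "dependency": self.dependency,
            "converged": self.converged,
        }


class PowerLawRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of ``y = a * x**b``, scikit-learn style.

    Parameters
    ----------
    weighting : {None, "inverse_y2"}
        ``None`` fits ordinary (unweighted) least squares.  ``"inverse_y2"``
        weights each residual by ``1 / y**2``, which equalizes relative
        errors and down-weights the long bouts of low-count animals.
    ci_level : float
        Confidence level for parameter intervals and bands (default 0.95).
    fix_b : float, optional
        Fix the exponent (e.g. -1) and fit only the scale ``a``, which then
        has the closed form ``a = sum(w x^b y) / sum(w x^{2b})``.
    weighted_r2 : bool
        If True and weights are in play, report R² from weighted sums of
        squares.  Default False: R² is always the unweighted
        ``1 - SS_res/SS_tot`` so weighted and unweighted fits stay
        comparable.
    tol : float
        Relative tolerance on the sum of squares for the minimizer.
    max_iter : int
        Cap on objective evaluations for the minimizer.

    Attributes
    ----------
    a_, b_ : float
        Fitted scale and exponent.
    covariance_ : ndarray, shape (2, 2)
        Covariance of (a, b); row/col for a fixed exponent are zero.
    r_squared_, ss_res_, ss_tot_ : float
    ci_a_, ci_b_ : tuple of float
    dependency_ : float
        Squared correlation between the a and b estimates, in [0, 1].
    n_, dof_ : int
    converged_ : bool
    result_ : PowerLawFit
    """

    def __init__(
        self,
        weighting: str | None = None,
        ci_level: float = 0.95,
        fix_b: float | None = None,
        weighted_r2: bool = False,
        tol: float = 1e-10,
        max_iter: int = 500,
    ):
        self.weighting = weighting
        self.ci_level = ci_level
        self.fix_b = fix_b
        self.weighted_r2 = weighted_r2
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _validate(X, y, sample_weight):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be a single column of bout counts")
            x = x[:, 0]
        elif x.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("X and y lengths differ")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        if (x <= 0).any():
            raise ValueError("bout counts must be positive (x >= 1)")
        if (y <= 0).any():
            raise ValueError("mean bout lengths must be positive")
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != x.shape or (w <= 0).any():
                raise ValueError("sample_weight must be positive and match X")
        else:
            w = None
        return x, y, w

    def fit(self, X, y, sample_weight=None):
        """Fit the power law to (bout count, mean bout length) points."""
        x, y, w = self._validate(X, y, sample_weight)
        n = len(x)
        n_params = 1 if self.fix_b is not None else 2
        if n < n_params + 1:
            raise InsufficientDataError(
                f"need at least {n_params + 1} points for a {n_params}-parameter fit, got {n}"
            )
        if self.fix_b is None and len(np.unique(x)) < 2:
            raise UnidentifiableModelError(
                "all bout counts identical: the exponent cannot be identified"
            )
        if w is None:
            if self.weighting == "inverse_y2":
                w = 1.0 / y**2
            elif self.weighting is None:
                w = np.ones_like(y)
            else:
                raise ValueError(f"unknown weighting {self.weighting!r}")
        sw = np.sqrt(w)

        dof = n - n_params
        converged = True

        if self.fix_b is not None:
            b = float(self.fix_b)
            xb = x**b
            a = float(np.sum(w * xb * y) / np.sum(w * xb**2))
            resid_w = sw * (y - a * xb)
            ss_res_w = float(resid_w @ resid_w)
            s2 = ss_res_w / dof
            var_a = s2 / float(np.sum(w * xb**2))
            cov = np.array([[var_a, 0.0], [0.0, 0.0]])
        else:
            # log-log OLS start makes Levenberg-Marquardt deterministic
            slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
            p0 = np.array([np.exp(intercept), slope])

            def resid(p):
                return sw * (y - p[0] * x ** p[1])

            def jac(p):
                xb = x ** p[1]
                return np.column_stack([-sw * xb, -sw * p[0] * xb * np.log(x)])

            sol = optimize.least_squares(
                resid,
                p0,
                jac=jac,
                method="lm",
                ftol=self.tol,
                xtol=self.tol,
                gtol=self.tol,
                max_nfev=self.max_iter * 3,
            )
            converged = bool(sol.success)
            a, b = float(sol.x[0]), float(sol.x[1])
            ss_res_w = float(2 * sol.cost)
            s2 = ss_res_w / dof
            jtj = sol.jac.T @ sol.jac
            try:
                cov = s2 * np.linalg.inv(jtj)
            except np.linalg.LinAlgError:
                cov = s2 * np.linalg.pinv(jtj)
                converged = False

        yhat = a * x**b
        resid_raw = y - yhat
        if self.weighted_r2:
            ybar_w = float(np.sum(w * y) / np.sum(w))
            ss_res = float(np.sum(w * resid_raw**2))
            ss_tot = float(np.sum(w * (y - ybar_w) ** 2))
        else:
            ss_res = float(resid_raw @ resid_raw)
            ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot

        tcrit = stats.t.ppf(0.5 + self.ci_level / 2, dof)
        se_a = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_b = float(np.sqrt(max(cov[1, 1], 0.0)))
        ci_a = (a - tcrit * se_a, a + tcrit * se_a)
        ci_b = (b, b) if self.fix_b is not None else (b - tcrit * se_b, b + tcrit * se_b)

        if cov[0, 0] > 0 and cov[1, 1] > 0:
            dep = float(cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1]))
        else:
            dep = float("nan")

        self.a_, self.b_ = a, b
        self.covariance_ = cov
        self.r_squared_ = r2
        self.ss_res_, self.ss_tot_ = ss_res, ss_tot
        self.ci_a_, self.ci_b_ = ci_a, ci_b
        self.dependency_ = dep
        self.n_, self.dof_ = n, dof
        self.converged_ = converged
        self.result_ = PowerLawFit(
            a=a, b=b, covariance=cov, r_squared=r2, ss_res=ss_res, ss_tot=ss_tot,
            ci_a=ci_a, ci_b=ci_b, dependency=dep, n=n, dof=dof, converged=converged,
        )
        return self

    def predict(self, X):
        """Fitted mean bout length at the given bout counts."""
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.a_ * x**self.b_

    def confidence_band(self, x_grid, level: float | None = None) -> pd.DataFrame:
        """Delta-method confidence band for the fitted curve.

        At each x the band is ``yhat(x) +- t * sqrt(g^T C g)`` with gradient
        ``g = (x^b, a x^b ln x)`` and C the parameter covariance.
        """
        return confidence_band(self.result_, x_grid, level or self.ci_level)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_powerlaw(
    x: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    label: str | None = None,
    **kwargs,
) -> PowerLawFit:
    """Ordinary (or explicitly weighted) least-squares fit of ``y = a x^b``."""
    est = PowerLawRegressor(**kwargs).fit(np.asarray(x), np.asarray(y), sample_weight=weights)
    est.result_.label = label
    return est.result_


def weighted_fit_1_over_y2(
    x: Sequence[float], y: Sequence[float], label: str | None = None, **kwargs
) -> PowerLawFit:
    """Fit with relative weighting ``w_i = 1 / y_i**2``."""
    est = PowerLawRegressor(weighting="inverse_y2", **kwargs).fit(np.asarray(x), np.asarray(y))
    est.result_.label = label
    return est.result_


def r_squared(x, y, fit: PowerLawFit) -> float:
    """Coefficient of determination ``1 - SS_res/SS_tot`` of ``fit`` on data.

    SS_tot is taken about the mean of y (the horizontal mean line).  May be
    negative for a fit worse than that line; NaN when all y are equal
    (SS_tot = 0, R² undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - fit.predict(x)) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def dependency(fit: PowerLawFit) -> float:
    """Squared correlation between the a and b estimates; in [0, 1].

    Values near 1 mean the two parameters are nearly redundant for the
    data at hand.  NaN when either variance is zero.
    """
    cov = fit.covariance
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return float("nan")
    return float(cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1]))


def confidence_band(fit: PowerLawFit, x_grid, level: float = 0.95) -> pd.DataFrame:
    """Delta-method confidence band of the fitted curve on a grid of x.

    Returns a DataFrame with columns ``x``, ``fit``, ``lower``, ``upper``.
    The band always contains the fitted curve; its half-width at x is
    ``t_{(1+level)/2, dof} * sqrt(g(x)^T C g(x))``.
    """
    x = np.asarray(x_grid, dtype=float)
    if (x <= 0).any():
        raise ValueError("the power law is defined for x > 0 only")
    xb = x**fit.b
    yhat = fit.a * xb
    g = np.column_stack([xb, fit.a * xb * np.log(x)])
    var = np.einsum("ij,jk,ik->i", g, fit.covariance, g)
    tcrit = stats.t.ppf(0.5 + level / 2, fit.dof)
    half = tcrit * np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame({"x": x, "fit": yhat, "lower": yhat - half, "upper": yhat + half})
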