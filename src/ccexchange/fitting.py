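"""Kinetic and thermodynamic parameter extraction from exchange time courses.

The workhorse model is the three-parameter exponential rise

    F(t) = F0 + A * (1 - exp(-k_obs * t))

fitted by nonlinear least squares under pseudo-first-order conditions
(unlabelled material in large excess).  From fitted ``k_obs`` values the
module derives half-lives (t1/2 = ln2 / k_obs), apparent second-order rate
constants (ordinary least squares of k_obs on concentration) and Arrhenius
activation enthalpies (regression of ln k_obs on 1/T, with the gas constant
fixed at R = 1.987e-3 kcal mol^-1 K^-1).

Estimators follow the scikit-learn protocol: construct with hyperparameters,
``fit(X, y)``, fitted attributes carry a trailing underscore, and they
compose with sklearn model-selection tooling.  The module-level functions
(`fit_exponential_rise`, `fit_arrhenius`, ...) are thin wrappers that
construct, fit and return the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DegenerateTraceError,
    DomainError,
    FitFailureError,
    InputError,
)

__all__ = [
    "R_GAS_KCAL",
    "ExponentialRiseModel",
    "ConcentrationDependenceModel",
    "ArrheniusModel",
    "ReplicateSummary",
    "fit_exponential_rise",
    "fit_concentration_dependence",
    "fit_arrhenius",
    "half_life",
    "normalize_timecourse",
    "summarize_replicates",
    "arrhenius_scale",
    "celsius_to_kelvin",
]

#: Gas constant in kcal mol^-1 K^-1.
R_GAS_KCAL = 1.987e-3


def celsius_to_kelvin(t_celsius) -> np.ndarray | float:
    """The single Celsius -> Kelvin conversion point of the package."""
    return np.asarray(t_celsius, float) + 273.15


def arrhenius_scale(
    k_ref: float, ea_kcal: float, t_celsius: float, t_ref_celsius: float = 25.0
) -> float:
    """Scale a rate constant from ``t_ref_celsius`` to ``t_celsius``.

    ``k(T) = k_ref * exp(-Ea/R * (1/T - 1/T_ref))`` with Ea in kcal/mol.
    """
    t = float(celsius_to_kelvin(t_celsius))
    t_ref = float(celsius_to_kelvin(t_ref_celsius))
    return k_ref * math.exp(-(ea_kcal / R_GAS_KCAL) * (1.0 / t - 1.0 / t_ref))


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(X, float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x.ravel()
    if x.ndim != 1:
        raise InputError("X must be 1-D (or a single-column 2-D array)")
    yv = np.asarray(y, float).ravel()
    if yv.shape != x.shape:
        raise InputError(f"X and y lengths differ: {x.size} vs {yv.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(yv))):
        raise InputError("X and y must be finite")
    return x, yv


def _rise(t, f0, a, k):
    return f0 + a * (1.0 - np.exp(-k * t))


class ExponentialRiseModel(RegressorMixin, BaseEstimator):
    """Exponential-rise fit ``F(t) = F0 + A (1 - exp(-k_obs t))``.

    Parameters
    ----------
    k_bounds : (low, high)
        Search range for k_obs in min^-1.
    n_restarts : int
        Number of log-spaced k initializations tried after the data-driven
        initial guess fails; the order is deterministic.
    min_development : float
        Minimum required signal development ``k_obs * t_span`` (in units of
        ln 2, i.e. half-lives); a fitted rate below this is unresolvable on
        the given span and raises :class:`FitFailureError`.

    Fitted attributes: ``F0_``, ``A_``, ``k_obs_`` with standard errors
    ``F0_stderr_``, ``A_stderr_``, ``k_obs_stderr_`` from the fit
    covariance, ``r_squared_``, ``n_points_``, ``half_life_``, plus
    ``decaying_`` flagging a negative amplitude.
    """

    def __init__(
        self,
        k_bounds: tuple[float, float] = (1e-6, 1e3),
        n_restarts: int = 5,
        min_development: float = 0.5,
    ):
        self.k_bounds = k_bounds
        self.n_restarts = n_restarts
        self.min_development = min_development

    # -- initial guesses ----------------------------------------------------

    def _initial_k(self, t: np.ndarray, y: np.ndarray) -> float:
        """ln2 / (time at half-rise), linearly interpolated."""
        y0, y1 = y[0], y[-1]
        half = 0.5 * (y0 + y1)
        sign = 1.0 if y1 >= y0 else -1.0
        crossed = np.nonzero(sign * (y - half) >= 0)[0]
        t_half = None
        for i in crossed:
            if i > 0:
                dy = y[i] - y[i - 1]
                frac = (half - y[i - 1]) / dy if dy != 0 else 0.0
                t_half = t[i - 1] + frac * (t[i] - t[i - 1])
                break
        if t_half is None or t_half <= 0:
            t_half = (t[-1] - t[0]) / 3.0 or 1.0
        k = math.log(2.0) / t_half
        lo, hi = self.k_bounds
        return float(np.clip(k, lo, hi))

    def fit(self, X, y) -> "ExponentialRiseModel":
        t, yv = _as_xy(X, y)
        if t.size < 5:
            raise InputError(f"need >= 5 time points, got {t.size}")
        if np.any(t < 0):
            raise InputError("times must be non-negative")
        lo, hi = self.k_bounds
        k_starts = [self._initial_k(t, yv)] + list(
            np.logspace(math.log10(lo * 10), math.log10(hi / 10), self.n_restarts)
        )
        p0_f0, p0_a = yv[0], yv[-1] - yv[0]
        last_err: Exception | None = None
        popt = pcov = None
        for k0 in k_starts:
            try:
                popt, pcov = curve_fit(
                    _rise,
                    t,
                    yv,
                    p0=[p0_f0, p0_a, k0],
                    bounds=([-np.inf, -np.inf, lo], [np.inf, np.inf, hi]),
                    maxfev=20000,
                )
                break
            except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
                last_err = err
        if popt is None:
            raise FitFailureError(
                f"exponential-rise fit did not converge after "
                f"{len(k_starts)} starts: {last_err}"
            )
        f0, a, k = (float(v) for v in popt)
        span = float(t[-1] - t[0])
        if k * span < self.min_development * math.log(2.0):
            raise FitFailureError(
                f"rate {k:.3g}/min is unresolvable on a {span:.3g} min span "
                f"(< {self.min_development} half-lives of development)"
            )
        resid = yv - _rise(t, *popt)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        self.F0_, self.A_, self.k_obs_ = f0, a, k
        err = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        self.F0_stderr_, self.A_stderr_, self.k_obs_stderr_ = (float(e) for e in err)
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else -math.inf
        self.n_points_ = int(t.size)
        self.residual_sd_ = math.sqrt(ss_res / max(t.size - 3, 1))
        self.decaying_ = a < 0
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, float)
        if t.ndim == 2:
            t = t.ravel()
        return _rise(t, self.F0_, self.A_, self.k_obs_)

    @property
    def half_life_(self) -> float:
        return half_life(self.k_obs_)

    @property
    def plateau_(self) -> float:
        return self.F0_ + self.A_

    def to_dict(self) -> dict:
        return {
            "F0": self.F0_,
            "A": self.A_,
            "k_obs_per_min": self.k_obs_,
            "F0_stderr": self.F0_stderr_,
            "A_stderr": self.A_stderr_,
            "k_obs_stderr": self.k_obs_stderr_,
            "half_life_min": self.half_life_,
            "r_squared": self.r_squared_,
            "n_points": self.n_points_,
        }


class ConcentrationDependenceModel(RegressorMixin, BaseEstimator):
    """OLS line of k_obs against unlabelled concentration.

    The slope is the apparent second-order rate constant (per uM per min).
    Fitted attributes: ``slope_``, ``intercept_``, ``slope_stderr_``,
    ``intercept_stderr_``, ``r_squared_``.
    """

    def fit(self, X, y) -> "ConcentrationDependenceModel":
        conc, kobs = _as_xy(X, y)
        if conc.size < 3:
            raise InputError(f"need >= 3 (concentration, k_obs) pairs, got {conc.size}")
        if np.unique(conc).size < 3:
            raise InputError("concentrations must be distinct")
        beta, cov, ss_res, ss_tot = _linfit(conc, kobs)
        self.slope_, self.intercept_ = float(beta[1]), float(beta[0])
        self.slope_stderr_ = float(np.sqrt(cov[1, 1]))
        self.intercept_stderr_ = float(np.sqrt(cov[0, 0]))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else -math.inf
        self.n_points_ = int(conc.size)
        return self

    def predict(self, X) -> np.ndarray:
        c = np.asarray(X, float).ravel()
        return self.intercept_ + self.slope_ * c


class ArrheniusModel(RegressorMixin, BaseEstimator):
    """Arrhenius regression: ln k_obs on 1/T_K.

    ``Ea_`` (kcal/mol) is ``-slope * R``; ``lnA_`` is the intercept.
    Unweighted OLS by default; when per-point standard errors of k are
    passed to :meth:`fit`, inverse-variance weights are used and the
    parameter covariance is computed from those provided variances
    (absolute-sigma convention), not rescaled by the residuals.
    """

    def fit(self, X, y, k_stderr=None) -> "ArrheniusModel":
        t_c, k = _as_xy(X, y)
        if t_c.size < 3:
            raise InputError(f"need >= 3 (temperature, k_obs) pairs, got {t_c.size}")
        if np.any(k <= 0):
            raise DomainError("k_obs values must be positive")
        t_k = celsius_to_kelvin(t_c)
        if np.any(t_k <= 0):
            raise DomainError("temperatures must be above absolute zero")
        x = 1.0 / t_k
        ylog = np.log(k)
        if k_stderr is not None:
            sig = np.asarray(k_stderr, float).ravel()
            if sig.shape != k.shape:
                raise InputError("k_stderr length must match k_obs")
            if np.any(sig <= 0):
                raise DomainError("k standard errors must be positive")
            sigma_log = sig / k  # delta method for ln k
            beta, cov, ss_res, ss_tot = _linfit(x, ylog, sigma=sigma_log)
            self.weighted_ = True
        else:
            beta, cov, ss_res, ss_tot = _linfit(x, ylog)
            self.weighted_ = False
        slope, intercept = float(beta[1]), float(beta[0])
        self.Ea_ = -slope * R_GAS_KCAL
        self.lnA_ = intercept
        self.Ea_stderr_ = float(np.sqrt(cov[1, 1])) * R_GAS_KCAL
        self.lnA_stderr_ = float(np.sqrt(cov[0, 0]))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else -math.inf
        self.n_points_ = int(t_c.size)
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted k_obs at the given temperatures (Celsius)."""
        x = 1.0 / celsius_to_kelvin(np.asarray(X, float).ravel())
        return np.exp(self.lnA_ - (self.Ea_ / R_GAS_KCAL) * x)

    def to_dict(self) -> dict:
        return {
            "Ea_kcal_per_mol": self.Ea_,
            "Ea_stderr": self.Ea_stderr_,
            "lnA": self.lnA_,
            "lnA_stderr": self.lnA_stderr_,
            "r_squared": self.r_squared_,
            "n_points": self.n_points_,
            "weighted": self.weighted_,
        }


def _linfit(x: np.ndarray, y: np.ndarray, sigma: np.ndarray | None = None):
    """Closed-form (weighted) straight-line fit.

    Returns (beta = [intercept, slope], covariance, weighted SS_res, SS_tot).
    Unweighted: covariance scaled by the residual variance (n-2 dof).
    Weighted with known sigma: covariance is (X^T W X)^-1 unscaled.
    """
    design = np.column_stack([np.ones_like(x), x])
    if sigma is None:
        w = np.ones_like(x)
    else:
        w = 1.0 / sigma**2
    xtwx = design.T @ (w[:, None] * design)
    xtwy = design.T @ (w * y)
    beta = np.linalg.solve(xtwx, xtwy)
    resid = y - design @ beta
    ss_res = float(w @ resid**2)
    ybar = float(np.average(y, weights=w))
    ss_tot = float(w @ (y - ybar) ** 2)
    cov = np.linalg.inv(xtwx)
    if sigma is None:
        dof = max(x.size - 2, 1)
        cov = cov * (ss_res / dof)
    return beta, cov, ss_res, ss_tot


# ---------------------------------------------------------------------------
# replicate summaries and convenience functions


@dataclass
class ReplicateSummary:
    """Mean, one standard deviation (n-1 denominator) and replicate count."""

    mean: float
    sd: float
    n: int

    @property
    def stderr(self) -> float:
        return self.sd / math.sqrt(self.n) if self.n > 0 else math.nan


def summarize_replicates(values: Sequence[float]) -> ReplicateSummary:
    v = np.asarray(list(values), float)
    if v.size == 0:
        raise InputError("no replicate values given")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return ReplicateSummary(mean=float(v.mean()), sd=sd, n=int(v.size))


def half_life(k_obs: float) -> float:
    """t1/2 = ln 2 / k_obs, in minutes."""
    if k_obs <= 0:
        raise DomainError(f"k_obs must be positive, got {k_obs}")
    return math.log(2.0) / k_obs


def fit_exponential_rise(times, values, **kwargs) -> ExponentialRiseModel:
    return ExponentialRiseModel(**kwargs).fit(times, values)


def fit_concentration_dependence(conc, k_obs) -> ConcentrationDependenceModel:
    return ConcentrationDependenceModel().fit(conc, k_obs)


def fit_arrhenius(temps_celsius, k_obs, k_stderr=None) -> ArrheniusModel:
    return ArrheniusModel().fit(temps_celsius, k_obs, k_stderr=k_stderr)


def normalize_timecourse(times, values, noise_floor_sds: float = 3.0) -> np.ndarray:
    """Normalize a raw trace to ~[0, 1] using its own fit anchors.

    Subtracts the fitted baseline F0 and divides by the fitted amplitude
    (plateau - baseline), so the result is idempotent and invariant to any
    affine transform of the raw fluorescence.  A trace whose amplitude is
    below ``noise_floor_sds`` times the residual noise is degenerate.
    """
    t, yv = _as_xy(times, values)
    if t.size < 5:
        raise InputError(f"need >= 5 time points, got {t.size}")
    if np.ptp(yv) == 0:
        raise DegenerateTraceError("constant trace: no signal development")
    try:
        fit = ExponentialRiseModel().fit(t, yv)
    except FitFailureError as err:
        raise DegenerateTraceError(
            f"trace has no resolvable exponential rise: {err}"
        ) from err
    if abs(fit.A_) < noise_floor_sds * max(fit.residual_sd_, 1e-300):
        raise DegenerateTraceError(
            f"amplitude {fit.A_:.3g} is below {noise_floor_sds}x the "
            f"baseline noise {fit.residual_sd_:.3g}"
        )
    return (yv - fit.F0_) / fit.A_
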