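"""Kinetic models for cumulative methane time series.

Cumulative biogas curves from batch assays are classically sigmoidal: a lag
while the methanogenic community establishes, a near-linear production phase,
and a plateau at the ultimate methane potential.  The modified Gompertz model

    y(t) = A * exp(-exp(mu_m * e / A * (lam - t) + 1))

captures this with three interpretable parameters: A, the asymptotic yield
(same units as y, here umol CH4 per g substrate carbon); mu_m, the maximum
production rate (units of y per day, the slope at the inflection point); and
lam, the lag time in days.  Slow, non-sigmoidal producers (e.g. disaccharide
treatments and gas-fed controls) are better served by a straight line, so an
ordinary least-squares linear fit and an automatic model-choice rule are
provided alongside the nonlinear fitter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "MethaneSeries",
    "GompertzFit",
    "LinearFit",
    "TreatmentFit",
    "NoProductionError",
    "gompertz_predict",
    "gompertz_rate",
    "fit_gompertz",
    "fit_linear",
    "fit_treatment",
    "consolidate_group",
]

_E = math.e


class NoProductionError(ValueError):
    """Raised when a series has no methane at all (nothing to fit)."""


@dataclass(frozen=True)
class MethaneSeries:
    """Cumulative methane for one bottle (or one pooled treatment).

    ``values`` are cumulative CH4 in umol per g substrate carbon at the
    sampling ``times`` in days.
    """

    treatment: str
    replicate: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(t) and t[0] < 0:
            raise ValueError("times must be nonnegative")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.treatment}/{self.replicate}: times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError(f"{self.treatment}/{self.replicate}: cumulative methane must be nonnegative")


def gompertz_predict(A: float, mu_m: float, lam: float, t):
    """Modified Gompertz curve evaluated at time(s) t."""
    if A <= 0:
        raise ValueError(f"asymptote A must be positive, got {A}")
    t = np.asarray(t, dtype=float)
    inner = mu_m * _E / A * (lam - t) + 1.0
    # exp overflow for t far below lag is harmless: outer exp(-inf) -> 0
    with np.errstate(over="ignore"):
        out = A * np.exp(-np.exp(inner))
    return out if out.ndim else float(out)


def gompertz_rate(A: float, mu_m: float, lam: float, t):
    """Analytic time-derivative of the Gompertz curve.

    Its maximum over t is mu_m, attained at the inflection point where
    y = A/e.
    """
    t = np.asarray(t, dtype=float)
    inner = mu_m * _E / A * (lam - t) + 1.0
    with np.errstate(over="ignore"):
        out = mu_m * _E * np.exp(inner - np.exp(inner))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GompertzFit:
    A: float
    mu_m: float
    lam: float
    r_squared: float
    residuals: np.ndarray
    converged: bool
    stderr_A: float

    def predict(self, t):
        return gompertz_predict(self.A, self.mu_m, self.lam, t)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float

    def predict(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.intercept


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum(resid**2))
    if sst == 0.0:
        return 0.0
    return 1.0 - ssr / sst


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Robust starting point for sigmoid data with a possibly long lag."""
    A0 = float(y.max())
    below = t[y < 0.05 * A0]
    lam0 = float(below.max()) if below.size else 0.0
    dt = np.diff(t)
    slopes = np.diff(y)[dt > 0] / dt[dt > 0]  # pooled replicates repeat time points
    mu0 = A0 / max(t.max(), 1.0)
    if slopes.size and np.nanmax(slopes) > 0:
        mu0 = float(np.nanmax(slopes))
    return A0, mu0, lam0


def fit_gompertz(series: MethaneSeries) -> GompertzFit:
    """Fit the modified Gompertz model by bounded nonlinear least squares.

    Levenberg–Marquardt-style minimization of the residual sum of squares,
    run as a trust-region reflective problem so the physically meaningful
    box A in (0, 10*max(y)], mu_m > 0, lam in [0, max(t)] can be enforced.
    Non-convergence is reported through the ``converged`` flag rather than
    an exception; an all-zero series raises :class:`NoProductionError`.
    """
    t, y = series.times, series.values
    if len(t) < 5:
        raise ValueError(f"need >= 5 points to fit Gompertz, got {len(t)}")
    if y.max() <= 0:
        raise NoProductionError(
            f"{series.treatment}/{series.replicate}: no methane production in series"
        )

    A0, mu0, lam0 = _initial_guess(t, y)
    x0 = np.array([A0, mu0, lam0])
    lo = np.array([1e-9, 1e-9, 0.0])
    hi = np.array([10.0 * y.max(), np.inf, float(t.max())])
    x0 = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, x0))

    def resid(p):
        return gompertz_predict(p[0], p[1], p[2], t) - y

    sol = optimize.least_squares(
        resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    A, mu_m, lam = sol.x
    r = sol.fun
    # stderr of A from the Gauss-Newton covariance (J'J)^-1 * s^2
    dof = max(len(t) - 3, 1)
    s2 = float(r @ r) / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        stderr_A = float(math.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        stderr_A = float("inf")
    return GompertzFit(
        A=float(A),
        mu_m=float(mu_m),
        lam=float(lam),
        r_squared=_r_squared(y, r),
        residuals=r,
        converged=bool(sol.success),
        stderr_A=stderr_A,
    )


def fit_linear(series: MethaneSeries) -> LinearFit:
    """Ordinary least-squares straight line through the series."""
    t, y = series.times, series.values
    if len(t) < 3:
        raise ValueError(f"need >= 3 points for a linear fit, got {len(t)}")
    if np.allclose(y, y[0]):
        warnings.warn(
            f"{series.treatment}/{series.replicate}: constant series, slope 0 and R^2 reported as 0",
            stacklevel=2,
        )
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return LinearFit(slope=float(slope), intercept=float(intercept), r_squared=_r_squared(y, resid))


@dataclass(frozen=True)
class TreatmentFit:
    """Per-treatment summary: pooled fit plus replicate spread of A."""

    treatment: str
    model: str  # "gompertz" or "linear"
    A: float | None
    sd_A: float | None
    mu_m: float | None
    lam: float | None
    slope: float | None
    r_squared: float
    gompertz: GompertzFit | None
    linear: LinearFit


def fit_treatment(
    series_list: list[MethaneSeries],
    model: str = "auto",
    gompertz_r2_threshold: float = 0.6,
) -> TreatmentFit:
    """Fit one treatment from its replicate series.

    All replicate points are pooled for the reported parameter set; each
    replicate is additionally fitted on its own to attach a standard
    deviation to A.  With ``model="auto"`` the Gompertz fit is kept when it
    converges with R^2 >= ``gompertz_r2_threshold`` and a standard error of
    A smaller than A itself; otherwise the linear fit is reported.
    """
    if not series_list:
        raise ValueError("empty series list")
    treatment = series_list[0].treatment
    order = np.argsort(np.concatenate([s.times for s in series_list]), kind="stable")
    t = np.concatenate([s.times for s in series_list])[order]
    y = np.concatenate([s.values for s in series_list])[order]
    # pooled series may repeat time points; bypass the strict-increase check
    pooled = MethaneSeries.__new__(MethaneSeries)
    object.__setattr__(pooled, "treatment", treatment)
    object.__setattr__(pooled, "replicate", "pooled")
    object.__setattr__(pooled, "times", t)
    object.__setattr__(pooled, "values", y)

    if y.max() <= 0:
        raise NoProductionError(f"{treatment}: no methane production in any replicate")
    lin = fit_linear(pooled)
    gf: GompertzFit | None = None
    if model in ("auto", "gompertz"):
        gf = fit_gompertz(pooled)

    use_gompertz = model == "gompertz" or (
        model == "auto"
        and gf is not None
        and gf.converged
        and gf.r_squared >= gompertz_r2_threshold
        and gf.stderr_A < gf.A
    )

    sd_A = None
    if use_gompertz and len(series_list) > 1:
        per_rep = []
        for s in series_list:
            try:
                per_rep.append(fit_gompertz(s).A)
            except (NoProductionError, ValueError):
                continue
        if len(per_rep) > 1:
            sd_A = float(np.std(per_rep, ddof=1))

    if use_gompertz:
        assert gf is not None
        return TreatmentFit(
            treatment=treatment, model="gompertz", A=gf.A, sd_A=sd_A, mu_m=gf.mu_m,
            lam=gf.lam, slope=None, r_squared=gf.r_squared, gompertz=gf, linear=lin,
        )
    return TreatmentFit(
        treatment=treatment, model="linear", A=None, sd_A=None, mu_m=None, lam=None,
        slope=lin.slope, r_squared=lin.r_squared, gompertz=gf, linear=lin,
    )


def consolidate_group(
    series_list: list[MethaneSeries], name: str = "group"
) -> tuple[MethaneSeries, np.ndarray]:
    """Pointwise mean across treatments/replicates, with the s.d. attached.

    Series on different grids are linearly interpolated onto the union of
    all sampling times (restricted to the overlap, so no extrapolation).
    Returns ``(mean_series, sd)``.
    """
    if not series_list:
        raise ValueError("cannot consolidate an empty group")
    t_lo = max(s.times.min() for s in series_list)
    t_hi = min(s.times.max() for s in series_list)
    if t_hi < t_lo:
        raise ValueError("series have no overlapping time range")
    grid = np.unique(np.concatenate([s.times for s in series_list]))
    grid = grid[(grid >= t_lo) & (grid <= t_hi)]
    mat = np.vstack([np.interp(grid, s.times, s.values) for s in series_list])
    mean = MethaneSeries(name, "mean", grid, mat.mean(axis=0))
    sd = mat.std(axis=0, ddof=1) if len(series_list) > 1 else np.zeros_like(grid)
    return mean, sd
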