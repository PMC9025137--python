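"""Gompertz shelf-life model of redness a*(t) and factor regressions.

Two-step phenomenological description, in the style of predictive
microbiology: a modified (Zwietering-parameterized) Gompertz curve captures
the three-phase kinetics of the redness coordinate a* — lag plateau,
exponential-like decay, final plateau — through four parameters (initial and
final a*, maximum rate of change μmax, lag time); log-linear regressions then
express lag and μmax as functions of the storage factors (temperature,
headspace O₂, aging time, cutting angle).

The curve is

    a*(t) = a0 + (af − a0) · exp(−exp( μmax·e·(lag − t) / ((af − a0)·c) + 1 ))

with ``c`` a configurable log₁₀ factor on the denominator (default ln 10).
With c = 1 the tangent at the inflection has slope exactly μmax; in general
the slope is μmax/c, so fitted μmax values are only comparable under a fixed
choice of c.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .colormap import ColorKinetics
from .rdsolver import StorageConditions

__all__ = [
    "LN10",
    "GompertzParams",
    "FactorRegression",
    "GompertzFitError",
    "gompertz_a",
    "lag_from_factors",
    "mumax_from_factors",
    "GompertzRegressor",
    "FactorResponseRegression",
    "fit_gompertz",
    "fit_factor_regression",
    "predict_phenom",
    "LAG_TERM_NAMES",
    "MUMAX_TERM_NAMES",
]

LN10 = math.log(10.0)

LAG_TERM_NAMES = ("1", "pO2^2", "pO2*angle", "T*pO2", "angle^2", "pO2")
MUMAX_TERM_NAMES = ("1", "pO2", "pO2^2", "aging^2", "pO2*aging", "aging*angle")


class GompertzFitError(RuntimeError):
    """Nonlinear fit did not converge; carries best-so-far parameters."""

    def __init__(self, message: str, best: "GompertzParams | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz curve parameters for one storage condition.

    ``mumax`` is the maximum rate of change of a* (negative for browning),
    in a*-units·day⁻¹ divided by the log scale c; ``lag`` is in days.
    """

    a0: float
    af: float
    mumax: float
    lag: float

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.mumax > 1e-12:
            raise ValueError("mumax must be <= 0 for browning kinetics")
        if self.af > self.a0 + 1e-9:
            raise ValueError("af must not exceed a0 for browning kinetics")


@dataclass(frozen=True)
class FactorRegression:
    """Coefficients of the lag and μmax factor regressions.

    ``b`` (length 6) acts on (1, pO2², pO2·angle, T·pO2, angle², pO2) for
    log₁₀ lag; ``c`` (length 6) on (1, pO2, pO2², aging², pO2·aging,
    aging·angle) for log₁₀(−μmax). The aging-time factor ("maturation") is
    written Mat in some sources; both spellings denote aging days here.
    """

    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)
        if b.shape != (6,) or c.shape != (6,):
            raise ValueError("b and c must each have 6 coefficients")
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(c))):
            raise ValueError("coefficients must be finite")


def gompertz_a(
    t, p: GompertzParams, log_scale: float = LN10
):
    """Evaluate the modified Gompertz curve at time ``t`` (days).

    Limits: t ≪ lag → ≈ a0 (plateau); t → ∞ → af. A degenerate curve with
    a0 = af returns the constant a0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    span = p.af - p.a0
    if span == 0.0:
        out = np.full_like(t, p.a0)
        return float(out) if out.ndim == 0 else out
    inner = p.mumax * math.e * (p.lag - t) / (span * log_scale) + 1.0
    out = p.a0 + span * np.exp(-np.exp(np.clip(inner, -700.0, 700.0)))
    return float(out) if out.ndim == 0 else out


def _lag_design(T, pO2, angle) -> np.ndarray:
    T, pO2, angle = np.broadcast_arrays(
        np.asarray(T, float), np.asarray(pO2, float), np.asarray(angle, float)
    )
    return np.stack(
        [np.ones_like(pO2), pO2**2, pO2 * angle, T * pO2, angle**2, pO2], axis=-1
    )


def _mumax_design(pO2, aging, angle) -> np.ndarray:
    pO2, aging, angle = np.broadcast_arrays(
        np.asarray(pO2, float), np.asarray(aging, float), np.asarray(angle, float)
    )
    return np.stack(
        [np.ones_like(pO2), pO2, pO2**2, aging**2, pO2 * aging, aging * angle],
        axis=-1,
    )


def lag_from_factors(reg: FactorRegression, cond: StorageConditions) -> float:
    """Lag time (days) from the log-linear factor regression."""
    x = _lag_design(cond.T_C, cond.pO2_pct, cond.angle_deg)
    return float(10.0 ** (x @ reg.b))


def mumax_from_factors(reg: FactorRegression, cond: StorageConditions) -> float:
    """μmax (negative, a*-units·day⁻¹/c) from the factor regression."""
    x = _mumax_design(cond.pO2_pct, cond.aging_d, cond.angle_deg)
    return float(-(10.0 ** (x @ reg.c)))


# -- Gompertz curve fitting ------------------------------------------------


class GompertzRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the modified Gompertz curve.

    Parameters
    ----------
    log_scale : float, default ln(10)
        The c factor on the (af − a0) denominator.
    max_nfev : int
        Budget for :func:`scipy.optimize.least_squares` (TRF with bounds
        lag ∈ [0, t_max] and μmax ≤ 0).

    Attributes (after fit)
    ----------------------
    a0_, af_, mumax_, lag_ : fitted parameters
    params_ : GompertzParams
    rss_ : residual sum of squares
    degenerate_ : True for flat input (af ≈ a0 or lag at its bound)
    """

    def __init__(self, log_scale: float = LN10, max_nfev: int = 5000):
        self.log_scale = log_scale
        self.max_nfev = max_nfev

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        a = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != a.shape:
            raise ValueError("X and y must have the same length")
        if len(t) < 8:
            raise ValueError("need at least 8 time points spanning plateau and decay")
        order = np.argsort(t)
        t, a = t[order], a[order]
        t_max = float(t[-1])
        head = max(3, len(t) // 20)
        a0g = float(np.mean(a[:head]))
        afg = float(np.mean(a[-head:]))
        if afg > a0g:
            afg = min(afg, a0g)
        # steepest-descent guess for the inflection
        if len(t) >= 16:
            k = max(1, len(t) // 100)
            slopes = (a[k:] - a[:-k]) / np.maximum(t[k:] - t[:-k], 1e-12)
        else:
            slopes = np.diff(a) / np.maximum(np.diff(t), 1e-12)
        i_min = int(np.argmin(slopes))
        slope = float(min(slopes[i_min], -1e-6))
        t_infl = float(t[i_min])
        mug = slope * self.log_scale
        lagg = float(np.clip(t_infl - (a[i_min] - a0g) / slope, 0.0, t_max))

        c = self.log_scale

        def resid(x):
            a0, af, mu, lag = x
            span = af - a0
            if abs(span) < 1e-12:
                return a0 - a
            inner = mu * math.e * (lag - t) / (span * c) + 1.0
            return a0 + span * np.exp(-np.exp(np.clip(inner, -700, 700))) - a

        scale = max(np.ptp(a), 1e-6)
        lo = [a.min() - scale, a.min() - scale, -np.inf, 0.0]
        hi = [a.max() + scale, a.max() + scale, 0.0, t_max]
        x0 = [
            np.clip(a0g, lo[0], hi[0]),
            np.clip(afg, lo[1], hi[1]),
            min(mug, -1e-9),
            lagg,
        ]
        sol = least_squares(resid, x0, bounds=(lo, hi), max_nfev=self.max_nfev)
        a0, af, mu, lag = sol.x
        af = min(af, a0)
        mu = min(mu, 0.0)
        params = GompertzParams(a0=a0, af=af, mumax=mu, lag=lag)
        if not sol.success:
            raise GompertzFitError(f"Gompertz fit did not converge: {sol.message}",
                                   best=params)
        self.params_ = params
        self.a0_, self.af_, self.mumax_, self.lag_ = a0, af, mu, lag
        self.rss_ = float(np.sum(sol.fun**2))
        self.degenerate_ = bool(
            abs(af - a0) <= 1e-6 * max(abs(a0), 1.0)
            or lag >= t_max - 1e-9
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return gompertz_a(t, self.params_, self.log_scale)


def fit_gompertz(
    obs: ColorKinetics | tuple, log_scale: float = LN10
) -> tuple[GompertzParams, dict]:
    """Fit the Gompertz curve to an observed kinetics series.

    ``obs`` is a :class:`ColorKinetics` (times in hours, fitted on the day
    scale) or a ``(t_days, a_values)`` pair. Returns the parameters and a
    diagnostics dict (rss, degenerate flag, point count).
    """
    if isinstance(obs, ColorKinetics):
        t_d, a = obs.times_d, obs.values
    else:
        t_d, a = obs
    est = GompertzRegressor(log_scale=log_scale).fit(t_d, a)
    diag = {"rss": est.rss_, "degenerate": est.degenerate_, "n_points": len(np.asarray(t_d))}
    return est.params_, diag


# -- factor regression -----------------------------------------------------


def _scaled_lstsq(X: np.ndarray, y: np.ndarray, term_names) -> np.ndarray:
    """OLS with column scaling; raises on rank deficiency naming the terms."""
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        dead = [term_names[i] for i in np.flatnonzero(norms == 0)]
        raise np.linalg.LinAlgError(f"terms identically zero over the design: {dead}")
    Xs = X / norms
    rank = np.linalg.matrix_rank(Xs, tol=1e-8)
    if rank < X.shape[1]:
        _, Rd = np.linalg.qr(Xs)
        diag = np.abs(np.diag(Rd))
        bad = [term_names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"confounded terms: {bad or 'unidentified'}"
        )
    coef, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    return coef / norms


class FactorResponseRegression(BaseEstimator):
    """OLS of log₁₀(lag) and log₁₀(−μmax) on the storage-factor term sets.

    ``fit(X, y)`` takes X with columns (T_C, pO2_pct, aging_d, angle_deg)
    and y with columns (lag_d, mumax); ``predict`` returns the same two
    columns. The exact term sets are fixed (see module docstring).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must be (n, 4): T_C, pO2_pct, aging_d, angle_deg")
        if y.shape != (X.shape[0], 2):
            raise ValueError("y must be (n, 2): lag_d, mumax")
        if len(np.unique(X, axis=0)) < 6:
            raise np.linalg.LinAlgError(
                "need at least 6 distinct conditions to identify 6 coefficients"
            )
        lag, mumax = y[:, 0], y[:, 1]
        if np.any(lag <= 0):
            raise ValueError("lag values must be positive")
        if np.any(mumax >= 0):
            raise ValueError("mumax values must be negative")
        T, pO2, aging, angle = X.T
        b = _scaled_lstsq(_lag_design(T, pO2, angle), np.log10(lag), LAG_TERM_NAMES)
        c = _scaled_lstsq(
            _mumax_design(pO2, aging, angle), np.log10(-mumax), MUMAX_TERM_NAMES
        )
        self.regression_ = FactorRegression(b=b, c=c)
        self.b_, self.c_ = self.regression_.b, self.regression_.c
        self.n_features_in_ = 4
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        T, pO2, aging, angle = X.T
        lag = 10.0 ** (_lag_design(T, pO2, angle) @ self.b_)
        mumax = -(10.0 ** (_mumax_design(pO2, aging, angle) @ self.c_))
        return np.column_stack([lag, mumax])


def fit_factor_regression(table: pd.DataFrame) -> FactorRegression:
    """Fit the factor regressions from a per-condition results table.

    ``table`` needs columns T_C, pO2_pct, aging_d, angle_deg, lag_d, mumax.
    """
    req = ["T_C", "pO2_pct", "aging_d", "angle_deg", "lag_d", "mumax"]
    missing = [c for c in req if c not in table.columns]
    if missing:
        raise ValueError(f"results table lacks columns {missing}")
    est = FactorResponseRegression().fit(
        table[req[:4]].to_numpy(), table[["lag_d", "mumax"]].to_numpy()
    )
    return est.regression_


def predict_phenom(
    reg: FactorRegression,
    cond: StorageConditions,
    a0: float,
    af: float,
    times_d: Sequence[float] | np.ndarray,
    log_scale: float = LN10,
) -> ColorKinetics:
    """Compose the factor regressions with the Gompertz curve.

    Returns the a*/a*₀ series for one storage condition.
    """
    times_d = np.asarray(times_d, dtype=float)
    p = GompertzParams(
        a0=a0,
        af=af,
        mumax=mumax_from_factors(reg, cond),
        lag=lag_from_factors(reg, cond),
    )
    values = gompertz_a(times_d, p, log_scale) / a0
    return ColorKinetics(
        times_h=times_d * 24.0,
        values=np.clip(values, 0.0, 1.0),
        condition=cond,
        source="gompertz-model",
    )
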