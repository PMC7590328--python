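"""Nonlinear least-squares estimation of growth and product parameters.

Growth parameters (A, mu_m, lam) are estimated from (t, log10 N/N0) data and
product parameters (m, n, optionally an inhibition constant) from (t, P)
data given a fitted biomass trajectory.  Both fits use bounded trust-region
least squares (scipy ``least_squares``) started from data-driven heuristics.

Growth-fit window
-----------------
Neither sigmoid can represent a death phase, so the growth fit uses the data
from t = 0 up to the last index before two consecutive viable-count
decreases of more than 10% (the onset of sustained decline); in the absence
of such a decline the whole series is used.

Identifiability
---------------
Inhibition constants (P_max, HL_inh) are poorly identified when the product
stays well below them; they are therefore fitted on a log10 scale, bounded
below by the largest observed product (or undissociated-acid) level, and a
conditioning warning is attached when doubling or halving the fitted
constant changes the residual sum of squares by a relative factor < 1e-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DataError
from .gof import GofStats, rss
from .growth import GrowthParams, log_ratio
from .product import (
    AcidEnvironment,
    BiomassTrajectory,
    ProductParams,
    integrate_product,
    undissociated_fraction,
)
from .series import FermentationSeries

__all__ = [
    "FitResult",
    "fit_growth",
    "fit_product",
    "auto_initialize_growth",
    "auto_initialize_product",
    "growth_fit_window",
]

logger = logging.getLogger(__name__)

MIN_POINTS = 5
_MAX_NFEV = 2000
_FLOOR = 1e-8


@dataclass
class FitResult:
    """One fitted model: parameters, fit statistics and predicted curve."""

    model_id: str
    params: Union[GrowthParams, ProductParams]
    gof: Optional[GofStats]
    predicted: np.ndarray
    fit_window: tuple
    converged: bool
    n_iter: int
    warnings: list = field(default_factory=list)

    @property
    def estimates(self) -> dict:
        d = self.params.as_dict()
        d.pop("model_id", None)
        d.pop("time_unit", None)
        return d

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params.as_dict(),
            "gof": self.gof.as_dict() if self.gof is not None else None,
            "predicted": np.asarray(self.predicted).tolist(),
            "fit_window": list(self.fit_window),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "warnings": list(self.warnings),
        }


def growth_fit_window(series: FermentationSeries) -> tuple[int, int]:
    """Index window (start, stop) for the growth fit, excluding decline.

    Stops before the first pair of consecutive count decreases each larger
    than 10%; returns the full range when no sustained decline occurs.
    """
    if series.cfu is None:
        raise DataError("series has no cfu channel")
    c = series.cfu
    for i in range(len(c) - 2):
        if c[i + 1] < 0.9 * c[i] and c[i + 2] < 0.9 * c[i + 1]:
            return (0, i + 1)
    return (0, len(c))


def auto_initialize_growth(
    series: FermentationSeries,
    model_id: str = "gompertz",
    window: Optional[tuple[int, int]] = None,
) -> GrowthParams:
    """Heuristic starting values (A0, mu0, lam0) from the data.

    A0 is the maximum observed log-ratio; mu0 the steepest finite-difference
    slope; lam0 the time-axis intercept of the secant at the steepest point,
    floored at zero.
    """
    i0, i1 = window if window is not None else (0, len(series))
    t = series.t[i0:i1]
    y = series.log_ratio()[i0:i1]
    if t.size < MIN_POINTS:
        raise DataError(f"need >= {MIN_POINTS} points, got {t.size}")
    if np.ptp(y) <= 0:
        raise DataError("observations are constant; growth initialization undefined")
    a0 = max(float(y.max()), _FLOOR)
    slopes = np.diff(y) / np.diff(t)
    k = int(np.argmax(slopes))
    mu0 = max(float(slopes[k]), _FLOOR)
    t_mid = 0.5 * (t[k] + t[k + 1])
    y_mid = 0.5 * (y[k] + y[k + 1])
    lam0 = max(0.0, float(t_mid - y_mid / mu0))
    return GrowthParams(model_id=model_id, A=a0, mu_m=mu0, lam=lam0,
                        time_unit=series.time_unit)


def fit_growth(
    series: FermentationSeries,
    model_id: str = "gompertz",
    window: Union[str, tuple[int, int]] = "auto",
    init: Union[str, GrowthParams] = "auto",
    bounds: Optional[tuple] = None,
) -> FitResult:
    """Fit (A, mu_m, lam) to the observed log10(N/N0) by least squares.

    Non-convergence is flagged on the result, never raised; degenerate
    (constant) data yield ``converged=False`` with the heuristic fallback.
    """
    if series.cfu is None:
        raise DataError("growth fit requires the cfu channel")
    window_warnings = []
    if window == "auto":
        win = growth_fit_window(series)
        if win[1] - win[0] < MIN_POINTS <= len(series):
            # decline detected too early (noise can mimic it); keep the
            # minimum usable window rather than refusing to fit
            win = (win[0], win[0] + MIN_POINTS)
            window_warnings.append(
                "detected decline left fewer than "
                f"{MIN_POINTS} points; window extended to the minimum"
            )
    else:
        win = tuple(window)
    i0, i1 = win
    t = series.t[i0:i1]
    y = series.log_ratio()[i0:i1]
    if t.size < MIN_POINTS:
        raise DataError(f"growth window has {t.size} points; need >= {MIN_POINTS}")

    degenerate = False
    if init == "auto":
        try:
            p0 = auto_initialize_growth(series, model_id, win)
        except DataError:
            degenerate = True
            p0 = GrowthParams(model_id, A=_FLOOR * 10, mu_m=_FLOOR * 10, lam=0.0,
                              time_unit=series.time_unit)
    else:
        p0 = init

    lo, hi = bounds if bounds is not None else ((_FLOOR, _FLOOR, 0.0),
                                                (np.inf, np.inf, np.inf))

    def resid(theta: np.ndarray) -> np.ndarray:
        p = GrowthParams(model_id, *theta, time_unit=series.time_unit)
        return log_ratio(t, p) - y

    x0 = np.array([p0.A, p0.mu_m, p0.lam])
    res = least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=_MAX_NFEV,
        x_scale=np.maximum(np.abs(x0), 1e-3),
    )
    p_hat = GrowthParams(model_id, *res.x, time_unit=series.time_unit)
    pred = log_ratio(t, p_hat)
    try:
        gof = GofStats.from_curves(y, pred, n_params=3)
    except Exception:
        gof = None
    warnings = list(window_warnings)
    if degenerate:
        warnings.append("degenerate data: observations constant, fallback init used")
    return FitResult(
        model_id=model_id,
        params=p_hat,
        gof=gof,
        predicted=pred,
        fit_window=win,
        converged=bool(res.success) and not degenerate,
        n_iter=int(res.nfev),
        warnings=warnings,
    )


def auto_initialize_product(
    series: FermentationSeries,
    growth: FitResult,
    model_id: str,
) -> ProductParams:
    """Heuristic (m0, n0, inhibition) starting values.

    m0 regresses early product increments on biomass increments; n0 is the
    late-phase product slope divided by the plateau biomass; the inhibition
    constant starts at 10x the largest observed product (or undissociated
    acid) level.  All floored at small positive values.
    """
    if series.acidity is None:
        raise DataError("product initialization requires the acidity channel")
    t = series.t
    P = series.acidity
    if t.size < MIN_POINTS:
        raise DataError(f"need >= {MIN_POINTS} points, got {t.size}")
    gp: GrowthParams = growth.params
    X = log_ratio(t, gp)
    dX = np.diff(X)
    dP = np.diff(P)
    dt = np.diff(t)
    # late phase first: last third, biomass at plateau, growth term gone
    k = max(2, t.size // 3)
    slope = float(np.polyfit(t[-k:], P[-k:], 1)[0])
    plateau = max(float(X[-1]), _FLOOR)
    n0 = max(slope / plateau, _FLOOR)
    # early phase: intervals carrying most of the biomass increase; subtract
    # the non-growth-associated contribution before regressing dP on dX
    mask = dX > 0.1 * dX.max() if dX.max() > 0 else np.zeros_like(dX, dtype=bool)
    if mask.any() and np.dot(dX[mask], dX[mask]) > 0:
        x_mid = 0.5 * (X[:-1] + X[1:])
        dP_growth = dP - n0 * x_mid * dt
        m0 = float(np.dot(dP_growth[mask], dX[mask]) / np.dot(dX[mask], dX[mask]))
    else:
        m0 = _FLOOR
    m0 = max(m0, _FLOOR)
    if model_id == "monteagudo":
        return ProductParams(model_id, m=m0, n=n0,
                             P_max=10.0 * max(float(P.max()), _FLOOR))
    if model_id == "balannec":
        if series.pH is None:
            raise DataError("balannec initialization requires the pH channel")
        hl_max = float(undissociated_fraction(P, series.pH).max())
        return ProductParams(model_id, m=m0, n=n0,
                             HL_inh=10.0 * max(hl_max, _FLOOR))
    return ProductParams(model_id, m=m0, n=n0)


def fit_product(
    series: FermentationSeries,
    growth: FitResult,
    model_id: str,
    init: Union[str, ProductParams] = "auto",
    bounds: Optional[tuple] = None,
    pKa: Optional[float] = None,
    h_max: float = 0.1,
) -> FitResult:
    """Fit a product-formation model to measured acidity over the full series.

    The biomass trajectory is the fitted growth curve (analytic value and
    rate); P(0) is pinned to the first measured acidity; for the balannec
    model the measured pH samples are interpolated piecewise-linearly.
    """
    if series.acidity is None:
        raise DataError("product fit requires the acidity channel")
    if model_id == "balannec" and series.pH is None:
        raise DataError("balannec fit requires the pH channel")
    if not growth.converged:
        raise DataError("growth fit did not converge; refusing to fit product models")
    t = series.t
    P_obs = series.acidity
    if t.size < MIN_POINTS:
        raise DataError(f"need >= {MIN_POINTS} points, got {t.size}")

    bio = BiomassTrajectory.from_growth(growth.params)
    env = None
    if model_id == "balannec":
        kw = {} if pKa is None else {"pKa": pKa}
        env = AcidEnvironment.from_series(t, series.pH, **kw)
    P0 = float(P_obs[0])

    p_init = auto_initialize_product(series, growth, model_id) if init == "auto" else init
    has_inh = model_id in ("monteagudo", "balannec")

    def unpack(theta: np.ndarray) -> ProductParams:
        m, n = theta[0], theta[1]
        if model_id == "monteagudo":
            return ProductParams(model_id, m=m, n=n, P_max=10.0 ** theta[2])
        if model_id == "balannec":
            return ProductParams(model_id, m=m, n=n, HL_inh=10.0 ** theta[2])
        return ProductParams(model_id, m=m, n=n)

    def resid(theta: np.ndarray) -> np.ndarray:
        return (
            integrate_product(unpack(theta), bio, t, P0, env=env, h_max=h_max) - P_obs
        )

    if has_inh:
        k0 = p_init.P_max if model_id == "monteagudo" else p_init.HL_inh
        if model_id == "monteagudo":
            k_floor = max(float(P_obs.max()), _FLOOR)
        else:
            k_floor = max(float(undissociated_fraction(P_obs, series.pH).max()), _FLOOR)
        x0 = np.array([p_init.m, p_init.n, np.log10(max(k0, k_floor * 1.0000001))])
        lo = (0.0, 0.0, np.log10(k_floor))
        hi = (np.inf, np.inf, 12.0)
    else:
        x0 = np.array([p_init.m, p_init.n])
        lo, hi = (0.0, 0.0), (np.inf, np.inf)
    if bounds is not None:
        lo, hi = bounds

    res = least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=_MAX_NFEV,
        x_scale=np.maximum(np.abs(x0), 1e-3),
    )
    p_hat = unpack(res.x)
    pred = integrate_product(p_hat, bio, t, P0, env=env, h_max=h_max)
    gof = GofStats.from_curves(P_obs, pred, n_params=x0.size)

    warnings = []
    if has_inh:
        base = rss(P_obs, pred)
        perturbed = []
        for fac in (0.5, 2.0):
            th = res.x.copy()
            th[2] = np.clip(th[2] + np.log10(fac), lo[2], hi[2])
            perturbed.append(rss(P_obs, resid(th) + P_obs))
        rel = max(abs(r - base) for r in perturbed) / max(base, 1e-300)
        if rel < 1e-6:
            warnings.append(
                "inhibition constant is poorly identified: RSS is flat across a "
                "2x change (relative change < 1e-6)"
            )
            logger.warning("poorly identified inhibition constant for %s", model_id)

    return FitResult(
        model_id=model_id,
        params=p_hat,
        gof=gof,
        predicted=pred,
        fit_window=(0, t.size),
        converged=bool(res.success),
        n_iter=int(res.nfev),
        warnings=warnings,
    )
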