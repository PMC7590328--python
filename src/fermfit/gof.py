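"""Goodness-of-fit statistics and the model-selection rule.

The fit-quality battery used throughout the package:

* uncentered R^2 = (sum obs*pred)^2 / (sum obs^2 * sum pred^2) — the squared
  cosine similarity of the observed and predicted vectors.  It lies in
  [0, 1] by Cauchy-Schwarz and equals 1 iff pred is proportional to obs;
  being scale-blind it cannot distinguish a proportional fit from an equal
  one, which is why the conventional R^2 is always reported alongside.
* conventional R^2 = 1 - RSS/TSS (can be negative).
* reduced chi-square = RSS / (N - n), with n the number of fitted parameters.
* RMSE = sqrt(RSS / N).
* RSS = sum of squared residuals.
* MAPE = (100/N') * sum |obs - pred| / |obs| over the N' points with
  obs != 0; zero-observation points are excluded and the exclusion count is
  logged.

Model selection ranks fits by uncentered R^2 (descending); ties within 1e-6
are broken by reduced chi-square, then RMSE, then MAPE, then RSS (all
ascending).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cmp_to_key
from typing import Sequence

import numpy as np

from .exceptions import ComparisonError, DegreesOfFreedomError, UndefinedStatisticError

__all__ = [
    "GofStats",
    "r2_uncentered",
    "r2_conventional",
    "chi2_reduced",
    "rmse",
    "rss",
    "mape",
    "select_best",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-6


def _pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise UndefinedStatisticError("obs and pred must be 1-d arrays of equal length")
    if obs.size < 2:
        raise UndefinedStatisticError("need at least 2 points")
    return obs, pred


def r2_uncentered(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    so, sp = np.dot(obs, obs), np.dot(pred, pred)
    if so == 0.0 or sp == 0.0:
        raise UndefinedStatisticError("uncentered R^2 undefined for a zero-norm vector")
    return float(np.dot(obs, pred) ** 2 / (so * sp))


def r2_conventional(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedStatisticError("conventional R^2 undefined for constant obs")
    return 1.0 - rss(obs, pred) / tss


def rss(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    return float(np.sum((obs - pred) ** 2))


def rmse(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    return float(np.sqrt(rss(obs, pred) / obs.size))


def chi2_reduced(obs, pred, n_params: int) -> float:
    obs, pred = _pair(obs, pred)
    dof = obs.size - n_params
    if dof <= 0:
        raise DegreesOfFreedomError(
            f"need N > n_params, got N={obs.size}, n_params={n_params}"
        )
    return rss(obs, pred) / dof


def mape(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    mask = obs != 0.0
    n_excluded = int((~mask).sum())
    if not mask.any():
        raise UndefinedStatisticError("MAPE undefined when every observation is zero")
    if n_excluded:
        logger.info("MAPE: excluded %d zero-observation point(s)", n_excluded)
    return float(100.0 * np.mean(np.abs((obs[mask] - pred[mask]) / obs[mask])))


@dataclass(frozen=True)
class GofStats:
    """The full fit-quality battery for one (obs, pred) pair."""

    r2_uncentered: float
    r2_conventional: float
    chi2_reduced: float
    rmse: float
    rss: float
    mape: float
    n_points: int
    n_params: int

    @classmethod
    def from_curves(cls, obs, pred, n_params: int) -> "GofStats":
        obs, pred = _pair(obs, pred)
        try:
            r2c = r2_conventional(obs, pred)
        except UndefinedStatisticError:
            r2c = float("nan")
        try:
            mp = mape(obs, pred)
        except UndefinedStatisticError:
            mp = float("nan")
        return cls(
            r2_uncentered=r2_uncentered(obs, pred),
            r2_conventional=r2c,
            chi2_reduced=chi2_reduced(obs, pred, n_params),
            rmse=rmse(obs, pred),
            rss=rss(obs, pred),
            mape=mp,
            n_points=int(obs.size),
            n_params=int(n_params),
        )

    def as_dict(self) -> dict:
        return {
            "r2_uncentered": self.r2_uncentered,
            "r2_conventional": self.r2_conventional,
            "chi2_reduced": self.chi2_reduced,
            "rmse": self.rmse,
            "rss": self.rss,
            "mape": self.mape,
            "n_points": self.n_points,
            "n_params": self.n_params,
        }


def _rank_cmp(f, g) -> int:
    a, b = f.gof, g.gof
    if abs(a.r2_uncentered - b.r2_uncentered) > _TIE_TOL:
        return -1 if a.r2_uncentered > b.r2_uncentered else 1
    for attr in ("chi2_reduced", "rmse", "mape", "rss"):
        x, y = getattr(a, attr), getattr(b, attr)
        if np.isnan(x) and np.isnan(y):
            continue
        if abs(x - y) > _TIE_TOL:
            return -1 if x < y else 1
    return 0


def select_best(fits: Sequence) -> list:
    """Rank fits, best first, by the ordered goodness-of-fit criteria.

    All fits must cover the same data window; a stable sort preserves input
    order on exact ties.
    """
    fits = list(fits)
    if len(fits) < 2:
        return fits
    windows = {tuple(f.fit_window) for f in fits}
    if len(windows) > 1:
        raise ComparisonError(f"fits cover different data windows: {sorted(windows)}")
    return sorted(fits, key=cmp_to_key(_rank_cmp))
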