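"""Primary sigmoidal growth models on the log10(N/N0) scale.

Two classical predictive-microbiology forms are provided, both in the
Zwietering reparameterization in which the three parameters are directly
interpretable from a growth curve:

* ``A`` — asymptotic log10 increase of the population (the upper plateau of
  log10(N/N0)),
* ``mu_m`` — maximum specific growth rate, the literal maximum slope of
  log10(N/N0) versus time (1/time),
* ``lam`` — lag period, the time-axis intercept of the tangent at the point
  of maximum slope (time).

Modified Gompertz:  y(t) = A * exp(-exp((mu_m * e / A) * (lam - t) + 1))
Logistic:           y(t) = A / (1 + exp(2 + (4 * mu_m / A) * (lam - t)))

Both functions are strictly increasing from 0 to A, and both analytic time
derivatives attain their global maximum mu_m at the inflection point.  The
time unit is carried as metadata on the parameter set (hours by default) and
is never hard-coded into the mathematics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DomainError

__all__ = [
    "GrowthParams",
    "gompertz_log_ratio",
    "gompertz_rate",
    "logistic_log_ratio",
    "logistic_rate",
    "log_ratio",
    "growth_rate",
    "GROWTH_MODEL_IDS",
]

GROWTH_MODEL_IDS = ("gompertz", "logistic")

# Clamp on exponent arguments: exp(+-700) is the edge of double range.
_EXP_CLAMP = 700.0
_E = float(np.e)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of a named sigmoidal growth model.

    Attributes
    ----------
    model_id:
        ``"gompertz"`` or ``"logistic"``.
    A:
        Asymptotic log10 population increase, dimensionless, > 0.
    mu_m:
        Maximum specific growth rate, 1/``time_unit``, > 0.
    lam:
        Lag period, in ``time_unit``, >= 0.
    time_unit:
        Unit of the time axis the parameters refer to (metadata only).
    """

    model_id: str
    A: float
    mu_m: float
    lam: float
    time_unit: str = "hr"

    def __post_init__(self) -> None:
        if self.model_id not in GROWTH_MODEL_IDS:
            raise DomainError(
                f"model_id must be one of {GROWTH_MODEL_IDS}, got {self.model_id!r}"
            )
        for name in ("A", "mu_m", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v!r}")
        if self.A <= 0:
            raise DomainError(f"A must be > 0, got {self.A}")
        if self.mu_m <= 0:
            raise DomainError(f"mu_m must be > 0, got {self.mu_m}")
        if self.lam < 0:
            raise DomainError(f"lam must be >= 0, got {self.lam}")

    def with_lag(self, lam: float) -> "GrowthParams":
        return replace(self, lam=lam)

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "A": self.A,
            "mu_m": self.mu_m,
            "lam": self.lam,
            "time_unit": self.time_unit,
        }


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DomainError("t must be finite")
    return t


def _require(p: GrowthParams, model_id: str) -> None:
    if p.model_id != model_id:
        raise DomainError(f"params are for {p.model_id!r}, expected {model_id!r}")


def gompertz_log_ratio(t, p: GrowthParams):
    """Modified Gompertz log10(N/N0) at time(s) ``t``. Negative t is allowed."""
    t = _check_time(t)
    _require(p, "gompertz")
    u = (p.mu_m * _E / p.A) * (p.lam - t) + 1.0
    u = np.clip(u, -_EXP_CLAMP, _EXP_CLAMP)
    # exp(u) <= 1e304 after the clamp; exp(-exp(u)) then underflows cleanly
    return p.A * np.exp(-np.exp(u))


def gompertz_rate(t, p: GrowthParams):
    """Analytic d/dt of :func:`gompertz_log_ratio`; maximum over t equals mu_m."""
    t = _check_time(t)
    _require(p, "gompertz")
    u = (p.mu_m * _E / p.A) * (p.lam - t) + 1.0
    u = np.clip(u, -_EXP_CLAMP, _EXP_CLAMP)
    # dy/dt = A * exp(-e^u) * e^u * (mu_m e / A); written as exp(u - e^u) for stability
    return p.mu_m * _E * np.exp(u - np.exp(u))


def logistic_log_ratio(t, p: GrowthParams):
    """Logistic log10(N/N0) at time(s) ``t``. y(lam) = A / (1 + e^2)."""
    t = _check_time(t)
    _require(p, "logistic")
    s = 2.0 + (4.0 * p.mu_m / p.A) * (p.lam - t)
    s = np.clip(s, -_EXP_CLAMP, _EXP_CLAMP)
    return p.A / (1.0 + np.exp(s))


def logistic_rate(t, p: GrowthParams):
    """Analytic d/dt of :func:`logistic_log_ratio`; maximum over t equals mu_m."""
    t = _check_time(t)
    _require(p, "logistic")
    s = 2.0 + (4.0 * p.mu_m / p.A) * (p.lam - t)
    s = np.clip(s, -_EXP_CLAMP, _EXP_CLAMP)
    sig = 1.0 / (1.0 + np.exp(s))
    return 4.0 * p.mu_m * sig * (1.0 - sig)


_VALUE = {"gompertz": gompertz_log_ratio, "logistic": logistic_log_ratio}
_RATE = {"gompertz": gompertz_rate, "logistic": logistic_rate}


def log_ratio(t, p: GrowthParams):
    """Dispatch to the value function named by ``p.model_id``."""
    return _VALUE[p.model_id](t, p)


def growth_rate(t, p: GrowthParams):
    """Dispatch to the analytic rate function named by ``p.model_id``."""
    return _RATE[p.model_id](t, p)
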