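"""Lactic-acid production kinetics coupled to a biomass trajectory.

Three rate laws of the Luedeking-Piret family relate the product formation
rate dP/dt (g/L per unit time) to the biomass curve X(t), here the relative
cell population log10(N/N0) from a fitted growth model:

* Luedeking-Piret:      dP/dt = m dX/dt + n X
* Monteagudo et al.:    dP/dt = m dX/dt + n X (1 - P / P_max)
* Balannec et al.:      dP/dt = m dX/dt + n X (1 - [HL] / HL_inh)

``m`` is the growth-associated coefficient (product formed per unit increase
in X) and ``n`` the non-growth-associated coefficient (rate per unit X).
The Monteagudo form shuts the non-growth term down as total product
approaches the inhibitory concentration P_max; the Balannec form uses the
undissociated acid [HL] instead, obtained from total acid and pH by the
Henderson-Hasselbalch partition [HL] = P / (1 + 10^(pH - pKa)) with
pKa = 3.86 for lactic acid by default.

Concentration-versus-time curves are produced by a deterministic fixed-step
classical RK4 integration (the right-hand sides are smooth and non-stiff);
the internal step is min(0.1 time-unit, grid spacing / 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .exceptions import DataError, DomainError
from .growth import GrowthParams, growth_rate, log_ratio

__all__ = [
    "ProductParams",
    "BiomassTrajectory",
    "AcidEnvironment",
    "luedeking_piret_rate",
    "monteagudo_rate",
    "balannec_rate",
    "undissociated_fraction",
    "integrate_product",
    "integrate_to_plateau",
    "PRODUCT_MODEL_IDS",
    "LACTIC_PKA",
]

PRODUCT_MODEL_IDS = ("luedeking_piret", "monteagudo", "balannec")

#: pKa of lactic acid at 25 C
LACTIC_PKA = 3.86


@dataclass(frozen=True)
class ProductParams:
    """Parameters of a named product-formation model.

    Exactly the fields demanded by ``model_id`` must be set: ``P_max`` only
    for ``monteagudo``, ``HL_inh`` only for ``balannec``.
    """

    model_id: str
    m: float
    n: float
    P_max: Optional[float] = None
    HL_inh: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_id not in PRODUCT_MODEL_IDS:
            raise DomainError(
                f"model_id must be one of {PRODUCT_MODEL_IDS}, got {self.model_id!r}"
            )
        if not np.isfinite(self.m) or self.m < 0:
            raise DomainError(f"m must be >= 0 and finite, got {self.m!r}")
        if not np.isfinite(self.n) or self.n < 0:
            raise DomainError(f"n must be >= 0 and finite, got {self.n!r}")
        if self.model_id == "monteagudo":
            if self.P_max is None or not np.isfinite(self.P_max) or self.P_max <= 0:
                raise DomainError("P_max must be > 0 for the monteagudo model")
            if self.HL_inh is not None:
                raise DomainError("HL_inh is not a monteagudo parameter")
        elif self.model_id == "balannec":
            if self.HL_inh is None or not np.isfinite(self.HL_inh) or self.HL_inh <= 0:
                raise DomainError("HL_inh must be > 0 for the balannec model")
            if self.P_max is not None:
                raise DomainError("P_max is not a balannec parameter")
        else:
            if self.P_max is not None or self.HL_inh is not None:
                raise DomainError(
                    "luedeking_piret takes no inhibition constant (P_max/HL_inh)"
                )

    def as_dict(self) -> dict:
        d = {"model_id": self.model_id, "m": self.m, "n": self.n}
        if self.P_max is not None:
            d["P_max"] = self.P_max
        if self.HL_inh is not None:
            d["HL_inh"] = self.HL_inh
        return d


@dataclass(frozen=True)
class BiomassTrajectory:
    """A biomass curve as a (value, rate) pair of callables over time.

    ``value`` returns the relative cell population X = log10(N/N0) and
    ``rate`` its time derivative; both accept scalars or arrays.
    """

    value: Callable[[np.ndarray], np.ndarray]
    rate: Callable[[np.ndarray], np.ndarray]
    provenance: str = "unknown"

    @classmethod
    def from_growth(cls, p: GrowthParams) -> "BiomassTrajectory":
        """Exact trajectory from fitted growth parameters (analytic rate)."""
        return cls(
            value=lambda t: log_ratio(t, p),
            rate=lambda t: growth_rate(t, p),
            provenance=f"growth:{p.model_id}",
        )

    @classmethod
    def from_series(cls, t: Sequence[float], x: Sequence[float]) -> "BiomassTrajectory":
        """Monotone cubic (PCHIP) interpolation of a tabulated X(t) series."""
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        if t.size != x.size or t.size < 2:
            raise DataError("need matching t and x arrays with at least 2 points")
        interp = PchipInterpolator(t, x, extrapolate=True)
        return cls(value=interp, rate=interp.derivative(), provenance="series")

    @classmethod
    def constant(cls, x: float) -> "BiomassTrajectory":
        """Stationary-phase trajectory: X fixed, dX/dt = 0."""
        return cls(
            value=lambda t: np.full_like(np.asarray(t, dtype=float), float(x)),
            rate=lambda t: np.zeros_like(np.asarray(t, dtype=float)),
            provenance=f"constant:{x}",
        )


@dataclass(frozen=True)
class AcidEnvironment:
    """pH(t) callable plus the acid dissociation constant pKa."""

    pH: Callable[[np.ndarray], np.ndarray]
    pKa: float = LACTIC_PKA

    @classmethod
    def from_series(
        cls, t: Sequence[float], ph: Sequence[float], pKa: float = LACTIC_PKA
    ) -> "AcidEnvironment":
        """Piecewise-linear interpolation of measured pH, clamped at the ends."""
        t = np.asarray(t, dtype=float)
        ph = np.asarray(ph, dtype=float)
        if t.size != ph.size or t.size < 2:
            raise DataError("need matching t and pH arrays with at least 2 points")
        if np.any(ph <= 0) or np.any(ph >= 14):
            raise DomainError("pH values must lie in (0, 14)")
        return cls(pH=lambda tq: np.interp(tq, t, ph), pKa=pKa)


def _check_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise DomainError("X must be >= 0")
    return X


def luedeking_piret_rate(X, dXdt, p: ProductParams):
    """dP/dt = m dX/dt + n X."""
    X = _check_X(X)
    return p.m * np.asarray(dXdt, dtype=float) + p.n * X


def monteagudo_rate(X, dXdt, P, p: ProductParams):
    """dP/dt = m dX/dt + n X (1 - P/P_max); total-product inhibition."""
    X = _check_X(X)
    if p.model_id != "monteagudo":
        raise DomainError(f"params are for {p.model_id!r}, expected 'monteagudo'")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > p.P_max):
        raise DomainError(f"P must lie in [0, P_max={p.P_max}]")
    return p.m * np.asarray(dXdt, dtype=float) + p.n * X * (1.0 - P / p.P_max)


def balannec_rate(X, dXdt, HL, p: ProductParams):
    """dP/dt = m dX/dt + n X (1 - [HL]/HL_inh); undissociated-acid inhibition."""
    X = _check_X(X)
    if p.model_id != "balannec":
        raise DomainError(f"params are for {p.model_id!r}, expected 'balannec'")
    HL = np.asarray(HL, dtype=float)
    if np.any(HL < 0) or np.any(HL > p.HL_inh):
        raise DomainError(f"HL must lie in [0, HL_inh={p.HL_inh}]")
    return p.m * np.asarray(dXdt, dtype=float) + p.n * X * (1.0 - HL / p.HL_inh)


def undissociated_fraction(P_total, pH, pKa: float = LACTIC_PKA):
    """Undissociated acid [HL] from total acid and pH (Henderson-Hasselbalch).

    [HL] = P_total / (1 + 10^(pH - pKa)); monotone decreasing in pH and
    bounded by 0 <= [HL] <= P_total.
    """
    P_total = np.asarray(P_total, dtype=float)
    if np.any(P_total < 0):
        raise DomainError("P_total must be >= 0")
    return P_total / (1.0 + np.power(10.0, np.asarray(pH, dtype=float) - pKa))


def _fine_grid(t_grid: np.ndarray, h_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Refine the sample grid; returns (nodes, index of each sample in nodes)."""
    nodes = [np.array([t_grid[0]])]
    idx = np.empty(t_grid.size, dtype=int)
    idx[0] = 0
    count = 0
    for i in range(t_grid.size - 1):
        t0, t1 = t_grid[i], t_grid[i + 1]
        dt = t1 - t0
        h = min(h_max, dt / 10.0)
        n_sub = max(1, math.ceil(dt / h - 1e-12))
        nodes.append(t0 + dt * np.arange(1, n_sub + 1) / n_sub)
        count += n_sub
        idx[i + 1] = count
    return np.concatenate(nodes), idx


def integrate_product(
    p: ProductParams,
    bio: BiomassTrajectory,
    t_grid,
    P0: float,
    env: Optional[AcidEnvironment] = None,
    h_max: float = 0.1,
) -> np.ndarray:
    """Integrate a product-formation rate law over a biomass trajectory.

    Parameters
    ----------
    p, bio:
        Rate-law parameters and the biomass curve supplying X and dX/dt.
    t_grid:
        Strictly increasing sample times; the returned P is evaluated there.
    P0:
        Initial product concentration (g/L) at ``t_grid[0]``.
    env:
        Acid environment (pH curve + pKa); required iff ``p`` is the
        balannec model, ignored otherwise.
    h_max:
        Upper bound on the internal RK4 step (time units).

    Near the inhibition boundary the bracketed term is floored at zero so
    rounding can never drive the rate negative.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise DataError("t_grid must be strictly increasing with >= 2 points")
    if not np.isfinite(P0) or P0 < 0:
        raise DomainError(f"P0 must be >= 0, got {P0!r}")
    if p.model_id == "balannec" and env is None:
        raise DataError("the balannec model requires an AcidEnvironment")

    T, sample_idx = _fine_grid(t_grid, h_max)
    mids = 0.5 * (T[:-1] + T[1:])
    h = np.diff(T)

    Xn = np.asarray(bio.value(T), dtype=float)
    dXn = np.asarray(bio.rate(T), dtype=float)
    Xm = np.asarray(bio.value(mids), dtype=float)
    dXm = np.asarray(bio.rate(mids), dtype=float)
    if np.any(Xn < 0) or np.any(Xm < 0):
        raise DomainError("biomass trajectory produced negative X")

    m, n = p.m, p.n
    model = p.model_id
    if model == "balannec":
        # fraction of total acid that is undissociated, at nodes and midpoints
        fn = 1.0 / (1.0 + np.power(10.0, np.asarray(env.pH(T), dtype=float) - env.pKa))
        fm = 1.0 / (
            1.0 + np.power(10.0, np.asarray(env.pH(mids), dtype=float) - env.pKa)
        )
        K = p.HL_inh
    elif model == "monteagudo":
        K = p.P_max

    out = np.empty(t_grid.size, dtype=float)
    out[0] = P = float(P0)
    j_out = 1
    for j in range(T.size - 1):
        hj = h[j]
        if model == "luedeking_piret":
            k1 = m * dXn[j] + n * Xn[j]
            k23 = m * dXm[j] + n * Xm[j]
            k2 = k3 = k23
            k4 = m * dXn[j + 1] + n * Xn[j + 1]
        elif model == "monteagudo":
            k1 = m * dXn[j] + n * Xn[j] * max(0.0, 1.0 - P / K)
            k2 = m * dXm[j] + n * Xm[j] * max(0.0, 1.0 - (P + 0.5 * hj * k1) / K)
            k3 = m * dXm[j] + n * Xm[j] * max(0.0, 1.0 - (P + 0.5 * hj * k2) / K)
            k4 = m * dXn[j + 1] + n * Xn[j + 1] * max(
                0.0, 1.0 - (P + hj * k3) / K
            )
        else:  # balannec
            k1 = m * dXn[j] + n * Xn[j] * max(0.0, 1.0 - P * fn[j] / K)
            k2 = m * dXm[j] + n * Xm[j] * max(
                0.0, 1.0 - (P + 0.5 * hj * k1) * fm[j] / K
            )
            k3 = m * dXm[j] + n * Xm[j] * max(
                0.0, 1.0 - (P + 0.5 * hj * k2) * fm[j] / K
            )
            k4 = m * dXn[j + 1] + n * Xn[j + 1] * max(
                0.0, 1.0 - (P + hj * k3) * fn[j + 1] / K
            )
        P += hj / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if model == "monteagudo" and P > K:
            P = K
        if j + 1 == sample_idx[j_out]:
            out[j_out] = P
            j_out += 1
    return out


def integrate_to_plateau(
    p: ProductParams,
    X: float,
    P0: float = 0.0,
    rate_tol: float = 1e-9,
    h: float = 1.0,
    t_max: float = 1e7,
) -> float:
    """Long-horizon limit of an inhibited rate law at constant biomass.

    Holds X fixed (dX/dt = 0) and steps the ODE with RK4 until the
    production rate falls below ``rate_tol`` (g/L per time unit); returns
    the limiting concentration.  For the monteagudo model this approaches
    P_max; only inhibited models have a finite plateau.
    """
    if p.model_id == "luedeking_piret" and p.n * X > rate_tol:
        raise DomainError("luedeking_piret has no finite plateau at constant X > 0")
    X = float(X)
    if X < 0:
        raise DomainError("X must be >= 0")

    if p.model_id == "monteagudo":
        def rate(P: float) -> float:
            return p.n * X * max(0.0, 1.0 - P / p.P_max)
    elif p.model_id == "balannec":
        # constant-environment plateau: treats all acid as undissociated
        def rate(P: float) -> float:
            return p.n * X * max(0.0, 1.0 - P / p.HL_inh)
    else:
        def rate(P: float) -> float:
            return p.n * X

    P = float(P0)
    t = 0.0
    while rate(P) > rate_tol:
        if t > t_max:
            raise DataError(f"no plateau reached by t_max={t_max}")
        k1 = rate(P)
        k2 = rate(P + 0.5 * h * k1)
        k3 = rate(P + 0.5 * h * k2)
        k4 = rate(P + h * k3)
        P += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return P
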