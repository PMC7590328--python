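"""Seeded generator of gundruk-like fermentation trajectories.

The generator produces the statistical structure the analysis assumes —
sigmoidal LAB growth on the log10 scale, product accumulation obeying one of
the rate laws, pH falling with acid production — so the whole
simulate -> fit pipeline can be exercised without external data.

Structure of a noiseless run (shared code paths with the analysis modules,
so the noiseless generator + fitter is an exact round trip):

* counts: cfu(t) = N0 * 10^(X(t) - D(t)) where X is the growth model curve
  and D an optional post-peak log-linear decline (death phase).  The
  decline exists to exercise the growth-fit window rule and is never part
  of the fitted model.
* acidity: P(t) from :func:`fermfit.product.integrate_product` with the
  configured product model over the growth curve.
* pH: exponential saturation coupled to produced acid,
  pH(t) = pH_min + (pH0 - pH_min) * exp(-k * (P(t) - P0)), plus an optional
  slow late rise, clipped to [pH_min, pH0].

Noise: multiplicative lognormal on counts (plate-count error structure),
additive Gaussian on acidity and pH.  Everything is deterministic given the
config seed.

The default scenario (:func:`gundruk_scenario`) emulates a 16-day
spontaneous mustard-leaf (gundruk) fermentation sampled every 24 h: counts
rising from 6.03e4 cfu/g to ~9.5e8 cfu/g by day 3, declining to a ~6.3e7
plateau after day 8; titratable acidity rising from 0.95 g/L to ~12 g/L by
day 12 and then nearly constant; pH falling from 6.59 towards 3.71 by day 9
and rising slightly afterwards.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import DataError, DomainError
from .growth import GrowthParams, log_ratio
from .product import (
    AcidEnvironment,
    BiomassTrajectory,
    ProductParams,
    integrate_product,
)
from .series import FermentationSeries

__all__ = [
    "DeclineConfig",
    "PHCurve",
    "NoiseSpec",
    "SamplingConfig",
    "SimConfig",
    "simulate",
    "gundruk_scenario",
    "replicate_batch",
]


@dataclass(frozen=True)
class DeclineConfig:
    """Post-peak log-linear death phase: log10 counts fall by
    ``rate * (t - start_hr)`` after ``start_hr``, capped at ``max_drop``."""

    start_hr: float
    rate: float  # log10 units per hour
    max_drop: float  # log10 units

    def __post_init__(self) -> None:
        if self.rate < 0 or self.max_drop < 0:
            raise DomainError("decline rate and max_drop must be >= 0")

    def drop(self, t: np.ndarray) -> np.ndarray:
        return np.clip(self.rate * (np.asarray(t, float) - self.start_hr),
                       0.0, self.max_drop)


@dataclass(frozen=True)
class PHCurve:
    """Exponential-saturation pH-acid coupling with an optional late rise."""

    pH0: float = 6.59
    pH_min: float = 3.71
    k: float = 0.5  # per (g/L) of produced acid
    late_rise: float = 0.0  # pH units added linearly after rise_start_hr
    rise_start_hr: float = 216.0

    def __post_init__(self) -> None:
        if not (0 < self.pH_min < self.pH0 < 14):
            raise DomainError("require 0 < pH_min < pH0 < 14")
        if self.k < 0 or self.late_rise < 0:
            raise DomainError("k and late_rise must be >= 0")

    def evaluate(self, t: np.ndarray, P: np.ndarray, P0: float,
                 t_end: float) -> np.ndarray:
        ph = self.pH_min + (self.pH0 - self.pH_min) * np.exp(
            -self.k * (np.asarray(P, float) - P0)
        )
        if self.late_rise > 0 and t_end > self.rise_start_hr:
            ramp = np.clip(
                (np.asarray(t, float) - self.rise_start_hr)
                / (t_end - self.rise_start_hr),
                0.0, 1.0,
            )
            ph = ph + self.late_rise * ramp
        return np.clip(ph, self.pH_min, self.pH0)


@dataclass(frozen=True)
class NoiseSpec:
    """Channel noise: lognormal CV on counts, additive Gaussian elsewhere."""

    count_cv: float = 0.0
    acid_sd: float = 0.0  # g/L
    pH_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("count_cv", "acid_sd", "pH_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SamplingConfig:
    t_start: float = 0.0
    t_end: float = 384.0  # 16 days
    interval: float = 24.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise DomainError("interval must be > 0")
        if self.t_end <= self.t_start:
            raise DomainError("t_end must exceed t_start")

    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.interval))
        return self.t_start + self.interval * np.arange(n + 1)


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic fermentation experiment."""

    growth: GrowthParams
    product: ProductParams
    N0: float = 6.03e4  # cfu/g
    P0: float = 0.95  # g/L
    decline: Optional[DeclineConfig] = None
    pH_curve: PHCurve = field(default_factory=PHCurve)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise DomainError("N0 must be > 0")
        if self.P0 < 0:
            raise DomainError("P0 must be >= 0")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["growth"] = self.growth.as_dict()
        d["product"] = self.product.as_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        try:
            growth = GrowthParams(**d.pop("growth"))
            product = ProductParams(**d.pop("product"))
            decline = d.pop("decline", None)
            return cls(
                growth=growth,
                product=product,
                decline=DeclineConfig(**decline) if decline else None,
                pH_curve=PHCurve(**d.pop("pH_curve", {})),
                sampling=SamplingConfig(**d.pop("sampling", {})),
                noise=NoiseSpec(**d.pop("noise", {})),
                **d,
            )
        except TypeError as exc:
            raise DataError(f"invalid simulation config: {exc}") from exc


def gundruk_scenario() -> SimConfig:
    """Default gundruk-like scenario (noiseless trajectory endpoints match
    the observed fermentation: see module docstring)."""
    return SimConfig(
        growth=GrowthParams("gompertz", A=4.1997, mu_m=0.19, lam=13.0),
        product=ProductParams("monteagudo", m=0.1104, n=0.035, P_max=12.5),
        N0=6.03e4,
        P0=0.95,
        decline=DeclineConfig(start_hr=120.0, rate=0.0164, max_drop=1.18),
        pH_curve=PHCurve(pH0=6.59, pH_min=3.71, k=0.5, late_rise=0.08,
                         rise_start_hr=216.0),
        sampling=SamplingConfig(0.0, 384.0, 24.0),
        noise=NoiseSpec(count_cv=0.10, acid_sd=0.2, pH_sd=0.05),
        seed=0,
    )


def _noiseless(config: SimConfig) -> tuple[np.ndarray, ...]:
    t = config.sampling.grid()
    X = log_ratio(t, config.growth)
    bio = BiomassTrajectory.from_growth(config.growth)
    t_end = float(t[-1])

    if config.product.model_id == "balannec":
        # pH depends on P which depends on pH: resolve by fixed-point
        # iteration from the uninhibited curve (weak coupling, converges fast)
        P = integrate_product(
            ProductParams("luedeking_piret", m=config.product.m, n=config.product.n),
            bio, t, config.P0,
        )
        for _ in range(3):
            ph = config.pH_curve.evaluate(t, P, config.P0, t_end)
            env = AcidEnvironment.from_series(t, ph)
            P = integrate_product(config.product, bio, t, config.P0, env=env)
    else:
        P = integrate_product(config.product, bio, t, config.P0)
    ph = config.pH_curve.evaluate(t, P, config.P0, t_end)

    log_counts = np.log10(config.N0) + X
    if config.decline is not None:
        log_counts = log_counts - config.decline.drop(t)
    return t, 10.0 ** log_counts, P, ph


def simulate(config: SimConfig) -> FermentationSeries:
    """Generate one fermentation series; deterministic given ``config.seed``.

    With all noise terms zero and no decline, the cfu channel is exactly
    ``N0 * 10^X(t)`` and the acidity channel is bit-identical to
    :func:`fermfit.product.integrate_product` at the sample times.
    """
    t, cfu, P, ph = _noiseless(config)
    rng = np.random.default_rng(config.seed)
    noise = config.noise
    if noise.count_cv > 0:
        sigma = np.sqrt(np.log1p(noise.count_cv**2))
        cfu = cfu * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.size)
    if noise.acid_sd > 0:
        P = np.maximum(P + rng.normal(0.0, noise.acid_sd, size=t.size), 0.0)
    if noise.pH_sd > 0:
        ph = np.clip(ph + rng.normal(0.0, noise.pH_sd, size=t.size), 0.01, 13.99)
    return FermentationSeries(t=t, cfu=cfu, acidity=P, pH=ph, N0=config.N0)


def replicate_batch(
    config: SimConfig, n_reps: int, base_seed: int
) -> list[FermentationSeries]:
    """n_reps independent series with seeds base_seed, base_seed+1, ..."""
    if n_reps < 0:
        raise DataError("n_reps must be >= 0")
    return [simulate(replace(config, seed=base_seed + i)) for i in range(n_reps)]
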