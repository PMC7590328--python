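# Methods

## Growth models and their parameterization

Both primary growth models act on the response `X(t) = log10(N(t)/N0)`,
the log-ratio of viable counts to the initial population — never on raw
cfu. The Zwietering parameterization is used throughout, so the three
parameters have direct curve meaning: `A` (dimensionless) is the upper
plateau of the log-ratio, `mu_m` (1/time) is the literal maximum slope,
and `lambda` (time) is the time-axis intercept of the tangent through the
inflection point. The modified Gompertz form is

    X(t) = A exp(−exp((mu_m e / A)(lambda − t) + 1)),

which contains Euler's `e` so that `max_t dX/dt = mu_m` exactly; some
renderings of this equation omit the factor, but without it `mu_m` loses
its maximum-slope meaning and the logistic companion form (which encodes
the same convention through its `2 + 4 mu_m/A` argument) would be
inconsistent. The time unit is metadata on the parameter set (hours by
default) and is never assumed by the mathematics.

Numerics: the inner exponent is clamped to ±700 before exponentiation, the
edge of double range. Beyond the clamp the value saturates cleanly at 0 or
`A` (and the rate underflows to 0), so both functions are monotone
non-decreasing over the entire float line and strictly increasing wherever
the value is representable.

## Product-formation models

The three rate laws of the Luedeking–Piret family (see README) take as
biomass input the *relative cell population* — the fitted growth curve
`X(t)` with its analytic derivative, not raw counts and not a dry-mass
concentration. This keeps the product models on exactly the scale the
growth fit estimates and makes `m` "g/L of acid per log10-unit of
population increase" and `n` "g/L/hr per log10-unit of population".

The undissociated-acid fraction for the Balannec model uses the
monoprotic Henderson–Hasselbalch partition with pKa 3.86 (lactic acid,
25 °C), configurable. During fitting, pH(t) is the piecewise-linear
interpolation of the measured pH samples — the simplest choice that adds
no parameters.

Integration is classical fixed-step RK4 with internal step
`min(0.1 hr, grid-spacing/10)`. The right-hand sides are smooth and
non-stiff, so RK4 at this step is converged far below measurement
resolution (halving the step moves a 720-hr endpoint by < 1e-8 g/L, and
the curve agrees with a tight-tolerance adaptive Runge–Kutta reference to
< 1e-7 g/L); a fixed step also makes results bit-reproducible, which the
tests rely on. At the inhibition boundary the bracketed term is floored at
zero so rounding can never drive the rate negative, and Monteagudo
trajectories are capped at `P_max`.

## Estimation

Both fits minimize the residual sum of squares with scipy's bounded
trust-region `least_squares` (all parameters bounded below by zero,
cost/step/gradient tolerances 1e-12–1e-13, at most 2000 function
evaluations). Non-convergence is flagged on the result, never raised.

Starting values are data-driven: for growth, `A0` is the largest observed
log-ratio, `mu0` the steepest secant slope (which bounds the maximum
tangent slope from below on sigmoid data), and `lambda0` the time-axis
intercept of that secant, floored at zero. For product models, `n0` comes
first from the late-phase acidity slope divided by the plateau biomass;
`m0` then regresses the early acid increments — after subtracting the
estimated non-growth contribution `n0·X·dt` — on the biomass increments;
the inhibition constant starts at 10× the largest observed product (or
undissociated-acid) level.

**Growth-fit window.** Neither sigmoid can represent a death phase, so the
growth fit stops before the first pair of consecutive viable-count drops
each exceeding 10% (the onset of sustained decline); absent such a pattern
the full series is used. Because plate-count noise can mimic this pattern
on a plateau, a detected decline that would leave fewer than the 5 points
required for a 3-parameter fit is overridden: the window is extended to
the 5-point minimum and a warning is attached.

**Identifiability.** When the product stays well below the inhibition
threshold, `P_max`/`HL_inh` is nearly unidentifiable (the model degenerates
to plain Luedeking–Piret). Mitigations: the constant is fitted on a log10
scale, bounded below by the largest observed product (or undissociated
acid) level and above at 1e12; and a conditioning warning is attached when
halving or doubling the fitted constant changes the RSS by a relative
factor below 1e-6.

**Response baseline.** A series may carry an explicit `N0`. Model-generated
counts start at `N0·10^X(0)` with `X(0)` small but nonzero (for the
logistic, `X(0) = A/(1 + e^(2 + 4 mu_m lambda / A))` is not negligible);
re-baselining to the first *observed* count would shift the response out
of the model family. Generated data therefore record the true baseline,
while measured CSVs, which have no baseline column, default to the first
count — the convention a plate-count experiment implies.

## Goodness of fit and selection

Six statistics are computed per fit: uncentered R², conventional R²
(1 − RSS/TSS), reduced χ² (RSS/(N−n)), RMSE, RSS, and MAPE (standard
percentage form; zero-observation points are excluded with a logged
count). Selection ranks by uncentered R² descending with ties within 1e-6
broken by χ², RMSE, MAPE, then RSS ascending, and refuses to compare fits
on different data windows. The uncentered R² is scale-blind (any curve
proportional to the data scores 1), which is why the conventional R² is
always reported next to it.

## Synthetic-data generator

The generator emulates a 16-day spontaneous mustard-leaf fermentation at
ambient temperature, sampled every 24 h. The default scenario pins the
noiseless trajectory to the endpoints such fermentations show: initial LAB
load 6.03×10⁴ cfu/g rising ~4.2 log10 units by day 3 (`A = 4.1997`,
`mu_m = 0.19 hr⁻¹`, `lambda = 13 hr`), a death phase after day 5 declining
log-linearly to a plateau ~1.18 log10 below the peak (≈6.3×10⁷ cfu/g),
acidity rising from 0.95 g/L (0.095% w/v) to 12.0 g/L (1.200%) by day 12,
and pH falling from 6.59 towards 3.71 by day 9 with a slight late rise.

Design choices in the defaults:

* The product model is Monteagudo with `m = 0.1104` and an inhibition
  constant `P_max = 12.5 g/L` with `n = 0.035 hr⁻¹` calibrated so the
  noiseless curve passes through 12.0 g/L at day 12 and is nearly flat
  afterwards. In a real fermentation the acidity ceiling reflects both
  end-product inhibition and substrate exhaustion; substrate kinetics are
  out of scope, so the default inhibition constant absorbs the observed
  ceiling rather than representing a pure inhibition threshold.
* pH couples to *produced* acid, `pH = pH_min + (pH0 − pH_min)·
  exp(−k(P − P0))`, so that pH(0) is exactly the configured initial pH;
  the optional late rise is a linear ramp (default +0.08 units from day 9),
  matching the slight terminal rise such fermentations show. This is an
  empirical shape, not a buffer model.
* Count noise is multiplicative lognormal (CV parameterized; plate-count
  error structure); acidity and pH noise are additive Gaussian. The
  death-phase decline exists to exercise the growth-window rule and is
  deliberately outside the fitted model family.

What passing the pipeline tests does and does not show: the noiseless
generator shares the growth and integration code with the fitter, so
noiseless round-trip recovery validates the estimator's correctness and
the optimizer's ability to find the global minimum from automatic starts —
it does not validate the models against real fermentations, where
succession of LAB species, substrate depletion and temperature drift all
violate the single-population, constant-environment assumptions.

## Problem sizes

Recovery experiments use 25-point growth grids (2-hr spacing over 48–72 hr)
and 65–121-point product grids (6-hr spacing over 384–720 hr); the longer
product horizon is chosen so that end-product inhibition is actually
expressed in the data (at 384 hr a `P_max` of ~117 g/L bends the curve by
only a few percent). The noise-robustness check uses 50 seeded replicates
with σ = 0.05 Gaussian noise on the log-ratio. The stationary-phase
plateau is integrated with a 1-hr RK4 step until the rate falls below
1e-9 g/L/hr.

## Known limitations

* No secondary models (temperature/pH dependence of `mu_m`), no Baranyi or
  Richards growth forms, no death-phase model, no substrate kinetics.
* No confidence intervals; the reporting is point estimates plus the
  goodness-of-fit battery.
* The Balannec fit assumes the measured pH series is dense enough for
  linear interpolation; with very sparse pH data the undissociated-acid
  curve inherits the interpolation error.
* Model selection on near-perfect fits (R² ties at < 1e-6) devolves to the
  χ²/RMSE tie-break chain, whose ordering below measurement precision is
  not scientifically meaningful.
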