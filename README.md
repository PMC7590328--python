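# fermfit

Kinetic analysis of natural lactic-acid vegetable fermentations (such as
*gundruk*, spontaneously fermented mustard leaves): primary growth models
for the lactic acid bacteria (LAB) population, product-formation models for
lactic acid with end-product inhibition, nonlinear least-squares parameter
estimation, and a goodness-of-fit battery for model selection. A seeded
synthetic-trajectory generator makes the whole pipeline testable and
reproducible without any measured data.

It is aimed at food microbiologists and fermentation engineers who have a
sampled trajectory — time, viable counts (cfu/g), titratable acidity, pH —
and want the standard kinetic parameters plus a defensible model ranking.

## Models

**Growth** is modelled on the response scale `X = log10(N/N0)` with two
sigmoids in the Zwietering parameterization, where `A` is the asymptotic
log10 population increase, `mu_m` the maximum specific growth rate (the
literal maximum slope, hr⁻¹) and `lambda` the lag period (hr):

    Modified Gompertz:  X(t) = A exp(−exp((mu_m e / A)(lambda − t) + 1))
    Logistic:           X(t) = A / (1 + exp(2 + (4 mu_m / A)(lambda − t)))

**Lactic-acid production** couples the rate `dP/dt` (g/L/hr) to the biomass
curve through the Luedeking–Piret family, with `m` the growth-associated
and `n` the non-growth-associated coefficient:

    Luedeking–Piret:   dP/dt = m dX/dt + n X
    Monteagudo et al.: dP/dt = m dX/dt + n X (1 − P/P_max)
    Balannec et al.:   dP/dt = m dX/dt + n X (1 − [HL]/(HL)_inh)

`P_max` is the total-acid concentration at which the non-growth term is
fully inhibited; the Balannec form uses instead the undissociated acid
`[HL] = P / (1 + 10^(pH − pKa))` (Henderson–Hasselbalch, pKa = 3.86 for
lactic acid). Product curves are integrated with a deterministic fixed-step
RK4 scheme and fitted to measured acidity by bounded trust-region least
squares.

**Model selection** ranks fits by the uncentered R² (the squared cosine of
the observed and predicted vectors), with ties broken by reduced χ², RMSE,
MAPE and RSS; the conventional R² is always reported alongside because the
uncentered form is scale-blind.

## Worked example

Simulate a 16-day gundruk-like fermentation (daily sampling, realistic
plate-count, titration and pH noise) and fit every model:

    $ fermfit simulate --out gundruk.csv --seed 42
    wrote 17 rows to gundruk.csv (config: gundruk.csv.config.json)

    $ fermfit fit gundruk.csv --out report.json
    Growth models
    -------------
    Model                Parameters                                                 R2      chi2     RMSE       RSS    MAPE%
    Modified Gompertz    mu_m = 0.2309 hr^-1, lam = 15.21 hr, A = 4.15          0.9999    0.0026   0.0361    0.0078    0.689
    Logistic             mu_m = 0.2032 hr^-1, lam = 14.06 hr, A = 4.14          0.9999    0.0034   0.0414    0.0103    0.799

    Product formation models
    ------------------------
    Model                Parameters                                                 R2      chi2     RMSE       RSS    MAPE%
    Monteagudo et al.    m = 0.2016, n = 0.03453, P_max = 12.5780 g/L           0.9997    0.0322   0.1628    0.4507    2.116
    Balannec et al.      m = 0.1172, n = 0.03118, HL_inh = 7.0523 g/L           0.9993    0.0885   0.2699    1.2386    3.466
    Luedeking-Piret      m = 1.272, n = 0.005276                                0.9866    1.4920   1.1474   22.3805   16.129

    Best growth model: Modified Gompertz
    Best product model: Monteagudo et al.

Reading the output: the LAB population rose by `A ≈ 4.15` log10 units with
a maximum specific growth rate of `0.23 hr⁻¹` after a `15 hr` lag, and the
fit correctly identifies the generating (Gompertz) growth shape and the
generating (Monteagudo) production law — mixed-type kinetics (`m` and `n`
both positive) with the non-growth term shutting down as acid approaches
`P_max ≈ 12.6 g/L`. The death phase visible after day 5 is automatically
excluded from the growth-fit window, since neither sigmoid can represent
decline. `fermfit recover` automates this simulate/refit loop over many
seeds and reports per-parameter bias and RMSE.

The same `fit` command works on measured data: a CSV with header
`time_hr,cfu_per_g,acidity_g_per_l,pH` (acidity alternatively as
`acidity_pct`, converted at 1% w/v = 10 g/L).

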