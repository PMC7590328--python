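"""Parameter recovery from noiseless self-generated data, initialization
heuristics, the growth-fit window rule and fit invariants."""

import numpy as np
import pytest

from fermfit import (
    DataError,
    FermentationSeries,
    GrowthParams,
    ProductParams,
    auto_initialize_growth,
    auto_initialize_product,
    fit_growth,
    fit_product,
    growth_fit_window,
    integrate_product,
    log_ratio,
    rss,
)
from fermfit.product import BiomassTrajectory

from conftest import N0, make_growth_series


class TestGrowthRecovery:
    def test_gompertz_noiseless(self, gompertz_series):
        fit = fit_growth(gompertz_series, "gompertz")
        assert fit.converged
        e = fit.estimates
        assert e["A"] == pytest.approx(3.79, rel=1e-4)
        assert e["mu_m"] == pytest.approx(0.37, rel=1e-4)
        assert e["lam"] == pytest.approx(4.84, rel=1e-4)

    def test_logistic_noiseless(self, logistic_series):
        fit = fit_growth(logistic_series, "logistic")
        assert fit.converged
        e = fit.estimates
        assert e["A"] == pytest.approx(3.77, rel=1e-4)
        assert e["mu_m"] == pytest.approx(0.186, rel=1e-4)
        assert e["lam"] == pytest.approx(10.30, rel=1e-4)

    def test_constant_data_fails_gracefully(self):
        s = FermentationSeries(t=np.arange(6.0), cfu=np.full(6, 1e5))
        fit = fit_growth(s, "gompertz")
        assert not fit.converged
        assert fit.warnings

    def test_too_few_points_rejected(self):
        s = FermentationSeries(t=np.arange(4.0), cfu=np.array([1e4, 1e5, 1e6, 1e7]))
        with pytest.raises(DataError, match="5"):
            fit_growth(s, "gompertz")

    def test_rss_not_worse_than_init_and_matches_definition(self, gompertz_series):
        init = GrowthParams("gompertz", A=2.0, mu_m=0.2, lam=2.0)
        fit = fit_growth(gompertz_series, "gompertz", init=init)
        i0, i1 = fit.fit_window
        y = gompertz_series.log_ratio()[i0:i1]
        rss_init = rss(y, log_ratio(gompertz_series.t[i0:i1], init))
        assert fit.gof.rss <= rss_init
        assert fit.gof.rss == pytest.approx(rss(y, fit.predicted), rel=1e-12)

    def test_refit_idempotent(self, gompertz_series):
        fit1 = fit_growth(gompertz_series, "gompertz")
        fit2 = fit_growth(gompertz_series, "gompertz", init=fit1.params)
        for k in ("A", "mu_m", "lam"):
            assert fit2.estimates[k] == pytest.approx(fit1.estimates[k], rel=1e-6)


class TestWindowRule:
    def test_death_phase_excluded(self, gompertz_params):
        t = np.arange(0.0, 385.0, 24.0)
        log_counts = np.log10(N0) + log_ratio(t, gompertz_params)
        # sustained decline (>10% per step) from 120 h onwards
        drop = np.clip(0.02 * (t - 120.0), 0.0, 1.2)
        s = FermentationSeries(t=t, cfu=10 ** (log_counts - drop), N0=N0)
        i0, i1 = growth_fit_window(s)
        assert i0 == 0
        assert t[i1 - 1] <= 144.0  # window stops at the decline onset
        fit = fit_growth(s, "gompertz")
        assert fit.converged
        assert fit.estimates["A"] == pytest.approx(3.79, rel=1e-3)

    def test_full_window_without_decline(self, gompertz_series):
        assert growth_fit_window(gompertz_series) == (0, len(gompertz_series))


class TestGrowthInit:
    def test_amplitude_within_5_percent(self, gompertz_series):
        init = auto_initialize_growth(gompertz_series)
        assert init.A == pytest.approx(3.79, rel=0.05)

    def test_plateau_duplicates_do_not_change_init(self, gompertz_series):
        s = gompertz_series
        t2 = np.concatenate([s.t, [s.t[-1] + 2, s.t[-1] + 4]])
        cfu2 = np.concatenate([s.cfu, [s.cfu[-1], s.cfu[-1]]])
        ext = FermentationSeries(t=t2, cfu=cfu2, N0=N0)
        a, b = auto_initialize_growth(s), auto_initialize_growth(ext)
        assert (a.A, a.mu_m, a.lam) == (b.A, b.mu_m, b.lam)

    def test_secant_slope_does_not_exceed_true_mu(self, gompertz_params):
        # chord slopes of a sigmoid underestimate the max tangent slope
        s = make_growth_series(gompertz_params, np.arange(0.0, 48.1, 0.5))
        init = auto_initialize_growth(s)
        assert init.mu_m <= 0.37 * 1.2

    def test_constant_data_rejected(self):
        s = FermentationSeries(t=np.arange(6.0), cfu=np.full(6, 1e5))
        with pytest.raises(DataError, match="constant"):
            auto_initialize_growth(s)


def _product_series(growth_params, product_params, t, env=None, P0=0.0):
    bio = BiomassTrajectory.from_growth(growth_params)
    P = integrate_product(product_params, bio, t, P0, env=env)
    return FermentationSeries(
        t=t, cfu=N0 * 10 ** log_ratio(t, growth_params), acidity=P, N0=N0
    )


class TestProductRecovery:
    def test_luedeking_piret_noiseless(self, gompertz_params, lp_params):
        t = np.arange(0.0, 385.0, 6.0)
        s = _product_series(gompertz_params, lp_params, t)
        growth = fit_growth(s, "gompertz")
        fit = fit_product(s, growth, "luedeking_piret")
        assert fit.converged
        assert fit.estimates["m"] == pytest.approx(0.1620, rel=1e-3)
        assert fit.estimates["n"] == pytest.approx(0.0099, rel=1e-3)

    def test_zero_production_hits_lower_bounds(self, gompertz_params):
        t = np.arange(0.0, 385.0, 24.0)
        p0 = ProductParams("luedeking_piret", m=0.0, n=0.0)
        s = _product_series(gompertz_params, p0, t, P0=0.5)
        growth = fit_growth(s, "gompertz")
        fit = fit_product(s, growth, "luedeking_piret")
        assert fit.estimates["m"] == pytest.approx(0.0, abs=1e-6)
        assert fit.estimates["n"] == pytest.approx(0.0, abs=1e-6)
        assert fit.gof.rss == pytest.approx(0.0, abs=1e-12)

    def test_missing_channels_rejected(self, gompertz_series):
        growth = fit_growth(gompertz_series, "gompertz")
        with pytest.raises(DataError, match="acidity"):
            fit_product(gompertz_series, growth, "luedeking_piret")
        t = gompertz_series.t
        s = FermentationSeries(t=t, cfu=gompertz_series.cfu,
                               acidity=np.linspace(0, 5, t.size), N0=N0)
        with pytest.raises(DataError, match="pH"):
            fit_product(s, growth, "balannec")


class TestProductInit:
    def test_inits_within_order_of_magnitude(self, gompertz_params, lp_params):
        t = np.arange(0.0, 385.0, 6.0)
        s = _product_series(gompertz_params, lp_params, t)
        growth = fit_growth(s, "gompertz")
        init = auto_initialize_product(s, growth, "luedeking_piret")
        assert 0.1 * 0.1620 <= init.m <= 10 * 0.1620
        assert 0.1 * 0.0099 <= init.n <= 10 * 0.0099

    @pytest.mark.parametrize("m,n,small", [(0.0, 0.01, "m"), (0.15, 0.0, "n")])
    def test_pure_modes_start_near_zero(self, gompertz_params, m, n, small):
        t = np.arange(0.0, 385.0, 6.0)
        p = ProductParams("luedeking_piret", m=m, n=n)
        s = _product_series(gompertz_params, p, t)
        growth = fit_growth(s, "gompertz")
        init = auto_initialize_product(s, growth, "luedeking_piret")
        assert getattr(init, small) < 0.01
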