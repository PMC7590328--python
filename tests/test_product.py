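"""Rate-law arithmetic, the Henderson-Hasselbalch partition, and the RK4
product integration against closed forms and an independent ODE solver."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fermfit import (
    AcidEnvironment,
    BiomassTrajectory,
    DataError,
    DomainError,
    ProductParams,
    balannec_rate,
    gompertz_rate,
    integrate_product,
    integrate_to_plateau,
    log_ratio,
    luedeking_piret_rate,
    monteagudo_rate,
    undissociated_fraction,
)


class TestRateLaws:
    def test_luedeking_piret_hand_value(self):
        p = ProductParams("luedeking_piret", m=0.1620, n=0.0099)
        # m*dXdt + n*X = 0.1620*0.37 + 0.0099*3.79
        assert luedeking_piret_rate(3.79, 0.37, p) == pytest.approx(0.097461, rel=1e-12)
        assert luedeking_piret_rate(1.0, 0.0, p) == pytest.approx(0.0099)
        assert luedeking_piret_rate(0.0, 0.0, p) == 0.0

    def test_monteagudo_hand_value_and_limits(self, monteagudo_params):
        p = monteagudo_params
        # half inhibition: n-term halves
        assert monteagudo_rate(3.79, 0.0, 58.272, p) == pytest.approx(
            0.0042 * 3.79 * 0.5, rel=1e-12
        )
        assert monteagudo_rate(2.0, 0.0, p.P_max, p) == 0.0
        lp = ProductParams("luedeking_piret", m=p.m, n=p.n)
        assert monteagudo_rate(2.5, 0.1, 0.0, p) == luedeking_piret_rate(2.5, 0.1, lp)

    def test_balannec_hand_value_and_limits(self, balannec_params):
        p = balannec_params
        assert balannec_rate(2.0, 0.1, 10.7432, p) == pytest.approx(0.01878, rel=1e-12)
        assert balannec_rate(2.0, 0.0, p.HL_inh, p) == 0.0
        lp = ProductParams("luedeking_piret", m=p.m, n=p.n)
        assert balannec_rate(2.0, 0.1, 0.0, p) == luedeking_piret_rate(2.0, 0.1, lp)

    def test_domain_errors(self, monteagudo_params, balannec_params):
        lp = ProductParams("luedeking_piret", m=0.1, n=0.01)
        with pytest.raises(DomainError):
            luedeking_piret_rate(-1.0, 0.0, lp)
        with pytest.raises(DomainError):
            monteagudo_rate(1.0, 0.0, monteagudo_params.P_max + 1, monteagudo_params)
        with pytest.raises(DomainError):
            balannec_rate(1.0, 0.0, -0.1, balannec_params)

    @pytest.mark.parametrize("kwargs", [
        dict(model_id="monteagudo", m=0.1, n=0.01),               # missing P_max
        dict(model_id="luedeking_piret", m=0.1, n=0.01, P_max=5.0),
        dict(model_id="balannec", m=0.1, n=0.01, P_max=5.0),       # wrong constant
        dict(model_id="monteagudo", m=-0.1, n=0.01, P_max=5.0),
    ])
    def test_param_field_discipline(self, kwargs):
        with pytest.raises(DomainError):
            ProductParams(**kwargs)


class TestUndissociatedFraction:
    def test_half_dissociated_at_pka(self):
        assert undissociated_fraction(8.0, 3.86, 3.86) == pytest.approx(4.0)

    def test_fully_protonated_at_low_ph(self):
        assert undissociated_fraction(5.0, 0.5, 3.86) == pytest.approx(5.0, rel=1e-3)

    def test_value_at_final_fermentation_ph(self):
        expected = 12.0 / (1.0 + 10.0 ** (3.71 - 3.86))
        assert undissociated_fraction(12.0, 3.71, 3.86) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(7.026, abs=5e-3)

    def test_monotone_decreasing_in_ph(self):
        ph = np.linspace(2.0, 9.0, 50)
        hl = undissociated_fraction(10.0, ph, 3.86)
        assert np.all(np.diff(hl) < 0)
        assert np.all(hl >= 0) and np.all(hl <= 10.0)


@pytest.fixture(scope="module")
def t_grid():
    return np.arange(0.0, 385.0, 6.0)


class TestIntegration:
    def test_growth_associated_limit_is_exact(self, gompertz_biomass,
                                              gompertz_params, t_grid):
        # n = 0 collapses the ODE to dP = m dX
        p = ProductParams("luedeking_piret", m=0.3, n=0.0)
        P = integrate_product(p, gompertz_biomass, t_grid, 1.0)
        X = log_ratio(t_grid, gompertz_params)
        np.testing.assert_allclose(P - 1.0, 0.3 * (X - X[0]), atol=1e-9)

    def test_constant_biomass_is_linear(self, t_grid):
        p = ProductParams("luedeking_piret", m=0.0, n=0.02)
        bio = BiomassTrajectory.constant(3.0)
        P = integrate_product(p, bio, t_grid, 0.5)
        np.testing.assert_allclose(P, 0.5 + 0.02 * 3.0 * t_grid, rtol=1e-12)

    def test_monteagudo_closed_form(self):
        # m=0, constant X: P(t) = Pmax - (Pmax - P0) exp(-nc t / Pmax)
        p = ProductParams("monteagudo", m=0.0, n=0.01, P_max=20.0)
        c, P0 = 3.0, 1.0
        t = np.arange(0.0, 1001.0, 10.0)
        P = integrate_product(p, BiomassTrajectory.constant(c), t, P0)
        exact = 20.0 - (20.0 - P0) * np.exp(-0.01 * c * t / 20.0)
        np.testing.assert_allclose(P, exact, rtol=1e-6)

    def test_against_independent_ode_solver(self, gompertz_biomass,
                                            monteagudo_params, t_grid):
        P = integrate_product(monteagudo_params, gompertz_biomass, t_grid, 0.0)
        bio, p = gompertz_biomass, monteagudo_params

        def rhs(t, y):
            return [p.m * bio.rate(t) + p.n * bio.value(t) * (1 - y[0] / p.P_max)]

        sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [0.0], t_eval=t_grid,
                        rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(P, sol.y[0], atol=1e-7)

    def test_step_size_converged(self, gompertz_biomass, monteagudo_params, t_grid):
        P1 = integrate_product(monteagudo_params, gompertz_biomass, t_grid, 0.0,
                               h_max=0.1)
        P2 = integrate_product(monteagudo_params, gompertz_biomass, t_grid, 0.0,
                               h_max=0.05)
        assert abs(P1[-1] - P2[-1]) < 1e-8

    def test_nondecreasing_and_bounded(self, gompertz_biomass, monteagudo_params,
                                       t_grid):
        P = integrate_product(monteagudo_params, gompertz_biomass, t_grid, 0.0)
        assert np.all(np.diff(P) >= 0)
        assert np.all(P <= monteagudo_params.P_max)

    @pytest.mark.parametrize("model_id,big", [("monteagudo", "P_max"),
                                              ("balannec", "HL_inh")])
    def test_inhibited_models_reduce_to_luedeking_piret(self, model_id, big,
                                                        gompertz_biomass, t_grid):
        lp = ProductParams("luedeking_piret", m=0.1620, n=0.0099)
        inhibited = ProductParams(model_id, m=0.1620, n=0.0099, **{big: 1e9})
        env = None
        if model_id == "balannec":
            env = AcidEnvironment.from_series(t_grid, np.full(t_grid.size, 4.0))
        P_lp = integrate_product(lp, gompertz_biomass, t_grid, 0.0)
        P_in = integrate_product(inhibited, gompertz_biomass, t_grid, 0.0, env=env)
        assert np.max(np.abs(P_lp - P_in)) < 1e-4

    def test_plateau_approaches_p_max(self, monteagudo_params):
        plateau = integrate_to_plateau(monteagudo_params, X=3.79)
        assert plateau == pytest.approx(116.544, rel=1e-3)

    def test_errors(self, gompertz_biomass, balannec_params):
        lp = ProductParams("luedeking_piret", m=0.1, n=0.01)
        with pytest.raises(DataError, match="increasing"):
            integrate_product(lp, gompertz_biomass, [0.0, 2.0, 1.0], 0.0)
        with pytest.raises(DataError, match="balannec"):
            integrate_product(balannec_params, gompertz_biomass, [0.0, 1.0, 2.0], 0.0)
        with pytest.raises(DomainError, match="P0"):
            integrate_product(lp, gompertz_biomass, [0.0, 1.0], -1.0)
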