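import numpy as np
import pytest

from fermfit import (
    BiomassTrajectory,
    FermentationSeries,
    GrowthParams,
    ProductParams,
    gompertz_log_ratio,
    log_ratio,
)

N0 = 6.03e4


@pytest.fixture(scope="session")
def gompertz_params() -> GrowthParams:
    """Reference modified-Gompertz parameter set (hours)."""
    return GrowthParams("gompertz", A=3.79, mu_m=0.37, lam=4.84)


@pytest.fixture(scope="session")
def logistic_params() -> GrowthParams:
    return GrowthParams("logistic", A=3.77, mu_m=0.186, lam=10.30)


@pytest.fixture(scope="session")
def lp_params() -> ProductParams:
    return ProductParams("luedeking_piret", m=0.1620, n=0.0099)


@pytest.fixture(scope="session")
def monteagudo_params() -> ProductParams:
    return ProductParams("monteagudo", m=0.1104, n=0.0042, P_max=116.544)


@pytest.fixture(scope="session")
def balannec_params() -> ProductParams:
    return ProductParams("balannec", m=0.0348, n=0.0153, HL_inh=21.4864)


def make_growth_series(p: GrowthParams, t: np.ndarray) -> FermentationSeries:
    """Noiseless counts generated exactly from a growth model."""
    return FermentationSeries(t=t, cfu=N0 * 10.0 ** log_ratio(t, p), N0=N0)


@pytest.fixture(scope="session")
def gompertz_series(gompertz_params) -> FermentationSeries:
    return make_growth_series(gompertz_params, np.arange(0.0, 49.0, 2.0))


@pytest.fixture(scope="session")
def logistic_series(logistic_params) -> FermentationSeries:
    return make_growth_series(logistic_params, np.arange(0.0, 73.0, 2.0))


@pytest.fixture(scope="session")
def gompertz_biomass(gompertz_params) -> BiomassTrajectory:
    return BiomassTrajectory.from_growth(gompertz_params)
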