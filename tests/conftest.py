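import numpy as np
import pandas as pd
import pytest

from pollenomics import sensitivity as sens
from pollenomics import synthetic
from pollenomics.market import solve_equilibrium


@pytest.fixture(scope="session")
def dataset():
    return synthetic.generate_market_dataset(synthetic.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def model(dataset):
    return sens.build_model(dataset)


@pytest.fixture(scope="session")
def shock_table(dataset):
    return sens.build_shocks(dataset)


@pytest.fixture(scope="session")
def state(dataset, model, shock_table):
    return solve_equilibrium(model, shocks=shock_table)


@pytest.fixture(scope="session")
def printed_table():
    return synthetic.table1_fixture()


def make_closed_market(eps_s: float, eps_d: float):
    """A single-region, single-commodity autarky baseline with p0 = q0 = 1."""
    from pollenomics.market import BaselineMarket, calibrate_baseline

    n, c = 1, 1
    b = BaselineMarket(
        region_ids=["R"],
        commodity_ids=["X"],
        in_europe=np.array([True]),
        in_eu=np.array([True]),
        production=np.ones((n, c)),
        demand=np.ones((n, c)),
        producer_price=np.ones((n, c)),
        consumer_price=np.ones((n, c)),
        area=np.ones((n, c)),
        flows=np.zeros((n, n, c)),
        tau=np.zeros((n, n, c)),
        eps_s=np.full((n, c), eps_s),
        eps_d=np.full((n, c), eps_d),
        eta=np.zeros((n, c)),
        sigma1=np.full((n, c), 2.0),
        sigma2=np.full((n, c), 2.0),
        land_elasticity=np.zeros(n),
        gdp=np.full(n, 1.0e9),
        population=np.full(n, 1.0e6),
        households=np.full(n, 4.0e5),
    )
    return calibrate_baseline(b)


@pytest.fixture
def closed_market_factory():
    return make_closed_market
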