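"""Shared fixtures: clean benchmark datasets reused across test modules."""

import numpy as np
import pytest

import esindy as es
from esindy.library import pde_terms
from esindy.systems import default_spec


@pytest.fixture(scope="session")
def lorenz_spec():
    return es.SystemSpec("lorenz", dt=0.01, m=2500)


@pytest.fixture(scope="session")
def lorenz_clean(lorenz_spec):
    return es.simulate_system(lorenz_spec)


@pytest.fixture(scope="session")
def lorenz_library(lorenz_clean):
    return es.build_ode_library(lorenz_clean, poly_order=3)


@pytest.fixture(scope="session")
def lorenz_truth(lorenz_spec, lorenz_library):
    return es.true_xi(lorenz_spec, lorenz_library.terms)


@pytest.fixture(scope="session")
def burgers_field():
    return es.simulate_system(default_spec("burgers_inviscid"))


@pytest.fixture(scope="session")
def kdv_field():
    return es.simulate_system(default_spec("kdv"))


@pytest.fixture(scope="session")
def scalar_pde_terms():
    return pde_terms(1, poly_order=2, max_deriv=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
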