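"""Shared fixtures: small synthetic panels and their transition records."""

import numpy as np
import pytest

import worklife as wl


@pytest.fixture(scope="session")
def annual_config():
    return wl.default_config(n_persons=1500, step=1, seed=11)


@pytest.fixture(scope="session")
def annual_panel(annual_config):
    return wl.generate_panel(annual_config)


@pytest.fixture(scope="session")
def annual_records(annual_panel):
    return wl.build_transition_records(annual_panel)


@pytest.fixture(scope="session")
def biennial_config():
    return wl.default_config(n_persons=1500, step=2, seed=12)


@pytest.fixture(scope="session")
def biennial_panel(biennial_config):
    return wl.generate_panel(biennial_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
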