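"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from lncgba import SimulationParams, simulate_dataset, write_fixture


@pytest.fixture(scope="session")
def small_params():
    """A fast, small planted-structure dataset for unit tests."""
    return SimulationParams(
        n_samples=40,
        n_lncrnas=2,
        n_pcgs=300,
        targets_per_lnc=30,
        target_correlation=0.8,
        n_terms=8,
        planted_term_overlap=0.8,
        seed=7,
        dataset_id="small",
    )


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return simulate_dataset(small_params)


@pytest.fixture(scope="session")
def small_fixture_dir(small_bundle, small_params, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_small")
    write_fixture(small_bundle, out, small_params)
    return out


@pytest.fixture(scope="session")
def study_params():
    """The study-scale conditions: 50 samples, 2 lncRNAs x 50 targets at
    latent rho 0.8, 2000 unassociated genes, 1 planted + 10 decoy terms
    per lncRNA."""
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def study_bundle(study_params):
    return simulate_dataset(study_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20241)
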