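"""Shared fixtures: small simulated datasets and toy inputs.

All fixtures are generated programmatically with fixed seeds; nothing
is loaded from disk.
"""

import numpy as np
import pytest

import mhc2learn as m


@pytest.fixture(scope="session")
def sim_small():
    """Default-condition simulation, 100+100 records per domain."""
    cfg = m.SimConfig(n_pos=100, n_neg=100, seed=11)
    antigenic, immunogenic, truth = m.simulate_dataset(cfg)
    return cfg, antigenic, immunogenic, truth


@pytest.fixture(scope="session")
def toy_proteome():
    return m.simulate_proteome(n_proteins=30, length=200, seed=5)


@pytest.fixture(scope="session")
def toy_alleles(sim_small):
    _, antigenic, _, _ = sim_small
    return antigenic.alleles


@pytest.fixture(scope="session")
def trained_el(sim_small):
    """A small trained presentation model on the separable task."""
    cfg = m.SimConfig.separable(n_pos=250, n_neg=250, seed=3)
    antigenic, _, _ = m.simulate_dataset(cfg)
    el_cfg = m.ElConfig(epochs=5, d_model=24, lr=3e-3, seed=3)
    return antigenic, m.ElPresentationModel(
        antigenic, antigenic.alleles, el_cfg).fit()
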