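"""Shared fixtures: small deterministic networks and assembled communities."""

import logging

import numpy as np
import pytest

import mutustab as ms
from mutustab.networks import BipartiteNetwork

logging.getLogger("mutustab").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def full_net():
    """Fully connected 10 x 10 network."""
    return BipartiteNetwork(np.ones((10, 10), dtype=np.int8))


@pytest.fixture(scope="session")
def matching_net():
    """Perfect matching: 6 plants, 6 animals, one private partner each."""
    return BipartiteNetwork(np.eye(6, dtype=np.int8))


@pytest.fixture(scope="session")
def sparse_net():
    """Sparse 21 x 20 network with a skewed degree sequence."""
    deg_p, deg_a = ms.study_degree_sequences(21, 20, 0.2, rng_seed=7)
    return ms.sample_network(deg_p, deg_a, rng_seed=8)


@pytest.fixture(scope="session")
def community_a(sparse_net):
    """Facultative weak-mutualism community (regime A parameters)."""
    meta = ms.MetaParameters.from_preset("A", gamma0=0.1)
    return ms.assemble_community(sparse_net, meta, rng_seed=4)


@pytest.fixture(scope="session")
def community_obligatory(sparse_net):
    """Mutualism obligatory for animals (regime E parameters)."""
    meta = ms.MetaParameters.from_preset("E")
    return ms.assemble_community(sparse_net, meta, rng_seed=11)


@pytest.fixture(scope="session")
def eff_a(community_a):
    return ms.effective_system(ms.equivalent_lv(community_a))


@pytest.fixture(scope="session")
def eff_obligatory(community_obligatory):
    return ms.effective_system(ms.equivalent_lv(community_obligatory))


@pytest.fixture(scope="session")
def small_community():
    """Small (12+12) community cheap enough for repeated ODE integration."""
    net = ms.sample_network(
        *ms.study_degree_sequences(12, 12, 0.25, rng_seed=20), rng_seed=21
    )
    meta = ms.MetaParameters.from_preset("A", gamma0=0.1)
    return ms.assemble_community(net, meta, rng_seed=22)
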