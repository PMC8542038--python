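"""Shared fixtures: a small two-condition genome with planted architecture.

Everything is generated programmatically; the fixtures use a reduced
resolution ladder (4 fine bins per compartment bin, 2 per TAD bin) so unit
tests stay fast while exercising the full multi-resolution path.
"""
import numpy as np
import pytest

import chromarch as ca


@pytest.fixture(scope="session")
def small_spec():
    return ca.synthetic_genome(2, 30, bin_size=25_000, comp_factor=4, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return ca.plant_architecture(
        small_spec, flip_fraction=0.1, weaken_fraction=0.5,
        loop_loss_fraction=0.3, seed=7, comp_factor=4, tad_factor=2,
        depth=2000.0)


@pytest.fixture(scope="session")
def sampled(small_truth):
    """Condition-1 fine matrices for the small genome."""
    return ca.sample_contact_matrix(small_truth, 1, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_symmetric(n, rng, positive=True):
    a = rng.random((n, n)) + (0.5 if positive else 0.0)
    m = (a + a.T) / 2
    return m
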