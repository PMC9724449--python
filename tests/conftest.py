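import numpy as np
import pytest

from modsig import (
    CANONICAL_SCHEME,
    MutationCatalog,
    SignatureSet,
    SimulationConfig,
    sample_signature_pool,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def scheme():
    return CANONICAL_SCHEME


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset with a known injected modulatory process."""
    config = SimulationConfig(n_datasets=1, n_samples=25, seed=99)
    rng = np.random.default_rng(99)
    pool = sample_signature_pool(config, rng=rng)
    return simulate_dataset(config, pool, rng=rng)


@pytest.fixture(scope="session")
def uniform_signatures(scheme):
    """Two signatures: uniform, and one concentrated on the first 48 channels."""
    flat = np.full(96, 1 / 96)
    half = np.zeros(96)
    half[:48] = 1 / 48
    return SignatureSet(["FLAT", "HALF"], np.stack([flat, half]), scheme)


def catalog_from_counts(counts, scheme=CANONICAL_SCHEME, types=None):
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    ids = [f"S{i}" for i in range(counts.shape[0])]
    return MutationCatalog(ids, counts, scheme, types)
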