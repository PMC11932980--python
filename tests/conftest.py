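import numpy as np
import pytest

from evoppi import (
    DAEConfig,
    FixedMatrix,
    SyntheticSpec,
    generate_benchmark,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-signal benchmark shared by pipeline-level tests."""
    spec = SyntheticSpec(
        n_proteins=45, n_positive_pairs=60, n_negative_pairs=60,
        separation=2.0, seed=11,
    )
    return generate_benchmark(spec)


@pytest.fixture(scope="session")
def fast_dae_config():
    """A small autoencoder that trains in well under a second."""
    return DAEConfig(layer_sizes=(64, 16), epochs=25, batch_size=32, seed=5)


def make_scaled_matrix(rng, protein_id="p", method="equal_size"):
    values = rng.random((20, 20))
    values[0, 0], values[-1, -1] = 0.0, 1.0  # pin the range
    return FixedMatrix(protein_id=protein_id, values=values, method=method, scaled=True)


@pytest.fixture
def scaled_matrices(rng):
    return [make_scaled_matrix(rng, f"p{i}") for i in range(30)]
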