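import numpy as np
import pytest

from mircausal import io, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """Scaled-down planted benchmark for fast structural tests."""
    config = synthetic.GeneratorConfig(
        n_mirnas=24,
        n_diseases=12,
        n_families=4,
        n_cell_types=6,
        n_pathways=15,
        seed=11,
    )
    return synthetic.generate_dataset(config)


@pytest.fixture(scope="session")
def small_md(small_dataset):
    return io.build_association_matrix(small_dataset.association_table)


@pytest.fixture(scope="session")
def default_dataset():
    """The benchmark at its default study conditions (60 x 40, seed 7)."""
    return synthetic.generate_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
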