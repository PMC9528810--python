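import numpy as np
import pytest

from snarpred import descriptors, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 120-row synthetic bundle shared across tests."""
    return synthetic.generate(synthetic.GeneratorConfig(n_samples=120, seed=42))


@pytest.fixture(scope="session")
def small_xy(small_dataset):
    X, y, columns = descriptors.assemble(
        small_dataset.reaction_table,
        small_dataset.descriptor_table,
        descriptors.FeatureSetSpec(name="X_full"),
    )
    return X, y, columns


@pytest.fixture
def rng():
    return np.random.default_rng(0)
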