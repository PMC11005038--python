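import numpy as np
import pytest

from cholepk import synthetic
from cholepk.qivive import PhysiologyConfig


@pytest.fixture(scope="session")
def small_dataset():
    """120-compound synthetic dataset shared by read-only tests."""
    return synthetic.generate(synthetic.SyntheticConfig(n_compounds=120,
                                                        seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phys_deterministic():
    """Physiology with Monte-Carlo variability switched off."""
    return PhysiologyConfig(variability_cv=0.0)
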