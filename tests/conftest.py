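import numpy as np
import pytest

import herbgrade as hg
from herbgrade.sensory import PairwiseComparison, binary_comparison_weights
from herbgrade.synthetic import CRITERIA


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic cohort (seed 42), shared across tests."""
    return hg.generate_dataset()


@pytest.fixture(scope="session")
def strict_weights():
    """Strict-ranking criterion weights (0.4, 0.3, 0.2, 0.1)."""
    return binary_comparison_weights(PairwiseComparison.from_ranking(CRITERIA))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
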