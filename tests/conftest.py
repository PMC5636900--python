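import dataclasses

import numpy as np
import pytest

from barrelpt.cohort import default_config, generate_cohort
from barrelpt.morphology import default_layers


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layers():
    return default_layers()


@pytest.fixture(scope="session")
def small_cohort():
    """19-cell cohort at the reconstructed-sample group sizes (no duals)."""
    config = default_config()
    groups = [
        dataclasses.replace(g, n_cells=n) for g, n in zip(config.groups, (5, 5, 5, 4))
    ]
    config = dataclasses.replace(config, groups=groups, dual_fraction=0.0)
    return generate_cohort(config, seed=2024)
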