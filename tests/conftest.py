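import numpy as np
import pytest

import markergp as mg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240354)


@pytest.fixture(scope="session")
def small_config():
    """A GA configuration small enough for fast unit tests."""
    return mg.GAConfig(
        population_size=80,
        max_generations=12,
        tournament_size=4,
        hall_of_fame_size=10,
        n_restarts=2,
        seed=3,
    )


def random_trees(config, rng, n, depth=4):
    """Sample n random trees, alternating grow/full construction."""
    return [
        mg.random_tree(config, depth, rng, method="grow" if i % 2 else "full")
        for i in range(n)
    ]
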