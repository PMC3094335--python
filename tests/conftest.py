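import pytest

from wormtx import simulate
from wormtx.datasets import example_history


@pytest.fixture(scope="session")
def mini_history():
    """Packaged history with the two documented WormBase merges."""
    return example_history()


@pytest.fixture(scope="session")
def expression_fixture():
    """Seeded paired expression table with planted regulation labels."""
    table, labels = simulate.simulate_expression(simulate.ExpressionSimConfig(seed=17))
    return table, labels


@pytest.fixture(scope="session")
def random_histories():
    """A batch of small seeded histories with their truth maps."""
    out = []
    for seed in range(40):
        cfg = simulate.HistorySimConfig(n_genes=50, n_releases=5, seed=seed)
        out.append(simulate.simulate_history(cfg))
    return out
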