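import numpy as np
import pytest

from popscale.simulate import simulate_rates, simulate_scores


@pytest.fixture(scope="session")
def small_table():
    """A small synthetic score table shared by read-only tests."""
    scores, truth = simulate_scores(
        n_genes=50, variants_per_gene=20, base_correlation=0.5, seed=11
    )
    return scores, truth


@pytest.fixture(scope="session")
def small_rates(small_table):
    scores, _ = small_table
    return simulate_rates(scores, total_mu=0.35, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
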