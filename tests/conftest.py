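import numpy as np
import pytest

from adapt_daa import (
    AdaptConfig,
    CountTable,
    ScenarioConfig,
    censor,
    make_toy_example,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array([[5, 0], [3, 2], [0, 10]])
    return CountTable(counts, ["tA", "tB", "tC"], ["s1", "s2"])


@pytest.fixture
def toy():
    return make_toy_example()


@pytest.fixture
def null_dataset():
    """A seeded global-null simulated dataset (no DA taxa)."""
    cfg = ScenarioConfig(n_taxa=60, n_samples=50, da_proportion=0.0)
    return simulate_dataset(cfg, seed=7)


@pytest.fixture
def da_dataset():
    """A seeded dataset with a 10% unbalanced DA minority."""
    cfg = ScenarioConfig(
        n_taxa=60,
        n_samples=100,
        da_proportion=0.1,
        mean_fold_change=5.0,
        direction="unbalanced",
        mean_library_size=2e4,
    )
    return simulate_dataset(cfg, seed=11)


@pytest.fixture
def quick_config():
    return AdaptConfig()
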