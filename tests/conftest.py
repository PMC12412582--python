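import numpy as np
import pytest

from polyorigin.simulate import (
    SimConfig,
    simulate_depth,
    simulate_offspring,
    simulate_parents,
    simulate_snp_observations,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale config: 6 groups of 60 kb, 2/4 kb windows."""
    return SimConfig(
        seed=11,
        n_groups=6,
        group_length=60_000,
        depth_window=2_000,
        score_window=4_000,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    parents = simulate_parents(small_cfg)
    offspring, truth = simulate_offspring(parents, small_cfg)
    return parents, offspring, truth


@pytest.fixture(scope="session")
def small_observations(small_cfg, small_sim):
    parents, offspring, truth = small_sim
    depth = simulate_depth(offspring, truth, small_cfg)
    alleles = simulate_snp_observations(parents, offspring, small_cfg)
    return depth, alleles


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
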