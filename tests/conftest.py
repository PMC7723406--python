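import numpy as np
import pytest

import radmut


@pytest.fixture(scope="session")
def three_taxon_tree():
    """The worked 3-taxon chronogram: ((A:1,B:1):1,C:2);"""
    return radmut.parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial simulation configuration."""
    return radmut.SimulationConfig(
        n_pairs=3, n_extra=1, n_genes=40, sites_per_gene=30, theta=0.05, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return radmut.simulate_dataset(small_config)


def random_ultrametric_tree(rng, n_pairs=3, n_extra=1, depth=1.0):
    cfg = radmut.SimulationConfig(
        n_pairs=n_pairs, n_extra=n_extra, tree_depth=depth,
        seed=int(rng.integers(2**31)),
    )
    return radmut.simulate_pair_tree(cfg)
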