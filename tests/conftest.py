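import dendropy
import numpy as np
import pandas as pd
import pytest

from thermodiv.bisse import RateParams
from thermodiv.datasets import (SimBisseConfig, SimCommunityConfig,
                                generate_community, simulate_bisse_tree)


def newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick")


@pytest.fixture
def toy_tree():
    """The hand-integrable 3-tip tree."""
    return newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_community():
    """Planted specialist/generalist community at the default design:
    8 groups x 7 replicates, noiseless detection."""
    cfg = SimCommunityConfig(seed=1234)
    return generate_community(cfg)


@pytest.fixture(scope="session")
def yule_tree40():
    tree, states = simulate_bisse_tree(SimBisseConfig(
        rates=RateParams(1, 1, 0, 0, 0, 0), n_tips_target=40, seed=3))
    return tree, states


def toy_2x2_table():
    """2 groups x 2 samples with one species occupying exactly 2 samples."""
    table = pd.DataFrame(
        {"G1R1": [5], "G1R2": [0], "G2R1": [3], "G2R2": [0]},
        index=pd.Index(["sp1"], name="species"))
    meta = pd.DataFrame({
        "sample_id": ["G1R1", "G1R2", "G2R1", "G2R2"],
        "group": ["G1", "G1", "G2", "G2"],
        "temperature_C": [80.0, 80.0, 60.0, 60.0],
        "replicate": [1, 2, 1, 2],
    })
    return table, meta


@pytest.fixture
def toy_occupancy():
    return toy_2x2_table()


def rng_seeds(n, seed):
    return np.random.default_rng(seed).integers(2 ** 31, size=n)
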