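import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from airwaytopo.synthetic import TreeGenParams, generate_airway_tree


def random_graph_tree(rng, n_nodes=50):
    """A random combinatorial tree with random embedded positions: node k's
    parent is uniform among earlier nodes.  Used by the persistence oracles
    (structure matters, geometry is free)."""
    from airwaytopo import AirwayTree

    parents = [-1] + [int(rng.integers(0, k)) + 1 for k in range(1, n_nodes)]
    ids = np.arange(1, n_nodes + 1)
    pos = rng.normal(size=(n_nodes, 3)) * 20
    return AirwayTree(ids=ids, positions=pos, parent_ids=np.asarray(parents))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_tree():
    """A small seeded synthetic airway tree with its event log."""
    return generate_airway_tree(
        TreeGenParams(generations=4, upward_turn_rate=0.8, seed=42)
    )
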