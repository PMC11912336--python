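import numpy as np
import pytest

from toxgat import gat_net
from toxgat.mol_graph import featurize
from toxgat.protocols import run_transfer_protocol


@pytest.fixture(scope="session")
def small_config():
    return gat_net.ModelConfig(embed_dim=16, n_conv_layers=2, n_global_heads=4)


@pytest.fixture(scope="session")
def random_model(small_config):
    """Untrained (fixed random weights) regression model."""
    return gat_net.init_model(small_config, seed=123)


@pytest.fixture(scope="session")
def random_classifier():
    config = gat_net.ModelConfig(
        embed_dim=16, n_conv_layers=2, n_global_heads=4,
        head_kind="binary-classification",
    )
    return gat_net.init_model(config, seed=321)


@pytest.fixture(scope="session")
def benzene():
    return featurize("c1ccccc1")


@pytest.fixture(scope="session")
def ethanol():
    return featurize("CCO")


@pytest.fixture(scope="session")
def path7():
    return featurize("CCCCCCC")


@pytest.fixture(scope="session")
def transfer_runs():
    """Five seeded desk-scale transfer-protocol runs (shared; ~4 min)."""
    return [run_transfer_protocol(seed) for seed in range(5)]


def permute_graph(graph, perm):
    """Relabel atoms of a MoleculeGraph by permutation ``perm`` (new = perm[old])."""
    from toxgat.mol_graph import MoleculeGraph

    perm = np.asarray(perm)
    m = graph.num_atoms
    inv = np.empty(m, dtype=int)
    inv[perm] = np.arange(m)
    node_features = graph.node_features[inv]
    adjacency = graph.adjacency[np.ix_(inv, inv)]
    bond_list = [tuple(sorted((int(perm[i]), int(perm[j]))))
                 for (i, j) in graph.bond_list]
    return MoleculeGraph(
        smiles=graph.smiles,
        node_features=node_features,
        bond_list=bond_list,
        bond_features=graph.bond_features.copy(),
        adjacency=adjacency,
    )
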