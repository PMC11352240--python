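import numpy as np
import pytest

from d3ns.data_io import MutationMatrix
from d3ns.network import GeneNetwork, build_transition_matrix
from d3ns.synthetic_data import SyntheticSpec, generate


@pytest.fixture
def chain_network():
    """A - B - C chain with unit scores."""
    net = GeneNetwork(edges={})
    net.add_edge("A", "B", 1.0)
    net.add_edge("B", "C", 1.0)
    return net


@pytest.fixture
def chain_W(chain_network):
    return build_transition_matrix(chain_network, ["A", "B", "C"])


@pytest.fixture
def single_patient_chain():
    return MutationMatrix(
        patients=["P1"], genes=["A", "B", "C"], values=np.array([[1, 0, 0]])
    )


def small_spec(**overrides) -> SyntheticSpec:
    """Desk-scale synthetic cohort: 80 patients x 600 genes, 3 subtypes."""
    params = dict(
        n_patients=80,
        n_genes=600,
        k_true=3,
        module_size=10,
        modules_per_subtype=2,
        p_in=0.4,
        p_out=0.02,
        p_driver=0.2,
        target_sparsity=0.97,
        hazards=(0.06, 0.03, 0.015),
        seed=7,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


@pytest.fixture(scope="session")
def small_cohort():
    return generate(small_spec())


def random_transition(rng: np.random.Generator, n_genes: int):
    """Random undirected graph on n_genes nodes and its row-walk operator."""
    names = [f"g{i}" for i in range(n_genes)]
    net = GeneNetwork(edges={})
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < 0.3:
                net.add_edge(names[i], names[j], float(rng.random()))
    return names, net, build_transition_matrix(net, names)
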