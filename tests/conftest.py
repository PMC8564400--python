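import numpy as np
import pytest

from hexconn.connect import ConnectivityGraph
from hexconn.geometry import LatticeSpec
from hexconn.simulate import Cell, CircuitAnnotation


@pytest.fixture
def spec55() -> LatticeSpec:
    """The culture condition: L = 55 μm hexagons, D = 70 μm gaps."""
    return LatticeSpec(edge_length_L=55.0, gap_D=70.0, rows=10, cols=10)


def make_cell(cell_id, soma_pattern, dendrites, axons, soma_point=(0.0, 0.0)):
    return Cell(
        cell_id=cell_id,
        soma_point=soma_point,
        soma_pattern=soma_pattern,
        dendrite_patterns=frozenset(dendrites),
        axon_patterns=frozenset(axons),
    )


def annotation_of(*cells) -> CircuitAnnotation:
    return CircuitAnnotation(cells=tuple(cells))


def graph_from_edges(nodes, edges) -> ConnectivityGraph:
    return ConnectivityGraph(nodes=frozenset(nodes), edges=frozenset(edges))


def graph_from_adj(adj: np.ndarray) -> ConnectivityGraph:
    n = adj.shape[0]
    edges = {(i, j) for i in range(n) for j in range(n) if i != j and adj[i, j]}
    return ConnectivityGraph(nodes=frozenset(range(n)), edges=frozenset(edges))


def random_graph(rng: np.random.Generator, n: int, p: float) -> ConnectivityGraph:
    adj = rng.random((n, n)) < p
    np.fill_diagonal(adj, False)
    return graph_from_adj(adj)
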