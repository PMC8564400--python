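"""Connectome reconstruction from pattern co-occupancy.

Two neurons are considered synaptically connected when the axon of one and
the dendrites of the other occupy the same hexagonal pattern; the edge is
directed presynaptic → postsynaptic.  Because the repulsive gap confines
neurites to patterns, co-occupancy is a reliable proxy for synapse
formation (>90% of co-occupied patterns show synaptic markers), so the
reconstruction applies the rule deterministically — stochasticity belongs
to the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ConnectivityGraph:
    """Simple directed graph of cells.

    ``edges`` are ordered (pre, post) pairs; multiplicity of shared patterns
    is folded into ``evidence`` (edge → frozenset of contact patterns).
    """

    nodes: frozenset
    edges: frozenset
    evidence: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for pre, post in self.edges:
            if pre not in self.nodes or post not in self.nodes:
                raise ValueError(f"edge ({pre}, {post}) references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def successors(self, node) -> set:
        return {post for pre, post in self.edges if pre == node}

    def predecessors(self, node) -> set:
        return {pre for pre, post in self.edges if post == node}

    def adjacency(self, order=None):
        """Dense boolean adjacency matrix and the node order used."""
        import numpy as np

        order = sorted(self.nodes) if order is None else list(order)
        pos = {n: i for i, n in enumerate(order)}
        a = np.zeros((len(order), len(order)), dtype=bool)
        for pre, post in self.edges:
            a[pos[pre], pos[post]] = True
        return a, order

    def transpose(self) -> "ConnectivityGraph":
        return ConnectivityGraph(
            nodes=self.nodes,
            edges=frozenset((b, a) for a, b in self.edges),
            evidence={(b, a): ev for (a, b), ev in self.evidence.items()},
        )


def build_graph(annotation, keep_self_loops: bool = False) -> ConnectivityGraph:
    """Apply the contact rule to an annotation.

    Edge i → j exists for every ordered pair i ≠ j whose axon(i) and
    dendrite(j) pattern sets intersect; the intersection is retained as edge
    evidence.  Autapses (a cell's own axon meeting its own dendrites) are
    excluded unless ``keep_self_loops`` — the downstream path and motif
    machinery presupposes distinct nodes.
    """
    ids = [c.cell_id for c in annotation.cells]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate cell_id in annotation")

    # index dendrite occupancy by pattern to avoid the full quadratic scan
    dend_at: dict = {}
    for c in annotation.cells:
        for p in c.dendrite_patterns:
            dend_at.setdefault(p, []).append(c)

    evidence: dict = {}
    for pre in annotation.cells:
        for p in pre.axon_patterns:
            for post in dend_at.get(p, ()):
                if pre.cell_id == post.cell_id and not keep_self_loops:
                    continue
                key = (pre.cell_id, post.cell_id)
                evidence.setdefault(key, set()).add(p)

    edges = frozenset(evidence)
    evidence = {k: frozenset(v) for k, v in evidence.items()}
    return ConnectivityGraph(nodes=frozenset(ids), edges=edges, evidence=evidence)


def components(graph: ConnectivityGraph) -> dict:
    """Split a graph into network segments and isolated nodes.

    Segments are weakly connected components of size ≥ 2, ordered by size
    descending with ties broken by smallest member id; nodes with no edges
    are reported separately as isolated.
    """
    undirected: dict = {n: set() for n in graph.nodes}
    for a, b in graph.edges:
        undirected[a].add(b)
        undirected[b].add(a)

    seen: set = set()
    comps: list[frozenset] = []
    for start in graph.nodes:
        if start in seen:
            continue
        stack, comp = [start], {start}
        seen.add(start)
        while stack:
            u = stack.pop()
            for v in undirected[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    stack.append(v)
        comps.append(frozenset(comp))

    segments = [c for c in comps if len(c) >= 2]
    segments.sort(key=lambda c: (-len(c), min(c)))
    isolated = frozenset().union(*[c for c in comps if len(c) == 1]) if any(
        len(c) == 1 for c in comps
    ) else frozenset()
    return {"segments": segments, "isolated": isolated}


def subgraph(graph: ConnectivityGraph, nodes) -> ConnectivityGraph:
    """Induced subgraph on a node subset."""
    nodes = frozenset(nodes)
    edges = frozenset((a, b) for a, b in graph.edges if a in nodes and b in nodes)
    ev = {e: graph.evidence[e] for e in edges if e in graph.evidence}
    return ConnectivityGraph(nodes=nodes, edges=edges, evidence=ev)
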