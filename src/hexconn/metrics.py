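"""Directed-graph statistics of reconstructed circuits.

Degrees, eccentricity, closeness and betweenness centrality on the
unweighted directed connectome, plus the hub-role tagging used to pick out
integrator/distributor hubs, pacemaker (driver) cells, bottlenecks and
connector hubs.

Conventions for fragmented directed graphs (the reconstructed cultures are
mostly collections of small segments):

* distances are hop counts; unreachable pairs carry the ``UNREACHABLE``
  sentinel (infinity) and are excluded from sums,
* closeness of node n is R(n) / Σ d(n, m) over the R(n) nodes reachable
  from n, and exactly 0 for an isolated node — so a node one hop from its
  whole reachable set scores 1,
* betweenness is directed, endpoint-excluding and unnormalized,
* eccentricity of a node that reaches nothing is 0; radius and diameter
  are taken over nodes with finite positive eccentricity.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .connect import ConnectivityGraph

UNREACHABLE = np.inf


@dataclass(frozen=True)
class PathStats:
    """All-pairs shortest-path structure of an unweighted digraph.

    ``dist[i, j]`` is the hop count of the shortest directed path from node
    ``order[i]`` to ``order[j]`` (``UNREACHABLE`` if none); ``sigma[i, j]``
    counts the distinct shortest paths.
    """

    order: tuple
    dist: np.ndarray
    sigma: np.ndarray

    def sigma_through(self, s: int, t: int, n: int) -> float:
        """Number of shortest s→t paths passing through interior node n."""
        if n in (s, t):
            raise ValueError("n must differ from both endpoints")
        d = self.dist
        if not np.isfinite(d[s, t]):
            return 0.0
        if d[s, n] + d[n, t] == d[s, t]:
            return float(self.sigma[s, n] * self.sigma[n, t])
        return 0.0


@dataclass
class NodeMetrics:
    k_in: int
    k_out: int
    eccentricity: int
    closeness: float
    betweenness: float
    tags: set = field(default_factory=set)


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float
    density_std: float
    radius: int | None
    diameter: int | None


def shortest_paths(graph: ConnectivityGraph) -> PathStats:
    """BFS from every node, accumulating shortest-path counts layer by layer."""
    adj, order = graph.adjacency()
    n = len(order)
    succ = [np.flatnonzero(adj[i]) for i in range(n)]
    dist = np.full((n, n), UNREACHABLE)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in succ[u]:
                if not np.isfinite(dist[s, v]):
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
                if dist[s, v] == dist[s, u] + 1:
                    sigma[s, v] += sigma[s, u]
    return PathStats(order=tuple(order), dist=dist, sigma=sigma)


def node_metrics(graph: ConnectivityGraph, stats: PathStats | None = None) -> dict:
    """Per-node degree, eccentricity and centrality values (no tags yet)."""
    if stats is None:
        stats = shortest_paths(graph)
    order = stats.order
    pos = {node: i for i, node in enumerate(order)}
    n = len(order)
    d, sigma = stats.dist, stats.sigma

    k_in = {node: 0 for node in order}
    k_out = {node: 0 for node in order}
    for pre, post in graph.edges:
        k_out[pre] += 1
        k_in[post] += 1

    out: dict = {}
    for node in order:
        i = pos[node]
        row = d[i]
        reach = np.isfinite(row)
        reach[i] = False
        r_n = int(reach.sum())
        ecc = int(row[reach].max()) if r_n else 0
        closeness = r_n / float(row[reach].sum()) if r_n else 0.0
        out[node] = NodeMetrics(
            k_in=k_in[node], k_out=k_out[node],
            eccentricity=ecc, closeness=closeness, betweenness=0.0,
        )

    # betweenness from the stored path counts:
    # sigma_st(n) = sigma_sn * sigma_nt when n lies on a shortest s->t path
    finite = np.isfinite(d)
    for s in range(n):
        for t in range(n):
            if s == t or not finite[s, t] or sigma[s, t] == 0:
                continue
            on_path = finite[s, :] & finite[:, t] & (d[s, :] + d[:, t] == d[s, t])
            on_path[s] = on_path[t] = False
            if on_path.any():
                contrib = sigma[s, on_path] * sigma[on_path, t] / sigma[s, t]
                for j, c in zip(np.flatnonzero(on_path), contrib):
                    out[order[j]].betweenness += float(c)
    return out


def network_summary(graph: ConnectivityGraph, metrics: dict | None = None) -> NetworkSummary:
    """Whole-graph size, density and eccentricity range.

    Density follows the per-node-budget reading k/N with k = |E|; the
    standard directed density |E| / (N (N−1)) is carried alongside as
    ``density_std``.
    """
    if graph.n_nodes == 0:
        raise ValueError("summary undefined for an empty graph")
    if metrics is None:
        metrics = node_metrics(graph)
    n, e = graph.n_nodes, graph.n_edges
    eccs = [m.eccentricity for m in metrics.values() if m.eccentricity > 0]
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        density=e / n,
        density_std=e / (n * (n - 1)) if n > 1 else 0.0,
        radius=min(eccs) if eccs else None,
        diameter=max(eccs) if eccs else None,
    )


DEFAULT_THRESHOLDS = {"deg_hi": 5, "closeness_q": 0.9, "betweenness_q": 0.9}


def classify_hubs(metrics: dict, thresholds: dict | None = None) -> dict:
    """Tag hub roles in place and return the metrics dict.

    A node is an integrator (distributor) hub when its in- (out-) degree
    reaches ``deg_hi``; a pacemaker is a distributor hub whose closeness is
    in the top quantile; a bottleneck has top-quantile positive betweenness;
    a connector is a bottleneck that also distributes widely.  Degree
    cut-offs are per-network in practice ("4 or 5 depending on the
    network"), hence configurable.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if not metrics:
        return metrics
    deg_hi = th["deg_hi"]
    clos = np.array([m.closeness for m in metrics.values()])
    betw = np.array([m.betweenness for m in metrics.values()])
    clos_hi = float(np.quantile(clos, th["closeness_q"]))
    betw_hi = float(np.quantile(betw, th["betweenness_q"]))

    for m in metrics.values():
        tags = set()
        if m.k_in >= deg_hi:
            tags.add("integrator_hub")
        if m.k_out >= deg_hi:
            tags.add("distributor_hub")
        if "distributor_hub" in tags and m.closeness >= clos_hi and m.closeness > 0:
            tags.add("pacemaker")
        if m.betweenness >= betw_hi and m.betweenness > 0:
            tags.add("bottleneck")
            if m.k_out >= deg_hi - 1:
                tags.add("connector")
        m.tags = tags
    return metrics
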