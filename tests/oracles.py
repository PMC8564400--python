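"""Independent reference implementations used only to check the package.

Everything here works by explicit enumeration (DFS over simple paths,
permutation search over triads) so it shares no machinery with the
BFS/sigma-accumulation and canonical-code implementations under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_shortest_paths(adj: np.ndarray, s: int, t: int):
    """All shortest directed s→t paths by exhaustive DFS over simple paths."""
    n = adj.shape[0]
    if s == t:
        return 0, [[s]]
    best: list[int] = [n + 1]
    found: list[list[int]] = []

    def dfs(node, path):
        if len(path) - 1 > best[0]:
            return
        for nxt in range(n):
            if adj[node, nxt] and nxt not in path:
                if nxt == t:
                    length = len(path)
                    if length < best[0]:
                        best[0] = length
                        found.clear()
                    if length == best[0]:
                        found.append(path + [t])
                else:
                    dfs(nxt, path + [nxt])

    dfs(s, [s])
    if not found:
        return None, []
    return best[0], found


def metrics_oracle(adj: np.ndarray):
    """Eccentricity, closeness and betweenness by brute-force path counting.

    Conventions match the package contract: closeness is the number of
    reachable nodes over the summed distances to them (0 when nothing is
    reachable); betweenness is directed, endpoint-excluding, unnormalized;
    eccentricity is the largest finite distance (0 if none).
    """
    n = adj.shape[0]
    dist = {}
    paths = {}
    for s in range(n):
        for t in range(n):
            d, ps = enumerate_shortest_paths(adj, s, t)
            dist[s, t] = d
            paths[s, t] = ps

    ecc = []
    clos = []
    for s in range(n):
        finite = [dist[s, t] for t in range(n) if t != s and dist[s, t] is not None]
        ecc.append(max(finite) if finite else 0)
        clos.append(len(finite) / sum(finite) if finite and sum(finite) else 0.0)

    betw = [0.0] * n
    for s in range(n):
        for t in range(n):
            if s == t or not paths[s, t]:
                continue
            total = len(paths[s, t])
            for node in range(n):
                if node in (s, t):
                    continue
                through = sum(1 for p in paths[s, t] if node in p[1:-1])
                betw[node] += through / total
    return ecc, clos, betw


def naive_triad_class(adj3: np.ndarray, representatives: dict[int, np.ndarray]):
    """Classify a 3-node adjacency by permutation search against representatives."""
    und = adj3 | adj3.T
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in range(3):
            if und[u, v] and v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) < 3:
        return None
    for cid, rep in representatives.items():
        for p in itertools.permutations(range(3)):
            if np.array_equal(adj3[np.ix_(p, p)], rep):
                return cid
    raise AssertionError("triad matched no representative")


def naive_motif_profile(adj: np.ndarray, representatives: dict[int, np.ndarray]):
    """Triad census by permutation-search isomorphism testing."""
    n = adj.shape[0]
    counts = {cid: 0 for cid in representatives}
    disconnected = 0
    for trio in itertools.combinations(range(n), 3):
        sub = adj[np.ix_(trio, trio)]
        cid = naive_triad_class(sub, representatives)
        if cid is None:
            disconnected += 1
        else:
            counts[cid] += 1
    return counts, disconnected
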