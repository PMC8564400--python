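"""Three-node motif (triad) census.

Every unordered triplet of nodes induces one of 64 labeled 3-node digraphs
(each of the three node pairs is absent, forward, backward or reciprocal).
Under node permutation these collapse to 16 isomorphism classes, 13 of
which are weakly connected — the motif alphabet of the census.  Classes are
numbered deterministically by ascending edge count with ties broken by
canonical adjacency code, then anchored so that the feedforward triangle
(A→B, B→C, A→C) is class 5 and the feedback 3-cycle (A→B→C→A) is class 6,
the two classes conventionally singled out in neural-circuit work.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .connect import ConnectivityGraph

#: census label for triads whose underlying undirected graph is disconnected
DISCONNECTED = 0

# ordered off-diagonal entries (i, j); bit 5 is (0,1), bit 0 is (2,1)
_PAIR_BITS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
_PERMS = list(itertools.permutations(range(3)))


@dataclass(frozen=True)
class TriadClass:
    class_id: int
    canonical_code: int
    n_edges: int
    members: frozenset  # all labeled codes in the class


def _code_of(adj: np.ndarray) -> int:
    code = 0
    for bit, (i, j) in enumerate(reversed(_PAIR_BITS)):
        if adj[i, j]:
            code |= 1 << bit
    return code


def _adj_of(code: int) -> np.ndarray:
    adj = np.zeros((3, 3), dtype=bool)
    for bit, (i, j) in enumerate(reversed(_PAIR_BITS)):
        if code >> bit & 1:
            adj[i, j] = True
    return adj


def _canonical(code: int) -> int:
    adj = _adj_of(code)
    return min(_code_of(adj[np.ix_(p, p)]) for p in _PERMS)


def _connected(code: int) -> bool:
    adj = _adj_of(code)
    und = adj | adj.T
    reach = {0}
    frontier = [0]
    while frontier:
        u = frontier.pop()
        for v in np.flatnonzero(und[u]):
            if v not in reach:
                reach.add(int(v))
                frontier.append(int(v))
    return len(reach) == 3


_FEEDFORWARD = _canonical(_code_of(np.array(
    [[0, 1, 1], [0, 0, 1], [0, 0, 0]], dtype=bool)))
_FEEDBACK = _canonical(_code_of(np.array(
    [[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=bool)))


def enumerate_classes() -> list[TriadClass]:
    """The 13 connected triad classes, numbered as described above.

    Brute force over all 64 labeled digraphs, grouped by canonical code
    (minimum over the 6 node permutations).
    """
    groups: dict[int, set[int]] = {}
    for code in range(64):
        groups.setdefault(_canonical(code), set()).add(code)

    connected = [c for c in groups if _connected(c)]
    connected.sort(key=lambda c: (bin(c).count("1"), c))

    # anchor the feedforward triangle at 5 and the cycle at 6 inside the
    # 3-edge block; remaining 3-edge classes fill slots 4 and 7 in order
    three_edge = [c for c in connected if bin(c).count("1") == 3]
    others = [c for c in three_edge if c not in (_FEEDFORWARD, _FEEDBACK)]
    reordered = (
        [c for c in connected if bin(c).count("1") == 2]
        + [others[0], _FEEDFORWARD, _FEEDBACK, others[1]]
        + [c for c in connected if bin(c).count("1") > 3]
    )
    return [
        TriadClass(
            class_id=i + 1,
            canonical_code=c,
            n_edges=bin(c).count("1"),
            members=frozenset(groups[c]),
        )
        for i, c in enumerate(reordered)
    ]


def _lookup_table() -> np.ndarray:
    """code (0..63) → class_id, DISCONNECTED for unconnected triads."""
    table = np.full(64, DISCONNECTED, dtype=np.int64)
    for cls in enumerate_classes():
        for code in cls.members:
            table[code] = cls.class_id
    return table


_LOOKUP = _lookup_table()


def classify_triad(sub_adjacency) -> int:
    """Class id (1–13) of a 3×3 induced adjacency, or DISCONNECTED."""
    adj = np.asarray(sub_adjacency, dtype=bool)
    if adj.shape != (3, 3):
        raise ValueError("sub_adjacency must be 3x3")
    if adj[np.diag_indices(3)].any():
        raise ValueError("triad adjacency must have a zero diagonal")
    return int(_LOOKUP[_code_of(adj)])


@dataclass(frozen=True)
class MotifProfile:
    counts: dict  # class_id 1..13 → count
    frequencies: dict  # counts / total connected triads
    n_disconnected_triads: int

    @property
    def n_connected_triads(self) -> int:
        return sum(self.counts.values())


def motif_profile(graph: ConnectivityGraph) -> MotifProfile:
    """Census of all C(N, 3) induced triads of a graph."""
    adj, order = graph.adjacency()
    n = len(order)
    counts = {cid: 0 for cid in range(1, 14)}
    n_disc = 0
    if n >= 3:
        triples = np.array(list(itertools.combinations(range(n), 3)))
        i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
        codes = (
            (adj[i, j].astype(np.int64) << 5)
            | (adj[i, k].astype(np.int64) << 4)
            | (adj[j, i].astype(np.int64) << 3)
            | (adj[j, k].astype(np.int64) << 2)
            | (adj[k, i].astype(np.int64) << 1)
            | adj[k, j].astype(np.int64)
        )
        ids, freq = np.unique(_LOOKUP[codes], return_counts=True)
        for cid, c in zip(ids, freq):
            if cid == DISCONNECTED:
                n_disc = int(c)
            else:
                counts[int(cid)] = int(c)
    total = sum(counts.values())
    freqs = {cid: (c / total if total else 0.0) for cid, c in counts.items()}
    return MotifProfile(counts=counts, frequencies=freqs, n_disconnected_triads=n_disc)
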