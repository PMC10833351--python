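"""Per-node graphlet orbit counting (graphlet degree vectors).

Graphlets are the nine connected *induced* subgraphs on 2-4 nodes
(G0 edge; G1 3-path, G2 triangle; G3 4-path, G4 3-star, G5 4-cycle,
G6 paw/tadpole, G7 diamond, G8 K4).  Their nodes fall into 15
automorphism classes — orbits 0..14 — and the graphlet degree vector (GDV)
of a node counts, per orbit, how many induced-subgraph occurrences touch
the node at that orbit.  Orbit 0 is the plain node degree.

Two counters are provided:

``count_orbits``
    The production counter.  Orbits 0-3 come from degree / common-neighbour
    identities; orbits 4-14 from a numba-compiled ESU enumeration of
    connected induced 4-node subgraphs, classified by their internal degree
    sequence.

``brute_force_orbits``
    A deliberately naive oracle: iterate every 2/3/4-node subset, test
    connectivity of the induced subgraph, classify.  Definitionally correct
    and kept entirely independent of the production code path; the two must
    agree entrywise on every graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from numba import njit

from .contact_graph import ContactGraph

__all__ = ["OrbitMatrix", "count_orbits", "brute_force_orbits", "N_ORBITS"]

N_ORBITS = 15

# orbit of a node given (subgraph size, sorted degree sequence, own degree);
# normative numbering follows the standard 2-4-node graphlet taxonomy
_ORBIT_OF_DEGREE = {
    (2, (1, 1)): {1: 0},
    (3, (1, 1, 2)): {1: 1, 2: 2},           # G1 path
    (3, (2, 2, 2)): {1: 3, 2: 3},           # G2 triangle (orbit 3 for all)
    (4, (1, 1, 2, 2)): {1: 4, 2: 5},        # G3 4-path: ends 4, middles 5
    (4, (1, 1, 1, 3)): {1: 6, 3: 7},        # G4 3-star: leaves 6, centre 7
    (4, (2, 2, 2, 2)): {2: 8},              # G5 4-cycle
    (4, (1, 2, 2, 3)): {1: 9, 2: 10, 3: 11},  # G6 paw
    (4, (2, 2, 3, 3)): {2: 12, 3: 13},      # G7 diamond
    (4, (3, 3, 3, 3)): {3: 14},             # G8 K4
}
_ORBIT_OF_DEGREE[(3, (2, 2, 2))] = {2: 3}

#: number of nodes of the parent graphlet lying on each orbit
ORBIT_MULTIPLICITY = {
    0: 2, 1: 2, 2: 1, 3: 3, 4: 2, 5: 2, 6: 3, 7: 1,
    8: 4, 9: 1, 10: 2, 11: 1, 12: 2, 13: 2, 14: 4,
}

#: parent graphlet (G index) of each orbit
ORBIT_GRAPHLET = {
    0: 0, 1: 1, 2: 1, 3: 2, 4: 3, 5: 3, 6: 4, 7: 4,
    8: 5, 9: 6, 10: 6, 11: 6, 12: 7, 13: 7, 14: 8,
}


@dataclass
class OrbitMatrix:
    """N x 15 matrix of orbit degrees; rows follow the graph's node order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[1] != N_ORBITS:
            raise ValueError(f"orbit matrix must have {N_ORBITS} columns")
        if v.size and (np.any(v < 0) or not np.issubdtype(v.dtype, np.integer)):
            raise ValueError("orbit degrees must be nonnegative integers")
        self.values = v.astype(np.int64)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_frame(self, model=None):
        """Orbit table as a DataFrame, optionally with atom identity columns."""
        import pandas as pd

        df = pd.DataFrame(self.values, columns=[f"O{k}" for k in range(N_ORBITS)])
        if model is not None:
            ident = pd.DataFrame(
                {
                    "chain": [a.chain_id for a in model.atoms],
                    "res_seq": [a.res_seq for a in model.atoms],
                    "atom_name": [a.atom_name for a in model.atoms],
                }
            )
            df = pd.concat([ident, df], axis=1)
        return df

    def to_tsv(self, path: str | Path, model=None) -> None:
        self.to_frame(model).to_csv(path, sep="\t", index=False)


@njit(cache=True)
def _has_edge(indptr, indices, u, v):  # pragma: no cover - numba
    lo, hi = indptr[u], indptr[u + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        if indices[mid] < v:
            lo = mid + 1
        elif indices[mid] > v:
            hi = mid
        else:
            return True
    return False


@njit(cache=True)
def _count_triangles(indptr, indices, tri):  # pragma: no cover - numba
    n = indptr.shape[0] - 1
    for i in range(n):
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if j <= i:
                continue
            # merge-intersect sorted neighbour lists, keep k > j so each
            # triangle {i < j < k} is found exactly once
            a, b = indptr[i], indptr[j]
            ea, eb = indptr[i + 1], indptr[j + 1]
            while a < ea and b < eb:
                u, v = indices[a], indices[b]
                if u < v:
                    a += 1
                elif u > v:
                    b += 1
                else:
                    if u > j:
                        tri[i] += 1
                        tri[j] += 1
                        tri[u] += 1
                    a += 1
                    b += 1


@njit(cache=True)
def _count_size4(indptr, indices, counts):  # pragma: no cover - numba
    """ESU enumeration of connected induced 4-node subgraphs.

    Each connected 4-set is generated exactly once (rooted at its minimum
    node, extensions restricted to larger indices and exclusive
    neighbourhoods); the induced subgraph is classified by edge count and
    degree sequence and every member node's orbit column is incremented.
    """
    n = indptr.shape[0] - 1
    maxdeg = 0
    for v in range(n):
        d = indptr[v + 1] - indptr[v]
        if d > maxdeg:
            maxdeg = d
    cap = 3 * maxdeg + 4
    ext1 = np.empty(cap, np.int64)
    ext2 = np.empty(cap, np.int64)
    ext3 = np.empty(cap, np.int64)
    sub = np.empty(4, np.int64)
    deg = np.empty(4, np.int64)
    for v in range(n):
        n1 = 0
        for p in range(indptr[v], indptr[v + 1]):
            u = indices[p]
            if u > v:
                ext1[n1] = u
                n1 += 1
        for i1 in range(n1):
            w1 = ext1[i1]
            n2 = 0
            for t in range(i1 + 1, n1):
                ext2[n2] = ext1[t]
                n2 += 1
            for p in range(indptr[w1], indptr[w1 + 1]):
                u = indices[p]
                if u > v and not _has_edge(indptr, indices, v, u):
                    ext2[n2] = u
                    n2 += 1
            for i2 in range(n2):
                w2 = ext2[i2]
                n3 = 0
                for t in range(i2 + 1, n2):
                    ext3[n3] = ext2[t]
                    n3 += 1
                for p in range(indptr[w2], indptr[w2 + 1]):
                    u = indices[p]
                    if (
                        u > v
                        and u != w1
                        and not _has_edge(indptr, indices, v, u)
                        and not _has_edge(indptr, indices, w1, u)
                    ):
                        ext3[n3] = u
                        n3 += 1
                for i3 in range(n3):
                    sub[0] = v
                    sub[1] = w1
                    sub[2] = w2
                    sub[3] = ext3[i3]
                    e = 0
                    for a in range(4):
                        deg[a] = 0
                    for a in range(4):
                        for b in range(a + 1, 4):
                            if _has_edge(indptr, indices, sub[a], sub[b]):
                                e += 1
                                deg[a] += 1
                                deg[b] += 1
                    if e == 3:
                        star = deg[0] == 3 or deg[1] == 3 or deg[2] == 3 or deg[3] == 3
                        for a in range(4):
                            if star:
                                counts[sub[a], 7 if deg[a] == 3 else 6] += 1
                            else:
                                counts[sub[a], 5 if deg[a] == 2 else 4] += 1
                    elif e == 4:
                        cycle = (
                            deg[0] == 2 and deg[1] == 2 and deg[2] == 2 and deg[3] == 2
                        )
                        for a in range(4):
                            if cycle:
                                counts[sub[a], 8] += 1
                            elif deg[a] == 1:
                                counts[sub[a], 9] += 1
                            elif deg[a] == 2:
                                counts[sub[a], 10] += 1
                            else:
                                counts[sub[a], 11] += 1
                    elif e == 5:
                        for a in range(4):
                            counts[sub[a], 12 if deg[a] == 2 else 13] += 1
                    else:
                        for a in range(4):
                            counts[sub[a], 14] += 1


def count_orbits(graph: ContactGraph) -> OrbitMatrix:
    """Count all 15 orbit degrees for every node of the graph."""
    n = graph.n_nodes
    counts = np.zeros((n, N_ORBITS), dtype=np.int64)
    if n == 0 or graph.n_edges == 0:
        return OrbitMatrix(counts)
    indptr, indices = graph.csr()
    d = graph.degrees

    counts[:, 0] = d
    tri = np.zeros(n, dtype=np.int64)
    _count_triangles(indptr, indices, tri)
    counts[:, 3] = tri
    # orbit 2: centre of an induced 3-path = neighbour pairs minus triangles
    counts[:, 2] = d * (d - 1) // 2 - tri
    # orbit 1: end of an induced 3-path
    s = np.zeros(n, dtype=np.int64)
    e = graph.edges
    np.add.at(s, e[:, 0], d[e[:, 1]])
    np.add.at(s, e[:, 1], d[e[:, 0]])
    counts[:, 1] = s - d - 2 * tri

    _count_size4(indptr, indices, counts)
    return OrbitMatrix(counts)


def brute_force_orbits(graph: ContactGraph, max_nodes: int = 40) -> OrbitMatrix:
    """Oracle counter by exhaustive induced-subgraph enumeration.

    Refuses graphs above *max_nodes* (the subset count is combinatorial).
    """
    n = graph.n_nodes
    if n > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes, got {n}")
    adj = [0] * n
    for i, j in graph.edges:
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    counts = np.zeros((n, N_ORBITS), dtype=np.int64)
    for size in (2, 3, 4):
        for nodes in combinations(range(n), size):
            mask = 0
            for v in nodes:
                mask |= 1 << v
            # connectivity of the induced subgraph by bitmask expansion
            reach = 1 << nodes[0]
            for _ in range(size - 1):
                grow = reach
                for v in nodes:
                    if adj[v] & reach:
                        grow |= 1 << v
                reach = grow
            if reach & mask != mask:
                continue
            degs = tuple((adj[v] & mask).bit_count() for v in nodes)
            table = _ORBIT_OF_DEGREE[(size, tuple(sorted(degs)))]
            for v, dv in zip(nodes, degs):
                counts[v, table[dv]] += 1
    return OrbitMatrix(counts)
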