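"""Atom contact graphs.

A structure is turned into a simple undirected graph: atoms are nodes and an
edge joins two atoms whose centre-to-centre distance is strictly below the
cutoff.  Environment atoms are ordinary nodes here; they are filtered out
only when the regression rows are assembled.

Neighbour search uses a k-d tree; correctness against the all-pairs check is
part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureModel

__all__ = ["ContactGraph", "build_contact_graph", "neighbors_within"]

#: default cutoff for the GDV model graph, Å
GDV_CUTOFF = 5.0
#: default cutoff for the contact (number-of-contacts) model graph, Å
CONTACT_CUTOFF = 7.0


@dataclass
class ContactGraph:
    """Simple undirected graph over atom indices.

    ``edges`` is an (m, 2) integer array with ``edges[:, 0] < edges[:, 1]``,
    sorted lexicographically; node indices follow the atom order of the
    originating :class:`~gdvb.structure_io.StructureModel`.
    """

    n_nodes: int
    edges: np.ndarray
    cutoff: float | None = None
    _adj: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size:
            lo = np.minimum(e[:, 0], e[:, 1])
            hi = np.maximum(e[:, 0], e[:, 1])
            if np.any(lo == hi):
                raise ValueError("self-loops are not allowed")
            if lo.min() < 0 or hi.max() >= self.n_nodes:
                raise ValueError("edge index out of range")
            e = np.unique(np.column_stack([lo, hi]), axis=0)
        self.edges = e

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(d, self.edges[:, 0], 1)
            np.add.at(d, self.edges[:, 1], 1)
        return d

    def adjacency(self) -> list[np.ndarray]:
        """Sorted neighbour array per node (cached)."""
        if self._adj is None:
            nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, j in self.edges:
                nbrs[i].append(j)
                nbrs[j].append(i)
            self._adj = [np.array(sorted(n), dtype=np.int64) for n in nbrs]
        return self._adj

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) compressed adjacency with sorted neighbours."""
        adj = self.adjacency()
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        for i, a in enumerate(adj):
            indptr[i + 1] = indptr[i] + len(a)
        indices = (
            np.concatenate(adj) if self.n_nodes and indptr[-1] else np.empty(0, np.int64)
        )
        return indptr, indices.astype(np.int64)

    def write_edge_list(self, path: str | Path) -> None:
        """Dump edges as two whitespace-separated 0-based index columns."""
        with open(path, "w") as fh:
            for i, j in self.edges:
                fh.write(f"{i} {j}\n")


def _check_coordinates(model: StructureModel) -> np.ndarray:
    xyz = model.coordinates
    bad = ~np.all(np.isfinite(xyz), axis=1)
    if bad.any():
        a = model.atoms[int(np.flatnonzero(bad)[0])]
        raise ValueError(
            f"non-finite coordinate for atom {a.chain_id}/{a.res_seq}/{a.atom_name}"
        )
    return xyz


def build_contact_graph(model: StructureModel, cutoff: float = GDV_CUTOFF) -> ContactGraph:
    """Build the contact graph: edge (i, j) iff distance(i, j) < cutoff.

    The inequality is strict; a pair at exactly the cutoff distance is not
    connected.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(model.atoms) == 0:
        raise ValueError("model has no atoms")
    xyz = _check_coordinates(model)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]  # query_pairs is inclusive at r
    return ContactGraph(n_nodes=len(model.atoms), edges=pairs, cutoff=cutoff)


def neighbors_within(model: StructureModel, radius: float) -> list[np.ndarray]:
    """Indices of other atoms at distance <= radius of each atom (inclusive).

    Used by feature smoothing; note the inclusive boundary, in contrast to
    the strict cutoff of the contact graph.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    xyz = _check_coordinates(model)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    out: list[list[int]] = [[] for _ in range(len(model.atoms))]
    for i, j in pairs:
        out[i].append(j)
        out[j].append(i)
    return [np.array(sorted(n), dtype=np.int64) for n in out]
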