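"""Cell neighborhood graphs for multicell simulations.

The neighbor mean ``<X_j>_i`` used by the circuit equations is a weighted
average over the neighbors of cell *i*; the graph stores the row-normalized
weight matrix ``W`` so that ``<X>` = W @ X``.  Periodic hexagonal (6-regular)
and square (4-regular) lattices are provided; arbitrary weighted graphs (for
example the contact-length graphs of the Potts crypt) use the CUSTOM
topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["Topology", "NeighborGraph", "build_lattice", "checkerboard_score"]


class Topology(Enum):
    HEX_PERIODIC = "hex_periodic"
    SQUARE_PERIODIC = "square_periodic"
    CUSTOM = "custom"


@dataclass(frozen=True)
class NeighborGraph:
    """Weighted adjacency defining per-cell neighbor averaging.

    ``W`` is (n, n), nonnegative with rows summing to 1 (isolated cells have
    an all-zero row); the support of ``W`` must be symmetric.
    """

    W: np.ndarray
    topology: Topology = Topology.CUSTOM

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(W) != 0):
            raise ValueError("cells are not their own neighbors")
        rows = W.sum(axis=1)
        ok = np.isclose(rows, 1.0) | np.isclose(rows, 0.0)
        if not np.all(ok):
            raise ValueError("rows of W must sum to 1 (or 0 for isolated cells)")
        if not np.array_equal(W > 0, W.T > 0):
            raise ValueError("adjacency support must be symmetric")
        object.__setattr__(self, "W", W)

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return (self.W > 0).sum(axis=1)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges (i < j) of the adjacency support."""
        A = self.W > 0
        return [(i, j) for i in range(self.n_cells) for j in range(i + 1, self.n_cells) if A[i, j]]

    @classmethod
    def from_adjacency(cls, A: np.ndarray, topology: Topology = Topology.CUSTOM) -> "NeighborGraph":
        """Row-normalize a (possibly weighted) symmetric adjacency matrix."""
        A = np.asarray(A, dtype=float)
        rows = A.sum(axis=1)
        W = np.divide(A, rows[:, None], out=np.zeros_like(A), where=rows[:, None] > 0)
        return cls(W=W, topology=topology)

    @classmethod
    def pair(cls) -> "NeighborGraph":
        """Two mutually neighboring cells."""
        return cls(W=np.array([[0.0, 1.0], [1.0, 0.0]]), topology=Topology.CUSTOM)

    @classmethod
    def single_self_coupled(cls) -> "NeighborGraph":
        """One cell whose neighbor mean is its own state (homogeneous-state trick).

        Used to compute spatially uniform fixed points: on a vertex-transitive
        lattice every cell sees ``<X_j> = X`` at a homogeneous state.
        """
        g = cls.__new__(cls)
        object.__setattr__(g, "W", np.array([[1.0]]))
        object.__setattr__(g, "topology", Topology.CUSTOM)
        return g


def build_lattice(rows: int, cols: int, topology: Topology = Topology.HEX_PERIODIC) -> NeighborGraph:
    """Build a periodic lattice graph with uniform 1/degree weights.

    The hexagonal lattice uses axial coordinates on a torus: each cell
    (r, c) neighbors (r, c+-1), (r+-1, c), (r-1, c+1) and (r+1, c-1), giving
    a 6-regular graph.  ``rows`` and ``cols`` must be >= 3 so that periodic
    wrapping produces a simple regular graph.
    """
    if rows < 3 or cols < 3:
        raise ValueError("periodic lattices require rows, cols >= 3")
    n = rows * cols

    def idx(r: int, c: int) -> int:
        return (r % rows) * cols + (c % cols)

    if topology is Topology.HEX_PERIODIC:
        offsets = [(0, 1), (0, -1), (1, 0), (-1, 0), (-1, 1), (1, -1)]
    elif topology is Topology.SQUARE_PERIODIC:
        offsets = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    else:
        raise ValueError("build_lattice supports the periodic topologies only")

    A = np.zeros((n, n))
    for r in range(rows):
        for c in range(cols):
            i = idx(r, c)
            for dr, dc in offsets:
                A[i, idx(r + dr, c + dc)] = 1.0
    return NeighborGraph.from_adjacency(A, topology=topology)


def checkerboard_score(labels, graph: NeighborGraph) -> float:
    """Fraction of graph edges whose endpoints carry different labels.

    1.0 for a perfect two-coloring of a bipartite lattice, 0.0 for a uniform
    labeling, and about 0.5 for i.i.d. fair random labels.
    """
    labels = np.asarray(labels)
    edges = graph.edges()
    if not edges:
        raise ValueError("graph has no edges")
    diff = sum(1 for i, j in edges if labels[i] != labels[j])
    return diff / len(edges)
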