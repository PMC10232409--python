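"""Triangulated surface meshes and discrete geodesics.

The mesh is the substrate for every spatial operation in the pipeline:
atlas construction, boundary perturbation, patch extraction, and the
geodesic distances used by template matching and position variability.
Geodesic distance is defined as the shortest path over mesh edges with
Euclidean edge weights (a standard discrete approximation).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra


class ConfigurationError(ValueError):
    """Raised for infeasible or unknown configuration values."""


@dataclass(frozen=True)
class SurfaceMesh:
    """A triangulated surface with derived edge/adjacency structure.

    Parameters
    ----------
    coords : (V, 3) float array
        Vertex coordinates in arbitrary units.
    triangles : (F, 3) int array
        Vertex index triples; every edge must belong to >= 1 triangle.
    """

    coords: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        tris = np.asarray(self.triangles, dtype=np.int64)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "triangles", tris)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ConfigurationError("coords must be (V, 3)")
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise ConfigurationError("triangles must be (F, 3)")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) array with i < j."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [0, 2]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        d = self.coords[self.edges[:, 0]] - self.coords[self.edges[:, 1]]
        lengths = np.linalg.norm(d, axis=1)
        if np.any(lengths <= 0):
            raise ConfigurationError("degenerate mesh edge of length 0")
        return lengths

    @property
    def mean_edge_length(self) -> float:
        return float(self.edge_lengths.mean())

    @cached_property
    def adjacency(self) -> csr_matrix:
        """Sparse symmetric vertex adjacency weighted by edge length."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.edge_lengths
        n = self.n_vertices
        return csr_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )

    @cached_property
    def neighbors(self) -> list[np.ndarray]:
        """Per-vertex array of adjacent vertex indices."""
        adj = self.adjacency
        return [adj.indices[adj.indptr[v]: adj.indptr[v + 1]] for v in range(self.n_vertices)]

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1

    def geodesic_distances(self, sources=None) -> np.ndarray:
        """Shortest-path distances from ``sources`` (default: all vertices).

        Returns an (S, V) array, or (V, V) for all-pairs.
        """
        if sources is None:
            return dijkstra(self.adjacency, directed=False)
        sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
        return np.atleast_2d(dijkstra(self.adjacency, directed=False, indices=sources))

    def scaled(self, factor: float) -> "SurfaceMesh":
        """Return the same mesh with coordinates scaled by ``factor``."""
        return SurfaceMesh(self.coords * factor, self.triangles)


def _icosphere_for(n_vertices: int) -> SurfaceMesh:
    # icosphere vertex counts are 12, 42, 162, 642, 2562, ... = 10*4^s + 2;
    # pick the subdivision level whose count is closest to the request
    counts = [10 * 4 ** s + 2 for s in range(7)]
    s = int(np.argmin([abs(c - n_vertices) for c in counts]))
    m = trimesh.creation.icosphere(subdivisions=s, radius=1.0)
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


def _grid_mesh(n_vertices: int) -> SurfaceMesh:
    rows = max(2, int(round(np.sqrt(n_vertices))))
    cols = max(2, int(round(n_vertices / rows)))
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([jj.ravel(), ii.ravel(), np.zeros(rows * cols)]).astype(float)

    def v(i, j):
        return i * cols + j

    tris = []
    # standard diagonal split: every quad cut along the (i,j)-(i+1,j+1) diagonal
    for i in range(rows - 1):
        for j in range(cols - 1):
            tris.append((v(i, j), v(i, j + 1), v(i + 1, j + 1)))
            tris.append((v(i, j), v(i + 1, j + 1), v(i + 1, j)))
    return SurfaceMesh(coords, np.asarray(tris, dtype=np.int64))


def make_mesh(n_vertices: int, topology: str = "icosphere") -> SurfaceMesh:
    """Build a connected triangulated mesh with about ``n_vertices`` vertices.

    ``topology`` is ``"icosphere"`` (closed sphere, vertex counts snap to
    12/42/162/642/2562/...) or ``"grid"`` (flat rectangular sheet with a
    consistent diagonal split, so interior vertices have degree 6).
    Deterministic for fixed arguments.
    """
    if n_vertices < 12:
        raise ConfigurationError("n_vertices must be >= 12")
    if topology == "icosphere":
        return _icosphere_for(n_vertices)
    if topology == "grid":
        return _grid_mesh(n_vertices)
    raise ConfigurationError(f"unsupported topology: {topology!r}")
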