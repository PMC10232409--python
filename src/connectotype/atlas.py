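"""Population-level atlas: per-vertex network and ROI labels.

The atlas plays the role of a group-level functional parcellation: every
vertex carries one of ``n_networks`` fine network labels and one of
``n_rois`` ROI labels, each ROI is a connected patch nested inside exactly
one network, and the fine networks map onto 7 canonical networks.  ROIs
are grown as geodesic Voronoi cells around farthest-point-sampled seed
vertices, which yields compact connected patches of roughly even size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .mesh import ConfigurationError, SurfaceMesh

UNRECOGNIZED = 0  # ROI label reserved for vertices no matching rule could place


@dataclass(frozen=True)
class Atlas:
    """Per-vertex network (1..n_networks) and ROI (1..n_rois) labels.

    ``network_of_roi[r-1]`` gives the parent network of ROI ``r``;
    ``canonical_of_network[k-1]`` maps fine network ``k`` to one of the
    7 canonical networks.
    """

    network_of_vertex: np.ndarray
    roi_of_vertex: np.ndarray
    network_of_roi: np.ndarray
    canonical_of_network: np.ndarray

    @property
    def n_networks(self) -> int:
        return len(self.canonical_of_network)

    @property
    def n_rois(self) -> int:
        return len(self.network_of_roi)

    @property
    def n_vertices(self) -> int:
        return len(self.roi_of_vertex)

    def roi_vertices(self, roi: int) -> np.ndarray:
        return np.flatnonzero(self.roi_of_vertex == roi)

    def with_labels(self, roi_of_vertex: np.ndarray) -> "Atlas":
        """Same ROI/network structure, different per-vertex ROI labels.

        Network labels are re-derived from the ROI labels so the invariant
        roi -> network stays a function. Vertices labeled UNRECOGNIZED get
        network 0.
        """
        roi_of_vertex = np.asarray(roi_of_vertex, dtype=np.int64)
        net = np.zeros_like(roi_of_vertex)
        ok = roi_of_vertex > 0
        net[ok] = self.network_of_roi[roi_of_vertex[ok] - 1]
        return Atlas(net, roi_of_vertex, self.network_of_roi, self.canonical_of_network)


def label_components(mesh: SurfaceMesh, members: np.ndarray) -> int:
    """Number of connected components of a vertex set on the mesh graph."""
    members = np.asarray(members)
    if members.size == 0:
        return 0
    sub = mesh.adjacency[np.ix_(members, members)]
    n_comp, _ = connected_components(sub, directed=False)
    return n_comp


def farthest_point_sample(mesh: SurfaceMesh, k: int, seed: int) -> np.ndarray:
    """Deterministic farthest-point sampling of ``k`` seed vertices."""
    rng = np.random.default_rng(seed)
    first = int(rng.integers(mesh.n_vertices))
    seeds = [first]
    mind = mesh.geodesic_distances([first])[0]
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        seeds.append(nxt)
        mind = np.minimum(mind, mesh.geodesic_distances([nxt])[0])
    return np.asarray(seeds, dtype=np.int64)


def _voronoi_labels(mesh: SurfaceMesh, seeds: np.ndarray) -> np.ndarray:
    """Assign each vertex to its geodesically nearest seed (1-based label)."""
    d = mesh.geodesic_distances(seeds)  # (k, V)
    return np.argmin(d, axis=0).astype(np.int64) + 1


def _repair_components(mesh: SurfaceMesh, labels: np.ndarray) -> np.ndarray:
    """Reattach disconnected minority fragments of any label to a neighbor.

    Geodesic Voronoi cells are connected up to distance ties; on symmetric
    meshes ties can strand a few vertices.  Any non-largest component of a
    label is relabeled to the majority label among its graph neighbors.
    """
    labels = labels.copy()
    for _ in range(10):
        changed = False
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            sub = mesh.adjacency[np.ix_(members, members)]
            n_comp, comp = connected_components(sub, directed=False)
            if n_comp <= 1:
                continue
            sizes = np.bincount(comp)
            keep = int(np.argmax(sizes))
            for c in range(n_comp):
                if c == keep:
                    continue
                frag = members[comp == c]
                neigh_labels = np.concatenate([labels[mesh.neighbors[v]] for v in frag])
                neigh_labels = neigh_labels[neigh_labels != lab]
                if neigh_labels.size:
                    vals, counts = np.unique(neigh_labels, return_counts=True)
                    labels[frag] = vals[np.argmax(counts)]
                    changed = True
        if not changed:
            break
    return labels


def _ensure_min_size(mesh: SurfaceMesh, labels: np.ndarray, min_size: int) -> np.ndarray:
    """Grow undersized Voronoi cells by stealing adjacent vertices.

    The smallest cell repeatedly annexes a boundary vertex of its largest
    adjacent cell, provided the donor stays connected and above
    ``min_size``.  Deterministic: candidates are scanned in index order.
    """
    labels = labels.copy()
    for _ in range(20 * len(labels)):
        sizes = np.bincount(labels)
        small = [l for l in np.nonzero(sizes)[0] if l > 0 and sizes[l] < min_size]
        if not small:
            return labels
        lab = min(small, key=lambda l: (sizes[l], l))
        members = np.flatnonzero(labels == lab)
        # adjacent foreign vertices, preferring the largest donors
        cands = []
        for v in members:
            for u in mesh.neighbors[v]:
                if labels[u] != lab:
                    cands.append(int(u))
        cands = sorted(set(cands), key=lambda u: (-sizes[labels[u]], u))
        moved = False
        for u in cands:
            donor = labels[u]
            if sizes[donor] <= min_size:
                continue
            rest = np.flatnonzero(labels == donor)
            rest = rest[rest != u]
            sub = mesh.adjacency[np.ix_(rest, rest)]
            n_comp, _ = connected_components(sub, directed=False)
            if n_comp == 1:
                labels[u] = lab
                moved = True
                break
        if not moved:
            raise ConfigurationError("could not balance ROI sizes; reduce n_rois")
    raise ConfigurationError("ROI size balancing did not converge")


def make_atlas(mesh: SurfaceMesh, n_networks: int = 18, n_rois: int = 116,
               seed: int = 0) -> Atlas:
    """Build a population atlas of connected ROI patches grouped into networks.

    ROIs are geodesic Voronoi cells around ``n_rois`` farthest-point seeds;
    each ROI joins the network of its geodesically nearest network seed
    (the first ``n_networks`` ROI seeds).  Fine networks map onto 7
    canonical networks in contiguous blocks.  Deterministic in ``seed``.
    """
    if n_rois < n_networks:
        raise ConfigurationError("n_rois must be >= n_networks")
    if n_rois > mesh.n_vertices // 4:
        raise ConfigurationError(
            f"n_rois={n_rois} infeasible on {mesh.n_vertices} vertices (need >= 4 per ROI)"
        )
    if n_rois == 1:
        V = mesh.n_vertices
        return Atlas(np.ones(V, dtype=np.int64), np.ones(V, dtype=np.int64),
                     np.ones(1, dtype=np.int64), np.ones(n_networks, dtype=np.int64))

    roi_seeds = farthest_point_sample(mesh, n_rois, seed)
    roi_labels = _repair_components(mesh, _voronoi_labels(mesh, roi_seeds))
    roi_labels = _ensure_min_size(mesh, roi_labels, min_size=4)
    # renumber in case a repair emptied a label (does not happen in practice,
    # but keeps labels dense 1..n)
    uniq = np.unique(roi_labels)
    if len(uniq) != n_rois:
        raise ConfigurationError("atlas construction produced an empty ROI; change seed")

    net_seeds = roi_seeds[:n_networks]
    d = mesh.geodesic_distances(net_seeds)  # (n_networks, V)
    network_of_roi = np.empty(n_rois, dtype=np.int64)
    for r in range(1, n_rois + 1):
        sv = roi_seeds[r - 1]
        network_of_roi[r - 1] = int(np.argmin(d[:, sv])) + 1
    network_of_vertex = network_of_roi[roi_labels - 1]

    # contiguous-block mapping of fine networks onto the 7 canonical networks
    canonical = (np.arange(n_networks) * min(7, n_networks) // n_networks) + 1
    return Atlas(network_of_vertex, roi_labels, network_of_roi,
                 canonical.astype(np.int64))
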