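"""Individual-specific network parcellation and ROI template matching.

Three stages turn one subject's cleaned vertex x time signals into a
subject-specific labeling of the atlas's ROIs:

1. **Iterative network mapping.**  Starting from the population atlas,
   each iteration computes a reference time series per network (SNR-
   weighted mean over the vertices currently assigned to it), scores
   every vertex against every network by Pearson correlation plus an
   atlas-prior bonus, and relabels each vertex to its best network.  The
   prior bonus ``lambda_t(v) = alpha_t * (1 - variability(v)) * (1 - snr(v))``
   shrinks to zero over the iterations, so the final map is driven by the
   subject's own data wherever the signal supports it, and anchored to
   the atlas where inter-individual variability is low or SNR is poor.

2. **Patch extraction.**  Each network's vertex set is split into its
   connected components ("patches") on the mesh graph.  A geodesic
   Gaussian smoothing of the patch indicator defines a smoothed support
   used only for matching bookkeeping; the original vertex set is never
   altered.

3. **Template matching.**  Patches are matched to the atlas ROIs of
   their own network by three rules: (1) a patch overlapping a single
   same-network ROI by more than ``overlap_min`` vertices inherits that
   ROI; (2) a patch overlapping several ROIs is split — overlapping
   vertices keep their atlas ROI and act as centers, remaining vertices
   join the geodesically nearest center; (3) a non-overlapping patch is
   assigned to the nearest same-network ROI iff its geodesic distance is
   below that ROI's internal mean pairwise vertex distance, otherwise its
   vertices are labeled unrecognized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .atlas import Atlas, UNRECOGNIZED
from .mesh import SurfaceMesh
from .qc import CensorMask, ValidationError

RULE_UNRECOGNIZED = 0


@dataclass(frozen=True)
class Patch:
    """A connected same-network component of an individual label map."""
    vertices: np.ndarray          # original (unsmoothed) vertex set
    network: int
    smoothed_support: np.ndarray  # used only during matching bookkeeping


@dataclass(frozen=True)
class IndividualParcellation:
    """Per-vertex network and matched-ROI labels for one subject.

    ``roi_of_vertex`` is 0 (UNRECOGNIZED) where no matching rule could
    place the vertex; ``provenance`` records which rule (1/2/3, 0 for
    unrecognized) assigned each vertex.
    """
    network_of_vertex: np.ndarray
    roi_of_vertex: np.ndarray
    provenance: np.ndarray
    n_rois: int

    def roi_sizes(self) -> np.ndarray:
        """Matched vertex count per ROI (length n_rois)."""
        return np.bincount(self.roi_of_vertex, minlength=self.n_rois + 1)[1:]

    def rule_counts(self) -> dict:
        vals, counts = np.unique(self.provenance, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two vertex index sets."""
    a, b = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


# ---------------------------------------------------------------------------
# step 1: iterative network mapping
# ---------------------------------------------------------------------------

def _row_standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # zero-variance rows correlate 0 with everything
    return (x - mu) / sd


def iterative_parcellation(signals: np.ndarray, atlas: Atlas,
                           variability_map: np.ndarray, snr_map: np.ndarray,
                           n_iter: int = 10, alpha_schedule=None,
                           change_tol: float = 0.001,
                           mask: CensorMask | None = None) -> np.ndarray:
    """Map a subject's networks by iterative atlas-guided relabeling.

    ``variability_map`` and ``snr_map`` are per-vertex weights in [0, 1];
    high variability or high SNR reduce the atlas prior at that vertex.
    ``alpha_schedule`` maps iteration index (0-based) to the global prior
    strength; the default decreases linearly from 1 to 0 over ``n_iter``.
    Stops early when fewer than ``change_tol`` of labels change.  When a
    censor ``mask`` is given, correlations use kept frames only
    (interpolated frames exist solely for the band-pass).

    Returns per-vertex network labels (1..n_networks).
    """
    signals = np.asarray(signals, dtype=float)
    if mask is not None:
        signals = signals[:, mask.kept_indices]
    V, T = signals.shape
    variability_map = np.asarray(variability_map, dtype=float)
    snr_map = np.asarray(snr_map, dtype=float)
    if variability_map.shape != (V,) or snr_map.shape != (V,):
        raise ValidationError("variability_map and snr_map must be per-vertex")
    if alpha_schedule is None:
        def alpha_schedule(t):
            return 1.0 - t / max(1, n_iter - 1)

    K = atlas.n_networks
    labels = atlas.network_of_vertex.copy()
    Z = _row_standardize(signals)
    prior_weight = (1.0 - variability_map) * (1.0 - snr_map)
    atlas_onehot = np.zeros((V, K))
    atlas_onehot[np.arange(V), atlas.network_of_vertex - 1] = 1.0

    for t in range(n_iter):
        refs = np.empty((K, T))
        for k in range(1, K + 1):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                members = np.flatnonzero(atlas.network_of_vertex == k)
                warnings.warn(f"network {k} empty at iteration {t}; reseeded from atlas")
            w = snr_map[members]
            if w.sum() == 0:
                w = np.ones_like(w)
            refs[k - 1] = (w[:, None] * signals[members]).sum(axis=0) / w.sum()
        corr = Z @ _row_standardize(refs).T / T  # (V, K)
        score = corr + alpha_schedule(t) * prior_weight[:, None] * atlas_onehot
        new_labels = np.argmax(score, axis=1).astype(np.int64) + 1
        changed = np.mean(new_labels != labels)
        labels = new_labels
        if changed < change_tol:
            break
    return labels


# ---------------------------------------------------------------------------
# step 2: patch extraction
# ---------------------------------------------------------------------------

def extract_patches(network_labels: np.ndarray, mesh: SurfaceMesh,
                    smoothing_sigma: float = 1.0,
                    geodesics: np.ndarray | None = None) -> list[Patch]:
    """Split each network's vertex set into connected mesh components.

    The smoothed support of a patch is the set of vertices where a
    geodesic Gaussian spread (kernel SD ``smoothing_sigma`` in mesh
    units) of the patch indicator, normalized by the kernel mass, exceeds
    0.5.  The stored original vertex set is never modified by smoothing.
    """
    network_labels = np.asarray(network_labels, dtype=np.int64)
    if geodesics is None:
        geodesics = mesh.geodesic_distances()
    kernel = np.exp(-0.5 * (geodesics / smoothing_sigma) ** 2)
    kernel_mass = kernel.sum(axis=1)
    patches = []
    for k in np.unique(network_labels):
        members = np.flatnonzero(network_labels == k)
        sub = mesh.adjacency[np.ix_(members, members)]
        n_comp, comp = connected_components(sub, directed=False)
        for c in range(n_comp):
            verts = members[comp == c]
            smooth = kernel[:, verts].sum(axis=1) / kernel_mass
            patches.append(Patch(vertices=verts, network=int(k),
                                 smoothed_support=np.flatnonzero(smooth > 0.5)))
    return patches


# ---------------------------------------------------------------------------
# step 3: template matching
# ---------------------------------------------------------------------------

def default_overlap_min(n_vertices: int, reference: int = 5124,
                        reference_overlap: int = 20) -> int:
    """Overlap threshold scaled from its calibration mesh, floored at 3."""
    return max(3, int(round(reference_overlap * n_vertices / reference)))


def _roi_internal_mean_distance(atlas: Atlas, roi: int, geodesics: np.ndarray) -> float:
    verts = atlas.roi_vertices(roi)
    if verts.size < 2:
        return 0.0
    d = geodesics[np.ix_(verts, verts)]
    iu = np.triu_indices(verts.size, k=1)
    return float(d[iu].mean())


def match_patches(patches: list[Patch], atlas: Atlas, mesh: SurfaceMesh,
                  overlap_min: int | None = None,
                  geodesics: np.ndarray | None = None) -> IndividualParcellation:
    """Assign each patch's vertices to homologous atlas ROIs by three rules.

    Matching is restricted to ROIs of the patch's own network.  Rule-2
    distance ties break toward the lower ROI id.
    """
    if geodesics is None:
        geodesics = mesh.geodesic_distances()
    if overlap_min is None:
        overlap_min = default_overlap_min(mesh.n_vertices)

    V = mesh.n_vertices
    roi_out = np.full(V, UNRECOGNIZED, dtype=np.int64)
    prov = np.full(V, RULE_UNRECOGNIZED, dtype=np.int64)
    net_out = np.zeros(V, dtype=np.int64)

    for patch in patches:
        verts = patch.vertices
        net_out[verts] = patch.network
        same_net_rois = np.flatnonzero(atlas.network_of_roi == patch.network) + 1
        atlas_roi_here = atlas.roi_of_vertex[verts]
        cand = [int(r) for r in same_net_rois
                if np.count_nonzero(atlas_roi_here == r) > 0]

        if len(cand) == 1 and np.count_nonzero(atlas_roi_here == cand[0]) > overlap_min:
            roi_out[verts] = cand[0]
            prov[verts] = 1
            continue

        if len(cand) >= 2:
            # rule 2: split around the overlap centers
            centers = {r: verts[atlas_roi_here == r] for r in cand}
            overlapping = np.isin(atlas_roi_here, cand)
            roi_out[verts[overlapping]] = atlas_roi_here[overlapping]
            rest = verts[~overlapping]
            if rest.size:
                # distance of each remaining vertex to each center set
                dmat = np.stack([geodesics[np.ix_(rest, centers[r])].min(axis=1)
                                 for r in cand])  # (n_cand, n_rest)
                nearest = np.argmin(dmat, axis=0)  # argmin: ties -> lower ROI id
                roi_out[rest] = np.asarray(cand)[nearest]
            prov[verts] = 2
            continue

        # rule 3: no overlap (or a single sub-threshold overlap)
        d_to_roi = {int(r): geodesics[np.ix_(verts, atlas.roi_vertices(int(r)))].min()
                    for r in same_net_rois}
        nearest_roi = min(d_to_roi, key=lambda r: (d_to_roi[r], r))
        threshold = _roi_internal_mean_distance(atlas, nearest_roi, geodesics)
        if d_to_roi[nearest_roi] < threshold:
            roi_out[verts] = nearest_roi
            prov[verts] = 3
        # else: stays UNRECOGNIZED with provenance 0

    return IndividualParcellation(network_of_vertex=net_out, roi_of_vertex=roi_out,
                                  provenance=prov, n_rois=atlas.n_rois)


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------

def roi_timeseries(signals: np.ndarray, roi_of_vertex: np.ndarray, n_rois: int,
                   mask: CensorMask | None = None):
    """Unweighted ROI-mean series over kept frames.

    Returns ``(roi_ts, counts)``: (n_rois, n_kept) with NaN rows for ROIs
    with zero matched vertices, and the per-ROI vertex counts.
    """
    signals = np.asarray(signals, dtype=float)
    if mask is not None:
        signals = signals[:, mask.kept_indices]
    roi_of_vertex = np.asarray(roi_of_vertex, dtype=np.int64)
    counts = np.bincount(roi_of_vertex, minlength=n_rois + 1)[1:]
    if counts.sum() == 0:
        raise ValidationError("no vertices matched to any ROI")
    out = np.full((n_rois, signals.shape[1]), np.nan)
    for r in range(1, n_rois + 1):
        members = np.flatnonzero(roi_of_vertex == r)
        if members.size:
            out[r - 1] = signals[members].mean(axis=0)
    return out, counts


def parcellate_subject(signals: np.ndarray, atlas: Atlas, mesh: SurfaceMesh,
                       variability_map: np.ndarray, snr_map: np.ndarray,
                       geodesics: np.ndarray | None = None,
                       n_iter: int = 10, overlap_min: int | None = None,
                       mask: CensorMask | None = None) -> IndividualParcellation:
    """Full chain: iterative mapping -> patches -> template matching."""
    if geodesics is None:
        geodesics = mesh.geodesic_distances()
    labels = iterative_parcellation(signals, atlas, variability_map, snr_map,
                                    n_iter=n_iter, mask=mask)
    patches = extract_patches(labels, mesh, geodesics=geodesics)
    return match_patches(patches, atlas, mesh, overlap_min=overlap_min,
                         geodesics=geodesics)
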