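"""Inter-individual variability of regional topography and connectivity.

Four per-ROI variability profiles are computed across subjects:

* **size** — sample SD (ddof=1) of the matched vertex count per ROI;
* **position** — mean geodesic distance between subjects' ROI centers,
  where a center is the geodesic medoid vertex of the ROI (the vertex
  minimizing summed geodesic distance to the ROI's vertices);
* **vertex-wise connectivity** — for each vertex, the mean over subject
  pairs of (1 - Pearson r) between the subjects' connectivity profiles
  at that vertex (profile = correlations to all atlas ROI mean series),
  then averaged over each atlas ROI's vertices;
* **ROI connectivity** — sample SD of each connection across subjects,
  averaged over the ROI's incident connections.

Profiles can then be correlated with each other across ROIs (Pearson).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .atlas import Atlas
from .mesh import SurfaceMesh
from .parcellation import IndividualParcellation
from .qc import ValidationError


def size_variability(parcellations: list[IndividualParcellation]) -> np.ndarray:
    """Per-ROI sample SD of matched vertex counts (unmatched counts as 0)."""
    if len(parcellations) < 2:
        raise ValidationError("need >= 2 subjects")
    sizes = np.stack([p.roi_sizes() for p in parcellations])  # (S, R)
    return sizes.std(axis=0, ddof=1)


def roi_center(roi_vertices: np.ndarray, geodesics: np.ndarray) -> int:
    """Geodesic medoid vertex of an ROI (deterministic tie-break: lowest id)."""
    sub = geodesics[np.ix_(roi_vertices, roi_vertices)]
    return int(roi_vertices[np.argmin(sub.sum(axis=1))])


def position_variability(parcellations: list[IndividualParcellation],
                         mesh: SurfaceMesh,
                         geodesics: np.ndarray | None = None) -> np.ndarray:
    """Mean geodesic distance between subjects' ROI centers, per ROI.

    Subjects in which an ROI is unmatched are omitted from that ROI's
    pairs; an ROI matched in < 2 subjects gets NaN.
    """
    if len(parcellations) < 2:
        raise ValidationError("need >= 2 subjects")
    if geodesics is None:
        geodesics = mesh.geodesic_distances()
    n_rois = parcellations[0].n_rois
    out = np.full(n_rois, np.nan)
    for r in range(1, n_rois + 1):
        centers = []
        for p in parcellations:
            verts = np.flatnonzero(p.roi_of_vertex == r)
            if verts.size:
                centers.append(roi_center(verts, geodesics))
        if len(centers) < 2:
            continue
        c = np.asarray(centers)
        d = geodesics[np.ix_(c, c)]
        iu = np.triu_indices(len(c), k=1)
        out[r - 1] = d[iu].mean()
    return out


def vertex_connectivity_profiles(signals: np.ndarray, atlas: Atlas,
                                 kept: np.ndarray | None = None) -> np.ndarray:
    """Per-vertex connectivity profile against the atlas ROI mean series.

    Returns a (V, n_rois) matrix of Pearson correlations — a desk-scale
    stand-in basis for full vertex-to-vertex profiles.
    """
    signals = np.asarray(signals, dtype=float)
    if kept is not None:
        signals = signals[:, kept]
    R = atlas.n_rois
    roi_means = np.stack([signals[atlas.roi_vertices(r)].mean(axis=0)
                          for r in range(1, R + 1)])

    def standardize(x):
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf
        return (x - mu) / sd

    T = signals.shape[1]
    return standardize(signals) @ standardize(roi_means).T / T


def vertex_variability(profiles: list[np.ndarray], atlas: Atlas):
    """Mean pairwise profile dissimilarity (1 - r) per vertex, and per ROI.

    ``profiles`` holds one (V, n_rois) matrix per subject on a common
    basis.  Returns ``(per_vertex, per_roi)``.  Vertices whose profile
    has zero variance in any subject are skipped with a warning.
    """
    if len(profiles) < 2:
        raise ValidationError("need >= 2 subjects")
    P = np.stack(profiles)  # (S, V, R)
    S, V, R = P.shape
    mu = P.mean(axis=2, keepdims=True)
    sd = P.std(axis=2, keepdims=True)
    degenerate = np.any(sd[:, :, 0] == 0, axis=0)  # (V,)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} vertices with zero-variance profiles skipped")
    sd[sd == 0] = np.inf
    Z = (P - mu) / sd
    per_vertex = np.zeros(V)
    n_pairs = S * (S - 1) // 2
    for a in range(S):
        for b in range(a + 1, S):
            r = np.einsum("vr,vr->v", Z[a], Z[b]) / R
            per_vertex += 1.0 - r
    per_vertex /= n_pairs
    per_vertex[degenerate] = np.nan
    per_roi = np.array([np.nanmean(per_vertex[atlas.roi_vertices(r)])
                        for r in range(1, atlas.n_rois + 1)])
    return per_vertex, per_roi


def roi_connectivity_variability(matrices: list[np.ndarray]) -> np.ndarray:
    """Mean across-subject SD of each ROI's incident connections.

    ``matrices`` are per-subject (R, R) connectivity values (NaN where
    masked).  Per connection, the sample SD across subjects with a valid
    value; per ROI, the mean over its R-1 incident connections.
    """
    if len(matrices) < 2:
        raise ValidationError("need >= 2 subjects")
    M = np.stack([np.asarray(m, dtype=float) for m in matrices])  # (S, R, R)
    R = M.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        conn_sd = np.nanstd(M, axis=0, ddof=1)  # (R, R)
    np.fill_diagonal(conn_sd, np.nan)
    return np.nanmean(conn_sd, axis=1)


def correlate_profiles(a: np.ndarray, b: np.ndarray):
    """Pearson r and two-sided p between two per-ROI profiles.

    NaN entries (ROIs undefined in either profile) are dropped pairwise;
    constant input yields (nan, nan).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("profiles must be equal length >= 3")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValidationError("fewer than 3 jointly defined ROIs")
    if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r), float(p)
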