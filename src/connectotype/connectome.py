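"""ROI x ROI functional connectivity and network-level aggregation.

Connectivity is the pairwise Pearson correlation of ROI mean time series
over kept frames (no Fisher z-transform by default; a flag enables it
for sensitivity analysis).  A symmetric n x n matrix vectorizes into
n(n-1)/2 strict upper-triangle features — 6670 for the default 116 ROIs.
Within-network connectivity of a network is the mean over ROI pairs with
both ROIs inside it; between-network connectivity averages all pairs with
exactly one ROI inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .qc import ValidationError


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson matrix with a mask for missing ROIs."""
    values: np.ndarray       # (R, R), NaN at masked entries
    missing: np.ndarray      # (R,) bool, True where the ROI is unmatched
    basis: str = "individual"

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def connectivity_matrix(roi_ts: np.ndarray, basis: str = "individual",
                        fisher_z: bool = False) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI series (rows) over kept frames.

    Rows that are entirely NaN (unmatched ROIs) or have zero variance are
    masked; the diagonal of valid ROIs is exactly 1.
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    R, T = roi_ts.shape
    if R < 2 or T < 3:
        raise ValidationError("need >= 2 ROIs with >= 3 kept frames")
    missing = np.any(np.isnan(roi_ts), axis=1)
    sd = np.zeros(R)
    sd[~missing] = roi_ts[~missing].std(axis=1)
    zero_var = (~missing) & (sd == 0)
    if zero_var.any():
        warnings.warn(f"zero-variance ROI series masked: {np.flatnonzero(zero_var) + 1}")
        missing = missing | zero_var
    vals = np.full((R, R), np.nan)
    ok = np.flatnonzero(~missing)
    if ok.size >= 2:
        c = np.corrcoef(roi_ts[ok])
        vals[np.ix_(ok, ok)] = np.clip(c, -1.0, 1.0)
    if fisher_z:
        diag = np.diag(vals).copy()
        with np.errstate(divide="ignore"):
            vals = np.arctanh(np.clip(vals, -1 + 1e-15, 1 - 1e-15))
        np.fill_diagonal(vals, diag)  # keep the unit diagonal un-transformed
    return ConnectivityMatrix(values=vals, missing=missing, basis=basis)


def feature_index_table(n_rois: int) -> np.ndarray:
    """(n_features, 2) table of 1-based (roi_i, roi_j) per feature slot.

    Features are the strict upper triangle in row-major order, so a
    116-ROI matrix yields 6670 features.
    """
    iu = np.triu_indices(n_rois, k=1)
    return np.column_stack([iu[0] + 1, iu[1] + 1])


def feature_vector(matrix: ConnectivityMatrix, atol: float = 1e-10) -> np.ndarray:
    """Strict upper triangle in row-major order (NaN at masked pairs)."""
    v = matrix.values
    finite = np.isfinite(v) & np.isfinite(v.T)
    if not np.allclose(v[finite.T & finite], v.T[finite.T & finite], atol=atol):
        raise ValidationError("connectivity matrix is not symmetric")
    iu = np.triu_indices(matrix.n_rois, k=1)
    return v[iu]


@dataclass(frozen=True)
class NetworkConnectivitySummary:
    """Per-network within/between mean connectivity."""
    within: np.ndarray       # (n_networks,), NaN where undefined
    between: np.ndarray      # (n_networks,)
    global_within: float
    global_between: float


def network_connectivity(matrix: ConnectivityMatrix,
                         network_of_roi: np.ndarray) -> NetworkConnectivitySummary:
    """Aggregate ROI pairs into per-network within/between means.

    within(k): mean over pairs with both ROIs in network k; between(k):
    mean over pairs with exactly one ROI in k.  Masked pairs are excluded;
    a network with a single ROI has undefined within (NaN).
    """
    network_of_roi = np.asarray(network_of_roi, dtype=np.int64)
    R = matrix.n_rois
    if len(network_of_roi) != R:
        raise ValidationError("network_of_roi length must equal n_rois")
    iu = np.triu_indices(R, k=1)
    vals = matrix.values[iu]
    ni, nj = network_of_roi[iu[0]], network_of_roi[iu[1]]
    valid = np.isfinite(vals)
    networks = np.unique(network_of_roi)
    K = int(networks.max())
    within = np.full(K, np.nan)
    between = np.full(K, np.nan)
    for k in networks:
        w = (ni == k) & (nj == k) & valid
        b = ((ni == k) ^ (nj == k)) & valid
        if w.any():
            within[k - 1] = vals[w].mean()
        if b.any():
            between[k - 1] = vals[b].mean()
    g_w = (ni == nj) & valid
    g_b = (ni != nj) & valid
    return NetworkConnectivitySummary(
        within=within, between=between,
        global_within=float(vals[g_w].mean()) if g_w.any() else float("nan"),
        global_between=float(vals[g_b].mean()) if g_b.any() else float("nan"),
    )


def between_network_shift(individual_summaries: list, atlas_summaries: list,
                          n_networks: int | None = None):
    """Per-network % change of between-network connectivity, with paired test.

    Compares the individual-specific basis against the atlas basis over
    the same subjects: mean percent change per network, paired t
    statistic, and Bonferroni-adjusted p over the number of networks.

    Returns a dict with ``percent_change``, ``t``, ``p_adjusted``, and the
    grand mean percent change.
    """
    if len(individual_summaries) != len(atlas_summaries):
        raise ValidationError("summary lists must cover the same subjects")
    if len(individual_summaries) < 3:
        raise ValidationError("need >= 3 subjects for a paired test")
    ind = np.stack([s.between for s in individual_summaries])   # (S, K)
    atl = np.stack([s.between for s in atlas_summaries])
    K = n_networks or ind.shape[1]
    # ratio of subject means per network: robust to near-zero values in
    # single subjects, and exact under uniform scaling
    with np.errstate(divide="ignore", invalid="ignore"):
        percent_change = 100.0 * (np.nanmean(ind, axis=0) - np.nanmean(atl, axis=0)) \
            / np.abs(np.nanmean(atl, axis=0))
    t = np.full(K, np.nan)
    p = np.full(K, np.nan)
    for k in range(K):
        ok = np.isfinite(ind[:, k]) & np.isfinite(atl[:, k])
        if ok.sum() >= 3:
            diff = ind[ok, k] - atl[ok, k]
            if np.allclose(diff, 0):
                t[k], p[k] = 0.0, 1.0
            else:
                res = stats.ttest_rel(ind[ok, k], atl[ok, k])
                t[k], p[k] = res.statistic, res.pvalue
    p_adj = np.minimum(1.0, p * K)
    return {
        "percent_change": percent_change,
        "t": t,
        "p_adjusted": p_adj,
        "mean_percent_change": float(np.nanmean(percent_change)),
    }
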