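"""Study-style evaluation harness: cohort -> features -> contrasts.

Bundles the full per-subject chain (cleaning, individual parcellation,
connectivity, feature extraction, for both the individual-specific and
the atlas basis) and the cohort-level analyses that mirror the study
design: genotype-stratified symptom prediction with both bases, merged
cross-genotype prediction, parcellation-recovery scoring, and top-set
composition.  Used by the reproduction scripts and the acceptance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import connectome, parcellation, prediction, qc, synthetic
from .parcellation import dice


@dataclass
class CohortEvaluation:
    records: list
    truth: synthetic.CohortTruth
    parcellations: dict          # subject_id -> IndividualParcellation
    features: dict               # basis -> (n_subjects, n_features)
    masks: dict
    subject_ids: list


def evaluate_cohort(config: synthetic.CohortConfig) -> CohortEvaluation:
    """Generate a cohort and run it through cleaning, parcellation, and
    connectivity for both bases.  Subjects excluded by the censoring rule
    are dropped (none at the default outlier rate)."""
    records, truth = synthetic.make_cohort(config)
    geo = truth.mesh.geodesic_distances()
    vm = synthetic.truth_variability_map(truth.atlas, truth.mesh)
    sm = synthetic.truth_snr_map(config.vertex_noise_sd, truth.mesh.n_vertices)
    parcs, masks = {}, {}
    feats = {"individual": [], "atlas": []}
    kept_records = []
    for rec in records:
        design = qc.NuisanceDesign.build(rec.nuisance["motion_params"],
                                         rec.nuisance["wm"], rec.nuisance["ventricle"])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cleaned, mask = qc.clean(rec.signals, rec.fd, rec.dvars, design,
                                         frame_interval_s=config.frame_interval_s)
        except qc.ValidationError:
            continue
        p = parcellation.parcellate_subject(cleaned, truth.atlas, truth.mesh,
                                            vm, sm, geodesics=geo, mask=mask)
        parcs[rec.subject_id] = p
        masks[rec.subject_id] = mask
        for basis, labels in (("individual", p.roi_of_vertex),
                              ("atlas", truth.atlas.roi_of_vertex)):
            ts, _ = parcellation.roi_timeseries(cleaned, labels,
                                                truth.atlas.n_rois, mask=mask)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = connectome.connectivity_matrix(ts, basis=basis)
            feats[basis].append(np.nan_to_num(connectome.feature_vector(m)))
        kept_records.append(rec)
    return CohortEvaluation(
        records=kept_records, truth=truth, parcellations=parcs,
        features={b: np.vstack(v) for b, v in feats.items()},
        masks=masks, subject_ids=[r.subject_id for r in kept_records])


def recovery_dice(ev: CohortEvaluation) -> np.ndarray:
    """Dice between each subject's matched ROIs and the true topography,
    pooled over subjects and ROIs."""
    out = []
    for rec in ev.records:
        matched = ev.parcellations[rec.subject_id].roi_of_vertex
        for r in range(1, ev.truth.atlas.n_rois + 1):
            out.append(dice(np.flatnonzero(matched == r),
                            np.flatnonzero(rec.true_labels == r)))
    return np.asarray(out)


def atlas_dice(ev: CohortEvaluation) -> np.ndarray:
    """Dice between matched ROIs and the population atlas (closure check)."""
    out = []
    for rec in ev.records:
        matched = ev.parcellations[rec.subject_id].roi_of_vertex
        for r in range(1, ev.truth.atlas.n_rois + 1):
            out.append(dice(np.flatnonzero(matched == r),
                            ev.truth.atlas.roi_vertices(r)))
    return np.asarray(out)


def prediction_contrasts(ev: CohortEvaluation, target: str = "mmse_like",
                         alpha: float = 0.001,
                         correction: str = "bonferroni") -> dict:
    """Genotype-stratified and merged LOOCV prediction with both bases.

    Returns per-genotype observed-vs-predicted r for the individual and
    atlas bases, top-set within/between composition for the individual
    basis, and the merged cross-genotype r.
    """
    table = connectome.feature_index_table(ev.truth.atlas.n_rois)
    out = {"per_genotype": {}, "merged_r": None}
    for genotype in synthetic.GENOTYPES:
        idx = [i for i, r in enumerate(ev.records) if r.genotype == genotype]
        if len(idx) < 10:
            continue
        y = np.array([ev.records[i].symptom_scores[target] for i in idx])
        conf = np.column_stack([[ev.records[i].age for i in idx],
                                [ev.records[i].sex for i in idx]])
        entry = {}
        for basis in ("individual", "atlas"):
            X = ev.features[basis][idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = prediction.predict_svr_loocv(X, y, conf, alpha=alpha,
                                                   correction=correction)
            entry[f"r_{basis}"] = rep.r
            if basis == "individual":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    contrib = prediction.contribution_analysis(
                        rep.fold_weights, table, ev.truth.atlas.network_of_roi,
                        ev.truth.atlas.canonical_of_network)
                entry["n_top_within"] = contrib.n_top_within
                entry["n_top_between"] = contrib.n_top_between
        out["per_genotype"][genotype] = entry
    y = np.array([r.symptom_scores[target] for r in ev.records])
    conf = np.column_stack([[r.age for r in ev.records],
                            [r.sex for r in ev.records]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = prediction.predict_svr_loocv(ev.features["individual"], y, conf,
                                           alpha=alpha, correction=correction)
    out["merged_r"] = rep.r
    return out


def contrast_cohort_config(seed: int, n_per_cell: int = 20,
                           boundary_shift_sd: float = 1.5) -> synthetic.CohortConfig:
    """Replicate-cohort conditions for the study's central contrasts:
    120 subjects (three clinical groups x two genotypes), 162-vertex mesh,
    6 networks / 24 ROIs, 196-frame series, discordant planted
    between-network effect maps per genotype."""
    return synthetic.CohortConfig(
        cells={(g, gt): n_per_cell for g in synthetic.GROUPS
               for gt in synthetic.GENOTYPES},
        n_vertices=162, n_networks=6, n_rois=24, timepoints=196,
        boundary_shift_sd=boundary_shift_sd, seed=seed)
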