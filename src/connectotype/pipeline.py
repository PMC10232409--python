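"""End-to-end orchestration: simulate -> qc -> parcellate -> connectome ->
variability -> predict, with a provenance manifest.

The pipeline is driven by a YAML config (see ``default_config``).  Every
stage writes its outputs under the run directory and records them, with
SHA-256 checksums, in ``manifest.json``; re-running with the same config
reproduces identical checksums for deterministic stages, and stages whose
outputs already exist are skipped (resume-from-cache).  Subject-level
inputs are regenerated deterministically from the config seed rather than
stored, so a run directory stays small.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np

from . import __version__, connectome, io, parcellation, prediction, qc, synthetic, variability
from .mesh import ConfigurationError

STAGES = ("simulate", "qc", "parcellate", "connectome", "variability", "predict")


def default_config() -> dict:
    """Demo-scale configuration: 162-vertex mesh, 30 subjects."""
    return {
        "schema_version": 1,
        "seed": 0,
        "cohort": {
            "n_vertices": 162,
            "n_networks": 6,
            "n_rois": 24,
            "timepoints": 150,
            "boundary_shift_sd": 1.0,
            "vertex_noise_sd": 0.5,
            "motion_outlier_rate": 0.05,
            "cells": {
                "NA,carrier": 5, "MCI,carrier": 5, "AD,carrier": 5,
                "NA,noncarrier": 5, "MCI,noncarrier": 5, "AD,noncarrier": 5,
            },
        },
        "qc": {
            "fd_thresh": 0.2, "dvars_thresh": 50.0,
            "pre": 1, "post": 2, "min_run": 5, "exclusion_fraction": 0.5,
            "low": 0.009, "high": 0.08, "frame_interval_s": 3.0,
        },
        "prediction": {
            "target": "mmse_like",
            "alpha": 0.001,
            "correction": "bonferroni",
            "n_permutations": 0,
            "classification_folds": 5,
        },
    }


def validate_config(cfg: dict) -> None:
    """Reject malformed configs before any compute, with field paths."""
    if cfg.get("schema_version", 1) != 1:
        raise ConfigurationError("schema_version: unsupported")
    q = cfg.get("qc", {})
    low, high = q.get("low", 0.009), q.get("high", 0.08)
    if not low < high:
        raise ConfigurationError("qc.high: band edge must exceed qc.low")
    tr = q.get("frame_interval_s", 3.0)
    if high >= 1.0 / (2.0 * tr):
        raise ConfigurationError("qc.high: must be below Nyquist for frame_interval_s")
    for key, n in cfg.get("cohort", {}).get("cells", {}).items():
        if n <= 0:
            raise ConfigurationError(f"cohort.cells.{key}: count must be positive")


def _cohort_config(cfg: dict) -> synthetic.CohortConfig:
    c = cfg.get("cohort", {})
    cells = {tuple(k.split(",")): v for k, v in c.get("cells", {}).items()} \
        if "cells" in c else dict(synthetic.DEFAULT_CELLS)
    kwargs = {k: c[k] for k in
              ("n_vertices", "n_networks", "n_rois", "timepoints",
               "boundary_shift_sd", "vertex_noise_sd", "motion_outlier_rate")
              if k in c}
    return synthetic.CohortConfig(cells=cells, seed=cfg.get("seed", 0), **kwargs)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


class PipelineRun:
    """Executes stages in fixed order, caching outputs under ``outdir``."""

    def __init__(self, cfg: dict, outdir):
        validate_config(cfg)
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "software_version": __version__,
            "config_hash": _config_hash(cfg),
            "seed": cfg.get("seed", 0),
            "stages": {},
            "excluded_subjects": [],
        }
        self._records = None
        self._truth = None
        self._geo = None
        self._clean = {}
        self._masks = {}
        self._parcs = {}

    # -- deterministic regeneration of in-memory state ---------------------

    def _cohort(self):
        if self._records is None:
            self._records, self._truth = synthetic.make_cohort(_cohort_config(self.cfg))
            self._geo = self._truth.mesh.geodesic_distances()
        return self._records, self._truth

    def _qc_all(self):
        if not self._clean:
            records, _ = self._cohort()
            q = self.cfg.get("qc", {})
            for rec in records:
                design = qc.NuisanceDesign.build(rec.nuisance["motion_params"],
                                                 rec.nuisance["wm"],
                                                 rec.nuisance["ventricle"])
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cleaned, mask = qc.clean(
                            rec.signals, rec.fd, rec.dvars, design,
                            frame_interval_s=q.get("frame_interval_s", 3.0),
                            fd_thresh=q.get("fd_thresh", 0.2),
                            dvars_thresh=q.get("dvars_thresh", 50.0),
                            pre=q.get("pre", 1), post=q.get("post", 2),
                            min_run=q.get("min_run", 5),
                            exclusion_fraction=q.get("exclusion_fraction", 0.5))
                except qc.ValidationError:
                    self.manifest["excluded_subjects"].append(
                        {"subject": rec.subject_id, "reason": "censored fraction above threshold"})
                    continue
                self._clean[rec.subject_id] = cleaned
                self._masks[rec.subject_id] = mask
        return self._clean, self._masks

    def _parcellate_all(self):
        if not self._parcs:
            records, truth = self._cohort()
            cleaned, masks = self._qc_all()
            cc = _cohort_config(self.cfg)
            vm = synthetic.truth_variability_map(truth.atlas, truth.mesh)
            sm = synthetic.truth_snr_map(cc.vertex_noise_sd, truth.mesh.n_vertices)
            for rec in records:
                if rec.subject_id not in cleaned:
                    continue
                self._parcs[rec.subject_id] = parcellation.parcellate_subject(
                    cleaned[rec.subject_id], truth.atlas, truth.mesh, vm, sm,
                    geodesics=self._geo, mask=self._masks[rec.subject_id])
        return self._parcs

    def _matrices(self, basis: str):
        records, truth = self._cohort()
        cleaned, masks = self._qc_all()
        parcs = self._parcellate_all()
        out = {}
        for rec in records:
            if rec.subject_id not in cleaned:
                continue
            if basis == "individual":
                labels = parcs[rec.subject_id].roi_of_vertex
            else:
                labels = truth.atlas.roi_of_vertex
            ts, _ = parcellation.roi_timeseries(cleaned[rec.subject_id], labels,
                                                truth.atlas.n_rois,
                                                mask=masks[rec.subject_id])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[rec.subject_id] = connectome.connectivity_matrix(ts, basis=basis)
        return out

    # -- stages -------------------------------------------------------------

    def _register(self, stage: str, paths: list, t0: float):
        self.manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(self.outdir)): io.sha256_of(p) for p in paths},
            "seconds": round(time.time() - t0, 3),
        }

    def _done(self, stage: str, *names) -> bool:
        return all((self.outdir / n).exists() for n in names)

    def stage_simulate(self):
        t0 = time.time()
        records, truth = self._cohort()
        mesh_p = self.outdir / "mesh.off"
        atlas_p = self.outdir / "atlas_roi_labels.tsv"
        net_p = self.outdir / "atlas_network_labels.tsv"
        pheno_p = self.outdir / "phenotypes.tsv"
        io.write_mesh_off(truth.mesh, mesh_p)
        io.write_labels_tsv(truth.atlas.roi_of_vertex, atlas_p, header="roi")
        io.write_labels_tsv(truth.atlas.network_of_vertex, net_p, header="network")
        with open(pheno_p, "w") as fh:
            fh.write("subject_id\tage\tsex\tgroup\tgenotype\tmmse_like\tlimm_like\n")
            for r in records:
                fh.write(f"{r.subject_id}\t{io.FLOAT_FMT % r.age}\t{r.sex}\t{r.group}"
                         f"\t{r.genotype}\t{io.FLOAT_FMT % r.symptom_scores['mmse_like']}"
                         f"\t{io.FLOAT_FMT % r.symptom_scores['limm_like']}\n")
        self._register("simulate", [mesh_p, atlas_p, net_p, pheno_p], t0)

    def stage_qc(self):
        t0 = time.time()
        records, _ = self._cohort()
        cleaned, masks = self._qc_all()
        report = {
            "n_subjects": len(records),
            "n_excluded": len(self.manifest["excluded_subjects"]),
            "censored_frames": {sid: int(m.n_censored) for sid, m in masks.items()},
        }
        p = self.outdir / "qc_report.json"
        io.write_json(report, p)
        self._register("qc", [p], t0)

    def stage_parcellate(self):
        t0 = time.time()
        parcs = self._parcellate_all()
        report = {
            sid: {"rule_counts": p.rule_counts(),
                  "n_unrecognized": int((p.roi_of_vertex == 0).sum())}
            for sid, p in parcs.items()
        }
        p = self.outdir / "parcellation_report.json"
        io.write_json(report, p)
        self._register("parcellate", [p], t0)

    def stage_connectome(self):
        t0 = time.time()
        _, truth = self._cohort()
        paths = []
        summaries = {}
        for basis in ("individual", "atlas"):
            mats = self._matrices(basis)
            sums = {sid: connectome.network_connectivity(m, truth.atlas.network_of_roi)
                    for sid, m in mats.items()}
            summaries[basis] = sums
            feat_p = self.outdir / f"features_{basis}.tsv"
            sids = sorted(mats)
            rows = [connectome.feature_vector(mats[sid]) for sid in sids]
            io.write_matrix_tsv(np.asarray(rows), feat_p, row_labels=sids)
            paths.append(feat_p)
        sids = sorted(summaries["individual"])
        shift = connectome.between_network_shift(
            [summaries["individual"][s] for s in sids],
            [summaries["atlas"][s] for s in sids])
        shift_p = self.outdir / "between_network_shift.json"
        io.write_json({k: v for k, v in shift.items()}, shift_p)
        paths.append(shift_p)
        table_p = self.outdir / "feature_index.tsv"
        io.write_matrix_tsv(connectome.feature_index_table(truth.atlas.n_rois), table_p)
        paths.append(table_p)
        self._register("connectome", paths, t0)

    def stage_variability(self):
        t0 = time.time()
        records, truth = self._cohort()
        cleaned, masks = self._qc_all()
        parcs = self._parcellate_all()
        sids = sorted(parcs)
        plist = [parcs[s] for s in sids]
        size_v = variability.size_variability(plist)
        pos_v = variability.position_variability(plist, truth.mesh, geodesics=self._geo)
        ind_m = self._matrices("individual")
        atl_m = self._matrices("atlas")
        ind_v = variability.roi_connectivity_variability([ind_m[s].values for s in sids])
        atl_v = variability.roi_connectivity_variability([atl_m[s].values for s in sids])
        profs = [variability.vertex_connectivity_profiles(
            cleaned[s], truth.atlas, kept=masks[s].kept_indices) for s in sids]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, vert_v = variability.vertex_variability(profs, truth.atlas)
        prof_p = self.outdir / "variability_profiles.tsv"
        with open(prof_p, "w") as fh:
            fh.write("roi\tsize_var\tposition_var\tindiv_conn_var\tatlas_conn_var\tvertex_conn_var\n")
            for r in range(truth.atlas.n_rois):
                vals = (size_v[r], pos_v[r], ind_v[r], atl_v[r], vert_v[r])
                fh.write(f"{r + 1}\t" + "\t".join(io.FLOAT_FMT % v for v in vals) + "\n")
        corr = {}
        for name, prof in (("size", size_v), ("position", pos_v),
                           ("atlas_conn", atl_v), ("vertex_conn", vert_v)):
            r, p = variability.correlate_profiles(ind_v, prof)
            corr[f"indiv_conn_vs_{name}"] = {"r": r, "p": p}
        corr_p = self.outdir / "variability_correlations.json"
        io.write_json(corr, corr_p)
        self._register("variability", [prof_p, corr_p], t0)

    def stage_predict(self):
        t0 = time.time()
        records, truth = self._cohort()
        pc = self.cfg.get("prediction", {})
        target = pc.get("target", "mmse_like")
        mats = {"individual": self._matrices("individual"),
                "atlas": self._matrices("atlas")}
        table = connectome.feature_index_table(truth.atlas.n_rois)
        report = {}
        for genotype in synthetic.GENOTYPES:
            recs = [r for r in records
                    if r.genotype == genotype and r.subject_id in mats["individual"]]
            if len(recs) < 10:
                report[genotype] = {"status": "not run", "reason": "too few subjects"}
                continue
            y = np.array([r.symptom_scores[target] for r in recs])
            conf = np.column_stack([[r.age for r in recs], [r.sex for r in recs]])
            entry = {}
            for basis in ("individual", "atlas"):
                feats = np.vstack([
                    np.nan_to_num(connectome.feature_vector(mats[basis][r.subject_id]))
                    for r in recs])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = prediction.predict_svr_loocv(
                        feats, y, conf, alpha=pc.get("alpha", 0.001),
                        correction=pc.get("correction", "bonferroni"))
                item = {"r": rep.r, "target": target}
                n_perm = pc.get("n_permutations", 0)
                if n_perm:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p, _ = prediction.permutation_test(
                            feats, y, conf, r_observed=rep.r, n_perm=n_perm,
                            seed=self.cfg.get("seed", 0),
                            alpha=pc.get("alpha", 0.001),
                            correction=pc.get("correction", "bonferroni"))
                    item["permutation_p"] = p
                if basis == "individual":
                    contrib = prediction.contribution_analysis(
                        rep.fold_weights, table, truth.atlas.network_of_roi,
                        truth.atlas.canonical_of_network)
                    item["n_top_within"] = contrib.n_top_within
                    item["n_top_between"] = contrib.n_top_between
                    item["top_connections"] = [
                        [int(table[f][0]), int(table[f][1])]
                        for f in contrib.top_connections]
                entry[basis] = item
            report[genotype] = entry
        p = self.outdir / "prediction_report.json"
        io.write_json(report, p)
        self._register("predict", [p], t0)

    def run(self, stages=STAGES, force: bool = False) -> dict:
        stage_outputs = {
            "simulate": ("phenotypes.tsv",), "qc": ("qc_report.json",),
            "parcellate": ("parcellation_report.json",),
            "connectome": ("between_network_shift.json",),
            "variability": ("variability_correlations.json",),
            "predict": ("prediction_report.json",),
        }
        for stage in STAGES:
            if stage not in stages:
                continue
            if not force and self._done(stage, *stage_outputs[stage]):
                self.manifest["stages"].setdefault(stage, {"outputs": "cached"})
                continue
            getattr(self, f"stage_{stage}")()
        manifest_p = self.outdir / "manifest.json"
        io.write_json(self.manifest, manifest_p)
        return self.manifest


def run_pipeline(config, outdir, stages=STAGES, force: bool = False) -> dict:
    """Execute the pipeline from a config dict or YAML path; returns manifest."""
    cfg = io.load_config(config) if isinstance(config, (str, Path)) else config
    return PipelineRun(cfg, outdir).run(stages=stages, force=force)


def summarize_run(manifest_or_dir) -> str:
    """Human-readable report of a completed run (partial runs are flagged)."""
    d = Path(manifest_or_dir)
    manifest = io.read_json(d / "manifest.json" if d.is_dir() else d)
    rundir = d if d.is_dir() else d.parent
    lines = [f"connectotype run (config {manifest['config_hash']}, "
             f"seed {manifest['seed']})", ""]
    for stage in STAGES:
        info = manifest["stages"].get(stage)
        lines.append(f"[{stage}] " + ("completed" if info else "not run"))
    excl = manifest.get("excluded_subjects", [])
    lines.append(f"excluded subjects: {len(excl)}")
    pred_p = rundir / "prediction_report.json"
    if pred_p.exists():
        pred = io.read_json(pred_p)
        lines.append("")
        lines.append("prediction (observed-vs-predicted Pearson r):")
        for genotype, entry in sorted(pred.items()):
            if "status" in entry:
                lines.append(f"  {genotype}: {entry['status']} ({entry['reason']})")
                continue
            for basis in ("individual", "atlas"):
                item = entry[basis]
                extra = (f", perm p={item['permutation_p']:.4g}"
                         if "permutation_p" in item else "")
                lines.append(f"  {genotype:<12} {basis:<11} r={item['r']:+.3f}{extra}")
    shift_p = rundir / "between_network_shift.json"
    if shift_p.exists():
        shift = io.read_json(shift_p)
        lines.append(f"between-network connectivity change (individual vs atlas): "
                     f"{shift['mean_percent_change']:+.2f}% mean")
    else:
        lines.append("connectome stage: not run")
    return "\n".join(lines)
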