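"""End-to-end orchestration of the regulatory analysis on a (synthetic) cohort.

Stages run in dependency order:
simulate -> qc -> metacells -> coaccess -> links -> dars -> conserve ->
chromvar -> footprint -> tfspecific -> nmf.
Each completed stage is checkpointed under the output directory, and the run
manifest records parameters, per-stage seeds and record counts; re-running
with ``resume=True`` restarts from the first missing checkpoint.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import pickle
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import coaccess as coaccess_mod
from . import differential, linking, preprocess, programs, tf
from .regions import GenomicRegion
from .simulate import SimulationConfig, simulate_cohort, write_cohort

log = logging.getLogger(__name__)

STAGES = [
    "simulate", "qc", "metacells", "coaccess", "links", "dars", "conserve",
    "chromvar", "footprint", "tfspecific", "nmf",
]


@dataclass
class PipelineConfig:
    out_dir: str = "creglink_run"
    seed: int = 0
    simulate: dict[str, Any] = field(default_factory=dict)
    qc_atac: dict[str, Any] = field(
        default_factory=lambda: dict(count_min=500, count_max=50_000,
                                     tss_min=2, nucleosome_max=4))
    qc_rna: dict[str, Any] = field(
        default_factory=lambda: dict(count_min=200, count_max=50_000, mito_max_pct=25))
    n_metacells: int = 200
    metacell_k: int = 50
    lsi_components: int = 150
    link_window: int = 500_000
    n_null: int = 1000
    fdr_cut: float = 0.1
    coaccess_cut: float = 0.2
    cancer_label: str | None = None
    distance_penalty_scale: float = 1.0
    nmf_k_min: int = 2
    nmf_k_max: int = 6
    nmf_nrun: int = 10
    nmf_min_cells: int = 500
    write_cohort_files: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {s: int(rng.integers(0, 2**31 - 1)) for s in STAGES}


def run_pipeline(config: PipelineConfig, resume: bool = False,
                 until: str | None = None) -> dict:
    """Execute all stages (or up to ``until``); returns the manifest (also
    written as JSON)."""
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(cfg),
        "seeds": seeds,
        "stages": [],
    }
    state: dict[str, Any] = {}

    def checkpoint_path(stage):
        return os.path.join(cfg.out_dir, f"stage_{stage}.pkl")

    def record(stage, t0, counts):
        manifest["stages"].append({
            "stage": stage,
            "seed": seeds[stage],
            "seconds": round(time.time() - t0, 2),
            "records": counts,
        })

    for stage in STAGES:
        t0 = time.time()
        cp = checkpoint_path(stage)
        if resume and os.path.exists(cp):
            with open(cp, "rb") as fh:
                state.update(pickle.load(fh))
            record(stage, t0, {"resumed": 1})
            continue
        try:
            counts = _STAGE_FUNCS[stage](cfg, seeds[stage], state)
        except Exception as exc:  # partial outputs are retained on disk
            manifest["stages"].append({"stage": stage, "error": str(exc)})
            _write_manifest(manifest, cfg.out_dir)
            raise StageFailure(stage, exc) from exc
        with open(cp, "wb") as fh:
            pickle.dump({k: state[k] for k in counts.pop("_keys", [])}, fh)
        record(stage, t0, counts)
        if until is not None and stage == until:
            break
    _write_manifest(manifest, cfg.out_dir)
    return manifest


def _write_manifest(manifest, out_dir):
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, seed, state):
    sim_cfg = SimulationConfig(**{"seed": seed, **cfg.simulate})
    cohort = simulate_cohort(sim_cfg)
    if cfg.write_cohort_files:
        write_cohort(cohort, os.path.join(cfg.out_dir, "cohort"))
    state["cohort"] = cohort
    return {"cells": len(cohort.atac.cells), "peaks": len(cohort.atac.peaks),
            "genes": len(cohort.rna.genes), "fragments": len(cohort.fragments),
            "_keys": ["cohort"]}


def _stage_qc(cfg, seed, state):
    cohort = state["cohort"]
    tss = cohort.rna.genes.rename(columns={"tss": "tss"})[["chrom", "tss"]]
    atac_metrics = preprocess.atac_qc_metrics(
        cohort.atac.counts, cohort.atac.cells, cohort.fragments, tss)
    atac_thr = preprocess.QCThresholds("atac", **cfg.qc_atac)
    atac_f, atac_report = preprocess.qc_filter(cohort.atac, atac_metrics, atac_thr)
    rna_metrics = preprocess.rna_qc_metrics(
        cohort.rna.counts, cohort.rna.genes, cohort.rna.cells)
    rna_thr = preprocess.QCThresholds("rna", **cfg.qc_rna)
    rna_f, rna_report = preprocess.qc_filter(cohort.rna, rna_metrics, rna_thr)
    shared = [c for c in atac_f.cells if c in set(rna_f.cells)]
    a_keep = [atac_f.cells.index(c) for c in shared]
    r_keep = [rna_f.cells.index(c) for c in shared]
    state["atac"] = atac_f.subset_cells(np.array(a_keep))
    state["rna"] = rna_f.subset_cells(np.array(r_keep))
    state["qc_reports"] = {"atac": atac_report.to_dict(), "rna": rna_report.to_dict()}
    return {"cells_kept": len(shared),
            "atac_removed": int(atac_report["total_removed"]),
            "rna_removed": int(rna_report["total_removed"]),
            "_keys": ["atac", "rna", "qc_reports"]}


def _stage_metacells(cfg, seed, state):
    atac = state["atac"]
    emb = preprocess.lsi_embedding(atac, n_components=cfg.lsi_components,
                                   random_state=seed)
    mc = preprocess.make_metacells(emb, k=cfg.metacell_k, seed=seed,
                                  n_groups=cfg.n_metacells)
    state["metacells"] = mc
    agg_atac = mc.aggregate(atac.counts)
    agg_rna = mc.aggregate(state["rna"].counts)
    state["agg_atac"] = np.asarray(preprocess.log_normalize(agg_atac).todense())
    state["agg_rna"] = np.asarray(preprocess.log_normalize(agg_rna).todense())
    return {"groups": len(mc), "_keys": ["metacells", "agg_atac", "agg_rna"]}


def _stage_coaccess(cfg, seed, state):
    pairs = coaccess_mod.coaccess_scores(
        state["agg_atac"], state["atac"].peaks,
        window_size=cfg.link_window,
        distance_penalty_scale=cfg.distance_penalty_scale)
    pairs.to_csv(os.path.join(cfg.out_dir, "coaccess_pairs.tsv"), sep="\t", index=False)
    state["coaccess_pairs"] = pairs
    return {"pairs": len(pairs), "_keys": ["coaccess_pairs"]}


def _stage_links(cfg, seed, state):
    atac, rna = state["atac"], state["rna"]
    cand = linking.candidate_pairs(atac.peaks, rna.genes, window=cfg.link_window)
    corr = linking.grouped_correlation(cand, state["agg_atac"], state["agg_rna"],
                                       rna.genes.index)
    null = linking.build_null(atac.peaks, rna.genes, state["agg_atac"],
                              state["agg_rna"], n_null=cfg.n_null, seed=seed)
    mu0, sd0 = null.lookup(corr["gene"])
    corr["z"], corr["p"] = linking.null_significance(corr["r"].to_numpy(), mu0, sd0)
    network = linking.build_link_network(
        corr, state["coaccess_pairs"], atac.peaks, rna.genes,
        fdr_cut=cfg.fdr_cut, coaccess_cut=cfg.coaccess_cut,
        cancer_label=cfg.cancer_label)
    if cfg.cancer_label in linking.PER_CANCER_FDR:
        log.info("cancer label %s triggered FDR override", cfg.cancer_label)
    from .regions import write_link_network
    write_link_network(network, os.path.join(cfg.out_dir, "link_network.tsv"))
    state["network"] = network
    return {"candidate_pairs": len(cand),
            "reliable_links": int(network["reliable"].sum()),
            "_keys": ["network"]}


def _stage_dars(cfg, seed, state):
    atac = state["atac"]
    lognorm = preprocess.log_normalize(atac.counts)
    meta = atac.cell_meta
    all_dars = []
    for cancer in sorted(meta["cancer_type"].unique()):
        mask = (meta["cancer_type"] == cancer).to_numpy()
        sub = lognorm[:, np.flatnonzero(mask)]
        labels = meta.loc[mask, "cell_type"].to_numpy()
        dars = differential.find_dars(sub, atac.peaks, labels, cancer_type=cancer)
        all_dars.append(dars)
    dars = pd.concat(all_dars, ignore_index=True) if all_dars else pd.DataFrame()
    dars.to_csv(os.path.join(cfg.out_dir, "dars.tsv"), sep="\t", index=False)
    state["dars"] = dars
    state["lognorm_atac"] = lognorm
    return {"dars": len(dars), "_keys": ["dars", "lognorm_atac"]}


def _stage_conserve(cfg, seed, state):
    dars, network = state["dars"], state["network"]
    atac = state["atac"]
    reliable = network[network["reliable"]]
    link_peaks = [atac.peaks[i] for i in sorted(reliable["peak_index"].unique())]
    conserved: dict[str, list] = {}
    cancers = sorted(dars["cancer_type"].unique()) if len(dars) else []
    for ct in sorted(dars["cell_type"].unique()) if len(dars) else []:
        by_cancer_links = {ca: link_peaks for ca in cancers}
        by_cancer_dars = {
            ca: [GenomicRegion.from_id(p) for p in
                 dars[(dars["cell_type"] == ct) & (dars["cancer_type"] == ca)]["peak"]]
            for ca in cancers
        }
        if len(cancers) >= 2:
            conserved[ct] = differential.conserved_regulatory_regions(
                by_cancer_links, by_cancer_dars)
    with open(os.path.join(cfg.out_dir, "conserved_regions.bed"), "w") as fh:
        for ct, regions in conserved.items():
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{ct}\n")
    state["conserved"] = conserved
    return {"cell_types": len(conserved),
            "regions": sum(len(v) for v in conserved.values()),
            "_keys": ["conserved"]}


def _stage_chromvar(cfg, seed, state):
    atac = state["atac"]
    cohort = state["cohort"]
    counts = atac.counts
    mean_acc = np.asarray(counts.mean(axis=1)).ravel()
    gc = atac.peak_gc if atac.peak_gc is not None else np.full(len(atac.peaks), 0.5)
    bg = tf.sample_background_peaks(gc, mean_acc, seed=seed)
    dev = tf.chromvar_deviations(counts, cohort.motif_matches, bg,
                                 cells=atac.cells, seed=seed)
    state["deviations"] = dev
    dev.z.T.to_csv(os.path.join(cfg.out_dir, "chromvar_z.tsv"), sep="\t",
                   float_format="%.5g")
    return {"motifs": dev.z.shape[1], "cells": dev.z.shape[0],
            "_keys": ["deviations"]}


def _stage_footprint(cfg, seed, state):
    cohort = state["cohort"]
    atac = state["atac"]
    meta = atac.cell_meta
    profiles: dict[str, dict[str, tf.FootprintProfile]] = {}
    for motif, sites in cohort.motif_sites.groupby("motif"):
        profiles[motif] = {}
        for label in ("Tumor", "Epithelial"):
            cells = meta.index[meta["cell_type"] == label]
            if not len(cells):
                continue
            try:
                profiles[motif][label] = tf.footprint_profile(
                    cohort.fragments, sites, cells, motif=motif, cell_type=label)
            except ValueError:
                continue
    state["footprints"] = profiles
    return {"motifs": len(profiles), "_keys": ["footprints"]}


def _stage_tfspecific(cfg, seed, state):
    rna = state["rna"]
    lognorm_rna = np.asarray(preprocess.log_normalize(rna.counts).todense())
    table = tf.tumor_specific_tfs(
        state["deviations"], state["footprints"], lognorm_rna,
        rna.genes.index, state["atac"].cell_meta["cell_type"].to_numpy())
    table.to_csv(os.path.join(cfg.out_dir, "tumor_specific_tfs.tsv"),
                 sep="\t", index=False)
    state["tf_table"] = table
    return {"selected": int(table["selected"].sum()), "_keys": ["tf_table"]}


def _stage_nmf(cfg, seed, state):
    rna = state["rna"]
    meta = rna.cell_meta
    rel = programs.relative_expression(
        rna.counts, rna.genes.index, rna.cells,
        meta["sample"].to_numpy(),
        (meta["cell_type"] == "Tumor").to_numpy(),
        min_cells=cfg.nmf_min_cells)
    sigs, W_by_sample, k_by_sample = programs.discover_programs(
        rel, k_range=range(cfg.nmf_k_min, cfg.nmf_k_max + 1),
        nrun=cfg.nmf_nrun, seed=seed)
    metas = programs.meta_programs(sigs, rel, W_by_sample, seed=seed)
    rows = []
    for i, mp in enumerate(metas):
        for g, s in zip(mp.signature, mp.signature_scores):
            rows.append((i, g, s))
    pd.DataFrame(rows, columns=["meta_program", "gene", "avg_nmf_score"]).to_csv(
        os.path.join(cfg.out_dir, "meta_programs.tsv"), sep="\t", index=False)
    state["meta_programs"] = metas
    state["nmf_k"] = k_by_sample
    return {"samples": len(rel), "programs": len(sigs),
            "meta_programs": len(metas),
            "k_by_sample": k_by_sample, "_keys": ["meta_programs", "nmf_k"]}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "metacells": _stage_metacells,
    "coaccess": _stage_coaccess,
    "links": _stage_links,
    "dars": _stage_dars,
    "conserve": _stage_conserve,
    "chromvar": _stage_chromvar,
    "footprint": _stage_footprint,
    "tfspecific": _stage_tfspecific,
    "nmf": _stage_nmf,
}
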