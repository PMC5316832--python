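"""End-to-end pipeline orchestration.

Stages (``simulate``, ``discover``, ``de``, ``drivers``, ``network``,
``clinical``, ``all``) read and write plain-text artefacts under a working
directory, each emitting a JSON report with effective parameters, seeds
and headline counts. A single global seed fans out to per-stage seeds by
stable hashing of stage names.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import discovery, drivers, network, recurrence
from .clinical import (
    clinical_odds_ratios,
    expression_split,
    gsea_preranked,
    km_logrank,
    nearest_template_subtype,
    signal2noise_rank,
    subclass_de,
)
from .genomic_core import read_bed, read_gtf, read_layout, write_bed, \
    write_gtf, write_layout
from .recurrence import CohortDesign
from .synthetic import SyntheticConfig, generate_cohort, stage_seed

__all__ = ["PipelineConfig", "PrerequisiteError", "run", "STAGES"]

log = logging.getLogger("lncrecur")

STAGES = ("simulate", "discover", "de", "drivers", "network", "clinical")


class PrerequisiteError(RuntimeError):
    """A stage was run before the stage producing its inputs."""


@dataclass
class PipelineConfig:
    """All tunable thresholds, at the field-standard defaults."""

    outdir: str = "lncrecur_run"
    seed: int = 0
    # discovery
    min_length: int = 200
    proximity_window: int = 2000
    fpkm_threshold: float = 0.5
    cpc_cutoff: float = 0.0
    come_cutoff: float = 0.5
    # differential expression
    gfold_sc: float = 0.01
    gfold_cutoff: float = 1.0
    gfold_draws: int = 10_000
    lfc_cutoff: float = 1.0
    q_cutoff: float = 0.05
    r_min_tumour: int = 8
    r_min_pvtt: int = 4
    n_perm_recurrence: int = 10_000
    recurrence_alpha: float = 0.05
    # drivers
    # 50 kb bins keep partial coverage of a ~150 kb deletion from diluting
    # edge bins below the per-sample aberration threshold
    cnv_bin_size: int = 50_000
    cnv_amp_threshold: float = 0.3
    cnv_del_threshold: float = -0.3
    # 2000 circular permutations keep the empirical p floor (1/(n+1)) fine
    # enough that a single aberrant bin can clear BH at q<0.25 over ~300 bins
    cnv_n_perm: int = 2000
    cnv_q_cut: float = 0.25
    meth_r_cut: float = -0.3
    promoter_upstream: int = 2000
    # network
    network_drop_fraction: float = 0.20
    bonferroni_alpha: float = 0.01
    mcl_inflation: float = 2.4
    cluster_min_size: int = 10   # genome-scale runs use 100; synthetic scale 10
    # clinical
    subclass_q_cutoff: float = 0.05
    subclass_fc_cutoff: float = 2.0
    survival_horizon_days: int = 1825
    snp_n_shuffles: int = 100
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _outdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    (p / "reports").mkdir(exist_ok=True)
    return p


def _report(cfg: PipelineConfig, stage: str, payload: dict) -> dict:
    payload = {"stage": stage, "seed": cfg.seed,
               "stage_seed": stage_seed(cfg.seed, stage),
               "params": asdict(cfg), **payload}
    path = _outdir(cfg) / "reports" / f"{stage}.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
    return payload


def _require(cfg: PipelineConfig, stage: str, *paths: str) -> None:
    out = Path(cfg.outdir)
    for rel in paths:
        if not (out / rel).exists():
            raise PrerequisiteError(
                f"stage '{stage}' needs {rel}; run the producing stage first"
            )


def run_simulate(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    syn = SyntheticConfig(**cfg.synthetic)
    bundle = generate_cohort(syn, stage_seed(cfg.seed, "simulate"))
    write_layout(bundle.genome.layout, out / "layout.tsv")
    write_gtf(bundle.genome.reference, out / "reference.gtf")
    write_gtf(bundle.genome.candidates, out / "candidates.gtf")
    bundle.counts.rename_axis("feature").to_csv(out / "counts.tsv", sep="\t")
    bundle.fpkm.rename_axis("feature").to_csv(out / "fpkm.tsv", sep="\t")
    bundle.design.write_tsv(out / "design.tsv")
    bundle.scores.to_csv(out / "scores.tsv", sep="\t")
    bundle.cnv.write_tsv(out / "segments.tsv")
    bundle.methylation.rename_axis("cpg_id").to_csv(out / "methylation.tsv",
                                                    sep="\t")
    bundle.cpg_coords.to_csv(out / "cpg_coords.tsv", sep="\t", index=False)
    write_bed(bundle.clinical["gwas"], out / "gwas_snps.bed")
    write_bed(bundle.clinical["background"], out / "background_snps.bed")
    bundle.clinical["survival"].to_csv(out / "survival.tsv", sep="\t")
    bundle.clinical["templates"].rename_axis("gene").to_csv(
        out / "templates.tsv", sep="\t")
    bundle.clinical["subtype_expr"].rename_axis("feature").to_csv(
        out / "subtype_expr.tsv", sep="\t")
    bundle.truth.to_json(out / "truth.json")
    return _report(cfg, "simulate", {
        "n_reference": len(bundle.genome.reference),
        "n_candidates": len(bundle.genome.candidates),
        "n_samples": bundle.counts.shape[1],
    })


def _load_cohort(cfg: PipelineConfig):
    out = Path(cfg.outdir)
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
    fpkm = pd.read_csv(out / "fpkm.tsv", sep="\t", index_col=0)
    design = CohortDesign.read_tsv(out / "design.tsv")
    truth = json.loads((out / "truth.json").read_text())
    return counts, fpkm, design, truth


def run_discover(cfg: PipelineConfig) -> dict:
    _require(cfg, "discover", "reference.gtf", "candidates.gtf", "fpkm.tsv",
             "scores.tsv")
    out = Path(cfg.outdir)
    reference = read_gtf(out / "reference.gtf")
    candidates = read_gtf(out / "candidates.gtf")
    fpkm = pd.read_csv(out / "fpkm.tsv", sep="\t", index_col=0)
    scores = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0)
    report = discovery.run_discovery_cascade(
        candidates, reference, fpkm, scores,
        proximity_window=cfg.proximity_window,
        fpkm_threshold=cfg.fpkm_threshold)
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    pd.Series(report.kept_ids, name="transcript_id").to_csv(
        out / "discovered_lncrnas.tsv", sep="\t", index=False)
    coding = [m for m in reference if m.biotype == "coding"]
    kept_models = [m for m in candidates
                   if m.transcript_id in set(report.kept_ids)]
    classes = discovery.classify_position(kept_models, coding,
                                          cis_window=cfg.proximity_window)
    classes.to_csv(out / "position_classes.tsv", sep="\t")

    layout = read_layout(out / "layout.tsv")
    gwas = read_bed(out / "gwas_snps.bed", "gwas", layout)
    background = read_bed(out / "background_snps.bed", "background", layout)
    lnc_models = kept_models + [m for m in reference if m.biotype == "lncRNA"]
    enr = discovery.snp_enrichment(
        [m.interval for m in lnc_models], gwas, background, layout,
        n_shuffles=cfg.snp_n_shuffles,
        seed=stage_seed(cfg.seed, "discover"))
    return _report(cfg, "discover", {
        "cascade": report.to_frame().to_dict("records"),
        "n_discovered": len(report.kept_ids),
        "position_classes": classes["position_class"].value_counts().to_dict(),
        "snp_odds_ratio": enr.odds_ratio,
        "snp_odds_ratio_control": enr.odds_ratio_control,
        "snp_p_value": enr.p_value,
    })


def _lnc_universe(cfg: PipelineConfig, fpkm: pd.DataFrame) -> list[str]:
    out = Path(cfg.outdir)
    discovered = pd.read_csv(out / "discovered_lncrnas.tsv", sep="\t")
    ref = read_gtf(out / "reference.gtf")
    ref_lnc = [m.transcript_id for m in ref if m.biotype == "lncRNA"]
    universe = list(discovered["transcript_id"]) + ref_lnc
    # expressed in the cohort at all
    return [f for f in universe if f in fpkm.index and fpkm.loc[f].max() > 0]


def run_de(cfg: PipelineConfig) -> dict:
    _require(cfg, "de", "counts.tsv", "fpkm.tsv", "design.tsv",
             "discovered_lncrnas.tsv")
    out = Path(cfg.outdir)
    counts, fpkm, design, _truth = _load_cohort(cfg)
    universe = _lnc_universe(cfg, fpkm)
    lib = counts.sum(axis=0)
    summary = {}
    for contrast, r_min in (("tumour_vs_normal", cfg.r_min_tumour),
                            ("pvtt_vs_tumour", cfg.r_min_pvtt)):
        calls = recurrence.per_patient_calls(
            counts.loc[universe], design, contrast,
            gfold_cutoff=cfg.gfold_cutoff, sc=cfg.gfold_sc,
            n_draws=cfg.gfold_draws,
            seed=stage_seed(cfg.seed, f"de:{contrast}"), lib_sizes=lib)
        calls.to_csv(out / f"calls_{contrast}.tsv", sep="\t", index=False)
        rec = recurrence.recurrence_counts(calls, universe)
        # the standard thresholds are operative; the permutation FDR at
        # and around them is estimated and reported alongside
        sets = recurrence.fdr_thresholded_sets(
            calls, rec, len(universe), r_floor=r_min,
            n_perm=cfg.n_perm_recurrence, alpha=cfg.recurrence_alpha,
            seed=stage_seed(cfg.seed, f"fdr:{contrast}"))
        for direction in ("up", "down"):
            res = sets[direction]["fdr"]
            if res is not None:
                res.table.to_csv(
                    out / f"recurrence_fdr_{direction}_{contrast}.tsv",
                    sep="\t")
        cls = recurrence.classify_bimorphic(rec, r_min)
        rec = rec.assign(recurrence_class=cls)
        rec.to_csv(out / f"recurrence_{contrast}.tsv", sep="\t")
        gfold_up = set(rec.index[rec["n_up"] >= r_min])
        gfold_down = set(rec.index[rec["n_down"] >= r_min])

        if contrast == "tumour_vs_normal":
            wil = recurrence.wilcoxon_de(fpkm.loc[universe], design, contrast,
                                         cfg.lfc_cutoff, cfg.q_cutoff)
            nbw = recurrence.nb_wald_de(counts.loc[universe], design,
                                        contrast, cfg.lfc_cutoff,
                                        cfg.q_cutoff)
            wil.to_csv(out / f"wilcoxon_{contrast}.tsv", sep="\t")
            nbw.to_csv(out / f"nb_wald_{contrast}.tsv", sep="\t")
            w_sets = (set(wil.index[wil["direction"] == "up"]),
                      set(wil.index[wil["direction"] == "down"]))
            n_sets = (set(nbw.index[nbw["direction"] == "up"]),
                      set(nbw.index[nbw["direction"] == "down"]))
        else:
            w_sets = n_sets = (set(), set())
        up, down = recurrence.intersect_methods(
            (gfold_up, gfold_down), n_sets, w_sets, contrast, logger=log)
        final = pd.DataFrame(
            [(f, "up") for f in sorted(up)] + [(f, "down") for f in sorted(down)],
            columns=["feature", "direction"])
        final.to_csv(out / f"recurrent_{contrast}.tsv", sep="\t", index=False)
        summary[contrast] = {
            "n_up": len(up), "n_down": len(down), "r_min": r_min,
            "fdr_rule_r_up": sets["up"]["r"],
            "fdr_rule_r_down": sets["down"]["r"],
        }
    return _report(cfg, "de", {"contrasts": summary,
                               "universe_size": len(universe)})


def run_drivers(cfg: PipelineConfig) -> dict:
    _require(cfg, "drivers", "segments.tsv", "methylation.tsv",
             "cpg_coords.tsv", "recurrence_tumour_vs_normal.tsv")
    out = Path(cfg.outdir)
    counts, fpkm, design, _ = _load_cohort(cfg)
    layout = read_layout(out / "layout.tsv")
    segset = drivers.CnvSegmentSet.read_tsv(out / "segments.tsv")
    rec = pd.read_csv(out / "recurrence_tumour_vs_normal.tsv", sep="\t",
                      index_col=0)
    rec_class = rec["recurrence_class"]
    models = {}
    for m in read_gtf(out / "reference.gtf") + read_gtf(out / "candidates.gtf"):
        models[m.transcript_id] = m

    gres = drivers.gscore_scan(
        segset, layout, bin_size=cfg.cnv_bin_size,
        amp_threshold=cfg.cnv_amp_threshold,
        del_threshold=cfg.cnv_del_threshold, n_perm=cfg.cnv_n_perm,
        q_cut=cfg.cnv_q_cut, seed=stage_seed(cfg.seed, "drivers"))
    gres.bins.to_csv(out / "gscore_bins.tsv", sep="\t", index=False)
    gres.regions.to_csv(out / "cnv_regions.tsv", sep="\t", index=False)
    cnv_calls = drivers.map_lncrna_cnv(rec_class, gres.regions, models)
    cnv_calls.to_csv(out / "cnv_driven.tsv", sep="\t", index=False)

    cpgs = pd.read_csv(out / "cpg_coords.tsv", sep="\t")
    meth = pd.read_csv(out / "methylation.tsv", sep="\t", index_col=0)
    recurrent = [f for f in rec_class.index
                 if rec_class[f] != "none" and f in models]
    cpg_map = drivers.assign_promoter_cpgs(
        [models[f] for f in recurrent], cpgs,
        upstream=cfg.promoter_upstream, layout=layout)
    meth_calls = drivers.methylation_driver_call(fpkm, meth, cpg_map,
                                                 r_cut=cfg.meth_r_cut)
    meth_calls.to_csv(out / "methylation_driven.tsv", sep="\t", index=False)
    summary = drivers.summarize_drivers(cnv_calls, meth_calls, rec_class)
    summary.to_csv(out / "driver_summary.tsv", sep="\t", index=False)
    return _report(cfg, "drivers", {
        "n_regions": len(gres.regions),
        "n_cnv_driven": len(cnv_calls),
        "n_methylation_driven": int(meth_calls["methylation_driven"].sum())
        if len(meth_calls) else 0,
    })


def run_network(cfg: PipelineConfig) -> dict:
    _require(cfg, "network", "fpkm.tsv", "discovered_lncrnas.tsv",
             "recurrent_tumour_vs_normal.tsv")
    out = Path(cfg.outdir)
    fpkm = pd.read_csv(out / "fpkm.tsv", sep="\t", index_col=0)
    kept = network.prefilter_low_expression(fpkm, cfg.network_drop_fraction)
    graph = network.build_graph(fpkm.loc[kept], alpha=cfg.bonferroni_alpha,
                                logger=log)
    clustering = network.mcl_cluster(graph, inflation=cfg.mcl_inflation)
    clustering = network.filter_and_link_clusters(clustering, graph,
                                                  cfg.cluster_min_size)
    clustering.labels().rename_axis("feature").to_csv(
        out / "clusters.tsv", sep="\t")
    edges = pd.DataFrame(
        [(a, b, d["r"], d["p_adj"]) for a, b, d in graph.edges(data=True)],
        columns=["node_a", "node_b", "r", "p_adj"])
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    recurrent = pd.read_csv(out / "recurrent_tumour_vs_normal.tsv", sep="\t")
    special = set(recurrent["feature"]) & set(graph.nodes)
    universe = set(graph.nodes)
    enr = network.cluster_set_enrichment(clustering, special, universe)
    enr.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)
    return _report(cfg, "network", {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_clusters_retained": len(clustering.retained),
        "inter_cluster_edges": clustering.inter_cluster_edges,
    })


def run_clinical(cfg: PipelineConfig) -> dict:
    _require(cfg, "clinical", "survival.tsv", "templates.tsv",
             "subtype_expr.tsv", "recurrent_tumour_vs_normal.tsv",
             "fpkm.tsv")
    out = Path(cfg.outdir)
    counts, fpkm, design, _ = _load_cohort(cfg)
    seed = stage_seed(cfg.seed, "clinical")

    # preranked enrichment of the recurrent set in the cohort's own ranking
    labels = pd.Series(
        {s: design.samples.loc[s, "tissue"]
         for s in design.samples.index
         if design.samples.loc[s, "tissue"] in ("tumour", "normal")})
    universe = _lnc_universe(cfg, fpkm)
    ranked = signal2noise_rank(fpkm.loc[universe], labels,
                               group_order=("tumour", "normal"))
    recurrent = pd.read_csv(out / "recurrent_tumour_vs_normal.tsv", sep="\t")
    up_set = set(recurrent.loc[recurrent["direction"] == "up", "feature"])
    if up_set:
        es, es_p = gsea_preranked(ranked, up_set, n_perm=200, seed=seed)
    else:
        es, es_p = float("nan"), float("nan")

    surv = pd.read_csv(out / "survival.tsv", sep="\t", index_col=0)
    groups = expression_split(surv["marker_expression"])
    surv = surv.assign(group=groups)
    _curves, logrank_p = km_logrank(surv, cfg.survival_horizon_days)
    ors = clinical_odds_ratios(
        surv[["afp_high", "vascular_invasion", "age_over_60"]], groups)
    ors.to_csv(out / "clinical_odds_ratios.tsv", sep="\t", index=False)

    templates = pd.read_csv(out / "templates.tsv", sep="\t", index_col=0)
    subtype_expr = pd.read_csv(out / "subtype_expr.tsv", sep="\t",
                               index_col=0)
    ntp = nearest_template_subtype(subtype_expr, templates, n_perm=200,
                                   seed=seed)
    ntp.to_csv(out / "subtypes.tsv", sep="\t")
    sde = subclass_de(subtype_expr, ntp["subclass"],
                      q_cutoff=cfg.subclass_q_cutoff,
                      fc_cutoff=cfg.subclass_fc_cutoff)
    sde.to_csv(out / "subclass_de.tsv", sep="\t", index=False)
    return _report(cfg, "clinical", {
        "gsea_es": es, "gsea_p": es_p,
        "logrank_p": logrank_p,
        "odds_ratios": ors.set_index("covariate")["odds_ratio"].to_dict(),
        "subtype_counts": ntp["subclass"].value_counts().to_dict(),
        "n_subclass_de": int(sde["significant"].sum()) if len(sde) else 0,
    })


_RUNNERS = {
    "simulate": run_simulate,
    "discover": run_discover,
    "de": run_de,
    "drivers": run_drivers,
    "network": run_network,
    "clinical": run_clinical,
}


def run(stage: str, cfg: PipelineConfig) -> dict:
    """Run one stage (or ``all``) and return its JSON report payload."""
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    if stage == "all":
        payload = {}
        for s in STAGES:
            t0 = time.time()
            payload[s] = _RUNNERS[s](cfg)
            log.info("stage %s finished in %.1f s", s, time.time() - t0)
        return payload
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; choose from "
                         f"{STAGES + ('all',)}")
    return _RUNNERS[stage](cfg)
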