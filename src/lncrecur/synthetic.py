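"""Synthetic matched-cohort generator with planted ground truth.

Emulates the processed data shapes of a 20-patient cohort with three
matched tissues per patient (adjacent normal, primary tumour, portal-vein
tumour thrombus): negative-binomial RNA-seq counts with per-patient random
effects, planted recurrently up/down lncRNAs, discovery-filter decoys, a
recurrent deletion, promoter hypermethylation anticorrelated with
expression, GWAS-SNP enrichment in lncRNA loci, planted co-expression
modules, survival and clinical covariates, and tumour-subtype templates.

Every generator is a pure function of (config, seed); the planted-truth
ledger is sufficient to score any downstream stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genomic_core import GenomeLayout, GenomicInterval, TranscriptModel
from .recurrence import CohortDesign

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "GenomeBundle",
    "CohortBundle",
    "stage_seed",
    "make_genome",
    "simulate_expression",
    "simulate_cnv",
    "simulate_methylation",
    "simulate_snps_and_clinical",
    "generate_cohort",
]

PATIENTS = [chr(ord("A") + i) for i in range(20)]
EXCLUDED_PVTT_PATIENT = "I"

DECOY_CLASSES = (
    "decoy_overlap",       # removed at exonic_overlap
    "decoy_short",         # removed at length_strand
    "decoy_proximal",      # removed at single_exon_proximity
    "decoy_lowexpr",       # removed at expression
    "decoy_coding",        # removed at coding_potential
)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed from a global one by stable hashing of the stage name,
    so adding a stage never perturbs another stage's randomness."""
    h = hashlib.sha256(f"{stage}".encode()).digest()
    return (int(seed) ^ int.from_bytes(h[:4], "big")) % (2**31 - 1)


@dataclass
class SyntheticConfig:
    """Study conditions of the emulated cohort."""

    # genome
    n_chroms: int = 3
    chrom_len: int = 10_000_000
    n_coding: int = 500
    n_ref_lncrna: int = 300
    n_lncrna: int = 800
    n_decoys: int = 300
    # cohort / expression
    n_patients: int = 20
    nb_dispersion: float = 0.1
    patient_sigma: float = 0.3
    libsize_sigma: float = 0.25
    effect_log2: float = 2.0
    n_tumour_up: int = 40
    n_tumour_down: int = 40
    tumour_recurrence: int = 12      # min planted patients per tumour feature
    tumour_recurrence_max: int = 18  # max; per-feature prevalence is drawn
    n_pvtt_up: int = 15
    n_pvtt_down: int = 15
    pvtt_recurrence: int = 5         # min planted patients per pvtt feature
    pvtt_recurrence_max: int = 9
    # co-expression modules
    n_modules: int = 4
    module_size_coding: int = 30
    module_size_lnc: int = 10
    module_sigma: float = 0.8
    # CNV
    n_cnv_features: int = 8
    cnv_penetrance: float = 0.6
    cnv_log2: float = -0.8
    cnv_log2_sd: float = 0.1
    # methylation
    n_meth_features: int = 10
    meth_r_target: float = -0.5
    cpg_per_promoter_lambda: float = 3.0
    # SNPs
    background_snp_spacing: int = 2_000
    gwas_base_spacing: int = 20_000
    gwas_enrichment_factor: float = 5.0
    # survival / clinical
    n_subjects: int = 150
    hazard_ratio: float = 2.0
    base_survival_scale: float = 1500.0
    horizon_days: int = 1825
    # subtypes
    n_signature_genes: int = 30
    n_subtype_samples: int = 60
    subtype_noise_sd: float = 0.8


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated cohort."""

    tumour_up: dict[str, list[str]] = field(default_factory=dict)
    tumour_down: dict[str, list[str]] = field(default_factory=dict)
    pvtt_up: dict[str, list[str]] = field(default_factory=dict)
    pvtt_down: dict[str, list[str]] = field(default_factory=dict)
    cnv_features: list[str] = field(default_factory=list)
    cnv_region: tuple[str, int, int] | None = None
    cnv_carriers: list[str] = field(default_factory=list)
    meth_features: list[str] = field(default_factory=list)
    modules: dict[str, list[str]] = field(default_factory=dict)
    decoy_stage: dict[str, str] = field(default_factory=dict)
    lnc_universe: list[str] = field(default_factory=list)
    survival_marker: str | None = None
    subtype_labels: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


@dataclass
class GenomeBundle:
    layout: GenomeLayout
    reference: list[TranscriptModel]   # coding + annotated lncRNA
    candidates: list[TranscriptModel]  # true lncRNAs + decoys
    decoy_stage: dict[str, str]        # decoy transcript -> removing stage
    true_lnc_ids: list[str]

    @property
    def models(self) -> dict[str, TranscriptModel]:
        out = {m.transcript_id: m for m in self.reference}
        out.update({m.transcript_id: m for m in self.candidates})
        return out


def _make_exons(chrom, start, strand, exon_lens, intron_lens):
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
        pos += int(el)
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    return exons, pos


def make_genome(n_chroms: int = 3, chrom_len: int = 10_000_000,
                n_coding: int = 500, n_lncrna: int = 800,
                n_decoys: int = 300, seed: int = 0,
                n_ref_lncrna: int = 300) -> GenomeBundle:
    """Lay out non-overlapping coding genes, annotated lncRNAs, candidate
    lncRNAs and filter decoys on a small genome.

    Decoy classes each violate exactly one discovery filter: same-strand
    exon overlap, sub-200-bp / unstranded, proximal single-exon, low-FPKM
    single-exon (long, weakly expressed), and ORF-bearing (flagged coding
    by the potential scores).
    """
    rng = np.random.default_rng(stage_seed(seed, "genome"))
    layout = GenomeLayout({f"chr{i+1}": chrom_len for i in range(n_chroms)})
    chroms = layout.chroms

    per_class = n_decoys // 5
    n_overlap = n_decoys - 4 * per_class
    queue: list[tuple[str, int]] = []
    queue += [("coding", i) for i in range(n_coding)]
    queue += [("ref_lnc", i) for i in range(n_ref_lncrna)]
    queue += [("lnc", i) for i in range(n_lncrna)]
    queue += [("decoy_short", i) for i in range(per_class)]
    queue += [("decoy_lowexpr", i) for i in range(per_class)]
    queue += [("decoy_coding", i) for i in range(per_class)]
    rng.shuffle(queue)

    cursors = {c: int(rng.integers(5_000, 15_000)) for c in chroms}
    reference: list[TranscriptModel] = []
    candidates: list[TranscriptModel] = []
    decoy_stage: dict[str, str] = {}
    true_lnc_ids: list[str] = []
    coding_models: list[TranscriptModel] = []

    ci = 0
    for kind, i in queue:
        chrom = chroms[ci % n_chroms]
        ci += 1
        start = cursors[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "coding":
            n_ex = int(rng.integers(3, 7))
            exon_lens = rng.integers(150, 500, n_ex)
            intron_lens = rng.integers(200, 2000, n_ex - 1)
            tid = f"CODING_{i:04d}"
            biotype = "coding"
        elif kind == "ref_lnc":
            n_ex = int(rng.integers(1, 4))
            exon_lens = rng.integers(300, 900, n_ex)
            intron_lens = rng.integers(200, 1500, max(n_ex - 1, 0))
            tid = f"REFLNC_{i:04d}"
            biotype = "lncRNA"
        elif kind == "lnc":
            if rng.random() < 0.6:
                n_ex = int(rng.integers(2, 4))
                exon_lens = rng.integers(250, 900, n_ex)
                intron_lens = rng.integers(200, 1500, n_ex - 1)
            else:
                n_ex = 1
                exon_lens = rng.integers(500, 2500, 1)
                intron_lens = np.array([], dtype=int)
            tid = f"XLOC_{i:05d}"
            biotype = "candidate"
        elif kind == "decoy_short":
            tid = f"DSHORT_{i:04d}"
            biotype = "candidate"
            if i % 2 == 0:
                exon_lens = rng.integers(100, 190, 1)
            else:
                exon_lens = rng.integers(300, 600, 1)
                strand = "."
            intron_lens = np.array([], dtype=int)
        elif kind == "decoy_lowexpr":
            tid = f"DLOW_{i:04d}"
            biotype = "candidate"
            exon_lens = rng.integers(8_000, 12_000, 1)
            intron_lens = np.array([], dtype=int)
        else:  # decoy_coding
            tid = f"DORF_{i:04d}"
            biotype = "candidate"
            exon_lens = rng.integers(400, 900, 2)
            intron_lens = rng.integers(300, 1200, 1)

        exons, end = _make_exons(chrom, start, strand, exon_lens, intron_lens)
        if end > chrom_len - 20_000:
            raise ValueError(
                "cannot place loci without overlap at the requested density"
            )
        hull = GenomicInterval(chrom, start, end, strand)
        model = TranscriptModel(tid, tid, hull, exons, biotype)
        if kind == "coding":
            reference.append(model)
            coding_models.append(model)
        elif kind == "ref_lnc":
            reference.append(model)
        else:
            candidates.append(model)
            if kind == "lnc":
                true_lnc_ids.append(tid)
            else:
                stage = {"decoy_short": "length_strand",
                         "decoy_lowexpr": "expression",
                         "decoy_coding": "coding_potential"}[kind]
                decoy_stage[tid] = stage
        cursors[chrom] = end + int(rng.integers(3_000, 9_000))

    # anchored decoys: same-strand exon overlap, and proximal single-exon
    for i in range(n_overlap):
        host = coding_models[int(rng.integers(0, len(coding_models)))]
        ex = host.exons[int(rng.integers(0, host.n_exons))]
        start = ex.start + max(1, len(ex) // 4)
        length = int(rng.integers(300, 800))
        iv = GenomicInterval(ex.chrom, start, start + length, ex.strand)
        tid = f"DOVER_{i:04d}"
        candidates.append(TranscriptModel(tid, tid, iv, [iv], "candidate"))
        decoy_stage[tid] = "exonic_overlap"
    for i in range(per_class):
        host = coding_models[int(rng.integers(0, len(coding_models)))]
        gap = int(rng.integers(200, 1500))
        start = host.interval.end + gap
        length = int(rng.integers(300, 600))
        iv = GenomicInterval(host.chrom, start, start + length,
                             host.strand)
        tid = f"DPROX_{i:04d}"
        candidates.append(TranscriptModel(tid, tid, iv, [iv], "candidate"))
        decoy_stage[tid] = "single_exon_proximity"

    return GenomeBundle(layout, reference, candidates, decoy_stage,
                        true_lnc_ids)


def make_design(cfg: SyntheticConfig) -> CohortDesign:
    rows = []
    patients = PATIENTS[: cfg.n_patients]
    for p in patients:
        for tissue in ("normal", "tumour", "pvtt"):
            rows.append({"sample_id": f"{p}_{tissue}", "patient": p,
                         "tissue": tissue})
    df = pd.DataFrame(rows).set_index("sample_id")
    excluded = {(EXCLUDED_PVTT_PATIENT, "pvtt")} \
        if EXCLUDED_PVTT_PATIENT in patients else set()
    return CohortDesign(df, excluded)


def coding_potential_scores(genome: GenomeBundle, seed: int) -> pd.DataFrame:
    """CPC/COME-style score table for all candidates: negative CPC and low
    COME for noncoding transcripts, positive CPC for ORF-bearing decoys."""
    rng = np.random.default_rng(stage_seed(seed, "scores"))
    rows = []
    for m in genome.candidates:
        if genome.decoy_stage.get(m.transcript_id) == "coding_potential":
            cpc = float(rng.normal(2.0, 0.5))
            come = float(rng.uniform(0.6, 0.95))
        else:
            cpc = float(rng.normal(-2.0, 0.5))
            come = float(rng.uniform(0.0, 0.4))
        rows.append({"transcript_id": m.transcript_id, "cpc_score": cpc,
                     "come_score": come})
    return pd.DataFrame(rows).set_index("transcript_id")


def _choose_patient_subsets(rng, features, patients, k_min, k_max):
    """Per-feature planted-patient subsets; prevalence is drawn uniformly
    from [k_min, k_max], emulating the spread of recurrence levels seen in
    real matched cohorts rather than a single fixed penetrance."""
    out = {}
    for f in features:
        k = int(rng.integers(k_min, min(k_max, len(patients)) + 1))
        out[f] = sorted(rng.choice(patients, size=k, replace=False))
    return out


def simulate_expression(genome: GenomeBundle, cfg: SyntheticConfig,
                        seed: int) -> tuple[pd.DataFrame, pd.DataFrame,
                                            CohortDesign, SyntheticTruth]:
    """Negative-binomial counts and FPKM for the matched cohort.

    Planted effects are per-(feature, patient): a tumour-contrast feature
    shifts its tumour AND PVTT samples (so the change persists into the
    thrombus and cancels in the PVTT-vs-tumour contrast) in exactly
    ``tumour_recurrence`` patients; PVTT-contrast features shift only the
    PVTT sample in ``pvtt_recurrence`` usable patients. CNV-planted
    features are down in the deletion carriers. Co-expression modules share
    a per-(module, patient) log-normal factor.
    """
    rng = np.random.default_rng(stage_seed(seed, "expression"))
    design = make_design(cfg)
    patients = design.patients
    usable_pvtt = [p for p in patients if (p, "pvtt") not in design.excluded]

    ref_ids = [m.transcript_id for m in genome.reference]
    cand_ids = [m.transcript_id for m in genome.candidates]
    features = ref_ids + cand_ids
    models = genome.models
    efflen = np.array([models[f].exonic_length for f in features], dtype=float)
    fidx = {f: i for i, f in enumerate(features)}

    coding_ids = [m.transcript_id for m in genome.reference
                  if m.biotype == "coding"]
    ref_lnc_ids = [m.transcript_id for m in genome.reference
                   if m.biotype == "lncRNA"]
    lnc_universe = ref_lnc_ids + genome.true_lnc_ids

    # baselines
    base = np.empty(len(features))
    for f in features:
        i = fidx[f]
        if genome.decoy_stage.get(f) == "expression":
            base[i] = 0.08 * np.exp(rng.normal(0.0, 0.3))
        elif f in coding_ids or f.startswith("CODING"):
            base[i] = np.exp(rng.normal(7.5, 0.6))
        else:
            base[i] = np.exp(rng.normal(7.2, 0.6))

    truth = SyntheticTruth(seed=seed, params=asdict(cfg))
    truth.lnc_universe = sorted(lnc_universe)

    # CNV-planted features: consecutive candidate lncRNAs on chr1
    chr1_lnc = [f for f in genome.true_lnc_ids
                if models[f].chrom == "chr1"]
    chr1_lnc.sort(key=lambda f: models[f].interval.start)
    k_cnv = min(cfg.n_cnv_features, len(chr1_lnc))
    start_at = int(rng.integers(0, max(len(chr1_lnc) - k_cnv, 1)))
    cnv_feats = chr1_lnc[start_at:start_at + k_cnv]
    truth.cnv_features = cnv_feats
    if cnv_feats:
        # the deleted segment extends well past the outermost affected
        # loci, as recurrent deletions do
        lo = min(models[f].interval.start for f in cnv_feats) - 25_000
        hi = max(models[f].interval.end for f in cnv_feats) + 25_000
        truth.cnv_region = ("chr1", max(lo, 0), hi)
    n_carriers = int(round(cfg.cnv_penetrance * cfg.n_patients))
    truth.cnv_carriers = sorted(rng.choice(patients, n_carriers,
                                           replace=False))

    # planted recurrent sets (disjoint; cnv features are part of tumour-down)
    pool = [f for f in lnc_universe if f not in cnv_feats]
    rng.shuffle(pool)
    need = (cfg.n_tumour_up + max(cfg.n_tumour_down - k_cnv, 0)
            + cfg.n_pvtt_up + cfg.n_pvtt_down)
    if need > len(pool):
        raise ValueError("not enough lncRNAs for the requested planted sets")
    it = iter(pool)
    up_feats = [next(it) for _ in range(cfg.n_tumour_up)]
    down_feats = cnv_feats + [next(it)
                              for _ in range(cfg.n_tumour_down - k_cnv)]
    pvtt_up_feats = [next(it) for _ in range(cfg.n_pvtt_up)]
    pvtt_down_feats = [next(it) for _ in range(cfg.n_pvtt_down)]

    truth.tumour_up = _choose_patient_subsets(
        rng, up_feats, patients, cfg.tumour_recurrence,
        cfg.tumour_recurrence_max)
    truth.tumour_down = _choose_patient_subsets(
        rng, [f for f in down_feats if f not in cnv_feats], patients,
        cfg.tumour_recurrence, cfg.tumour_recurrence_max)
    for f in cnv_feats:
        truth.tumour_down[f] = truth.cnv_carriers
    truth.pvtt_up = _choose_patient_subsets(
        rng, pvtt_up_feats, usable_pvtt, cfg.pvtt_recurrence,
        cfg.pvtt_recurrence_max)
    truth.pvtt_down = _choose_patient_subsets(
        rng, pvtt_down_feats, usable_pvtt, cfg.pvtt_recurrence,
        cfg.pvtt_recurrence_max)

    # methylation-driven subset of the tumour-down features (non-CNV)
    meth_pool = [f for f in down_feats if f not in cnv_feats]
    truth.meth_features = sorted(
        rng.choice(meth_pool, min(cfg.n_meth_features, len(meth_pool)),
                   replace=False))
    if truth.meth_features:
        truth.survival_marker = truth.meth_features[0]
    elif down_feats:
        truth.survival_marker = down_feats[0]

    # co-expression modules among unplanted features
    planted = set(up_feats) | set(down_feats) | set(pvtt_up_feats) \
        | set(pvtt_down_feats)
    free_coding = [f for f in coding_ids]
    free_lnc = [f for f in lnc_universe if f not in planted]
    rng.shuffle(free_coding)
    rng.shuffle(free_lnc)
    ic, il = iter(free_coding), iter(free_lnc)
    for mi in range(cfg.n_modules):
        members = [next(ic) for _ in range(cfg.module_size_coding)] \
            + [next(il) for _ in range(cfg.module_size_lnc)]
        truth.modules[f"module_{mi}"] = sorted(members)

    # mean matrix
    samples = list(design.samples.index)
    sidx = {s: j for j, s in enumerate(samples)}
    logmu = np.log(base)[:, None] * np.ones((1, len(samples)))
    # per-(feature, patient) random effect shared across the three tissues
    for p in patients:
        eff = rng.normal(0.0, cfg.patient_sigma, len(features))
        for tissue in ("normal", "tumour", "pvtt"):
            logmu[:, sidx[f"{p}_{tissue}"]] += eff
    # module factor per (module, patient)
    for mname, members in truth.modules.items():
        rows = [fidx[f] for f in members]
        for p in patients:
            z = rng.normal(0.0, cfg.module_sigma)
            for tissue in ("normal", "tumour", "pvtt"):
                logmu[np.ix_(rows, [sidx[f"{p}_{tissue}"]])] += z
    # planted effects
    ln2eff = cfg.effect_log2 * np.log(2.0)

    def bump(feature, patient, tissues, sign):
        for tissue in tissues:
            logmu[fidx[feature], sidx[f"{patient}_{tissue}"]] += sign * ln2eff

    for f, pats in truth.tumour_up.items():
        for p in pats:
            bump(f, p, ("tumour", "pvtt"), +1)
    for f, pats in truth.tumour_down.items():
        for p in pats:
            bump(f, p, ("tumour", "pvtt"), -1)
    for f, pats in truth.pvtt_up.items():
        for p in pats:
            bump(f, p, ("pvtt",), +1)
    for f, pats in truth.pvtt_down.items():
        for p in pats:
            bump(f, p, ("pvtt",), -1)

    # library-size factor per sample
    libfac = np.exp(rng.normal(0.0, cfg.libsize_sigma, len(samples)))
    logmu += np.log(libfac)[None, :]

    mu = np.exp(logmu)
    disp = cfg.nb_dispersion
    lam = rng.gamma(1.0 / disp, disp * mu)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=features, columns=samples)
    libsize = counts_df.sum(axis=0)
    fpkm = counts_df * 1e9 / np.outer(efflen, libsize.to_numpy())
    fpkm_df = pd.DataFrame(fpkm, index=features, columns=samples)
    return counts_df, fpkm_df, design, truth


def simulate_cnv(truth: SyntheticTruth, layout: GenomeLayout,
                 design: CohortDesign, cfg: SyntheticConfig, seed: int):
    """SEG-like copy-number segments: near-zero background everywhere, plus
    the planted deletion in carrier tumour and PVTT samples."""
    from .drivers import CnvSegmentSet

    rng = np.random.default_rng(stage_seed(seed, "cnv"))
    chrom_r, r_start, r_end = truth.cnv_region or ("", -1, -1)
    carriers = set(truth.cnv_carriers)
    rows = []
    for sample in design.samples.index:
        patient = design.samples.loc[sample, "patient"]
        tissue = design.samples.loc[sample, "tissue"]
        is_del = patient in carriers and tissue in ("tumour", "pvtt")
        for chrom in layout.chroms:
            L = layout[chrom]
            bps = sorted(set(
                [0, L] + list(rng.integers(0, L, 4))
                + ([r_start, r_end] if chrom == chrom_r else [])
            ))
            for a, b in zip(bps[:-1], bps[1:]):
                if b <= a:
                    continue
                if is_del and chrom == chrom_r and a >= r_start and b <= r_end:
                    val = cfg.cnv_log2 + rng.normal(0.0, cfg.cnv_log2_sd)
                else:
                    val = rng.normal(0.0, 0.05)
                rows.append({"sample_id": sample, "chrom": chrom,
                             "start": int(a), "end": int(b),
                             "log2ratio": float(val)})
    return CnvSegmentSet(pd.DataFrame(rows))


def simulate_methylation(truth: SyntheticTruth, genome: GenomeBundle,
                         fpkm: pd.DataFrame, cfg: SyntheticConfig,
                         seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter CpG coordinates and a beta-value matrix.

    Methylation-driven features get one promoter CpG that is
    hypermethylated in the tumour and PVTT samples of exactly the patients
    carrying the planted expression loss — the mechanistic direction of
    promoter silencing — with noise calibrated so the realised
    expression-beta Pearson correlation lands near ``meth_r_target``. All
    other CpGs are independent of expression.
    """
    from .genomic_core import promoter_of

    rng = np.random.default_rng(stage_seed(seed, "methylation"))
    models = genome.models
    samples = list(fpkm.columns)
    coords = []
    betas = []
    cpg_i = 0
    lnc_ids = [f for f in truth.lnc_universe if f in models]
    driven = set(truth.meth_features)
    for f in lnc_ids:
        prom = promoter_of(models[f], 2000, genome.layout)
        if prom is None:
            continue
        n_cpg = int(rng.poisson(cfg.cpg_per_promoter_lambda))
        if f in driven:
            n_cpg = max(n_cpg, 1)
        positions = sorted(rng.integers(prom.start, prom.end, n_cpg))
        for k, pos in enumerate(positions):
            cid = f"cg{cpg_i:06d}"
            cpg_i += 1
            coords.append({"cpg_id": cid, "chrom": prom.chrom,
                           "pos": int(pos)})
            if f in driven and k == 0:
                carriers = set(truth.tumour_down.get(f, []))
                hyper = np.array([
                    s.split("_", 1)[0] in carriers
                    and s.split("_", 1)[1] in ("tumour", "pvtt")
                    for s in samples
                ])
                beta = np.clip(
                    0.35 + 0.25 * hyper
                    + rng.normal(0.0, 0.13, len(samples)),
                    0.01, 0.99)
            else:
                centre = rng.uniform(0.2, 0.8)
                beta = np.clip(centre + rng.normal(0.0, 0.1, len(samples)),
                               0.0, 1.0)
            betas.append(beta)
    # background CpGs outside promoters
    for _ in range(1000):
        chrom = genome.layout.chroms[
            int(rng.integers(0, len(genome.layout.chroms)))]
        cid = f"cg{cpg_i:06d}"
        cpg_i += 1
        coords.append({"cpg_id": cid, "chrom": chrom,
                       "pos": int(rng.integers(0, genome.layout[chrom]))})
        centre = rng.uniform(0.2, 0.8)
        betas.append(np.clip(centre + rng.normal(0.0, 0.1, len(samples)),
                             0.0, 1.0))
    coords_df = pd.DataFrame(coords)
    beta_df = pd.DataFrame(np.vstack(betas), index=coords_df["cpg_id"],
                           columns=samples)
    return beta_df, coords_df


def simulate_snps_and_clinical(truth: SyntheticTruth, genome: GenomeBundle,
                               cfg: SyntheticConfig, seed: int) -> dict:
    """GWAS/background SNP catalogues, a survival table tied to the planted
    marker, clinical covariates with planted odds ratios, and subtype
    templates with a subtype-structured expression layer."""
    from .genomic_core import SnpCatalog

    rng = np.random.default_rng(stage_seed(seed, "snps_clinical"))
    layout = genome.layout
    models = genome.models
    lnc_ivs = [models[f].interval for f in truth.lnc_universe if f in models]

    bg_pairs = []
    gwas_pairs = []
    for chrom in layout.chroms:
        L = layout[chrom]
        n_bg = L // cfg.background_snp_spacing
        bg_pairs += [(chrom, int(p)) for p in rng.integers(0, L, n_bg)]
        n_gwas = L // cfg.gwas_base_spacing
        gwas_pairs += [(chrom, int(p)) for p in rng.integers(0, L, n_gwas)]
    # extra GWAS density inside lncRNA loci
    extra = cfg.gwas_enrichment_factor - 1.0
    for iv in lnc_ivs:
        lam = extra * len(iv) / cfg.gwas_base_spacing
        n = rng.poisson(lam)
        if n:
            gwas_pairs += [(iv.chrom, int(p))
                           for p in rng.integers(iv.start, iv.end, n)]
    gwas = SnpCatalog.from_pairs(gwas_pairs, "gwas", layout)
    background = SnpCatalog.from_pairs(bg_pairs, "background", layout)

    # survival cohort keyed to the planted marker's expression
    n = cfg.n_subjects
    subjects = [f"S{i:03d}" for i in range(n)]
    marker = pd.Series(np.exp(rng.normal(2.0, 1.0, n)), index=subjects,
                       name=truth.survival_marker)
    order = marker.sort_values(kind="mergesort").index
    n_low = int(round(n / 3))
    low = set(order[:n_low])
    scale = np.where([s in low for s in subjects],
                     cfg.base_survival_scale / cfg.hazard_ratio,
                     cfg.base_survival_scale)
    t_event = rng.exponential(scale)
    t_cens = rng.uniform(200, 2600, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    afp = rng.random(n) < np.where([s in low for s in subjects], 0.60, 0.33)
    vinv = rng.random(n) < np.where([s in low for s in subjects], 0.55, 0.30)
    age = rng.random(n) < 0.5
    survival = pd.DataFrame({
        "subject": subjects,
        "time_days": np.maximum(time, 1.0),
        "event": event,
        "marker_expression": marker.to_numpy(),
        "afp_high": afp.astype(int),
        "vascular_invasion": vinv.astype(int),
        "age_over_60": age.astype(int),
    }).set_index("subject")

    # subtype templates and a structured expression layer
    sig_genes = [f"SIG{i:03d}" for i in range(cfg.n_signature_genes)]
    block = cfg.n_signature_genes // 3
    T = -np.ones((cfg.n_signature_genes, 3))
    for k in range(3):
        T[k * block:(k + 1) * block, k] = 1.0
    templates = pd.DataFrame(T, index=sig_genes,
                             columns=["S1", "S2", "S3"])
    m = cfg.n_subtype_samples
    subtype_samples = [f"T{i:03d}" for i in range(m)]
    labels = {s: ["S1", "S2", "S3"][i % 3]
              for i, s in enumerate(subtype_samples)}
    X = np.empty((cfg.n_signature_genes, m))
    for j, s in enumerate(subtype_samples):
        k = ["S1", "S2", "S3"].index(labels[s])
        X[:, j] = 5.0 + 2.0 * T[:, k] + rng.normal(
            0.0, cfg.subtype_noise_sd, cfg.n_signature_genes)
    subtype_expr = pd.DataFrame(X, index=sig_genes, columns=subtype_samples)
    # one lncRNA markedly down in S2 for subclass DE
    s2 = [s for s in subtype_samples if labels[s] == "S2"]
    row = pd.Series(8.0 + rng.normal(0, 0.8, m), index=subtype_samples)
    row[s2] = 2.0 + rng.normal(0, 0.5, len(s2))
    subtype_expr.loc["SUBDE_LNC"] = row.clip(lower=0.01)
    truth.subtype_labels = labels

    return {
        "gwas": gwas,
        "background": background,
        "survival": survival,
        "templates": templates,
        "subtype_expr": subtype_expr,
        "subtype_labels": labels,
    }


@dataclass
class CohortBundle:
    """Everything one seeded generator run produces."""

    config: SyntheticConfig
    seed: int
    genome: GenomeBundle
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    design: CohortDesign
    truth: SyntheticTruth
    scores: pd.DataFrame
    cnv: "object"
    methylation: pd.DataFrame
    cpg_coords: pd.DataFrame
    clinical: dict


def generate_cohort(cfg: SyntheticConfig | None = None,
                    seed: int = 0) -> CohortBundle:
    """Generate the full matched cohort with all omics layers."""
    cfg = cfg or SyntheticConfig()
    genome = make_genome(cfg.n_chroms, cfg.chrom_len, cfg.n_coding,
                         cfg.n_lncrna, cfg.n_decoys, seed,
                         n_ref_lncrna=cfg.n_ref_lncrna)
    counts, fpkm, design, truth = simulate_expression(genome, cfg, seed)
    truth.decoy_stage = dict(genome.decoy_stage)
    scores = coding_potential_scores(genome, seed)
    cnv = simulate_cnv(truth, genome.layout, design, cfg, seed)
    meth, cpg_coords = simulate_methylation(truth, genome, fpkm, cfg, seed)
    clinical = simulate_snps_and_clinical(truth, genome, cfg, seed)
    return CohortBundle(cfg, seed, genome, counts, fpkm, design, truth,
                        scores, cnv, meth, cpg_coords, clinical)
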