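"""Candidate-lncRNA discovery: filter cascade, positional annotation,
conservation profiling and GWAS-SNP enrichment.

The cascade removes, in order: (1) candidates sharing >=1 exonic base on
the same strand with any reference exon; (2) transcripts with summed exon
length < 200 bp or no strand; (3) single-exon transcripts within 2,000 bp
of a same-strand reference gene; (4) single-exon transcripts never reaching
FPKM 0.5 in any sample; (5) transcripts with protein-coding potential
(CPC score > 0 or COME score > 0.5, or a long ORF under the fallback).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import (
    GenomeLayout,
    GenomicInterval,
    ScoreTrack,
    SnpCatalog,
    TranscriptModel,
    count_snp_overlaps,
    overlap_bases,
    shuffle_intervals,
)

__all__ = [
    "FilterReport",
    "SnpEnrichmentResult",
    "filter_exonic_overlap",
    "filter_length_strand",
    "filter_single_exon_proximity",
    "filter_expression",
    "filter_coding_potential",
    "run_discovery_cascade",
    "classify_position",
    "conservation_profile",
    "snp_enrichment",
    "longest_orf_codons",
]

CASCADE_STAGES = (
    "exonic_overlap",
    "length_strand",
    "single_exon_proximity",
    "expression",
    "coding_potential",
)


@dataclass
class FilterReport:
    """Per-stage attrition of the discovery cascade."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)
    kept_ids: list[str] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_kept: int) -> None:
        self.stages.append((name, n_in, n_kept, n_in - n_kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_in", "n_kept", "n_removed"]
        )


@dataclass
class SnpEnrichmentResult:
    """Odds ratio of GWAS-SNP density in a transcript set vs shuffled placements."""

    odds_ratio: float
    odds_ratio_control: float
    ratios: np.ndarray          # per-shuffle frac(obs)/frac(shuffled)
    ratios_control: np.ndarray  # same construction with control SNPs
    p_value: float              # paired t-test over the two ratio lists
    n_shuffles: int
    defined: bool = True


def _exon_index(models) -> dict[str, list[tuple[TranscriptModel, GenomicInterval]]]:
    idx: dict[str, list] = {}
    for m in models:
        for e in m.exons:
            idx.setdefault(e.chrom, []).append((m, e))
    return idx


def filter_exonic_overlap(candidates, reference):
    """Drop candidates with >=1 exonic base shared, same strand, with any
    reference exon."""
    idx = _exon_index(reference)
    kept, removed = [], []
    for c in candidates:
        hit = False
        for _ref, re_ in idx.get(c.chrom, ()):
            if hit:
                break
            for ce in c.exons:
                if overlap_bases(ce, re_, "same") >= 1:
                    hit = True
                    break
        (removed if hit else kept).append(c)
    return kept, removed


def filter_length_strand(candidates):
    """Drop transcripts with summed exon length < 200 bp or without strand."""
    kept, removed = [], []
    for c in candidates:
        if c.exonic_length < 200 or c.strand == ".":
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def filter_single_exon_proximity(candidates, reference, window: int = 2000):
    """Drop single-exon candidates within ``window`` bp of a same-strand
    reference gene (gap between intervals <= window, overlap included).
    Multi-exon candidates pass untouched."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append(r)
    kept, removed = [], []
    for c in candidates:
        if c.n_exons > 1:
            kept.append(c)
            continue
        hit = False
        for r in by_chrom.get(c.chrom, ()):
            if r.strand != c.strand or c.strand == ".":
                continue
            gap = max(r.interval.start - c.interval.end,
                      c.interval.start - r.interval.end)
            if gap <= window:
                hit = True
                break
        (removed if hit else kept).append(c)
    return kept, removed


def filter_expression(candidates, fpkm: pd.DataFrame, threshold: float = 0.5):
    """Drop single-exon candidates whose FPKM stays below ``threshold`` in
    every sample. Multi-exon candidates pass."""
    missing = [c.transcript_id for c in candidates
               if c.n_exons == 1 and c.transcript_id not in fpkm.index]
    if missing:
        raise KeyError(f"candidates missing from FPKM matrix: {missing}")
    kept, removed = [], []
    for c in candidates:
        if c.n_exons == 1 and fpkm.loc[c.transcript_id].max() < threshold:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_codons(seq: str) -> int:
    """Longest ATG-to-stop open reading frame, in codons (stop excluded)."""
    seq = seq.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def filter_coding_potential(candidates, scores: pd.DataFrame,
                            orf_fallback: bool = False,
                            sequences: dict[str, str] | None = None,
                            orf_min_codons: int = 100):
    """Drop candidates called coding (CPC score > 0 or COME score > 0.5).

    ``scores`` has columns ``cpc_score`` and ``come_score`` indexed by
    transcript_id. With the fallback enabled, candidates lacking scores are
    judged by the longest-ORF heuristic on ``sequences`` instead.
    """
    kept, removed = [], []
    for c in candidates:
        tid = c.transcript_id
        if tid in scores.index:
            row = scores.loc[tid]
            coding = row["cpc_score"] > 0 or row["come_score"] > 0.5
        elif orf_fallback:
            seq = (sequences or {}).get(tid, "")
            coding = longest_orf_codons(seq) >= orf_min_codons
        else:
            raise KeyError(f"no coding-potential scores for {tid} "
                           "and ORF fallback disabled")
        (removed if coding else kept).append(c)
    return kept, removed


def run_discovery_cascade(assembled, reference, fpkm: pd.DataFrame,
                          scores: pd.DataFrame, proximity_window: int = 2000,
                          fpkm_threshold: float = 0.5,
                          orf_fallback: bool = False,
                          sequences=None) -> FilterReport:
    """Apply the five discovery filters in order and report attrition."""
    report = FilterReport()
    current = list(assembled)

    kept, _ = filter_exonic_overlap(current, reference)
    report.add(CASCADE_STAGES[0], len(current), len(kept))
    current = kept

    kept, _ = filter_length_strand(current)
    report.add(CASCADE_STAGES[1], len(current), len(kept))
    current = kept

    kept, _ = filter_single_exon_proximity(current, reference, proximity_window)
    report.add(CASCADE_STAGES[2], len(current), len(kept))
    current = kept

    kept, _ = filter_expression(current, fpkm, fpkm_threshold)
    report.add(CASCADE_STAGES[3], len(current), len(kept))
    current = kept

    kept, _ = filter_coding_potential(current, scores, orf_fallback, sequences)
    report.add(CASCADE_STAGES[4], len(current), len(kept))

    report.kept_ids = [c.transcript_id for c in kept]
    return report


def classify_position(lncrnas, coding_reference,
                      cis_window: int = 2000) -> pd.DataFrame:
    """Assign each lncRNA one positional class relative to coding genes.

    Precedence: antisense (>=1 exonic base overlapping a reference exon on
    the opposite strand) > intronic (wholly inside a same-strand intron) >
    cis (within ``cis_window`` of a gene end) > intergenic.
    """
    exon_idx = _exon_index(coding_reference)
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for r in coding_reference:
        by_chrom.setdefault(r.chrom, []).append(r)

    rows = []
    for t in lncrnas:
        cls = "intergenic"
        for _ref, re_ in exon_idx.get(t.chrom, ()):
            if any(overlap_bases(ce, re_, "opposite") >= 1 for ce in t.exons):
                cls = "antisense"
                break
        if cls == "intergenic":
            for r in by_chrom.get(t.chrom, ()):
                if r.strand != t.strand:
                    continue
                if any(intron.contains(t.interval) for intron in r.introns()):
                    cls = "intronic"
                    break
        if cls == "intergenic":
            for r in by_chrom.get(t.chrom, ()):
                gap = max(r.interval.start - t.interval.end,
                          t.interval.start - r.interval.end)
                if gap <= cis_window:
                    cls = "cis"
                    break
        rows.append((t.transcript_id, cls))
    return pd.DataFrame(rows, columns=["transcript_id", "position_class"]
                        ).set_index("transcript_id")


def conservation_profile(t: TranscriptModel,
                         track: ScoreTrack) -> tuple[float, float]:
    """Mean per-base conservation over exonic and intronic bases.

    Unscored bases count 0. The intron mean is NaN for single-exon
    transcripts.
    """
    exon_mean = track.mean_over(t.exons)
    introns = t.introns()
    intron_mean = track.mean_over(introns) if introns else float("nan")
    return exon_mean, intron_mean


def snp_enrichment(intervals, gwas: SnpCatalog, background: SnpCatalog,
                   layout: GenomeLayout, n_shuffles: int = 100,
                   n_control_draws: int | None = None,
                   seed: int = 0) -> SnpEnrichmentResult:
    """Odds ratio of GWAS-SNP density in a transcript set.

    ``frac(obs)`` is (#gwas sites in the intervals) / (#background sites in
    the intervals); each shuffle recomputes the fraction on re-placed
    intervals; OR = frac(obs) / mean frac(shuffled). The control repeats the
    construction with sham "GWAS" sites placed uniformly over the genome
    (background SNPs shuffled genome-wide). Significance is a paired t-test
    over the per-shuffle ratio pairs.
    """
    if not len(background):
        raise ValueError("background catalogue is empty")
    intervals = list(intervals)
    if not intervals:
        raise ValueError("interval set is empty")
    rng = np.random.default_rng(seed)

    n_control = n_control_draws or len(gwas)
    chroms = layout.chroms
    weights = np.array([layout[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    chosen = rng.choice(len(chroms), size=n_control, p=weights)
    control_pairs = [
        (chroms[i], int(rng.integers(0, layout[chroms[i]]))) for i in chosen
    ]
    control = SnpCatalog.from_pairs(control_pairs, "control")

    def frac(ivs, numerator):
        denom = count_snp_overlaps(ivs, background)
        if denom == 0:
            return float("nan")
        return count_snp_overlaps(ivs, numerator) / denom

    frac_obs = frac(intervals, gwas)
    frac_obs_ctrl = frac(intervals, control)
    if math.isnan(frac_obs) or frac_obs == 0:
        return SnpEnrichmentResult(float("nan"), float("nan"),
                                   np.array([]), np.array([]),
                                   float("nan"), n_shuffles, defined=False)

    shuffles = shuffle_intervals(intervals, layout, n_shuffles,
                                 int(rng.integers(0, 2**31 - 1)))
    frac_shuf = np.array([frac(s, gwas) for s in shuffles])
    frac_shuf_ctrl = np.array([frac(s, control) for s in shuffles])
    if np.isnan(frac_shuf).all() or np.nanmean(frac_shuf) == 0:
        raise ValueError("all shuffle denominators empty; genome too sparse")

    odds_ratio = frac_obs / np.nanmean(frac_shuf)
    odds_ratio_control = (
        frac_obs_ctrl / np.nanmean(frac_shuf_ctrl)
        if np.nanmean(frac_shuf_ctrl) > 0 else float("nan")
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = frac_obs / frac_shuf
        ratios_ctrl = frac_obs_ctrl / frac_shuf_ctrl
    ok = np.isfinite(ratios) & np.isfinite(ratios_ctrl)
    if ok.sum() >= 2 and not np.allclose(ratios[ok], ratios_ctrl[ok]):
        p = float(stats.ttest_rel(ratios[ok], ratios_ctrl[ok]).pvalue)
    else:
        p = 1.0
    return SnpEnrichmentResult(float(odds_ratio), float(odds_ratio_control),
                               ratios, ratios_ctrl, p, n_shuffles)
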