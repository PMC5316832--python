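"""Genomic interval arithmetic and positional file I/O.

All internal coordinates are 0-based half-open ``[start, end)``. GTF input
(1-based inclusive) is converted at the parse boundary; BED and bedGraph are
native. Strand is ``"+"``, ``"-"`` or ``"."`` (unstranded).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GenomeLayout",
    "ScoreTrack",
    "SnpCatalog",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "read_layout",
    "write_layout",
    "overlap_bases",
    "promoter_of",
    "shuffle_intervals",
    "count_snp_overlaps",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """An exon-structured transcript; the unit flowing through discovery.

    ``interval`` is the exon hull. ``biotype`` tags the annotation class:
    ``coding``, ``lncRNA``, ``canonical_ncRNA`` or ``candidate``.
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = -1
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon {e} not on transcript chrom/strand"
                )
            if e.start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e.end
        if (
            self.exons[0].start < self.interval.start
            or self.exons[-1].end > self.interval.end
        ):
            raise ValueError(f"{self.transcript_id}: exon outside transcript interval")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons[:-1], self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    @property
    def tss(self) -> int:
        """Transcription start: left edge on '+', right edge on '-'."""
        if self.strand == "+":
            return self.interval.start
        if self.strand == "-":
            return self.interval.end
        raise ValueError(f"{self.transcript_id}: unstranded transcript has no TSS")


@dataclass
class GenomeLayout:
    """Chromosome name -> length in bases."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {n}")

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total(self) -> int:
        return sum(self.lengths.values())


class ScoreTrack:
    """Sparse per-base score track in [0, 1], stored as bedGraph-style runs.

    Bases not covered by any run score 0 (the convention of an absent
    bigWig value).
    """

    def __init__(self, runs: Mapping[str, Sequence[tuple[int, int, float]]],
                 layout: GenomeLayout | None = None):
        self._runs: dict[str, np.ndarray] = {}
        for chrom, rr in runs.items():
            arr = np.asarray(sorted(rr), dtype=float)
            if arr.size:
                if (arr[:, 2] < 0).any() or (arr[:, 2] > 1).any():
                    raise ValueError(f"{chrom}: scores outside [0, 1]")
                if (arr[:, 0] < 0).any():
                    raise ValueError(f"{chrom}: negative positions")
                if layout is not None and (arr[:, 1] > layout[chrom]).any():
                    raise ValueError(f"{chrom}: run beyond chromosome end")
            self._runs[chrom] = arr

    def interval_sum(self, iv: GenomicInterval) -> float:
        """Sum of per-base scores over ``iv`` (uncovered bases contribute 0)."""
        runs = self._runs.get(iv.chrom)
        if runs is None or not runs.size:
            return 0.0
        lo = np.minimum(runs[:, 1], iv.end)
        hi = np.maximum(runs[:, 0], iv.start)
        ov = np.clip(lo - hi, 0, None)
        return float((ov * runs[:, 2]).sum())

    def mean_over(self, ivs: Iterable[GenomicInterval]) -> float:
        """Per-base mean score over a set of (non-overlapping) intervals."""
        total = 0.0
        nbases = 0
        for iv in ivs:
            total += self.interval_sum(iv)
            nbases += len(iv)
        if nbases == 0:
            return float("nan")
        return total / nbases


@dataclass
class SnpCatalog:
    """A labelled set of single-base variant sites."""

    sites: dict[str, np.ndarray]  # chrom -> sorted unique positions
    label: str = "background"

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]], label: str = "background",
                   layout: GenomeLayout | None = None) -> "SnpCatalog":
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in pairs:
            by_chrom.setdefault(chrom, []).append(pos)
        sites = {c: np.unique(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}
        for c, p in sites.items():
            if p.size and p[0] < 0:
                raise ValueError(f"{c}: negative SNP position")
            if layout is not None and p.size and p[-1] >= layout[c]:
                raise ValueError(f"{c}: SNP position beyond chromosome length")
        return cls(sites=sites, label=label)

    def __len__(self) -> int:
        return sum(p.size for p in self.sites.values())


class GtfParseError(ValueError):
    """Raised on malformed GTF input, naming the offending line."""


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, val = part.split(" ", 1)
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    One model per transcript_id; the transcript interval is the exon hull.
    1-based inclusive GTF coordinates become 0-based half-open.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tx -> (gene_id, biotype)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_gtf_attributes(attr)
            if "transcript_id" not in attrs:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon without transcript_id"
                )
            tx = attrs["transcript_id"]
            gene = attrs.get("gene_id", tx)
            biotype = attrs.get("gene_biotype", "candidate")
            try:
                iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            except ValueError as exc:
                raise GtfParseError(f"{path}: line {lineno}: {exc}") from exc
            exons.setdefault(tx, []).append(iv)
            if tx not in meta:
                meta[tx] = (gene, biotype)
                order.append(tx)
    models = []
    for tx in order:
        ee = sorted(exons[tx], key=lambda e: e.start)
        hull = GenomicInterval(ee[0].chrom, ee[0].start, ee[-1].end, ee[0].strand)
        gene, biotype = meta[tx]
        models.append(TranscriptModel(tx, gene, hull, ee, biotype))
    return models


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write transcript models as exon GTF lines (source ``lncrecur``)."""
    with open(path, "w") as fh:
        for m in models:
            for e in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'gene_biotype "{m.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\tlncrecur\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def read_bed(path, label: str = "background",
             layout: GenomeLayout | None = None) -> SnpCatalog:
    """Read a BED3 of single-base sites (start column) into a catalogue."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["chrom", "start"])
    return SnpCatalog.from_pairs(
        zip(df["chrom"].astype(str), df["start"].astype(int)), label, layout
    )


def write_bed(catalog: SnpCatalog, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(catalog.sites):
            for pos in catalog.sites[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{catalog.label}\n")


def read_bedgraph(path, layout: GenomeLayout | None = None) -> ScoreTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "score"])
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        runs[str(chrom)] = list(
            zip(sub["start"].astype(int), sub["end"].astype(int),
                sub["score"].astype(float))
        )
    return ScoreTrack(runs, layout)


def read_layout(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, n in layout.lengths.items():
            fh.write(f"{chrom}\t{n}\n")


def overlap_bases(a: GenomicInterval, b: GenomicInterval,
                  strand_mode: str = "same") -> int:
    """Shared bases between two intervals under a strand rule.

    ``strand_mode`` is ``same`` (strands must match and be known),
    ``ignore`` (any strands) or ``opposite`` (strands must differ, both
    known). Returns 0 when chromosomes differ or the strand rule fails.
    """
    if a.chrom != b.chrom:
        return 0
    if strand_mode == "same":
        if a.strand == "." or b.strand == "." or a.strand != b.strand:
            return 0
    elif strand_mode == "opposite":
        if a.strand == "." or b.strand == "." or a.strand == b.strand:
            return 0
    elif strand_mode != "ignore":
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def promoter_of(t: TranscriptModel, upstream: int = 2000,
                layout: GenomeLayout | None = None) -> GenomicInterval | None:
    """The ``upstream``-bp window immediately upstream of the TSS.

    Clipped to chromosome bounds; returns None when clipping empties the
    window. Raises on unstranded transcripts.
    """
    if t.strand not in ("+", "-"):
        raise ValueError(f"{t.transcript_id}: promoter undefined without strand")
    chrom_len = layout[t.chrom] if layout is not None else None
    if t.strand == "+":
        start, end = t.interval.start - upstream, t.interval.start
    else:
        start, end = t.interval.end, t.interval.end + upstream
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    if start >= end:
        return None
    return GenomicInterval(t.chrom, start, end, t.strand)


def shuffle_intervals(intervals: Sequence[GenomicInterval], layout: GenomeLayout,
                      n_shuffles: int, seed: int) -> list[list[GenomicInterval]]:
    """Length- and chromosome-preserving uniform random placements.

    Each shuffle re-places every interval uniformly on its own chromosome,
    keeping its length and strand. Deterministic given ``seed``.
    """
    for iv in intervals:
        if len(iv) > layout[iv.chrom]:
            raise ValueError(
                f"interval of length {len(iv)} exceeds chromosome "
                f"{iv.chrom} ({layout[iv.chrom]} bp)"
            )
    rng = np.random.default_rng(seed)
    lens = np.array([len(iv) for iv in intervals], dtype=np.int64)
    maxstart = np.array(
        [layout[iv.chrom] - len(iv) for iv in intervals], dtype=np.int64
    )
    out = []
    for _ in range(n_shuffles):
        starts = rng.integers(0, maxstart + 1)
        out.append(
            [
                GenomicInterval(iv.chrom, int(s), int(s) + int(L), iv.strand)
                for iv, s, L in zip(intervals, starts, lens)
            ]
        )
    return out


def count_snp_overlaps(intervals: Iterable[GenomicInterval],
                       snps: SnpCatalog) -> int:
    """Number of catalogue sites inside the union of ``intervals``.

    Each site counts once even if covered by several intervals.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for chrom, spans in by_chrom.items():
        pos = snps.sites.get(chrom)
        if pos is None or not pos.size:
            continue
        # merge spans, then count sites per merged span
        spans.sort()
        hit = np.zeros(pos.shape, dtype=bool)
        for start, end in spans:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            hit[lo:hi] = True
        total += int(hit.sum())
    return total
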