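"""Copy-number and promoter-methylation attribution of recurrent
deregulation.

A GISTIC-style scan scores each genome bin by frequency x amplitude of
aberrant samples (G-score) against a circular-permutation null; recurrent
features are then flagged CNV-driven when their direction matches an
overlapping significant region (down in deletions, up in amplifications),
and methylation-driven when the promoter CpG with the most negative
expression-beta Pearson correlation falls below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .genomic_core import GenomeLayout, GenomicInterval, TranscriptModel, promoter_of

__all__ = [
    "CnvSegmentSet",
    "GScoreResult",
    "gscore_scan",
    "map_lncrna_cnv",
    "assign_promoter_cpgs",
    "methylation_driver_call",
    "summarize_drivers",
]


@dataclass
class CnvSegmentSet:
    """Per-sample copy-number segments with mean log2 copy-ratio.

    ``segments`` columns: sample_id, chrom, start, end, log2ratio.
    """

    segments: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample_id", "chrom", "start", "end", "log2ratio"}
        if not need <= set(self.segments.columns):
            raise ValueError(f"segment table needs columns {sorted(need)}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.segments["sample_id"].unique())

    @classmethod
    def read_tsv(cls, path) -> "CnvSegmentSet":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False)


@dataclass
class GScoreResult:
    """Binned G-scores with permutation q-values and significant regions."""

    bins: pd.DataFrame     # chrom, start, end, g_amp, g_del, p_amp, p_del,
                           # q_amp, q_del
    regions: pd.DataFrame  # chrom, start, end, kind (amp/del), max_g, min_q
    bin_size: int


def _bin_profiles(segset: CnvSegmentSet, layout: GenomeLayout,
                  bin_size: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample per-bin length-weighted mean log2ratio.

    Returns the bin coordinate table and an array (n_samples, n_bins).
    """
    bins = []
    for chrom in layout.chroms:
        L = layout[chrom]
        if bin_size > L:
            raise ValueError(
                f"bin_size {bin_size} exceeds chromosome {chrom} ({L} bp)"
            )
        starts = np.arange(0, L, bin_size)
        ends = np.minimum(starts + bin_size, L)
        bins.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bin_df = pd.concat(bins, ignore_index=True)

    samples = segset.samples
    prof = np.zeros((len(samples), len(bin_df)))
    weight = np.zeros_like(prof)
    offsets = {}
    pos = 0
    for chrom in layout.chroms:
        n = int(np.ceil(layout[chrom] / bin_size))
        offsets[chrom] = pos
        pos += n
    sindex = {s: i for i, s in enumerate(samples)}
    for row in segset.segments.itertuples(index=False):
        if row.chrom not in offsets:
            continue
        si = sindex[row.sample_id]
        off = offsets[row.chrom]
        b0 = int(row.start) // bin_size
        b1 = (int(row.end) - 1) // bin_size
        for b in range(b0, b1 + 1):
            bs, be = b * bin_size, (b + 1) * bin_size
            ov = min(row.end, be) - max(row.start, bs)
            if ov > 0:
                prof[si, off + b] += row.log2ratio * ov
                weight[si, off + b] += ov
    with np.errstate(invalid="ignore"):
        prof = np.where(weight > 0, prof / np.maximum(weight, 1e-12), 0.0)
    return bin_df, prof


def _gscores(prof: np.ndarray, amp_threshold: float,
             del_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    amp_contrib = np.where(prof >= amp_threshold, np.maximum(prof, 0.0), 0.0)
    del_contrib = np.where(prof <= del_threshold, np.maximum(-prof, 0.0), 0.0)
    return amp_contrib.sum(axis=0), del_contrib.sum(axis=0)


def _runs_to_regions(bin_df: pd.DataFrame, sig: np.ndarray, g: np.ndarray,
                     q: np.ndarray, kind: str) -> list[dict]:
    regions = []
    cur = None
    for i in range(len(bin_df)):
        row = bin_df.iloc[i]
        if sig[i] and cur is not None and cur["chrom"] == row["chrom"] \
                and cur["_last"] == i - 1:
            cur["end"] = int(row["end"])
            cur["max_g"] = max(cur["max_g"], float(g[i]))
            cur["min_q"] = min(cur["min_q"], float(q[i]))
            cur["_last"] = i
        elif sig[i]:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": row["chrom"], "start": int(row["start"]),
                   "end": int(row["end"]), "kind": kind,
                   "max_g": float(g[i]), "min_q": float(q[i]), "_last": i}
    if cur is not None:
        regions.append(cur)
    for r in regions:
        r.pop("_last")
    return regions


def gscore_scan(segset: CnvSegmentSet, layout: GenomeLayout,
                bin_size: int = 100_000, amp_threshold: float = 0.3,
                del_threshold: float = -0.3, n_perm: int = 1000,
                q_cut: float = 0.25, seed: int = 0) -> GScoreResult:
    """Frequency-x-amplitude aberration scan with a circular-permutation null.

    Per bin, the amplification G-score sums the log2 ratios of samples
    exceeding ``amp_threshold`` (deletions analogously with the sign
    flipped). The null circularly rotates each sample's genome-wide bin
    profile independently, preserving within-sample segment structure.
    Maximal runs of bins with BH q < ``q_cut`` are reported as regions.
    """
    if len(segset.samples) < 2:
        raise ValueError("need >= 2 samples for a G-score scan")
    bin_df, prof = _bin_profiles(segset, layout, bin_size)
    g_amp, g_del = _gscores(prof, amp_threshold, del_threshold)

    # shift-invariant per-sample contributions allow a roll-based null
    amp_c = np.where(prof >= amp_threshold, np.maximum(prof, 0.0), 0.0)
    del_c = np.where(prof <= del_threshold, np.maximum(-prof, 0.0), 0.0)
    rng = np.random.default_rng(seed)
    n_bins = prof.shape[1]
    exceed_amp = np.zeros(n_bins)
    exceed_del = np.zeros(n_bins)
    for _ in range(n_perm):
        shifts = rng.integers(0, n_bins, size=prof.shape[0])
        ga = np.zeros(n_bins)
        gd = np.zeros(n_bins)
        for si in range(prof.shape[0]):
            ga += np.roll(amp_c[si], shifts[si])
            gd += np.roll(del_c[si], shifts[si])
        exceed_amp += ga >= g_amp
        exceed_del += gd >= g_del
    p_amp = (exceed_amp + 1.0) / (n_perm + 1.0)
    p_del = (exceed_del + 1.0) / (n_perm + 1.0)
    q_amp = multipletests(p_amp, method="fdr_bh")[1]
    q_del = multipletests(p_del, method="fdr_bh")[1]

    bins = bin_df.assign(g_amp=g_amp, g_del=g_del, p_amp=p_amp, p_del=p_del,
                         q_amp=q_amp, q_del=q_del)
    regions = []
    regions += _runs_to_regions(bin_df, (q_amp < q_cut) & (g_amp > 0),
                                g_amp, q_amp, "amp")
    regions += _runs_to_regions(bin_df, (q_del < q_cut) & (g_del > 0),
                                g_del, q_del, "del")
    region_df = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "kind", "max_g", "min_q"]
    )
    return GScoreResult(bins, region_df, bin_size)


def map_lncrna_cnv(recurrence_class: pd.Series, regions: pd.DataFrame,
                   models: dict[str, TranscriptModel]) -> pd.DataFrame:
    """Flag recurrent features whose interval overlaps a direction-consistent
    significant region (down in deletions, up in amplifications)."""
    rows = []
    for feature, cls in recurrence_class.items():
        if cls not in ("recurrently_up", "recurrently_down", "bimorphic"):
            continue
        m = models.get(feature)
        if m is None:
            continue
        for reg in regions.itertuples(index=False):
            if reg.chrom != m.chrom:
                continue
            if min(reg.end, m.interval.end) <= max(reg.start, m.interval.start):
                continue
            consistent = (
                (cls == "recurrently_down" and reg.kind == "del")
                or (cls == "recurrently_up" and reg.kind == "amp")
                or (cls == "bimorphic")
            )
            if consistent:
                rows.append({
                    "feature": feature,
                    "cnv_driven": True,
                    "region": f"{reg.chrom}:{reg.start}-{reg.end}:{reg.kind}",
                })
                break
    return pd.DataFrame(rows, columns=["feature", "cnv_driven", "region"])


def assign_promoter_cpgs(models, cpg_coords: pd.DataFrame,
                         upstream: int = 2000,
                         layout: GenomeLayout | None = None
                         ) -> dict[str, list[str]]:
    """CpG ids whose position falls in each feature's promoter window.

    ``cpg_coords`` columns: cpg_id, chrom, pos.
    """
    by_chrom = {
        str(chrom): sub.sort_values("pos")
        for chrom, sub in cpg_coords.groupby("chrom")
    }
    out: dict[str, list[str]] = {}
    for m in models:
        prom = promoter_of(m, upstream, layout)
        if prom is None:
            out[m.transcript_id] = []
            continue
        sub = by_chrom.get(prom.chrom)
        if sub is None:
            out[m.transcript_id] = []
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, prom.start, side="left")
        hi = np.searchsorted(pos, prom.end, side="left")
        out[m.transcript_id] = sub["cpg_id"].iloc[lo:hi].tolist()
    return out


def methylation_driver_call(expr_fpkm: pd.DataFrame, meth: pd.DataFrame,
                            cpg_map: dict[str, list[str]],
                            r_cut: float = -0.3,
                            design=None,
                            feature_direction: pd.Series | None = None,
                            dm_alpha: float = 0.05) -> pd.DataFrame:
    """Best promoter-CpG expression-methylation correlation per feature.

    For each feature, the Pearson correlation between FPKM and beta across
    shared samples is computed for every assigned CpG; the most negative r
    is retained and the feature is called methylation-driven when it falls
    below ``r_cut``. Beta values must lie in [0, 1].

    Picking the most negative of several promoter CpGs inflates the
    nominal false-call rate, so when a cohort ``design`` is supplied a
    second criterion is applied: the best CpG must be differentially
    methylated between matched tumour and normal samples (paired t-test,
    p < ``dm_alpha``) in the direction consistent with the expression
    change (hypermethylated for down-regulated features, hypomethylated
    for up-regulated ones, from ``feature_direction``).
    """
    vals = meth.to_numpy()
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("beta values must be in [0, 1]")
    shared = [s for s in expr_fpkm.columns if s in meth.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    pairs = design.pairs("tumour_vs_normal") if design is not None else None
    rows = []
    for feature, cpgs in cpg_map.items():
        if feature not in expr_fpkm.index:
            continue
        x = expr_fpkm.loc[feature, shared].to_numpy(dtype=float)
        best_r, best_cpg = np.inf, None
        for cpg in cpgs:
            if cpg not in meth.index:
                continue
            y = meth.loc[cpg, shared].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if r < best_r:
                best_r, best_cpg = r, cpg
        if best_cpg is None:
            continue
        driven = best_r < r_cut
        dm_p = np.nan
        dm_delta = np.nan
        if driven and pairs is not None:
            beta_n = meth.loc[best_cpg, [sa for _, sa, _ in pairs]].to_numpy(
                dtype=float)
            beta_t = meth.loc[best_cpg, [sb for _, _, sb in pairs]].to_numpy(
                dtype=float)
            diff = beta_t - beta_n
            dm_delta = float(diff.mean())
            if np.allclose(diff, diff[0]):
                dm_p = 1.0
            else:
                dm_p = float(sp_stats.ttest_rel(beta_t, beta_n).pvalue)
            consistent = True
            if feature_direction is not None and feature in feature_direction:
                d = feature_direction[feature]
                if d == "recurrently_down" or d == "down":
                    consistent = dm_delta > 0
                elif d == "recurrently_up" or d == "up":
                    consistent = dm_delta < 0
            driven = dm_p < dm_alpha and consistent
        rows.append({
            "feature": feature,
            "best_cpg": best_cpg,
            "r": best_r,
            "dm_p": dm_p,
            "dm_delta_beta": dm_delta,
            "methylation_driven": driven,
        })
    return pd.DataFrame(rows, columns=["feature", "best_cpg", "r", "dm_p",
                                       "dm_delta_beta",
                                       "methylation_driven"])


def summarize_drivers(cnv_calls: pd.DataFrame, meth_calls: pd.DataFrame,
                      recurrence_class: pd.Series) -> pd.DataFrame:
    """Category counts per direction; flags overlap so marginals need not
    sum to the total."""
    cnv_set = set(cnv_calls["feature"]) if len(cnv_calls) else set()
    meth_set = (
        set(meth_calls.loc[meth_calls["methylation_driven"], "feature"])
        if len(meth_calls) else set()
    )
    rows = []
    for direction in ("recurrently_up", "recurrently_down", "bimorphic"):
        feats = set(recurrence_class[recurrence_class == direction].index)
        c = feats & cnv_set
        m = feats & meth_set
        rows.append({
            "class": direction,
            "total": len(feats),
            "cnv_driven": len(c),
            "methylation_driven": len(m),
            "both": len(c & m),
            "cnv_only": len(c - m),
            "methylation_only": len(m - c),
            "unexplained": len(feats - c - m),
        })
    return pd.DataFrame(rows)
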