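"""Recurrent differential expression across matched patients.

Three routes are combined: a per-patient posterior fold-change statistic
(GFOLD-like credible bound) followed by recurrence counting with a
permutation FDR; a cohort-level negative-binomial Wald test; and a paired
Wilcoxon signed-rank test. For the tumour-vs-normal contrast the final
recurrent sets are the three-way intersection per direction; for the
PVTT-vs-tumour contrast, where replicate-based methods lack power against
heterogeneous metastatic samples, the per-patient route alone is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortDesign",
    "RecurrenceFdrResult",
    "gfold_statistic",
    "per_patient_calls",
    "wilcoxon_de",
    "nb_wald_de",
    "size_factors",
    "recurrence_counts",
    "recurrence_fdr",
    "fdr_thresholded_sets",
    "intersect_methods",
    "classify_bimorphic",
]

CONTRASTS = {
    "tumour_vs_normal": ("normal", "tumour"),
    "pvtt_vs_tumour": ("tumour", "pvtt"),
}

TISSUES = ("normal", "tumour", "pvtt")


@dataclass
class CohortDesign:
    """Sample -> (patient, tissue) map for a matched multi-tissue cohort.

    ``excluded`` lists (patient, tissue) pairs whose sample exists but is
    unusable (e.g. a contaminated PVTT); contrasts skip those patients.
    """

    samples: pd.DataFrame  # index sample_id; columns patient, tissue
    excluded: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        dup = self.samples.duplicated(subset=["patient", "tissue"])
        if dup.any():
            raise ValueError(
                f"patients with >1 sample per tissue: "
                f"{self.samples[dup].to_dict('records')}"
            )
        bad = set(self.samples["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissues: {bad}")

    @property
    def patients(self) -> list[str]:
        return sorted(self.samples["patient"].unique())

    def sample_of(self, patient: str, tissue: str) -> str | None:
        if (patient, tissue) in self.excluded:
            return None
        sel = self.samples[
            (self.samples["patient"] == patient)
            & (self.samples["tissue"] == tissue)
        ]
        return sel.index[0] if len(sel) else None

    def pairs(self, contrast: str) -> list[tuple[str, str, str]]:
        """(patient, baseline_sample, case_sample) for usable patients."""
        if contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {contrast!r}")
        tis_a, tis_b = CONTRASTS[contrast]
        out = []
        for p in self.patients:
            sa, sb = self.sample_of(p, tis_a), self.sample_of(p, tis_b)
            if sa is not None and sb is not None:
                out.append((p, sa, sb))
        return out

    def tissue_samples(self, tissue: str) -> list[str]:
        sel = self.samples[self.samples["tissue"] == tissue]
        return [s for s in sel.index
                if (sel.loc[s, "patient"], tissue) not in self.excluded]

    @classmethod
    def read_tsv(cls, path) -> "CohortDesign":
        df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
        excluded = set()
        if "excluded" in df.columns:
            for _, row in df[df["excluded"] == "1"].iterrows():
                excluded.add((row["patient"], row["tissue"]))
        return cls(df[["patient", "tissue"]], excluded)

    def write_tsv(self, path) -> None:
        df = self.samples.copy()
        df["excluded"] = [
            int((df.loc[s, "patient"], df.loc[s, "tissue"]) in self.excluded)
            for s in df.index
        ]
        df.rename_axis("sample_id").to_csv(path, sep="\t")


def _gfold_core(counts_a, counts_b, lib_a, lib_b, sc, n_draws, rng):
    """Vectorised credible-bound log2 fold-change for arrays of counts.

    Posterior rates are Gamma(count+1, 1) scaled by 1/library-size; the
    returned value is the posterior sc-quantile of log2(rate_b/rate_a) when
    the median is positive, the (1-sc)-quantile when negative, and 0 when
    that bound crosses zero. Conditions are canonically ordered before
    drawing so swapping them negates the value exactly.
    """
    ca = np.atleast_1d(np.asarray(counts_a))
    cb = np.atleast_1d(np.asarray(counts_b))
    if not (np.equal(np.mod(ca, 1), 0).all() and np.equal(np.mod(cb, 1), 0).all()):
        raise ValueError("counts must be non-negative integers")
    if (ca < 0).any() or (cb < 0).any():
        raise ValueError("counts must be non-negative")
    la = float(lib_a)
    lb = float(lib_b)
    if la <= 0 or lb <= 0:
        raise ValueError("library sizes must be positive")

    # canonical orientation: larger (count, lib) key second; flip sign after
    flip = (ca > cb) | ((ca == cb) & (la > lb))
    lo = np.where(flip, cb, ca).astype(float)
    hi = np.where(flip, ca, cb).astype(float)
    lib_lo = np.where(flip, lb, la)
    lib_hi = np.where(flip, la, lb)

    n = lo.size
    g_lo = rng.gamma(lo + 1.0, size=(n_draws, n))
    g_hi = rng.gamma(hi + 1.0, size=(n_draws, n))
    z = (np.log2(g_hi) - np.log2(g_lo)) - np.log2(lib_hi / lib_lo)
    q_lo, med, q_hi = np.quantile(z, [sc, 0.5, 1.0 - sc], axis=0)

    val = np.zeros(n)
    pos = (med > 0) & (q_lo > 0)
    neg = (med < 0) & (q_hi < 0)
    val[pos] = q_lo[pos]
    val[neg] = q_hi[neg]
    val[flip] = -val[flip]
    return val


def gfold_statistic(count_a: int, count_b: int, lib_a: float, lib_b: float,
                    sc: float = 0.01, n_draws: int = 10_000,
                    seed: int = 0) -> float:
    """Signed conservative log2 fold-change of condition b over a.

    |value| > 1 means the log2 change exceeds 1 with posterior confidence
    1 - ``sc``; 0 means the credible interval crosses zero.
    """
    rng = np.random.default_rng(seed)
    return float(_gfold_core(count_a, count_b, lib_a, lib_b, sc, n_draws, rng)[0])


def per_patient_calls(counts: pd.DataFrame, design: CohortDesign,
                      contrast: str, gfold_cutoff: float = 1.0,
                      sc: float = 0.01, n_draws: int = 10_000,
                      seed: int = 0,
                      lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """One differential call per (feature, usable patient).

    Returns a long table with columns feature, patient, statistic,
    direction (up/down/none). Library sizes default to column totals of
    the full count matrix.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    rng = np.random.default_rng(seed)
    frames = []
    for patient, sa, sb in design.pairs(contrast):
        vals = _gfold_core(
            counts[sa].to_numpy(), counts[sb].to_numpy(),
            float(lib_sizes[sa]), float(lib_sizes[sb]),
            sc, n_draws, rng,
        )
        direction = np.where(vals > gfold_cutoff, "up",
                             np.where(vals < -gfold_cutoff, "down", "none"))
        frames.append(pd.DataFrame({
            "feature": counts.index,
            "patient": patient,
            "statistic": vals,
            "direction": direction,
        }))
    if not frames:
        return pd.DataFrame(columns=["feature", "patient", "statistic",
                                     "direction"])
    out = pd.concat(frames, ignore_index=True)
    out["contrast"] = contrast
    return out


def _attach_significance(df: pd.DataFrame, lfc_cutoff: float,
                         q_cutoff: float) -> pd.DataFrame:
    df["q"] = multipletests(df["p"].fillna(1.0), method="fdr_bh")[1]
    sig = (df["log2fc"].abs() > lfc_cutoff) & (df["q"] < q_cutoff)
    df["direction"] = np.where(sig & (df["log2fc"] > 0), "up",
                               np.where(sig & (df["log2fc"] < 0), "down",
                                        "none"))
    return df


def wilcoxon_de(expr: pd.DataFrame, design: CohortDesign, contrast: str,
                lfc_cutoff: float = 1.0, q_cutoff: float = 0.05,
                pseudocount: float = 1.0) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank test per feature across matched patients.

    ``expr`` is a normalised expression matrix (FPKM); the test runs on
    log2(value + pseudocount) pairs so up- and down-shifts are treated
    symmetrically. The fold change is the median per-patient log2 ratio.
    """
    pairs = design.pairs(contrast)
    if len(pairs) < 6:
        raise ValueError(f"need >=6 paired patients, have {len(pairs)}")
    a = expr[[sa for _, sa, _ in pairs]].to_numpy()
    b = expr[[sb for _, _, sb in pairs]].to_numpy()
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    log2fc = np.median(lb - la, axis=1)

    d = lb - la
    all_tied = (d == 0).all(axis=1)
    p = np.ones(len(expr))
    if (~all_tied).any():
        res = stats.wilcoxon(lb[~all_tied], la[~all_tied], axis=1,
                             zero_method="wilcox", method="auto")
        p[~all_tied] = np.clip(np.atleast_1d(res.pvalue), 0.0, 1.0)
    df = pd.DataFrame({"feature": expr.index, "log2fc": log2fc, "p": p}
                      ).set_index("feature")
    return _attach_significance(df, lfc_cutoff, q_cutoff)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors (reference = geometric mean
    over samples, features with any zero excluded)."""
    logc = np.log(counts.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        ref = logc.mean(axis=1)
    ok = np.isfinite(ref)
    if not ok.any():
        raise ValueError("no feature has all-positive counts")
    sf = np.exp(np.median(logc[ok] - ref[ok, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def nb_wald_de(counts: pd.DataFrame, design: CohortDesign, contrast: str,
               lfc_cutoff: float = 1.0, q_cutoff: float = 0.05,
               pseudocount: float = 1.0) -> pd.DataFrame:
    """Negative-binomial Wald test treating patients as replicates.

    Size factors by median-of-ratios; per-feature method-of-moments
    dispersion (no shrinkage). Because the cohort is matched, the model is
    patient-blocked: the effect estimate is the mean per-patient log2
    ratio of normalised counts, with a delta-method Wald standard error
    from the NB variance mu + alpha*mu^2. Features with zero total count
    are excluded.
    """
    if not np.equal(np.mod(counts.to_numpy(), 1), 0).all():
        raise ValueError("counts must be integral")
    pairs = design.pairs(contrast)
    cols_a = [sa for _, sa, _ in pairs]
    cols_b = [sb for _, _, sb in pairs]
    sf = size_factors(counts[cols_a + cols_b])
    norm = counts[cols_a + cols_b] / sf

    keep = counts[cols_a + cols_b].sum(axis=1) > 0
    xa = norm.loc[keep, cols_a].to_numpy()
    xb = norm.loc[keep, cols_b].to_numpy()
    n_pat = len(pairs)
    # MoM dispersion from pooled within-tissue variability
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    mu = (xa.mean(axis=1) + xb.mean(axis=1)) / 2.0
    w = (va + vb) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.clip((w - mu) / mu**2, 0.0, None)
    alpha = np.nan_to_num(alpha)[:, None]

    deltas = np.log2((xb + pseudocount) / (xa + pseudocount))
    log2fc = deltas.mean(axis=1)
    ln2 = np.log(2.0)
    # delta method: var(log2(x + pc)) ~= (mu + alpha mu^2) / ((mu+pc) ln2)^2
    var_a = (xa + alpha * xa**2) / ((xa + pseudocount) * ln2) ** 2
    var_b = (xb + alpha * xb**2) / ((xb + pseudocount) * ln2) ** 2
    se = np.sqrt((var_a + var_b).sum(axis=1)) / n_pat
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    df = pd.DataFrame({"feature": counts.index[keep], "log2fc": log2fc,
                       "p": p}).set_index("feature")
    return _attach_significance(df, lfc_cutoff, q_cutoff)


def recurrence_counts(calls: pd.DataFrame,
                      features=None) -> pd.DataFrame:
    """Per-feature number of patients called up and down."""
    if features is None:
        features = calls["feature"].unique() if len(calls) else []
    out = pd.DataFrame(0, index=pd.Index(features, name="feature"),
                       columns=["n_up", "n_down"])
    if len(calls):
        up = calls[calls["direction"] == "up"].groupby("feature").size()
        down = calls[calls["direction"] == "down"].groupby("feature").size()
        out.loc[up.index, "n_up"] = up
        out.loc[down.index, "n_down"] = down
    return out


@dataclass
class RecurrenceFdrResult:
    """Permutation-estimated FDR of recurrence thresholds."""

    table: pd.DataFrame  # index r; observed_tail, null_mean_tail, fdr, flagged
    min_r: int | None    # smallest r with FDR < alpha, None if unattained
    n_perm: int
    alpha: float


def recurrence_fdr(per_patient_sizes, universe_size: int, observed_counts,
                   n_perm: int = 10_000, seed: int = 0, alpha: float = 0.05,
                   r_max: int | None = None,
                   chunk: int = 250) -> RecurrenceFdrResult:
    """Permutation FDR for "deregulated in >= r patients".

    Each permutation draws, for every patient i, ``k_i`` features uniformly
    without replacement from a universe of ``universe_size`` and tallies
    how many features recur in >= r patients. FDR(r) is the mean null tail
    count over permutations divided by the observed tail count (capped at
    1); where the observed tail is 0 the FDR is reported as 0 and flagged.
    """
    k = np.asarray(per_patient_sizes, dtype=np.int64)
    n_pat = k.size
    N = int(universe_size)
    if (k > N).any():
        raise ValueError("per-patient selection size exceeds universe")
    obs = np.asarray(observed_counts, dtype=np.int64)
    if r_max is None:
        r_max = n_pat
    r_grid = np.arange(1, r_max + 1)
    obs_tail = np.array([(obs >= r).sum() for r in r_grid], dtype=float)

    rng = np.random.default_rng(seed)
    null_tail_sum = np.zeros(r_grid.size)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        hits = np.zeros((m, N), dtype=np.int16)
        for ki in k:
            if ki == 0:
                continue
            u = rng.random((m, N))
            if ki >= N:
                hits += 1
                continue
            kth = np.partition(u, ki - 1, axis=1)[:, ki - 1:ki]
            hits += u <= kth
        for j, r in enumerate(r_grid):
            null_tail_sum[j] += (hits >= r).sum()
        done += m
    null_mean = null_tail_sum / n_perm

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_tail > 0, np.minimum(null_mean / obs_tail, 1.0), 0.0)
    flagged = obs_tail == 0
    table = pd.DataFrame({
        "observed_tail": obs_tail.astype(int),
        "null_mean_tail": null_mean,
        "fdr": fdr,
        "flagged_zero_observed": flagged,
    }, index=pd.Index(r_grid, name="r"))
    passing = r_grid[(fdr < alpha) & ~flagged]
    min_r = int(passing[0]) if passing.size else None
    return RecurrenceFdrResult(table, min_r, n_perm, alpha)


def fdr_thresholded_sets(calls: pd.DataFrame, rec: pd.DataFrame,
                         universe_size: int, r_floor: int,
                         n_perm: int = 10_000, seed: int = 0,
                         alpha: float = 0.05) -> dict:
    """Direction-specific recurrent sets at FDR-validated thresholds.

    The working threshold per direction is the smallest recurrence level
    whose permutation FDR is below ``alpha``, floored at the configured
    minimum ``r_floor`` — such fixed thresholds are the outcome of this
    selection rule on the original cohort, so the rule, not the constant,
    is what generalises to other universes.
    """
    out = {}
    for direction, col in (("up", "n_up"), ("down", "n_down")):
        k = calls[calls["direction"] == direction].groupby("patient").size()
        if not len(k):
            out[direction] = {"set": set(), "r": r_floor, "fdr": None}
            continue
        res = recurrence_fdr(k.to_numpy(), universe_size,
                             rec[col].to_numpy(), n_perm=n_perm,
                             seed=seed + (0 if direction == "up" else 1),
                             alpha=alpha)
        r_eff = max(r_floor, res.min_r) if res.min_r is not None else r_floor
        out[direction] = {
            "set": set(rec.index[rec[col] >= r_eff]),
            "r": int(r_eff),
            "fdr": res,
        }
    return out


def intersect_methods(gfold_sets: tuple[set, set], deseq_sets: tuple[set, set],
                      wilcoxon_sets: tuple[set, set],
                      contrast: str = "tumour_vs_normal",
                      logger=None) -> tuple[set, set]:
    """Final recurrent (up, down) sets.

    Tumour-vs-normal: three-way intersection per direction. PVTT-vs-tumour:
    the per-patient recurrence sets alone, since replicate-based methods
    call too few features on heterogeneous metastatic samples.
    """
    if contrast == "pvtt_vs_tumour":
        return set(gfold_sets[0]), set(gfold_sets[1])
    up = set(gfold_sets[0]) & set(deseq_sets[0]) & set(wilcoxon_sets[0])
    down = set(gfold_sets[1]) & set(deseq_sets[1]) & set(wilcoxon_sets[1])
    if logger is not None and not (up or down) and any(
        gfold_sets + deseq_sets + wilcoxon_sets
    ):
        logger.warning("method intersection is empty despite non-empty inputs")
    return up, down


def classify_bimorphic(counts: pd.DataFrame, r_min: int,
                       r_bi: int = 2) -> pd.Series:
    """Per-feature recurrence class.

    ``bimorphic`` when both directions recur in >= ``r_bi`` patients;
    otherwise ``recurrently_up`` / ``recurrently_down`` when the matching
    count reaches ``r_min``; else ``none``.
    """
    n_up = counts["n_up"].to_numpy()
    n_down = counts["n_down"].to_numpy()
    cls = np.full(len(counts), "none", dtype=object)
    cls[(n_up >= r_min)] = "recurrently_up"
    cls[(n_down >= r_min)] = "recurrently_down"
    cls[(n_up >= r_bi) & (n_down >= r_bi)] = "bimorphic"
    return pd.Series(cls, index=counts.index, name="recurrence_class")
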