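"""Clinical association of recurrent lncRNA sets and single markers.

Covers preranked gene-set enrichment against an external cohort ranking,
Kaplan-Meier survival with log-rank testing, clinical odds-ratio tables,
and nearest-template tumour subtype assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "signal2noise_rank",
    "gsea_preranked",
    "km_logrank",
    "expression_split",
    "clinical_odds_ratios",
    "nearest_template_subtype",
    "subclass_de",
]


def signal2noise_rank(expr: pd.DataFrame, labels: pd.Series,
                      group_order: tuple[str, str] | None = None) -> pd.Series:
    """Signal-to-noise ranking of features between two phenotype groups.

    score = (mu1 - mu2) / (s1 + s2), each s floored at
    max(0.2 * |mu|, 0.2); group 1 is ``group_order[0]`` (default: order of
    appearance). Returned descending with id tie-break.
    """
    groups = list(group_order) if group_order else list(labels.unique())
    if len(groups) != 2 or not set(labels) <= set(groups):
        raise ValueError(f"need exactly 2 groups covering labels, got {groups}")
    g1 = labels[labels == groups[0]].index
    g2 = labels[labels == groups[1]].index
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each group needs >= 3 samples")
    x1 = expr[g1].to_numpy(dtype=float)
    x2 = expr[g2].to_numpy(dtype=float)
    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    s1 = np.maximum(x1.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu1), 0.2))
    s2 = np.maximum(x2.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu2), 0.2))
    score = (mu1 - mu2) / (s1 + s2)
    out = pd.Series(score, index=expr.index, name="signal2noise")
    return _stable_desc(out)


def _stable_desc(s: pd.Series) -> pd.Series:
    df = s.rename("score").rename_axis("id").reset_index()
    df = df.sort_values(["score", "id"], ascending=[False, True],
                        kind="mergesort")
    return pd.Series(df["score"].to_numpy(), index=df["id"].to_numpy(),
                     name=s.name)


def _es_running(scores: np.ndarray, is_hit: np.ndarray, weight: float) -> float:
    """Signed maximal deviation of the weighted KS running sum."""
    w = np.abs(scores) ** weight
    hit_total = w[is_hit].sum()
    n_miss = (~is_hit).sum()
    if hit_total == 0 or n_miss == 0:
        inc = np.where(is_hit, 1.0 / max(is_hit.sum(), 1), 0.0)
    else:
        inc = np.where(is_hit, w / hit_total, 0.0)
    dec = np.where(~is_hit, 1.0 / max(n_miss, 1), 0.0)
    running = np.cumsum(inc - dec)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(ranked: pd.Series, gene_set: set[str], weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Weighted Kolmogorov-Smirnov enrichment of a gene set in a ranking.

    ``ranked`` is a descending score series indexed by feature. The p-value
    comes from random same-size gene sets under the fixed ranking.
    """
    scores = ranked.to_numpy(dtype=float)
    ids = np.asarray(ranked.index)
    hit = np.isin(ids, list(gene_set))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranking")
    es = _es_running(scores, hit, weight)

    rng = np.random.default_rng(seed)
    n = len(ids)
    more_extreme = 0
    matched_sign = 0
    for _ in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=n_hits, replace=False)] = True
        es_p = _es_running(scores, perm_hit, weight)
        if (es >= 0 and es_p >= 0) or (es < 0 and es_p < 0):
            matched_sign += 1
            if abs(es_p) >= abs(es):
                more_extreme += 1
    denom = max(matched_sign, 1)
    p = (more_extreme + 1) / (denom + 1)
    return es, float(p)


def km_logrank(surv: pd.DataFrame, horizon_days: int = 1825
               ) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan-Meier curves per group with a two-group log-rank p.

    ``surv`` columns: time_days, event (1 = death), group. Follow-up is
    administratively censored at ``horizon_days``.
    """
    if (surv["time_days"] <= 0).any():
        raise ValueError("times must be positive")
    groups = sorted(surv["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    t = np.minimum(surv["time_days"].to_numpy(dtype=float), horizon_days)
    e = surv["event"].to_numpy(dtype=int) & (
        surv["time_days"].to_numpy(dtype=float) <= horizon_days
    )
    curves = {}
    for g in groups:
        mask = (surv["group"] == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {g} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(g))
        curves[g] = kmf.survival_function_
    if len(groups) != 2:
        raise ValueError("log-rank comparison implemented for 2 groups")
    m = (surv["group"] == groups[0]).to_numpy()
    res = logrank_test(t[m], t[~m], e[m], e[~m])
    return curves, float(res.p_value)


def expression_split(marker_values: pd.Series, rule: str = "lower_tercile"
                     ) -> pd.Series:
    """Binary low/high split of subjects by a marker's expression.

    ``lower_tercile``: the lowest third (by value, subject-id tie-break) is
    "low"; ``median``: lower half is "low". Deterministic.
    """
    df = marker_values.rename("value").rename_axis("subject").reset_index()
    df = df.sort_values(["value", "subject"], kind="mergesort")
    n = len(df)
    if rule == "lower_tercile":
        n_low = int(round(n / 3))
    elif rule == "median":
        n_low = n // 2
    else:
        raise ValueError(f"unknown rule {rule!r}")
    labels = ["low"] * n_low + ["high"] * (n - n_low)
    return pd.Series(labels, index=df["subject"].to_numpy(), name="group"
                     ).reindex(marker_values.index)


def clinical_odds_ratios(covariates: pd.DataFrame, groups: pd.Series
                         ) -> pd.DataFrame:
    """Woolf odds ratio with log-scale 95% CI per binary covariate.

    For each covariate, the 2x2 table crosses group (low vs high) with the
    covariate; any zero cell triggers the Haldane 0.5 continuity
    correction on all cells.
    """
    rows = []
    low = groups == "low"
    for cov in covariates.columns:
        v = covariates[cov]
        if not set(v.dropna().unique()) <= {0, 1, True, False}:
            raise ValueError(f"covariate {cov} is not binary")
        ok = v.notna()
        a = float(((v == 1) & low & ok).sum())   # low & positive
        b = float(((v == 0) & low & ok).sum())
        c = float(((v == 1) & ~low & ok).sum())
        d = float(((v == 0) & ~low & ok).sum())
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        undefined = min(a, b, c, d) == 0
        if undefined:
            rows.append({"covariate": cov, "odds_ratio": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "undefined": True})
            continue
        or_ = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        rows.append({
            "covariate": cov,
            "odds_ratio": or_,
            "ci_low": float(np.exp(np.log(or_) - 1.96 * se)),
            "ci_high": float(np.exp(np.log(or_) + 1.96 * se)),
            "undefined": False,
        })
    return pd.DataFrame(rows)


def _cosine_dist(x: np.ndarray, t: np.ndarray) -> float:
    nx_ = np.linalg.norm(x)
    nt = np.linalg.norm(t)
    if nx_ == 0 or nt == 0:
        return 1.0
    return float(1.0 - (x @ t) / (nx_ * nt))


def nearest_template_subtype(expr: pd.DataFrame, templates: pd.DataFrame,
                             n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Assign each sample the nearest subclass template by cosine distance.

    ``templates`` is signature-gene x subclass. The p-value per sample is
    the fraction of gene-label permutations of its signature vector whose
    distance to the assigned template is at most the observed one.
    """
    genes = [g for g in templates.index if g in expr.index]
    if len(genes) < 10:
        raise ValueError(f"only {len(genes)} signature genes present (< 10)")
    T = templates.loc[genes].to_numpy(dtype=float)
    T = T - T.mean(axis=0, keepdims=True)
    subclasses = list(templates.columns)
    rng = np.random.default_rng(seed)
    rows = []
    X = expr.loc[genes].to_numpy(dtype=float)
    # gene-wise centring per sample puts expression and +-1 templates on
    # a comparable scale for the cosine distance
    Xc = X - X.mean(axis=0, keepdims=True)
    for j, sample in enumerate(expr.columns):
        x = Xc[:, j]
        dists = [_cosine_dist(x, T[:, k]) for k in range(len(subclasses))]
        k_best = int(np.argmin(dists))
        d_obs = dists[k_best]
        count = 0
        for _ in range(n_perm):
            xp = x[rng.permutation(len(x))]
            if _cosine_dist(xp, T[:, k_best]) <= d_obs:
                count += 1
        rows.append({"sample": sample, "subclass": subclasses[k_best],
                     "distance": d_obs, "p": (count + 1) / (n_perm + 1)})
    return pd.DataFrame(rows).set_index("sample")


def subclass_de(expr: pd.DataFrame, subclass_labels: pd.Series,
                q_cutoff: float = 0.05, fc_cutoff: float = 2.0,
                pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-subclass-vs-rest Wilcoxon rank-sum differential expression.

    Significant when BH q < ``q_cutoff`` and fold change of means exceeds
    ``fc_cutoff`` in either direction. Subclasses with < 3 samples are
    skipped.
    """
    frames = []
    for sub in sorted(subclass_labels.unique()):
        in_g = subclass_labels[subclass_labels == sub].index
        out_g = subclass_labels[subclass_labels != sub].index
        if len(in_g) < 3 or len(out_g) < 3:
            continue
        x_in = expr[list(in_g)].to_numpy(dtype=float)
        x_out = expr[list(out_g)].to_numpy(dtype=float)
        res = stats.ranksums(x_in, x_out, axis=1)
        p = np.asarray(res.pvalue)
        constant = np.array([
            len(np.unique(np.concatenate([a, b]))) == 1
            for a, b in zip(x_in, x_out)
        ])
        p[constant] = 1.0
        fc = (x_in.mean(axis=1) + pseudocount) / (x_out.mean(axis=1)
                                                  + pseudocount)
        q = multipletests(p, method="fdr_bh")[1]
        sig = (q < q_cutoff) & (np.maximum(fc, 1.0 / fc) > fc_cutoff)
        frames.append(pd.DataFrame({
            "feature": expr.index, "subclass": sub, "p": p, "q": q,
            "fold_change": fc, "significant": sig,
        }))
    if not frames:
        return pd.DataFrame(columns=["feature", "subclass", "p", "q",
                                     "fold_change", "significant"])
    return pd.concat(frames, ignore_index=True)
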