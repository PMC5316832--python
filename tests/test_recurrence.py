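"""Per-patient fold-change statistic, cohort-level tests, recurrence
counting and the permutation FDR, each checked against independent
oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncrecur import recurrence as R


def exact_gfold(count_a, count_b, lib_a, lib_b, sc=0.01):
    """Closed-form oracle: with rate_a ~ Gamma(a+1), rate_b ~ Gamma(b+1),
    B = rate_b/(rate_a+rate_b) ~ Beta(b+1, a+1), so quantiles of
    log2(rate_b/rate_a) follow from beta.ppf exactly."""
    def q(p):
        bq = stats.beta.ppf(p, count_b + 1, count_a + 1)
        return np.log2(bq / (1 - bq)) - np.log2(lib_b / lib_a)
    med = q(0.5)
    if med > 0:
        lo = q(sc)
        return lo if lo > 0 else 0.0
    if med < 0:
        hi = q(1 - sc)
        return hi if hi < 0 else 0.0
    return 0.0


def brute_force_bh(p):
    """Step-up BH from first principles."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = running_min
    return q


def poisson_binomial_tail(ps, r):
    """P(sum of independent Bernoulli(p_i) >= r) by DP convolution."""
    dist = np.zeros(len(ps) + 1)
    dist[0] = 1.0
    for p in ps:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return dist[r:].sum()


class TestGfoldStatistic:
    def test_symmetric_counts_give_zero(self):
        assert R.gfold_statistic(100, 100, 1e6, 1e6, seed=1) == 0.0

    def test_strong_change_matches_exact_quantile(self):
        val = R.gfold_statistic(0, 500, 1e6, 1e6, n_draws=100_000, seed=2)
        expected = exact_gfold(0, 500, 1e6, 1e6)
        assert val > 1.0
        assert val == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize("ca,cb", [(10, 80), (300, 50), (5, 5), (0, 40)])
    def test_monte_carlo_agrees_with_beta_ppf_oracle(self, ca, cb):
        val = R.gfold_statistic(ca, cb, 2e6, 1e6, n_draws=100_000, seed=3)
        assert val == pytest.approx(exact_gfold(ca, cb, 2e6, 1e6), abs=0.06)

    def test_library_scale_invariance(self):
        a = R.gfold_statistic(50, 200, 1e6, 1e6, seed=4)
        b = R.gfold_statistic(50, 200, 2e6, 2e6, seed=4)
        assert a == pytest.approx(b)

    def test_antisymmetric_under_condition_swap(self):
        a = R.gfold_statistic(30, 300, 1e6, 2e6, seed=5)
        b = R.gfold_statistic(300, 30, 2e6, 1e6, seed=5)
        assert a == pytest.approx(-b)  # exact: mirrored canonical draws

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            R.gfold_statistic(1.5, 2, 1e6, 1e6)


class TestPerPatientCalls:
    def test_excluded_pvtt_patient_contributes_no_calls(self, cohort,
                                                        de_chain):
        calls = de_chain["pvtt_vs_tumour"]["calls"]
        assert "I" not in set(calls["patient"])
        assert calls["patient"].nunique() == 19

    def test_planted_effects_recovered_per_patient(self, cohort, de_chain):
        # per-pair power is capped near 0.90 by the study conditions: the
        # NB log2-ratio noise at dispersion 0.1 is ~0.68 and the credible
        # bound subtracts its own margin, so P(bound > 1 | true 4-fold)
        # ~= Phi((2 - 1.1)/0.68); assert comfortably above chance and
        # within that analytic ceiling
        b = cohort
        calls = de_chain["tumour_vs_normal"]["calls"]
        up = calls[calls["direction"] == "up"]
        hit = {(f, p) for f, p in zip(up["feature"], up["patient"])}
        planted = {(f, p) for f, pats in b.truth.tumour_up.items()
                   for p in pats}
        assert len(hit & planted) / len(planted) >= 0.85

    def test_all_zero_feature_has_no_direction(self, cohort):
        b = cohort
        counts = b.counts.iloc[:5].copy()
        counts.iloc[0] = 0
        calls = R.per_patient_calls(counts, b.design, "tumour_vs_normal",
                                    seed=0, n_draws=2000,
                                    lib_sizes=b.counts.sum(axis=0))
        first = calls[calls["feature"] == counts.index[0]]
        assert (first["direction"] == "none").all()


class TestWilcoxonDe:
    def test_identical_columns_all_null(self, cohort):
        b = cohort
        fpkm = b.fpkm.iloc[:50].copy()
        for _, sa, sb in b.design.pairs("tumour_vs_normal"):
            fpkm[sb] = fpkm[sa]
        out = R.wilcoxon_de(fpkm, b.design, "tumour_vs_normal")
        assert (out["q"] == 1.0).all()
        assert (out["direction"] == "none").all()

    def test_cohort_wide_fourfold_shift_detected(self, cohort):
        b = cohort
        rng = np.random.default_rng(0)
        base = rng.gamma(4, 25, size=(40, 60))
        fpkm = pd.DataFrame(base, columns=b.fpkm.columns)
        for _, sa, sb in b.design.pairs("tumour_vs_normal"):
            fpkm[sb] = fpkm[sa] * 4 * rng.lognormal(0, 0.1, 40)
        out = R.wilcoxon_de(fpkm, b.design, "tumour_vs_normal")
        assert (out["direction"] == "up").mean() >= 0.95
        assert out["log2fc"].median() == pytest.approx(2.0, abs=0.3)

    def test_bh_agrees_with_brute_force(self):
        rng = np.random.default_rng(7)
        for n in (4, 17, 100):
            p = rng.random(n)
            from statsmodels.stats.multitest import multipletests
            q = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, brute_force_bh(p))
        # the worked example: (0.01, 0.02, 0.03, 0.04) at m=4 -> all 0.04
        assert np.allclose(brute_force_bh([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_too_few_patients_rejected(self, cohort):
        b = cohort
        small = R.CohortDesign(
            b.design.samples[b.design.samples["patient"].isin(list("ABC"))])
        with pytest.raises(ValueError):
            R.wilcoxon_de(b.fpkm.iloc[:5], small, "tumour_vs_normal")


class TestNbWaldDe:
    def test_identical_groups_are_null(self, cohort):
        b = cohort
        counts = b.counts.iloc[:50].copy()
        for _, sa, sb in b.design.pairs("tumour_vs_normal"):
            counts[sb] = counts[sa]
        out = R.nb_wald_de(counts, b.design, "tumour_vs_normal")
        assert np.allclose(out["log2fc"], 0.0)
        assert (out["direction"] == "none").all()

    def test_size_factors_track_exact_column_scalings(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 1000, size=(200, 1)).astype(float)
        counts = pd.DataFrame(
            np.hstack([base, 2 * base, 4 * base]).astype(int),
            columns=["a", "b", "c"])
        sf = R.size_factors(counts)
        ratios = sf / sf.iloc[0]
        assert np.allclose(ratios, [1.0, 2.0, 4.0])

    def test_planted_fourfold_power(self, cohort, de_chain):
        b = cohort
        out = de_chain["nb_wald"]
        up = set(out.index[out["direction"] == "up"])
        down = set(out.index[out["direction"] == "down"])
        tu, td = set(b.truth.tumour_up), set(b.truth.tumour_down)
        assert len(up & tu) / len(tu) >= 0.85
        assert len(down & td) / len(td) >= 0.8

    def test_non_integer_counts_rejected(self, cohort):
        bad = cohort.counts.iloc[:3] + 0.5
        with pytest.raises(ValueError):
            R.nb_wald_de(bad, cohort.design, "tumour_vs_normal")


class TestRecurrence:
    def test_counting_directions_separately(self):
        calls = pd.DataFrame({
            "feature": ["f"] * 11,
            "patient": list("ABCDEFGHIJK"),
            "direction": ["up"] * 5 + ["down"] * 6,
        })
        rec = R.recurrence_counts(calls)
        assert rec.loc["f", "n_up"] == 5 and rec.loc["f", "n_down"] == 6

    def test_no_calls_gives_zeros(self):
        rec = R.recurrence_counts(pd.DataFrame(
            columns=["feature", "patient", "direction"]), ["a", "b"])
        assert (rec == 0).all().all()

    @pytest.mark.parametrize("n_up,n_down,r_min,expected", [
        (8, 0, 8, "recurrently_up"),
        (0, 9, 8, "recurrently_down"),
        (4, 5, 8, "bimorphic"),
        (1, 1, 8, "none"),
    ])
    def test_bimorphic_classification(self, n_up, n_down, r_min, expected):
        counts = pd.DataFrame({"n_up": [n_up], "n_down": [n_down]},
                              index=["f"])
        assert R.classify_bimorphic(counts, r_min).iloc[0] == expected


class TestRecurrenceFdr:
    def test_saturated_null_gives_fdr_one(self):
        obs = np.full(10, 3)
        res = R.recurrence_fdr([10, 10, 10], 10, obs, n_perm=50, seed=0)
        assert np.allclose(res.table["fdr"], 1.0)

    def test_monte_carlo_matches_poisson_binomial_oracle(self):
        # enumerable instance: each patient hits a feature independently
        # with p_i = k_i / N; the null tail count is N * P(X >= r)
        from .test_recurrence import poisson_binomial_tail
        k = np.array([3, 7, 11, 5, 9])
        N = 40
        n_perm = 4000
        obs = np.zeros(N, dtype=int)
        res = R.recurrence_fdr(k, N, obs, n_perm=n_perm, seed=5)
        ps = k / N
        for r in range(1, 6):
            exact = N * poisson_binomial_tail(ps, r)
            mc = res.table.loc[r, "null_mean_tail"]
            # binomial-ish SE of the mean tail count over permutations
            se = np.sqrt(max(exact, 1e-12)) / np.sqrt(n_perm) * 3
            assert abs(mc - exact) <= max(3 * se, 0.05 * exact + 1e-6), r

    def test_strong_recurrence_has_tiny_fdr(self):
        # 20 patients, N = 10,000, k_i = 100; one feature in 8 patients
        obs = np.zeros(10_000, dtype=int)
        obs[0] = 8
        res = R.recurrence_fdr([100] * 20, 10_000, obs, n_perm=400, seed=2)
        assert res.table.loc[8, "fdr"] < 0.001

    def test_zero_observed_tail_flagged(self):
        res = R.recurrence_fdr([5, 5], 100, np.zeros(100, dtype=int),
                               n_perm=50, seed=1)
        assert res.table["flagged_zero_observed"].all()
        assert (res.table["fdr"] == 0).all()

    def test_oversized_selection_rejected(self):
        with pytest.raises(ValueError):
            R.recurrence_fdr([101], 100, np.zeros(100), n_perm=10, seed=0)


class TestFdrThresholdedSets:
    def test_rule_floors_at_configured_minimum(self):
        # one feature called up by every patient; sparse calls otherwise
        calls = pd.DataFrame({
            "feature": ["f0"] * 10,
            "patient": [f"p{i}" for i in range(10)],
            "direction": ["up"] * 10,
        })
        rec = R.recurrence_counts(calls, [f"f{i}" for i in range(200)])
        out = R.fdr_thresholded_sets(calls, rec, 200, r_floor=4,
                                     n_perm=300, seed=0)
        assert out["up"]["r"] >= 4
        assert "f0" in out["up"]["set"]
        assert out["down"]["set"] == set()

    def test_dense_null_raises_threshold_above_floor(self):
        # a quarter of the universe is called per patient, so recurrence
        # levels reachable by chance must be excluded by the rule; one
        # planted feature recurs in all ten patients
        rng = np.random.default_rng(3)
        feats = [f"f{i}" for i in range(60)]
        rows = []
        for p in range(10):
            called = set(rng.choice(feats[1:], 14, replace=False)) | {"f0"}
            rows += [{"feature": f, "patient": f"p{p}", "direction": "up"}
                     for f in called]
        calls = pd.DataFrame(rows)
        rec = R.recurrence_counts(calls, feats)
        out = R.fdr_thresholded_sets(calls, rec, 60, r_floor=2,
                                     n_perm=400, seed=1)
        assert out["up"]["r"] > 2
        assert "f0" in out["up"]["set"]


class TestIntersection:
    def test_three_way_intersection(self):
        up = R.intersect_methods(({"A", "B", "C"}, set()),
                                 ({"B", "C", "D"}, set()),
                                 ({"C"}, set()))[0]
        assert up == {"C"}

    def test_disjoint_methods_give_empty(self):
        up, down = R.intersect_methods(({"A"}, set()), ({"B"}, set()),
                                       ({"C"}, set()))
        assert not up and not down

    def test_pvtt_contrast_uses_recurrence_alone(self):
        up, down = R.intersect_methods(({"A"}, {"B"}), (set(), set()),
                                       (set(), set()),
                                       contrast="pvtt_vs_tumour")
        assert up == {"A"} and down == {"B"}
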