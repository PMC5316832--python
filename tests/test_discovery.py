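"""The discovery filter cascade, positional classes, conservation and
SNP enrichment."""

import numpy as np
import pandas as pd
import pytest

from lncrecur import discovery as D
from lncrecur.genomic_core import (
    GenomeLayout,
    GenomicInterval,
    ScoreTrack,
    SnpCatalog,
    TranscriptModel,
)

from .test_genomic_core import make_tx


def fpkm_table(rows, columns=("s1", "s2")):
    return pd.DataFrame(rows, columns=list(columns))


class TestExonicOverlapFilter:
    ref = [make_tx("R", exons=((199, 300),), biotype="coding")]

    def test_single_base_overlap_removes(self):
        cand = [make_tx("C", exons=((100, 200),))]
        kept, removed = D.filter_exonic_overlap(cand, self.ref)
        assert not kept and removed[0].transcript_id == "C"

    def test_opposite_strand_overlap_kept(self):
        cand = [make_tx("C", exons=((100, 200),), strand="-")]
        kept, _ = D.filter_exonic_overlap(cand, self.ref)
        assert len(kept) == 1

    def test_intronic_candidate_kept_by_this_filter(self):
        ref = [make_tx("R", exons=((100, 200), (900, 1000)), biotype="coding")]
        cand = [make_tx("C", exons=((400, 700),))]
        kept, _ = D.filter_exonic_overlap(cand, ref)
        assert len(kept) == 1


class TestLengthStrandFilter:
    def test_199_bases_removed(self):
        cand = [make_tx("C", exons=((0, 100), (200, 299)))]
        kept, removed = D.filter_length_strand(cand)
        assert not kept and len(removed) == 1

    def test_exactly_200_kept(self):
        cand = [make_tx("C", exons=((0, 200),))]
        kept, _ = D.filter_length_strand(cand)
        assert len(kept) == 1

    def test_unstranded_removed_despite_length(self):
        cand = [make_tx("C", exons=((0, 500),), strand=".")]
        kept, removed = D.filter_length_strand(cand)
        assert not kept and len(removed) == 1


class TestProximityFilter:
    ref = [make_tx("R", exons=((10_000, 12_000),), biotype="coding")]

    def test_gap_1500_removed(self):
        cand = [make_tx("C", exons=((12_000 + 1500, 12_000 + 1500 + 400),))]
        kept, removed = D.filter_single_exon_proximity(cand, self.ref)
        assert not kept and len(removed) == 1

    def test_gap_2500_kept(self):
        cand = [make_tx("C", exons=((12_000 + 2500, 12_000 + 2500 + 400),))]
        kept, _ = D.filter_single_exon_proximity(cand, self.ref)
        assert len(kept) == 1

    def test_multi_exon_passes_untouched(self):
        cand = [make_tx("C", exons=((12_100, 12_300), (12_500, 12_700)))]
        kept, _ = D.filter_single_exon_proximity(cand, self.ref)
        assert len(kept) == 1


class TestExpressionFilter:
    def test_max_fpkm_below_threshold_removed(self):
        cand = [make_tx("C", exons=((0, 1000),))]
        fpkm = pd.DataFrame([[0.4, 0.2]], index=["C"])
        kept, removed = D.filter_expression(cand, fpkm)
        assert not kept and len(removed) == 1

    def test_boundary_is_strict(self):
        cand = [make_tx("C", exons=((0, 1000),))]
        fpkm = pd.DataFrame([[0.5, 0.1]], index=["C"])
        kept, _ = D.filter_expression(cand, fpkm)
        assert len(kept) == 1

    def test_multi_exon_passes_even_at_zero(self):
        cand = [make_tx("C")]
        fpkm = pd.DataFrame([[0.0, 0.0]], index=["C"])
        kept, _ = D.filter_expression(cand, fpkm)
        assert len(kept) == 1

    def test_missing_feature_raises_with_ids(self):
        cand = [make_tx("C", exons=((0, 1000),))]
        with pytest.raises(KeyError, match="C"):
            D.filter_expression(cand, pd.DataFrame(index=["other"]))


class TestCodingPotentialFilter:
    @pytest.mark.parametrize("cpc,come,removed", [
        (0.1, 0.2, True),    # CPC > 0
        (-1.0, 0.5, False),  # both boundaries are strict
        (-1.0, 0.8, True),   # COME > 0.5
    ])
    def test_score_rules(self, cpc, come, removed):
        cand = [make_tx("C")]
        scores = pd.DataFrame({"cpc_score": [cpc], "come_score": [come]},
                              index=["C"])
        kept, gone = D.filter_coding_potential(cand, scores)
        assert (len(gone) == 1) is removed

    def test_missing_scores_without_fallback(self):
        cand = [make_tx("C")]
        empty = pd.DataFrame(columns=["cpc_score", "come_score"])
        with pytest.raises(KeyError):
            D.filter_coding_potential(cand, empty)

    def test_orf_fallback(self):
        cand = [make_tx("C")]
        empty = pd.DataFrame(columns=["cpc_score", "come_score"])
        long_orf = "ATG" + "GCA" * 120 + "TAA"
        kept, gone = D.filter_coding_potential(
            cand, empty, orf_fallback=True, sequences={"C": long_orf})
        assert len(gone) == 1
        kept, gone = D.filter_coding_potential(
            cand, empty, orf_fallback=True, sequences={"C": "ATGGCATAA"})
        assert len(kept) == 1


class TestCascade:
    def test_empty_candidate_set(self):
        report = D.run_discovery_cascade(
            [], [], pd.DataFrame(), pd.DataFrame(
                columns=["cpc_score", "come_score"]))
        assert len(report.stages) == 5
        assert all(n_in == 0 and kept == 0 for _, n_in, kept, _ in
                   report.stages)

    def test_cascade_equals_manual_composition(self, cohort):
        b = cohort
        report = D.run_discovery_cascade(
            b.genome.candidates, b.genome.reference, b.fpkm, b.scores)
        cur, _ = D.filter_exonic_overlap(b.genome.candidates,
                                         b.genome.reference)
        cur, _ = D.filter_length_strand(cur)
        cur, _ = D.filter_single_exon_proximity(cur, b.genome.reference)
        cur, _ = D.filter_expression(cur, b.fpkm)
        cur, _ = D.filter_coding_potential(cur, b.scores)
        assert report.kept_ids == [c.transcript_id for c in cur]

    def test_attrition_bookkeeping_is_conserved(self, cohort):
        b = cohort
        report = D.run_discovery_cascade(
            b.genome.candidates, b.genome.reference, b.fpkm, b.scores)
        frame = report.to_frame()
        assert (frame["n_kept"] + frame["n_removed"] == frame["n_in"]).all()
        assert (frame["n_in"].iloc[1:].to_numpy()
                == frame["n_kept"].iloc[:-1].to_numpy()).all()

    def test_every_decoy_removed_at_its_designed_stage(self, cohort):
        b = cohort
        report = D.run_discovery_cascade(
            b.genome.candidates, b.genome.reference, b.fpkm, b.scores)
        kept = set(report.kept_ids)
        assert kept == set(b.genome.true_lnc_ids)
        # replay stage by stage and record where each decoy disappears
        stages = [
            lambda c: D.filter_exonic_overlap(c, b.genome.reference),
            D.filter_length_strand,
            lambda c: D.filter_single_exon_proximity(c, b.genome.reference),
            lambda c: D.filter_expression(c, b.fpkm),
            lambda c: D.filter_coding_potential(c, b.scores),
        ]
        cur = b.genome.candidates
        removed_at = {}
        for name, fn in zip(D.CASCADE_STAGES, stages):
            cur, removed = fn(cur)
            for m in removed:
                removed_at[m.transcript_id] = name
        for tid, designed in b.genome.decoy_stage.items():
            assert removed_at[tid] == designed, tid


class TestPositionClass:
    coding = [make_tx("G", exons=((10_000, 10_500), (20_000, 20_500)),
                      biotype="coding")]

    def classify(self, t):
        out = D.classify_position([t], self.coding)
        return out["position_class"].iloc[0]

    def test_antisense_beats_everything(self):
        t = make_tx("L", exons=((10_400, 10_800),), strand="-")
        assert self.classify(t) == "antisense"

    def test_intronic_within_same_strand_intron(self):
        t = make_tx("L", exons=((12_000, 13_000),))
        assert self.classify(t) == "intronic"

    def test_cis_within_2kb_of_gene_end(self):
        t = make_tx("L", exons=((21_000, 21_400),))
        assert self.classify(t) == "cis"

    def test_intergenic_far_from_everything(self):
        t = make_tx("L", exons=((80_000, 80_400),))
        assert self.classify(t) == "intergenic"

    def test_every_transcript_gets_exactly_one_class(self, cohort):
        b = cohort
        coding = [m for m in b.genome.reference if m.biotype == "coding"]
        lnc = [b.genome.models[f] for f in b.genome.true_lnc_ids[:100]]
        out = D.classify_position(lnc, coding)
        assert len(out) == 100
        assert out["position_class"].isin(
            ["intergenic", "antisense", "intronic", "cis"]).all()


class TestConservation:
    def test_constant_track(self):
        t = make_tx("T", exons=((100, 200), (300, 400)))
        track = ScoreTrack({"chr1": [(0, 1000, 0.8)]})
        ex, intr = D.conservation_profile(t, track)
        assert ex == pytest.approx(0.8) and intr == pytest.approx(0.8)

    def test_exon_intron_contrast(self):
        t = make_tx("T", exons=((100, 200), (300, 400)))
        track = ScoreTrack({"chr1": [(100, 200, 1.0), (300, 400, 1.0)]})
        ex, intr = D.conservation_profile(t, track)
        assert ex == pytest.approx(1.0) and intr == pytest.approx(0.0)

    def test_single_exon_intron_mean_is_missing(self):
        t = make_tx("T", exons=((100, 200),))
        ex, intr = D.conservation_profile(t, ScoreTrack({}))
        assert np.isnan(intr)

    def test_against_per_base_brute_force(self):
        rng = np.random.default_rng(11)
        runs = []
        pos = 0
        for _ in range(30):
            w = int(rng.integers(1, 8))
            runs.append((pos, pos + w, float(rng.random())))
            pos += w + int(rng.integers(0, 4))
        track = ScoreTrack({"chr1": runs})
        per_base = np.zeros(pos + 10)
        for a, b, v in runs:
            per_base[a:b] = v
        t = make_tx("T", exons=((3, 17), (25, 60)))
        ex, intr = D.conservation_profile(t, track)
        exp_ex = (per_base[3:17].sum() + per_base[25:60].sum()) / (14 + 35)
        exp_in = per_base[17:25].mean()
        assert ex == pytest.approx(exp_ex)
        assert intr == pytest.approx(exp_in)


class TestSnpEnrichment:
    layout = GenomeLayout({"chr1": 200_000})

    def _intervals(self):
        return [GenomicInterval("chr1", i * 10_000, i * 10_000 + 2_000, "+")
                for i in range(10)]

    def test_self_comparison_gives_or_near_one(self):
        rng = np.random.default_rng(0)
        sites = [("chr1", int(p)) for p in rng.integers(0, 200_000, 4000)]
        cat = SnpCatalog.from_pairs(sites)
        res = D.snp_enrichment(self._intervals(), cat, cat, self.layout,
                               n_shuffles=50, seed=1)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        bg = SnpCatalog.from_pairs(
            [("chr1", int(p)) for p in rng.integers(0, 200_000, 4000)])
        gw = SnpCatalog.from_pairs(
            [("chr1", int(p)) for p in rng.integers(0, 200_000, 400)])
        a = D.snp_enrichment(self._intervals(), gw, bg, self.layout,
                             n_shuffles=30, seed=4)
        b = D.snp_enrichment(self._intervals(), gw, bg, self.layout,
                             n_shuffles=30, seed=4)
        assert a.odds_ratio == b.odds_ratio and a.p_value == b.p_value

    def test_planted_enrichment_detected(self, cohort):
        b = cohort
        models = b.genome.models
        ivs = [models[f].interval for f in b.truth.lnc_universe]
        res = D.snp_enrichment(ivs, b.clinical["gwas"],
                               b.clinical["background"], b.genome.layout,
                               n_shuffles=100, seed=13)
        assert res.odds_ratio > res.odds_ratio_control
        assert res.odds_ratio > 2.0
        assert res.p_value < 0.01

    def test_label_swap_inverts_enrichment(self, cohort):
        b = cohort
        models = b.genome.models
        ivs = [models[f].interval for f in b.truth.lnc_universe[:400]]
        fwd = D.snp_enrichment(ivs, b.clinical["gwas"],
                               b.clinical["background"], b.genome.layout,
                               n_shuffles=40, seed=5)
        # an unenriched catalogue in the numerator behaves like the control
        swapped = D.snp_enrichment(ivs, b.clinical["background"],
                                   b.clinical["gwas"], b.genome.layout,
                                   n_shuffles=40, seed=5)
        assert fwd.odds_ratio > 1.5
        assert swapped.odds_ratio < fwd.odds_ratio
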