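"""Candidate classification rules: cutoffs, homology, repeats, read evidence."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpost.discovery import (
    BlastHit,
    ClassificationConfig,
    apply_score_cutoff,
    call_arm_dominance,
    classify_candidates,
    classify_conserved,
    collapse_unique_matures,
    filter_other_smallrna,
    filter_repeats,
    validate_novel,
)
from mirpost.simulate import SimConfig, simulate_candidates

from conftest import make_candidate, stack


class TestScoreCutoff:
    @pytest.mark.parametrize(
        "score,cutoff,kept",
        [
            (5.0, 4.0, True),
            (4.0, 4.0, False),  # "above the threshold" is strict
            (3.9, 4.0, False),
        ],
    )
    def test_strict_inequality(self, score, cutoff, kept):
        cand = make_candidate(score=score)
        assert (cand in apply_score_cutoff([cand], cutoff)) is kept

    def test_empty_input(self):
        assert apply_score_cutoff([], 4.0) == []

    def test_preserves_order(self):
        cands = [make_candidate(f"c{i}", score=s) for i, s in enumerate([9, 1, 7, 5])]
        kept = apply_score_cutoff(cands, 4.0)
        assert [c.candidate_id for c in kept] == ["c0", "c2", "c3"]

    @given(
        scores=st.lists(st.floats(-50, 50), max_size=30),
        lo=st.floats(-10, 10),
        delta=st.floats(0, 10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_raising_cutoff_never_keeps_more(self, scores, lo, delta):
        cands = [make_candidate(f"c{i}", score=s) for i, s in enumerate(scores)]
        assert len(apply_score_cutoff(cands, lo + delta)) <= len(
            apply_score_cutoff(cands, lo)
        )


class TestConservedClassification:
    def hit(self, e, subject="mir-25", bits=100.0, db="mirbase", query="cand-1"):
        return BlastHit(query, subject, db, e, bits)

    def test_boundary_evalue_included(self):
        cand = make_candidate()
        assert classify_conserved(cand, [self.hit(1e-06)]) == "mir-25"

    def test_above_threshold_not_conserved(self):
        assert classify_conserved(make_candidate(), [self.hit(1e-05)]) is None

    def test_best_hit_by_lowest_evalue(self):
        hits = [self.hit(1e-08, "mir-92"), self.hit(1e-10, "mir-25")]
        # oracle: the minimum E-value over all hits belongs to mir-25
        assert min(hits, key=lambda h: h.e_value).subject_id == "mir-25"
        assert classify_conserved(make_candidate(), hits) == "mir-25"

    def test_ties_broken_by_bitscore_then_name(self):
        hits = [
            self.hit(1e-08, "mir-b", bits=50.0),
            self.hit(1e-08, "mir-a", bits=80.0),
        ]
        assert classify_conserved(make_candidate(), hits) == "mir-a"
        hits = [self.hit(1e-08, "mir-b"), self.hit(1e-08, "mir-a")]
        assert classify_conserved(make_candidate(), hits) == "mir-a"

    def test_mismatched_query_rejected(self):
        with pytest.raises(ValueError, match="query"):
            classify_conserved(make_candidate(), [self.hit(1e-08, query="other")])


class TestSmallRnaAndRepeatFilters:
    def test_rfam_significant_hit_rejects(self):
        hit = BlastHit("cand-1", "RF00005", "rfam", 1e-09, 90.0)
        assert filter_other_smallrna(make_candidate(), [hit]) is False

    @pytest.mark.parametrize("e", [1e-2, 1.0])
    def test_weak_rfam_hit_kept(self, e):
        hit = BlastHit("cand-1", "RF00005", "rfam", e, 20.0)
        assert filter_other_smallrna(make_candidate(), [hit]) is True

    def test_no_hits_kept(self):
        assert filter_other_smallrna(make_candidate(), []) is True

    def genome_hits(self, n, e=1e-09):
        return [
            BlastHit("cand-1", f"c{i}", "genome", e, 80.0, (f"c{i}", 100, 170, "+"))
            for i in range(n)
        ]

    @pytest.mark.parametrize("n,kept", [(5, True), (6, False), (60, False)])
    def test_locus_count_rule(self, n, kept):
        assert filter_repeats(make_candidate(), self.genome_hits(n)) is kept

    def test_insignificant_hits_not_counted(self):
        assert filter_repeats(make_candidate(), self.genome_hits(60, e=0.1)) is True

    def test_overlapping_hsps_merge_to_one_locus(self):
        # 8 overlapping fragments on one contig+strand = one locus
        hits = [
            BlastHit("cand-1", "c1", "genome", 1e-09, 80.0, ("c1", 100 + 10 * i, 200 + 10 * i, "+"))
            for i in range(8)
        ]
        assert filter_repeats(make_candidate(), hits) is True

    def test_strands_count_separately(self):
        hits = [
            BlastHit("cand-1", "c1", "genome", 1e-09, 80.0, ("c1", 100, 170, s))
            for s in ("+", "-", "+")
        ]
        # merged: two loci (overlaps merge within strand)
        assert filter_repeats(make_candidate(), hits, max_loci=1) is False
        assert filter_repeats(make_candidate(), hits, max_loci=2) is True


class TestNovelValidation:
    def test_single_sample_rejected(self):
        cand = make_candidate(stacks=[stack("s1", "5p", count=20), stack("s1", "3p", count=20)])
        assert validate_novel(cand) == "insufficient_samples"

    def test_no_stacks_rejected(self):
        assert validate_novel(make_candidate()) == "insufficient_samples"

    def test_boundary_five_reads_is_not_enough(self):
        cand = make_candidate(
            stacks=[
                stack("s1", "5p", count=10),
                stack("s1", "3p", count=2),
                stack("s2", "3p", count=3),  # 3p pooled = 5, need > 5
            ]
        )
        assert validate_novel(cand) == "insufficient_arm_reads"

    def test_modal_fraction_rule(self):
        # 5p: 9/10 at the modal offset (>= 0.9), 3p: 7/7
        cand = make_candidate(
            stacks=[
                stack("s1", "5p", offset=12, count=9),
                stack("s1", "5p", offset=13, count=1),
                stack("s2", "3p", offset=48, count=7),
            ]
        )
        assert validate_novel(cand) is None

    def test_inconsistent_5p_end(self):
        cand = make_candidate(
            stacks=[
                stack("s1", "5p", offset=11, count=5),
                stack("s1", "5p", offset=14, count=5),
                stack("s2", "3p", count=10),
            ]
        )
        assert validate_novel(cand) == "inconsistent_5p_end"

    def test_raising_consistency_never_rescues(self):
        cand = make_candidate(
            stacks=[
                stack("s1", "5p", offset=11, count=8),
                stack("s1", "5p", offset=14, count=2),
                stack("s2", "3p", count=10),
            ]
        )
        # modal fraction on 5p is 0.8: rejected at 0.9, still rejected at 0.95
        assert validate_novel(cand, consistency_frac=0.9) == "inconsistent_5p_end"
        assert validate_novel(cand, consistency_frac=0.95) == "inconsistent_5p_end"
        assert validate_novel(cand, consistency_frac=0.75) is None


class TestArmDominance:
    def test_majority_arm(self):
        cand = make_candidate(stacks=[stack("s1", "5p", count=100), stack("s1", "3p", count=10)])
        assert call_arm_dominance(cand) == "5p"

    def test_codominant_on_tie(self):
        cand = make_candidate(stacks=[stack("s1", "5p", count=10), stack("s1", "3p", count=10)])
        assert call_arm_dominance(cand) == "codominant"

    def test_sums_across_samples(self):
        cand = make_candidate(
            stacks=[
                stack("s1", "5p", count=7),
                stack("s2", "5p", count=3),
                stack("s1", "3p", count=6),
                stack("s2", "3p", count=5),
            ]
        )
        assert call_arm_dominance(cand) == "3p"  # 11 > 10 by summation

    def test_no_reads_is_an_error(self):
        with pytest.raises(ValueError):
            call_arm_dominance(make_candidate())


class TestCollapseUniqueMatures:
    def test_identical_matures_collapse(self):
        a = make_candidate("a")
        b = make_candidate("b")  # same sequences as a
        genes = classify_candidates(
            [a, b],
            [BlastHit(q, "mir-1", "mirbase", 1e-9, 99.0) for q in ("a", "b")],
        )
        uniques = collapse_unique_matures(genes)
        assert len(uniques) == 2  # one 5p + one 3p entry
        assert sorted(len(v) for v in uniques.values()) == [2, 2]

    def test_single_nt_difference_stays_separate(self):
        from mirpost.discovery import AnnotatedGene

        a = AnnotatedGene("a", "novel", "c1", 1, 70, "+", "ACGUACGUACGUACGUACGUAC", "")
        b = AnnotatedGene("b", "novel", "c1", 200, 270, "+", "ACGUACGUACGUACGUACGUAA", "")
        assert len(collapse_unique_matures([a, b])) == 2

    def test_distinct_genes_give_two_per_gene(self):
        # all-distinct matures: no collapsing, 2 uniques per gene
        cands, hits, truth = simulate_candidates(
            SimConfig(seed=5, candidate_classes={"novel": 10}, n_family_pairs=0)
        )
        genes = classify_candidates(cands, hits)
        assert len(collapse_unique_matures(genes)) == 20


class TestClassificationChain:
    def test_planted_truth_recovered_exactly(self):
        cfg = SimConfig(seed=11)
        cands, hits, truth = simulate_candidates(cfg)
        genes = classify_candidates(cands, hits)
        assert len(genes) == len(cands) == truth.shape[0]
        for g in genes:
            assert g.status == truth.loc[g.gene_id, "status"]
            if g.status == "rejected":
                assert g.rejection_reason == truth.loc[g.gene_id, "reason"]
            if g.status == "conserved":
                assert g.family_annotation == truth.loc[g.gene_id, "family"]

    def test_every_candidate_classified_once(self):
        cands, hits, _ = simulate_candidates(SimConfig(seed=3))
        genes = classify_candidates(cands, hits)
        counts = {"conserved": 0, "novel": 0, "rejected": 0}
        for g in genes:
            counts[g.status] += 1
        assert sum(counts.values()) == len(cands)

    def test_order_independence(self):
        cands, hits, _ = simulate_candidates(SimConfig(seed=7))
        forward = {g.gene_id: g for g in classify_candidates(cands, hits)}
        backward = {g.gene_id: g for g in classify_candidates(cands[::-1], hits)}
        assert forward == backward

    def test_all_low_score_retains_nothing(self):
        cands, hits, _ = simulate_candidates(
            SimConfig(seed=2, candidate_classes={"low_score": 10})
        )
        genes = classify_candidates(cands, hits)
        assert all(g.status == "rejected" and g.rejection_reason == "low_score" for g in genes)
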