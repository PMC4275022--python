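"""Windowed identity, ECR calling and location classification."""

import numpy as np
import pytest

from ncecr.alignment import PairwiseAlignment
from ncecr.conservation import (
    call_ecrs,
    classify_location,
    ecr_reference_sequence,
    label_ecrs,
    windowed_identity,
)
from ncecr.intervals import GeneModel, GenomicInterval
from ncecr.synthetic_data import ConservedPairConfig, ImplantSpec, simulate_conserved_pair

from oracles import call_ecrs_oracle, window_identity_oracle


def _random_gapped_pair(rng, n_cols=500, gap_rate=0.05, match_rate=0.7):
    bases = "ACGT"
    ref, qry = [], []
    for _ in range(n_cols):
        u = rng.random()
        if u < gap_rate / 2:
            ref.append("-")
            qry.append(bases[rng.integers(0, 4)])
        elif u < gap_rate:
            ref.append(bases[rng.integers(0, 4)])
            qry.append("-")
        else:
            b = bases[rng.integers(0, 4)]
            ref.append(b)
            if rng.random() < match_rate:
                qry.append(b)
            else:
                qry.append(bases[rng.integers(0, 4)])
    return "".join(ref), "".join(qry)


class TestWindowedIdentity:
    def test_identical_pair_scores_one_everywhere(self):
        seq = "ACGT" * 50
        aln = PairwiseAlignment("r", "q", seq, seq)
        prof = windowed_identity(aln, 100)
        assert prof.identity.shape == (101,)
        assert np.all(prof.identity == 1.0)

    def test_alternating_mismatch_scores_half(self):
        ref = "ACAC" * 50
        qry = "AGAG" * 50  # every second column mismatches
        aln = PairwiseAlignment("r", "q", ref, qry)
        prof = windowed_identity(aln, 100)
        assert np.allclose(prof.identity, 0.5)

    def test_short_alignment_warns_and_returns_empty(self):
        aln = PairwiseAlignment("r", "q", "ACGTACGT", "ACGTACGT")
        with pytest.warns(UserWarning, match="shorter than window"):
            prof = windowed_identity(aln, 100)
        assert prof.identity.size == 0
        assert call_ecrs(prof) == []

    def test_window_must_be_positive(self):
        aln = PairwiseAlignment("r", "q", "ACGT", "ACGT")
        with pytest.raises(ValueError):
            windowed_identity(aln, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_recount_on_gapped_alignments(self, seed):
        rng = np.random.default_rng(seed)
        ref, qry = _random_gapped_pair(rng)
        aln = PairwiseAlignment("r", "q", ref, qry)
        prof = windowed_identity(aln, 50)
        expected = window_identity_oracle(aln.ref_text, aln.query_text, 50)
        assert np.allclose(prof.identity, expected, atol=1e-12)

    def test_query_insertions_penalize_identity(self):
        # 4 identical residues with a 2-base query insertion inside the span
        aln = PairwiseAlignment("r", "q", "AC--GT", "ACTTGT")
        prof = windowed_identity(aln, 4)
        assert prof.identity[0] == pytest.approx(4 / 6)


class TestCallEcrs:
    def test_implanted_block_yields_one_ecr_near_truth(self):
        cfg = ConservedPairConfig(
            seed=11, length=2000, background_divergence=0.45,
            implants=(ImplantSpec(900, 150, 0.85),),
        )
        aln, (truth,) = simulate_conserved_pair(cfg)
        prof = windowed_identity(aln, 100)
        ecrs = call_ecrs(prof)  # defaults: min_len 100, min_identity 0.75
        assert len(ecrs) == 1
        (ecr,) = ecrs
        assert abs(ecr.ref.start - truth.start) <= 100
        assert abs(ecr.ref.end - truth.end) <= 100
        assert ecr.identity >= 0.75 and ecr.length >= 100
        # extracted element sequence matches the coordinates
        seq = ecr_reference_sequence(aln, ecr)
        assert len(seq) == ecr.length

    def test_uniform_background_yields_no_ecrs(self):
        cfg = ConservedPairConfig(seed=12, length=2000, background_divergence=0.45)
        aln, _ = simulate_conserved_pair(cfg)
        assert call_ecrs(windowed_identity(aln, 100)) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_window_enumeration_oracle(self, seed):
        cfg = ConservedPairConfig(
            seed=100 + seed, length=1200, background_divergence=0.42,
            implants=(ImplantSpec(300, 160, 0.86), ImplantSpec(750, 140, 0.82)),
        )
        aln, _ = simulate_conserved_pair(cfg)
        got = call_ecrs(windowed_identity(aln, 100), min_len=100, min_identity=0.75)
        expected = call_ecrs_oracle(aln.ref_text, aln.query_text, 100, 100, 0.75)
        assert [(e.ref.start, e.ref.end) for e in got] == [(s, e) for s, e, _ in expected]
        assert np.allclose([e.identity for e in got], [i for _, _, i in expected])

    @pytest.mark.parametrize("seed", range(4))
    def test_reported_ecrs_satisfy_thresholds_post_hoc(self, seed):
        cfg = ConservedPairConfig(
            seed=200 + seed, length=1500, background_divergence=0.35,
            implants=(ImplantSpec(400, 200, 0.80),),
        )
        aln, _ = simulate_conserved_pair(cfg)
        for ecr in call_ecrs(windowed_identity(aln, 100)):
            assert ecr.length >= 100
            # recount from raw columns
            s = ecr.ref.start - aln.ref_offset
            c1, c2 = aln.ref_columns[s], aln.ref_columns[s + ecr.length - 1]
            cols = aln.match_columns[c1 : c2 + 1]
            assert cols.sum() / cols.size == pytest.approx(ecr.identity)

    def test_symmetry_under_role_swap_on_gapfree_alignment(self):
        # window is counted in reference residues, so exact role symmetry
        # holds when no indels are present
        cfg = ConservedPairConfig(
            seed=33, length=1500, background_divergence=0.45, indel_rate=0.0,
            implants=(ImplantSpec(500, 200, 0.88),),
        )
        aln, _ = simulate_conserved_pair(cfg)
        fwd = call_ecrs(windowed_identity(aln, 100))
        rev = call_ecrs(windowed_identity(aln.swapped(), 100))
        assert [(e.ref.start, e.ref.end) for e in rev] == [
            (e.query.start, e.query.end) for e in fwd
        ]
        assert [(e.query.start, e.query.end) for e in rev] == [
            (e.ref.start, e.ref.end) for e in fwd
        ]


def _gene(strand="+"):
    return GeneModel(
        gene=GenomicInterval("c", 1000, 5000, strand),
        exons=(GenomicInterval("c", 1000, 1200, strand),
               GenomicInterval("c", 4800, 5000, strand)),
        utrs=(GenomicInterval("c", 1000, 1050, strand),),
    )


def _ecr_at(start, end):
    from ncecr.conservation import ECR

    return ECR(GenomicInterval("c", start, end), GenomicInterval("q", start, end), 0.9)


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "start,end,strand,expected",
        [
            (2000, 2200, "+", "intronic"),      # strictly inside the intron
            (1100, 1150, "+", "exonic"),
            (5500, 5700, "+", "downstream"),
            (100, 300, "+", "upstream"),
            (5500, 5700, "-", "upstream"),      # minus-strand gene: right is upstream
            (100, 300, "-", "downstream"),
            (900, 1010, "+", "exonic"),         # straddles gene start into exon 1
        ],
    )
    def test_placement_truth_table(self, start, end, strand, expected):
        assert classify_location(_ecr_at(start, end), _gene(strand)) == expected

    def test_utr_only_overlap_reports_utr(self):
        gene = GeneModel(
            gene=GenomicInterval("c", 1000, 5000, "+"),
            exons=(GenomicInterval("c", 2000, 2200, "+"),),
            utrs=(GenomicInterval("c", 1000, 1100, "+"),),
        )
        assert classify_location(_ecr_at(1020, 1080), gene) == "utr"

    def test_different_chromosome_is_an_error(self):
        gene = _gene()
        from ncecr.conservation import ECR

        ecr = ECR(GenomicInterval("other", 10, 20), GenomicInterval("q", 10, 20), 0.9)
        with pytest.raises(ValueError, match="chromosome"):
            classify_location(ecr, gene)

    def test_exhaustive_placements_match_interval_logic(self):
        """Slide a 50 bp interval across the locus and verify the class
        against a direct overlap-based reimplementation."""
        gene = _gene("-")
        for start in range(0, 6000, 37):
            iv = GenomicInterval("c", start, start + 50)
            got = classify_location(iv, gene)
            if any(iv.overlap(e) for e in gene.exons):
                want = "exonic"
            elif any(iv.overlap(u) for u in gene.utrs):
                want = "utr"
            elif iv.overlap(gene.gene):
                want = "intronic"
            elif start >= gene.gene.end:
                want = "upstream"
            else:
                want = "downstream"
            assert got == want, f"placement {start}"


class TestLabels:
    def test_labels_follow_transcription_order_plus_strand(self):
        gene = _gene("+")
        ecrs = [_ecr_at(*span) for span in [(100, 200), (400, 500), (2000, 2100),
                                            (3000, 3100), (5500, 5600), (6000, 6100)]]
        label_ecrs(ecrs, gene)
        assert [e.label for e in ecrs] == ["U1", "U2", "In1", "In2", "D1", "D2"]

    def test_labels_follow_transcription_order_minus_strand(self):
        gene = _gene("-")
        ecrs = [_ecr_at(*span) for span in [(100, 200), (400, 500), (2000, 2100),
                                            (3000, 3100), (5500, 5600), (6000, 6100)]]
        label_ecrs(ecrs, gene)
        # transcription runs right to left: rightmost upstream element is U1
        assert [e.label for e in ecrs] == ["D2", "D1", "In2", "In1", "U2", "U1"]
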