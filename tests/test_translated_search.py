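"""Translation, Smith-Waterman scoring and Karlin-Altschul statistics."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ncyc import ScoringScheme, SequenceRead
from ncyc import _alignment as al
from ncyc.synthetic_community import make_reference_sets, _reverse_translate
from ncyc.translated_search import (ProteinDatabase, karlin_altschul,
                                    reverse_complement, search_reads,
                                    six_frame_translate, smith_waterman)

from _oracles import enumerate_local_score, recursive_local_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA20 = "ARNDCQEGHILKMFPSTWYV"


def blosum(a, b):
    return int(BLOSUM62[a][b])


class TestSixFrameTranslate:
    def test_forward_frame_standard_code(self):
        assert six_frame_translate("ATGGCC")[0] == "MA"

    def test_reverse_frame_is_reverse_complement_translation(self):
        frames = six_frame_translate("GGCCAT")
        assert frames[3] == "MA"

    def test_codon_with_n_translates_to_x(self):
        assert six_frame_translate("ATGNCC")[0] == "MX"

    def test_partial_trailing_codons_dropped(self):
        frames = six_frame_translate("ATGGCCA")
        assert frames[0] == "MA"      # ATG GCC, trailing A dropped
        assert frames[1] == "WP"      # TGG CCA
        assert frames[2] == "G"       # GGC, trailing CA dropped

    def test_stop_codons_emitted_as_star(self):
        assert six_frame_translate("ATGTAAGCC")[0] == "M*A"

    def test_six_frames_returned_in_order(self):
        seq = "ATGGCCTTTAAACCC"
        frames = six_frame_translate(seq)
        assert len(frames) == 6
        rc = reverse_complement(seq)
        for k in range(3):
            assert frames[3 + k] == six_frame_translate(rc)[k]


class TestSmithWaterman:
    def test_self_alignment_scores_sum_of_diagonal(self):
        pep = "HEAGAWGHEE"
        aln = smith_waterman(pep, pep)
        assert aln.raw_score == sum(blosum(c, c) for c in pep)
        assert aln.identity_fraction == 1.0
        assert (aln.q_start, aln.q_end) == (1, len(pep))

    def test_no_positive_pair_gives_empty_alignment(self):
        # glycine vs tryptophan scores -2; no positive-scoring cell exists
        aln = smith_waterman("GGGG", "WWWW")
        assert aln.raw_score == 0
        assert aln.aligned_cols == 0

    def test_matches_memoized_recursion_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        scheme = ScoringScheme()
        for _ in range(150):
            a = "".join(rng.choice(list(AA20), rng.integers(1, 9)))
            b = "".join(rng.choice(list(AA20), rng.integers(1, 9)))
            expected = recursive_local_score(a, b, blosum, 11, 1)
            assert smith_waterman(a, b, scheme).raw_score == expected

    def test_matches_exhaustive_enumeration_on_tiny_pairs(self):
        rng = np.random.default_rng(6)
        scheme = ScoringScheme()
        for _ in range(40):
            a = "".join(rng.choice(list(AA20), rng.integers(1, 5)))
            b = "".join(rng.choice(list(AA20), rng.integers(1, 5)))
            expected = enumerate_local_score(a, b, blosum, 11, 1)
            assert smith_waterman(a, b, scheme).raw_score == expected

    def test_matches_biotite_align_optimal_on_longer_pairs(self):
        """Independent library cross-check on realistic-length peptides."""
        import biotite.sequence as bseq
        import biotite.sequence.align as ba
        matrix = ba.SubstitutionMatrix.std_protein_matrix()
        rng = np.random.default_rng(7)
        scheme = ScoringScheme()
        for _ in range(60):
            a = "".join(rng.choice(list(AA20), rng.integers(10, 80)))
            b = "".join(rng.choice(list(AA20), rng.integers(10, 150)))
            # biotite charges (open, extend) as (first, later) gap columns:
            # (-12, -1) matches our open 11 + 1 per gapped column
            ref = ba.align_optimal(bseq.ProteinSequence(a),
                                   bseq.ProteinSequence(b), matrix,
                                   gap_penalty=(-12, -1), local=True,
                                   max_number=1)[0].score
            assert smith_waterman(a, b, scheme).raw_score == ref

    def test_gap_cost_is_affine_open_plus_length_times_extend(self):
        # AAAA vs AA|GGG|AA: bridging the insert (gap len 3, cost 11+3)
        # beats two split alignments of score 4+4
        a = "WCWC" * 3
        b = "WCWC" * 1 + "GGGGG" + "WCWC" * 2
        aln = smith_waterman(a, b)
        diag = sum(blosum(c, c) for c in a)
        assert aln.raw_score == diag - (11 + 5 * 1)
        assert aln.gap_opens == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "MA")


class TestKarlinAltschul:
    def test_closed_form_high_precision(self):
        scheme = ScoringScheme()
        bit, ev = karlin_altschul(100, scheme, m=100, n=10_000)
        expected_bit = (0.267 * 100 - math.log(0.041)) / math.log(2)
        assert bit == pytest.approx(expected_bit, abs=1e-12)
        assert ev == pytest.approx(100 * 10_000 * 2 ** (-expected_bit),
                                   rel=1e-12)

    def test_one_extra_bit_halves_the_evalue(self):
        scheme = ScoringScheme()
        s1 = 1 / scheme.lam * math.log(2)  # raw score worth one bit
        _, e0 = karlin_altschul(100, scheme, 50, 1000)
        _, e1 = karlin_altschul(100 + s1, scheme, 50, 1000)
        assert e1 == pytest.approx(e0 / 2, rel=1e-9)

    def test_zero_score_limit(self):
        scheme = ScoringScheme()
        bit, ev = karlin_altschul(0, scheme, m=7, n=13)
        assert bit == pytest.approx(-math.log(0.041) / math.log(2), abs=1e-12)
        assert ev == pytest.approx(7 * 13 * 0.041, rel=1e-9)


@pytest.fixture(scope="module")
def planted():
    refs = make_reference_sets(seed=3, n_taxa_per_family=2)
    source = refs.curated[0]  # a narG protein
    gene = refs.gene_nt[source.ref_id]
    return refs, source, gene[30:330]


class TestSearchReads:

    def test_noiseless_planted_read_finds_its_source(self, planted):
        refs, source, frag = planted
        read = SequenceRead("read1", frag)
        hits = search_reads([read], ProteinDatabase(refs.curated))
        best = hits["read1"][0]
        assert best.subject_id == source.ref_id
        assert best.identity_fraction == 1.0
        assert best.frame == 1

    def test_reverse_complement_swaps_frame_sign_keeps_score(self, planted):
        refs, source, frag = planted
        db = ProteinDatabase(refs.curated)
        fwd = search_reads([SequenceRead("f", frag)], db)["f"][0]
        rev = search_reads(
            [SequenceRead("r", reverse_complement(frag))], db)["r"][0]
        assert rev.raw_score == fwd.raw_score
        assert rev.frame == -fwd.frame
        # reverse-strand hits report q_start > q_end on the forward read
        assert rev.q_start > rev.q_end
        assert (rev.q_start, rev.q_end) == (fwd.q_end, fwd.q_start)

    def test_coordinates_lie_within_the_read(self, planted):
        refs, _source, frag = planted
        db = ProteinDatabase(refs.curated)
        for shift in (0, 1, 2):
            read = SequenceRead("s", frag[shift:])
            hit = search_reads([read], db)["s"][0]
            assert hit.frame in (1, 2, 3)
            lo, hi = sorted((hit.q_start, hit.q_end))
            assert 1 <= lo <= hi <= len(read.seq)
            # span length is a whole number of codons
            assert (hi - lo + 1) % 3 == 0

    def test_random_read_yields_no_hits(self, planted):
        refs, _, _ = planted
        rng = np.random.default_rng(10)
        read = SequenceRead("rnd", "".join(rng.choice(list("ACGT"), 300)))
        hits = search_reads([read], ProteinDatabase(refs.curated))
        assert "rnd" not in hits

    def test_prefilter_reproduces_exhaustive_hits_on_planted_reads(
            self, planted):
        refs, _source, frag = planted
        db = ProteinDatabase(refs.curated)
        read = SequenceRead("p", frag)
        full = search_reads([read], db)["p"]
        fast = search_reads([read], db, prefilter=True)["p"]
        assert [(h.subject_id, h.raw_score) for h in full] == \
            [(h.subject_id, h.raw_score) for h in fast]

    def test_evalue_calibration_on_shuffled_reads(self, planted):
        refs, _, _ = planted
        rng = np.random.default_rng(11)
        e0 = 1e-2
        n_reads = 150
        reads = [
            SequenceRead(f"n{i}", "".join(rng.choice(list("ACGT"), 250)))
            for i in range(n_reads)
        ]
        hits = search_reads(reads, ProteinDatabase(refs.curated),
                            evalue_cutoff=e0)
        n_sig = sum(len(v) for v in hits.values())
        assert n_sig <= 10 * e0 * n_reads

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            ProteinDatabase([])
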