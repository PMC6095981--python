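"""Barcode filtering pipeline: quality, merging, barcode extraction,
k-mer isotype calling, consensus building and error estimation."""

import numpy as np
import pytest

from bcrnet.germline import revcomp
from bcrnet.preprocess import (BarcodeGroup, ConsensusBCR, MergedRead,
                               ReadPair, assign_isotype, build_consensus,
                               collapse_barcode_groups,
                               estimate_precorrection_error, extract_barcode,
                               frame_and_ig_filter, median_phred, merge_pair,
                               quality_filter)

Q30 = chr(33 + 30)
Q35 = chr(33 + 35)
Q40 = chr(33 + 40)


def _pair(seq1, q1, seq2, q2):
    return ReadPair("r", seq1, q1, seq2, q2)


class TestQualityFilter:
    def test_high_quality_pair_retained(self):
        p = _pair("ACGT" * 10, Q40 * 40, "ACGT" * 10, Q40 * 40)
        kept, dropped = quality_filter([p])
        assert kept == [p] and dropped == 0

    def test_q30_mate_discards_pair(self):
        p = _pair("ACGT" * 10, Q40 * 40, "ACGT" * 10, Q30 * 40)
        kept, dropped = quality_filter([p])
        assert kept == [] and dropped == 1

    def test_even_length_median_is_midpoint_mean(self):
        # half Q30 / half Q40: median = 35 > 34 -> retained
        qual = Q30 * 20 + Q40 * 20
        assert median_phred(qual) == 35
        p = _pair("A" * 40, qual, "A" * 40, qual)
        kept, _ = quality_filter([p])
        assert kept == [p]


class TestMergePairs:
    def _mates(self, amplicon, read_len):
        return amplicon[:read_len], revcomp(amplicon[-read_len:])

    def test_sixty_bp_exact_overlap_merges(self):
        rng = np.random.default_rng(0)
        amp = "".join("ACGT"[i] for i in rng.integers(0, 4, size=140))
        s1, s2 = self._mates(amp, 100)   # overlap 60
        m = merge_pair(_pair(s1, Q40 * 100, s2, Q40 * 100))
        assert m is not None
        assert m.sequence == amp
        assert len(m.sequence) == 100 + 100 - 60

    def test_fifty_bp_overlap_discarded(self):
        # exactly 50 bp is not strictly greater than 50
        rng = np.random.default_rng(1)
        amp = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
        s1, s2 = self._mates(amp, 100)   # overlap 50
        assert merge_pair(_pair(s1, Q40 * 100, s2, Q40 * 100)) is None

    def test_overlap_with_one_mismatch_discarded(self):
        rng = np.random.default_rng(2)
        amp = "".join("ACGT"[i] for i in rng.integers(0, 4, size=140))
        s1, s2 = self._mates(amp, 100)
        mid = list(s2)
        pos = 70  # rc position 29: inside the 60 bp overlap
        mid[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mid[pos]]
        assert merge_pair(_pair(s1, Q40 * 100, "".join(mid), Q40 * 100)) is None


class TestExtractBarcode:
    BARCODE = "AAAATCCCCTGGGGT"

    def test_forward_strand(self):
        seq = self.BARCODE + "ACGTACGTACGTACGTACGT"
        hit = extract_barcode(MergedRead(seq, Q40 * len(seq)))
        assert hit == (self.BARCODE, "ACGTACGTACGTACGTACGT")

    def test_reverse_strand_gives_same_barcode(self):
        payload = "ACGAACGGACGCACGAACGG"  # no T: cannot fake the pattern
        seq = self.BARCODE + payload
        hit = extract_barcode(MergedRead(revcomp(seq), Q40 * len(seq)))
        assert hit == (self.BARCODE, payload)

    def test_broken_conserved_t_rejected(self):
        # C at 1-based position 10 breaks the conserved-base check
        bad = "AAAATAAAACAAAAT" + "GGGGGGGGGGGGGGG"  # rc prefix lacks T's too
        assert extract_barcode(MergedRead(bad, Q40 * len(bad))) is None


class TestAssignIsotype:
    def test_exact_constant_prefix_scores_41(self, germline):
        read = "ACGT" * 20 + germline.c("IGHG1").seq[:50]
        iso, score = assign_isotype(read, germline.c_genes)
        assert iso == "IGHG1" and score == 41

    def test_no_shared_kmer_is_ambiguous(self):
        from bcrnet.germline import CGene
        genes = [CGene("IGHM", "A" * 50), CGene("IGHG1", "C" * 50)]
        iso, score = assign_isotype("G" * 60, genes)
        assert iso is None and score == 0

    def test_single_central_mismatch_verified_by_enumeration(self, germline):
        prefix = germline.c("IGHA1").seq[:50]
        mutated = prefix[:25] + {"A": "C", "C": "A", "G": "T", "T": "G"}[prefix[25]] + prefix[26:]
        read = "ACGT" * 20 + mutated
        iso, score = assign_isotype(read, germline.c_genes)
        assert iso == "IGHA1"
        # independent oracle: direct 10-mer set intersection
        km = lambda s: {s[i:i + 10] for i in range(len(s) - 9)}
        expected = len(km(mutated) & km(prefix))
        assert score == expected
        assert expected == 41 - 10  # a central mismatch destroys 10 k-mers


class TestConsensus:
    def test_identical_reads(self):
        g = build_consensus(["ACGTACGT"] * 3)
        assert g.consensus == "ACGTACGT"
        assert g.certainty == 1.0
        assert g.read_count == 3

    def test_two_reads_25_of_100_differ_retained(self):
        rng = np.random.default_rng(3)
        r1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        pos = rng.choice(100, size=25, replace=False)
        r2 = list(r1)
        for p in pos:
            r2[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r2[p]]
        g = build_consensus([r1, "".join(r2)])
        assert g.certainty == pytest.approx((75 * 1.0 + 25 * 0.5) / 100)
        assert g.certainty > 0.8

    def test_two_reads_45_of_100_differ_discarded(self):
        rng = np.random.default_rng(4)
        r1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        pos = rng.choice(100, size=45, replace=False)
        r2 = list(r1)
        for p in pos:
            r2[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r2[p]]
        g = build_consensus([r1, "".join(r2)])
        assert g.certainty == pytest.approx(0.775)
        assert g.certainty <= 0.8

    def test_tie_breaks_lexicographically(self):
        g = build_consensus(["AAAA", "AAAC"])
        assert g.consensus == "AAAA"  # A < C at the tied position
        g = build_consensus(["AAAT", "AAAG"])
        assert g.consensus == "AAAG"  # G < T

    def test_modal_length_only(self):
        g = build_consensus(["ACGT", "ACGT", "ACGTA"])
        assert g.consensus == "ACGT"
        assert g.n_length_dropped == 1

    def test_empty_group_is_contract_violation(self):
        with pytest.raises(ValueError):
            build_consensus([])

    def test_certainty_threshold_monotonicity(self, germline):
        """Lowering the certainty threshold never decreases the number
        of retained groups."""
        rng = np.random.default_rng(5)
        tagged = []
        seen = set()
        for i in range(30):
            base = "".join("ACGT"[j] for j in rng.integers(0, 4, size=80))
            base += germline.c("IGHM").seq[:50]
            while True:
                ns = "".join("ACGT"[j] for j in rng.integers(0, 4, size=12))
                bc = ns[:4] + "T" + ns[4:8] + "T" + ns[8:] + "T"
                if bc not in seen:
                    seen.add(bc)
                    break
            for _ in range(3):
                noisy = list(base)
                for p in rng.choice(len(base), size=rng.integers(0, 30),
                                    replace=False):
                    noisy[p] = "ACGT"[rng.integers(4)]
                tagged.append((bc, "".join(noisy)))
        prev = None
        for thr in (0.95, 0.9, 0.8, 0.5, 0.0):
            recs, _, _ = collapse_barcode_groups(tagged, germline.c_genes,
                                                 certainty_threshold=thr)
            if prev is not None:
                assert len(recs) >= prev
            prev = len(recs)


class TestErrorEstimate:
    def test_noiseless_groups_give_zero(self):
        g = build_consensus(["ACGT" * 25] * 4)
        rate, mm, bases = estimate_precorrection_error([g])
        assert rate == 0.0 and mm == 0

    def test_hand_computed_two_read_group(self):
        # 2 reads, length 100, 2 mismatches -> 2 / 200 member bases
        r1 = "A" * 100
        r2 = "A" * 98 + "CC"
        g = build_consensus([r1, r2])
        rate, mm, bases = estimate_precorrection_error([g])
        assert bases == 200
        assert rate == pytest.approx(2 / 200)

    def test_no_multiread_group_returns_none(self):
        g = build_consensus(["ACGT"])
        assert estimate_precorrection_error([g]) is None


class TestFrameAndIgFilter:
    def _record(self, seq):
        return ConsensusBCR(barcode="B", sequence=seq, isotype="IGHM",
                            duplicate_count=1, certainty=1.0)

    def test_unmutated_molecule_retained(self, germline, small_repertoire):
        from bcrnet.simulate import cell_sequence
        cells, _ = small_repertoire
        cell = next(c for c in cells if not c.shm_positions)
        recs, dropped = frame_and_ig_filter(
            [self._record(cell_sequence(cell, germline))], germline)
        assert len(recs) == 1

    def test_random_sequence_removed(self, germline):
        rng = np.random.default_rng(6)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=360))
        recs, dropped = frame_and_ig_filter([self._record(junk)], germline)
        assert recs == [] and dropped["no_vj"] == 1

    def test_planted_stop_codon_removed(self, germline, small_repertoire):
        from bcrnet.simulate import cell_sequence
        cells, _ = small_repertoire
        cell = next(c for c in cells if not c.shm_positions)
        seq = cell_sequence(cell, germline)
        broken = seq[:30] + "TAA" + seq[33:]  # in-frame premature stop
        recs, dropped = frame_and_ig_filter([self._record(broken)], germline)
        assert recs == [] and dropped["stop_codon"] == 1
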