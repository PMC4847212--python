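"""Tests for duplicated-kmer collapse, alignment, classification and BED I/O."""

import math

import pytest

from itdfinder import sim
from itdfinder.annotate import (ITDCall, UndefinedAlleleFraction, align_collapsed,
                                allele_fraction, candidate_kmer_pairs,
                                classify_call, collapse_duplication,
                                count_junction_support, find_duplicated_kmer,
                                left_align, merge_calls, read_calls_bed,
                                rna_validate, write_calls_bed)
from itdfinder.assemble import Contig
from itdfinder.util import revcomp


class TestFindDuplicatedKmer:
    def test_leftmost_pair(self):
        assert find_duplicated_kmer("ACGTGACGTGTT", 3, 4, 10) == (0, 5)

    def test_all_distinct(self):
        assert find_duplicated_kmer("ACGTTGCAAC", 3, 4, 10) is None

    def test_range_exclusion(self):
        # repeats at distance 3 only; r_min=4 excludes them
        assert find_duplicated_kmer("ACGACGTT", 3, 4, 10) is None

    def test_candidate_pairs_sorted(self):
        pairs = candidate_kmer_pairs("ACGTGACGTGTT", 3, 4, 10)
        assert pairs[0] == (0, 5)
        assert pairs == sorted(pairs)


class TestCollapse:
    def test_hand_example(self):
        assert collapse_duplication("ACGTGACGTGTT", 0, 5) == "ACGTGTT"

    def test_degenerate_forbidden(self):
        with pytest.raises(ValueError):
            collapse_duplication("ACGT", 2, 2)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            collapse_duplication("ACGT", 1, 9)

    def test_collapsed_matches_reference(self):
        ref = sim.make_reference(400, 3)
        alt = sim.implant_itd(ref, 100, 30)
        contig = alt[60 : 200]
        p1, p2 = find_duplicated_kmer(contig, 10, 15, 61)
        collapsed = collapse_duplication(contig, p1, p2)
        assert collapsed in ref


class TestAlignCollapsed:
    def test_exact_unique_substring(self):
        ref = {"chr1": sim.make_reference(2000, 5)}
        query = ref["chr1"][400:460]
        hit = align_collapsed(query, ref)
        assert hit is not None
        assert (hit.ref_start, hit.ref_end) == (400, 460)
        assert hit.identity == pytest.approx(1.0)
        assert hit.strand == "+"

    def test_minus_strand(self):
        ref = {"chr1": sim.make_reference(2000, 5)}
        query = revcomp(ref["chr1"][400:460])
        hit = align_collapsed(query, ref)
        assert hit is not None and hit.strand == "-"
        assert (hit.ref_start, hit.ref_end) == (400, 460)

    def test_duplicated_reference_fails_specificity(self):
        base = sim.make_reference(800, 6)
        seg = base[100:160]
        ref = {"chr1": base + sim.make_reference(50, 7) + seg}
        assert align_collapsed(seg, ref) is None

    def test_random_query_absent(self):
        ref = {"chr1": sim.make_reference(2000, 8)}
        query = sim.make_reference(60, 909)
        assert align_collapsed(query, ref) is None

    def test_query_interval_mapping(self):
        ref = {"chr1": sim.make_reference(2000, 5)}
        query = ref["chr1"][400:460]
        hit = align_collapsed(query, ref)
        assert hit.map_query_interval(10, 25) == (410, 425)


class TestClassifyCall:
    def _hit(self, ref, query):
        return align_collapsed(query, ref)

    def test_coding_itd_with_gene(self):
        ref = {"chr1": sim.make_reference(2000, 5)}
        hit = self._hit(ref, ref["chr1"][400:460])
        cls, start, end, gene = classify_call(
            hit, 10, 20, targets=[("chr1", 380, 500, "FLT3_e14")])
        assert cls == "coding_ITD" and gene == "FLT3_e14"
        assert (start, end) == (410, 430)

    def test_off_target_when_interval_missing(self):
        ref = {"chr1": sim.make_reference(2000, 5)}
        hit = self._hit(ref, ref["chr1"][400:460])
        cls, *_ = classify_call(hit, 10, 20,
                                targets=[("chr1", 1500, 1600, "OTHER")])
        assert cls == "off_target"

    def test_intronic_without_targets(self):
        ref = {"chr1": sim.make_reference(2000, 5)}
        hit = self._hit(ref, ref["chr1"][400:460])
        cls, *_ = classify_call(hit, 10, 20, targets=None)
        assert cls == "intronic"

    def test_reference_gap_means_non_insertion(self):
        # query skips 6 reference bases: contiguity (<= 2 bp) violated
        base = sim.make_reference(2000, 9)
        query = base[300:350] + base[356:406]
        hit = self._hit({"chr1": base}, query)
        assert hit is not None and hit.max_ref_gap == 6
        cls, *_ = classify_call(hit, 5, 20,
                                targets=[("chr1", 200, 500, "G")])
        assert cls == "non_insertion"


class TestLeftAlign:
    def test_shifts_left_over_matching_base(self):
        #        0123456789
        ref = "GGAACGTAAC"
        # [3, 7) = ACGT; ref[2]=A == ref[6]=T? no -> stays
        assert left_align(ref, 3, 7) == (3, 7)
        # [4, 8): ref[3]=A == ref[7]=A -> shift to [3, 7)
        assert left_align(ref, 4, 8) == (3, 7)

    def test_equivalence_of_representations(self):
        ref = sim.make_reference(200, 11)
        for start in (50, 51, 52):
            s, e = left_align(ref, start, start + 20)
            assert sim.implant_itd(ref, s, 20) == \
                sim.implant_itd(ref, *_norm(ref, start, 20))


def _norm(ref, start, length):
    s, e = left_align(ref, start, start + length)
    return s, e - s


class TestAlleleFraction:
    def test_zero(self):
        assert allele_fraction(0, 100) == 0.0

    def test_ratio(self):
        assert allele_fraction(30, 150) == pytest.approx(0.2)

    def test_undefined(self):
        with pytest.raises(UndefinedAlleleFraction):
            allele_fraction(0, 0)

    def test_support_exceeds_depth(self):
        with pytest.raises(ValueError):
            allele_fraction(10, 5)


class TestJunctionSupport:
    def test_counts_spanning_reads_only(self):
        contig = Contig("c0", "A" * 100, frozenset({"a", "b", "c"}), 30,
                        layout={"a": (0, "+"), "b": (40, "+"), "c": (48, "+")})
        lengths = {"a": 75, "b": 20, "c": 75}
        # junction at 50: a spans 0-75 (yes), b 40-60 (yes), c 48-123 (no: starts at 48 > 45)
        assert count_junction_support(contig, 50, lengths) == 2


class TestRnaValidate:
    def _contig(self):
        ref = sim.make_reference(300, 21)
        alt = sim.implant_itd(ref, 140, 30)
        seq = alt[100:240]
        return seq, 70  # second copy starts at alt 170 -> offset 70

    def test_validated_with_exact_reads(self):
        seq, j = self._contig()
        reads = [seq[j - 30 : j + 30] for _ in range(12)]
        count, ok = rna_validate(seq, j, reads)
        assert count == 12 and ok

    def test_low_identity_not_validated(self):
        seq, j = self._contig()
        read = list(seq[j - 30 : j + 30])
        for p in range(0, 60, 18):  # ~5% mismatches -> identity ~0.95
            read[p] = "A" if read[p] != "A" else "C"
        reads = ["".join(read) for _ in range(12)]
        count, ok = rna_validate(seq, j, reads)
        assert not ok

    def test_expression_floor(self):
        seq, j = self._contig()
        reads = [seq[j - 30 : j + 30] for _ in range(9)]
        count, ok = rna_validate(seq, j, reads, min_reads=10)
        assert count == 9 and not ok


class TestMergeCalls:
    def _call(self, start=100, dup=20, support=10, contig="c0"):
        return ITDCall("chr1", start, start + dup, dup, "coding_ITD", "G",
                       support, 100, support / 100, contig, 50)

    def test_identical_events_merge_keep_max_support(self):
        merged = merge_calls([self._call(support=10, contig="bin20c0"),
                              self._call(support=25, contig="bin21c0")])
        assert len(merged) == 1 and merged[0].support_reads == 25

    def test_biallelic_distinct_lengths_kept(self):
        merged = merge_calls([self._call(dup=45), self._call(dup=51)])
        assert len(merged) == 2

    def test_empty(self):
        assert merge_calls([]) == []

    def test_sorted_by_locus(self):
        merged = merge_calls([self._call(start=500), self._call(start=100)])
        assert [c.start for c in merged] == [100, 500]


class TestBedRoundTrip:
    def test_lossless_bed_fields(self, tmp_path):
        calls = [
            ITDCall("chr1", 100, 130, 30, "coding_ITD", "FLT3", 40, 107,
                    40 / 107, "bin30c0", 65),
            ITDCall("chr2", 5, 25, 20, "intronic", None, 3, 0, float("nan"),
                    "bin20c1", 12),
        ]
        path = tmp_path / "calls.bed"
        write_calls_bed(str(path), calls, params_echo={"p_kmer": 10})
        back = read_calls_bed(str(path))
        for orig, rt in zip(calls, back):
            assert (orig.ref_name, orig.start, orig.end, orig.dup_length,
                    orig.gene, orig.support_reads, orig.classification,
                    orig.contig_id, orig.junction_offset) == \
                   (rt.ref_name, rt.start, rt.end, rt.dup_length, rt.gene,
                    rt.support_reads, rt.classification, rt.contig_id,
                    rt.junction_offset)
            assert (math.isnan(orig.allele_fraction) and
                    math.isnan(rt.allele_fraction)) or \
                orig.allele_fraction == rt.allele_fraction
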