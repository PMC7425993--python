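import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import dp_semiglobal
from conftest import make_individual
from vntrkit import simulate
from vntrkit.locus import build_allele_sequence, reverse_complement
from vntrkit.span import (
    SpanConfig,
    approx_contains,
    call_read,
    genotype_sample,
    max_fully_spannable,
    scan_six_plus,
)

CFG = SpanConfig()


def spanning_read(locus, c, left=6, right=6, pad_to=150, pad_char=None):
    """An exact read containing a full-span pattern, padded with real flank."""
    need = 150 - (left + c * 33 + right)
    extra_left = need // 2
    extra_right = need - extra_left
    return build_allele_sequence(locus, c, left + extra_left, right + extra_right).seq


class TestMaxFullySpannable:
    @pytest.mark.parametrize("read_len,expected", [(150, 4), (100, 2), (300, 8)])
    def test_known_values(self, locus, read_len, expected):
        assert max_fully_spannable(read_len, locus, CFG) == expected

    def test_too_short_rejected(self, locus):
        with pytest.raises(ValueError):
            max_fully_spannable(12, locus, CFG)


class TestApproxContains:
    def test_exact_substring(self):
        assert approx_contains("AAACGTACGTAAA", "CGTACGT", 2) == 0

    def test_reverse_complement_found(self):
        read = reverse_complement("AAACGTACGTAAA")
        assert approx_contains(read, "CGTACGT", 2) == 0

    def test_one_substitution(self, locus):
        pattern = locus.unit_seq
        read = "ACGT" + pattern[:10] + "T" + pattern[11:] + "ACGT"
        if pattern[10] == "T":  # ensure it is a real substitution
            read = "ACGT" + pattern[:10] + "A" + pattern[11:] + "ACGT"
        assert approx_contains(read, pattern, 2) == 1

    def test_three_substitutions_rejected(self, locus):
        pattern = locus.unit_seq
        mutated = list(pattern)
        for pos in (5, 15, 25):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        read = "ACGTAC" + "".join(mutated) + "GTACGT"
        # confirm with the DP oracle that the planned distance really is 3
        assert min(dp_semiglobal(pattern, read),
                   dp_semiglobal(pattern, reverse_complement(read))) == 3
        assert approx_contains(read, pattern, 2) is None

    def test_hamming_mode(self):
        # insertion: cheap for edit distance, expensive for hamming
        read = "CCATATGATATCC"
        assert approx_contains(read, "ATATATAT", 2, mode="edit") == 1
        assert approx_contains(read, "ATATATAT", 2, mode="hamming") is None

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_dp_oracle(self, data):
        rng_text = data.draw(st.text(alphabet="ACGT", min_size=10, max_size=60))
        pattern = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=15))
        expected = min(
            dp_semiglobal(pattern, rng_text),
            dp_semiglobal(pattern, reverse_complement(rng_text)),
        )
        got = approx_contains(rng_text, pattern, 2)
        if expected <= 2:
            assert got == expected
        else:
            assert got is None


class TestCallRead:
    def test_exact_full_span(self, locus):
        read = spanning_read(locus, 2)
        call = call_read(read, locus, CFG)
        assert call is not None and call.allele == 2 and call.kind == "full_span"

    @pytest.mark.parametrize("c", [1, 2, 3, 4])
    def test_all_spannable_alleles(self, locus, c):
        call = call_read(spanning_read(locus, c), locus, CFG)
        assert call.allele == c

    def test_partial_five_copy_interior(self, locus):
        # 150 bp drawn inside a 5-copy array: 4 full units + 18 nt of a fifth
        array = locus.unit_seq * 5
        read = array[:150]
        call = call_read(read, locus, CFG)
        assert call is not None and call.allele == 5 and call.kind == "partial"

    def test_partial_with_left_anchor(self, locus):
        # left flank anchor + 4 units + 12 nt of a fifth copy
        seq = build_allele_sequence(locus, 5, 6, 0).seq[:150]
        call = call_read(seq, locus, CFG)
        assert call is not None and call.allele == 5

    def test_three_units_without_flanks_is_nothing(self, locus):
        # 3 full units with < 6 nt beyond on either side and no flank
        array = locus.unit_seq * 5
        read = array[33 - 5 : 33 + 99 + 5]  # 5 nt of unit 1, units 2-4, 5 nt of unit 5
        assert len(read) == 109
        assert call_read(read, locus, CFG) is None

    def test_four_copy_full_span_not_partial(self, locus):
        # read fully spanning a 4-copy allele must be called 4, never 5
        read = build_allele_sequence(locus, 4, 9, 9).seq
        call = call_read(read, locus, CFG)
        assert call.allele == 4 and call.kind == "full_span"

    def test_flank_only_read_is_nothing(self, locus):
        read = locus.left_flank_seq[:150]
        assert call_read(read, locus, CFG) is None

    def test_strand_symmetry(self, locus):
        for c in (1, 3, 4):
            read = spanning_read(locus, c)
            fwd = call_read(read, locus, CFG)
            rev = call_read(reverse_complement(read), locus, CFG)
            assert fwd.allele == rev.allele

    def test_mutual_exclusivity_of_patterns(self, locus):
        # no read can be full-span evidence for two c values: verify the
        # inter-pattern distances exceed the tolerance by a wide margin
        left = locus.left_flank_seq[-6:]
        right = locus.right_flank_seq[:6]
        patterns = [left + locus.unit_seq * c + right for c in range(1, 5)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert dp_semiglobal(patterns[i], patterns[j]) > CFG.max_edit


class TestGenotypeSample:
    def _reads_for(self, locus, allele_counts):
        reads = []
        for allele, n in allele_counts.items():
            reads.extend([spanning_read(locus, allele)] * n)
        return reads

    def test_low_count_allele_dropped(self, locus):
        g = genotype_sample(self._reads_for(locus, {2: 5, 3: 7, 4: 1}), locus, CFG)
        assert g.status == "called" and g.alleles == (2, 3)
        assert g.raw_evidence == {2: 5, 3: 7, 4: 1}

    def test_multiallelic_excluded(self, locus):
        # evidence {2: 3, 3: 3, 5: 2} -> three surviving alleles
        reads = self._reads_for(locus, {2: 3, 3: 3})
        reads += [(locus.unit_seq * 5)[:150]] * 2
        g = genotype_sample(reads, locus, CFG)
        assert g.status == "excluded_multiallelic"

    def test_no_evidence_is_no_call(self, locus):
        g = genotype_sample([locus.left_flank_seq[:150]], locus, CFG)
        assert g.status == "no_call" and g.alleles == ()

    def test_single_allele_flag_and_diploid_convention(self, locus):
        g = genotype_sample(self._reads_for(locus, {3: 4}), locus, CFG)
        assert g.status == "called" and g.single_allele
        assert g.as_diploid() == (3, 3) and g.diploid_mean == 3.0

    def test_simulated_individual_recovered(self, locus, read_cfg):
        ind = make_individual(2, 5)
        reads = simulate.simulate_reads(ind, locus, read_cfg, rng=7)
        g = genotype_sample((r.seq for r in reads), locus, CFG, "s")
        assert g.status == "called" and g.alleles == (2, 5)

    def test_strand_symmetry_full_sample(self, locus, read_cfg):
        ind = make_individual(3, 4)
        reads = [r.seq for r in simulate.simulate_reads(ind, locus, read_cfg, rng=8)]
        a = genotype_sample(reads, locus, CFG, "s")
        b = genotype_sample([reverse_complement(r) for r in reads], locus, CFG, "s")
        assert a.alleles == b.alleles and a.read_counts == b.read_counts


class TestScanSixPlus:
    def test_constructed_six_copy_read_flagged(self, locus):
        unit = locus.unit_seq
        read = unit[-9:] + unit * 4 + unit[:9]
        assert len(read) == 150
        assert scan_six_plus([read], locus, CFG) == ["read:0"]

    def test_interior_six_copy_reads_flagged(self, locus):
        array6 = locus.unit_seq * 6
        reads = [array6[s : s + 150] for s in range(0, 48)]
        flagged = scan_six_plus(reads, locus, CFG)
        # exactly the windows leaving >= 6 nt of partial unit at both ends
        # (left partial in [6, 12] so the right partial is also >= 6) qualify
        expected = [f"read:{s}" for s in range(0, 48) if 6 <= 33 - (s % 33) <= 12]
        assert flagged == expected and len(flagged) == 7

    def test_five_copy_window_slide_never_flagged(self, locus):
        # every 150-nt window over the full 5-copy haplotype
        hap = build_allele_sequence(locus, 5, 200, 200).seq
        reads = [hap[s : s + 150] for s in range(len(hap) - 149)]
        assert scan_six_plus(reads, locus, CFG) == []

    def test_reference_read_not_flagged(self, locus):
        read = build_allele_sequence(locus, 3, 30, 21).seq
        assert scan_six_plus([read], locus, CFG) == []

    def test_short_read_length_rejected(self, locus):
        cfg = SpanConfig(read_length=120)
        with pytest.raises(ValueError, match="required for the scan"):
            scan_six_plus([], locus, cfg)

    def test_named_reads_reported_by_name(self, locus):
        unit = locus.unit_seq
        read = simulate.SimulatedRead(
            name="r1", seq=unit[-9:] + unit * 4 + unit[:9], hap=1, start=0, strand="+"
        )
        assert scan_six_plus([read], locus, CFG) == ["r1"]


class TestSpanConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_edit": -1},
            {"anchor_len": 0},
            {"read_length": 10},
            {"distance_mode": "foo"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpanConfig(**kwargs)
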