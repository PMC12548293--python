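"""Somatic filtering rules, SBS96/ID83 classification and matrix building."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msikit.somatic import (
    ID83_CLASSES,
    SBS96_CLASSES,
    SomaticVariant,
    build_matrices,
    classify_id83,
    classify_sbs96,
    filter_somatic,
    left_align,
    normalize_profile,
)

from oracles import oracle_filter, random_sequence

_COMP = str.maketrans("ACGT", "TGCA")


def _variant(**kw):
    base = dict(
        chrom="1", pos=100, ref="C", alt="T", sample_id="s1",
        tumor_depth=30, normal_depth=30, tumor_alt_reads=10, normal_alt_reads=0,
        in_dbsnp=False, shared_tumor_count=1,
    )
    base.update(kw)
    return SomaticVariant(**base)


def _random_variants(n, seed):
    rng = np.random.default_rng(seed)
    chroms = ["1", "7", "chr12", "X", "Y", "M", "chrX"]
    out = []
    for i in range(n):
        td = int(rng.integers(0, 40))
        nd = int(rng.integers(0, 40))
        out.append(
            _variant(
                chrom=chroms[int(rng.integers(len(chroms)))],
                pos=100 + i,
                tumor_depth=td,
                normal_depth=nd,
                tumor_alt_reads=int(rng.integers(0, td + 1)),
                normal_alt_reads=int(rng.integers(0, min(nd, 3) + 1)),
                in_dbsnp=bool(rng.random() < 0.2),
                shared_tumor_count=int(rng.integers(1, 4)),
            )
        )
    return out


class TestFilter:
    @pytest.mark.parametrize(
        "override, kept",
        [
            (dict(), True),
            (dict(tumor_depth=9, tumor_alt_reads=3), False),
            (dict(normal_depth=9), False),
            (dict(tumor_alt_reads=2), False),
            (dict(normal_alt_reads=1), False),
            (dict(chrom="X"), False),
            (dict(chrom="chrM"), False),
            (dict(in_dbsnp=True), False),
            (dict(shared_tumor_count=2), False),
            (dict(tumor_depth=10, normal_depth=10, tumor_alt_reads=3), True),
        ],
    )
    def test_each_rule(self, override, kept):
        retained, _, _ = filter_somatic([_variant(**override)])
        assert bool(retained) is kept

    def test_thousand_random_variants_match_brute_force_oracle(self):
        variants = _random_variants(1_000, seed=5)
        retained, tally, rejected = filter_somatic(variants)
        assert {id(v) for v in retained} == oracle_filter(variants)
        # partition and tally consistency
        assert len(retained) + len(rejected) == len(variants)
        assert sum(tally.values()) == len(rejected)

    def test_rules_commute(self):
        """The retained set does not depend on evaluation order."""
        variants = _random_variants(300, seed=9)
        retained, _, _ = filter_somatic(variants)
        retained_rev, _, _ = filter_somatic(list(reversed(variants)))
        assert {id(v) for v in retained} == {id(v) for v in retained_rev}


class TestSbs96:
    def test_purine_context_is_reverse_complemented(self):
        # G>A with 5' T and 3' T reads C>T at ACA on the pyrimidine strand
        assert classify_sbs96("G", "A", "T", "T") == "A[C>T]A"

    def test_pyrimidine_identity(self):
        assert classify_sbs96("C", "T", "A", "A") == "A[C>T]A"

    def test_exhaustive_two_to_one_mapping(self):
        tally = Counter(
            classify_sbs96(ref, alt, f, t)
            for ref in "ACGT"
            for alt in "ACGT"
            if alt != ref
            for f in "ACGT"
            for t in "ACGT"
        )
        assert set(tally) == set(SBS96_CLASSES)
        assert all(count == 2 for count in tally.values())

    def test_ambiguous_context_is_unclassifiable(self):
        with pytest.raises(ValueError):
            classify_sbs96("C", "T", "N", "A")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.sampled_from("ACGT"), st.sampled_from("ACGT"),
        st.sampled_from("ACGT"), st.sampled_from("ACGT"),
    )
    def test_strand_invariance(self, ref, alt, five, three):
        """Complementing ref/alt/context leaves the channel unchanged."""
        if ref == alt:
            return
        fwd = classify_sbs96(ref, alt, five, three)
        rev = classify_sbs96(
            ref.translate(_COMP), alt.translate(_COMP),
            three.translate(_COMP), five.translate(_COMP),
        )
        assert fwd == rev


class TestId83:
    def test_t_homopolymer_deletion_long(self):
        seq = "GCGT" + "T" * 8 + "GACG"
        assert classify_id83(4, "TT", "T", seq) == "1:Del:T:5"

    def test_a_deletion_maps_to_t_channel(self):
        seq = "GCG" + "A" * 3 + "GCG"
        assert classify_id83(3, "GA", "G", seq) == "1:Del:T:2"

    def test_isolated_c_deletion(self):
        seq = "GATAGCATTAG"
        assert classify_id83(5, "GC", "G", seq) == "1:Del:C:0"

    def test_ca_unit_deletion_from_seven_copies(self):
        seq = "GGCT" + "CA" * 7 + "GGTC"
        assert classify_id83(4, "TCA", "T", seq) == "2:Del:R:5"

    def test_microhomology_deletion(self):
        # TAG deleted; right flank begins TA (2-bp homology), no tandem copy
        seq = "GCCATAGTACCGG"
        assert classify_id83(4, "ATAG", "A", seq) == "3:Del:M:2"

    def test_insertion_into_homopolymer(self):
        seq = "GGCT" + "AAAA" + "GCGC"
        assert classify_id83(4, "T", "TA", seq) == "1:Ins:T:4"

    def test_novel_insertion_has_zero_copies(self):
        seq = "GGCTGCGC"
        assert classify_id83(4, "T", "TCA", seq) == "2:Ins:R:0"

    def test_channel_count_and_uniqueness(self):
        assert len(ID83_CLASSES) == 83
        assert len(set(ID83_CLASSES)) == 83

    def test_right_shifted_representation_is_normalized(self):
        """Equivalent right-shifted indels classify identically after left-alignment."""
        seq = "GCG" + "A" * 6 + "TCG"
        left = classify_id83(3, "GA", "G", seq)  # leftmost representation
        right = classify_id83(8, "AA", "A", seq)  # same event, shifted right
        assert left == right == "1:Del:T:5"

    def test_left_align_homopolymer_deletion(self):
        seq = "GAAAAT"
        pos, ref, alt = left_align(4, "AA", "A", seq)
        assert (pos, ref, alt) == (1, "GA", "G")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 5_000))
    def test_random_deletions_classify_and_shift_invariantly(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(300, seed=seed)
        start = int(rng.integers(10, 280))
        size = int(rng.integers(1, 5))
        deleted = seq[start : start + size]
        label = classify_id83(start, seq[start - 1] + deleted, seq[start - 1], seq)
        assert label in ID83_CLASSES
        # re-express shifted one base right when the sequence allows it
        if seq[start] == seq[start + size]:
            shifted = classify_id83(start + 1, seq[start] + seq[start + 1 : start + size + 1],
                                    seq[start], seq)
            assert shifted == label


class TestMatrices:
    def test_single_snv_vector(self):
        ref = {"1": "GGACATT"}
        v = _variant(chrom="1", pos=4, ref="C", alt="T")
        counts = build_matrices([v], ref)
        assert counts.sbs96.loc["A[C>T]A", "s1"] == 1
        assert counts.sbs96["s1"].sum() == 1
        assert counts.sbs6.loc["C>T", "s1"] == 1
        assert counts.burden.loc["BS", "s1"] == 1
        assert counts.burden.loc["indel", "s1"] == 0

    def test_empty_input(self):
        counts = build_matrices([], {"1": "ACGT"})
        assert counts.sbs96.empty or counts.sbs96.sum().sum() == 0

    def test_recovered_proportions_within_multinomial_error(self):
        """Drawing 2,000 SNVs from a known channel profile recovers it."""
        rng = np.random.default_rng(11)
        seq = random_sequence(6_000, seed=42)
        ref = {"1": seq}
        # target: C>T at any context 70%, C>A 30% (as available in the sequence)
        positions_c = [i for i in range(2, 5_998) if seq[i] == "C"]
        variants = []
        for j in range(2_000):
            pos0 = positions_c[int(rng.integers(len(positions_c)))]
            alt = "T" if rng.random() < 0.7 else "A"
            variants.append(_variant(chrom="1", pos=pos0 + 1, ref="C", alt=alt,
                                     sample_id="s"))
        counts = build_matrices(variants, ref)
        profile = normalize_profile(counts.sbs6)["s"]
        assert profile["C>T"] == pytest.approx(0.7, abs=3 * np.sqrt(0.7 * 0.3 / 2_000))
        assert profile["C>A"] == pytest.approx(0.3, abs=3 * np.sqrt(0.7 * 0.3 / 2_000))

    def test_normalized_profiles_sum_to_one(self):
        rng = np.random.default_rng(3)
        seq = random_sequence(2_000, seed=3)
        variants = []
        for j in range(50):
            i = int(rng.integers(2, 1_990))
            if seq[i] in "CT":
                alt = [b for b in "ACGT" if b != seq[i]][int(rng.integers(3))]
                variants.append(_variant(chrom="1", pos=i + 1, ref=seq[i], alt=alt))
        counts = build_matrices(variants, {"1": seq})
        norm = normalize_profile(counts.sbs96)
        assert norm["s1"].sum() == pytest.approx(1.0)
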