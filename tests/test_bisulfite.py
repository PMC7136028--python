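import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amplimeth import bisulfite, simulate
from amplimeth.bisulfite import (
    AlignmentScoring,
    AmpliconSNP,
    MethCall,
    ReferenceAmplicon,
    _nw_dp,
    _substitution_scores,
)
from amplimeth.errors import (
    AlleleMissingError,
    EmptyProfileError,
    InputError,
    UndefinedEfficiencyError,
)

from .oracles import brute_force_alignment_score

dna_short = st.text(alphabet="ACGT", min_size=1, max_size=8)


def _score(ref, read, snp=None):
    S = _substitution_scores(ref, read, snp, AlignmentScoring())
    return float(_nw_dp(S, -2.0)[-1, -1])


class TestConvertReference:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ACGT", "ATGT"), ("CCGG", "TTGG"), ("ATTA", "ATTA"), ("cg", "TG")],
    )
    def test_every_c_becomes_t(self, seq, expected):
        assert bisulfite.bisulfite_convert_reference(seq) == expected

    def test_rejects_ambiguity_codes(self):
        with pytest.raises(InputError):
            bisulfite.bisulfite_convert_reference("ACGN")


class TestReferenceAmplicon:
    def test_positions_must_index_cg(self):
        with pytest.raises(InputError):
            ReferenceAmplicon("x", "ACGTACGT", cpg_positions=(0,))

    def test_snp_must_be_a_cpg(self):
        with pytest.raises(InputError):
            ReferenceAmplicon("x", "ACGT", cpg_positions=(1,), snp=AmpliconSNP(offset=0))

    def test_tss_relative_labels(self):
        amp = ReferenceAmplicon("x", "CGAACG", cpg_positions=(0, 4), tss_offset=5)
        assert amp.cpg_labels == ("-5", "-1")

    def test_non_cpg_c_positions_exclude_annotated_sites(self):
        amp = ReferenceAmplicon("x", "CCGAC", cpg_positions=(1,))
        assert list(amp.non_cpg_c_positions) == [0, 4]


class TestAlignment:
    def test_fully_converted_read_aligns_gapless_full_score(self, plain_amplicon):
        read = bisulfite.bisulfite_convert_reference(plain_amplicon.sequence)
        aln = bisulfite.align_clone_to_reference(read, plain_amplicon)
        assert aln.score == len(plain_amplicon.sequence)
        assert np.array_equal(aln.ref_to_read, np.arange(len(read)))

    def test_unconverted_read_also_full_score(self, plain_amplicon):
        # fully methylated + zero conversion: C-C pairs are literal matches
        aln = bisulfite.align_clone_to_reference(plain_amplicon.sequence, plain_amplicon)
        assert aln.score == len(plain_amplicon.sequence)

    def test_ref_t_vs_read_c_is_penalized(self):
        # asymmetry: the reverse substitution is NOT conversion-consistent
        assert _score("T", "C") == -1.0
        assert _score("C", "T") == 1.0

    def test_snp_offset_tolerates_a_c_t_but_not_g(self):
        ref = "ACGA"
        assert _score(ref, "AAGA", snp=1) == 4.0   # A allele
        assert _score(ref, "ATGA", snp=1) == 4.0   # converted C allele
        assert _score(ref, "AGGA", snp=1) == 2.0   # G penalized
    def test_single_deletion_matches_enumeration(self):
        ref, read = "ACGTACGT", "ACGTCGT"
        assert _score(ref, read) == brute_force_alignment_score(ref, read)

    @given(dna_short, dna_short)
    def test_score_equals_brute_force_on_short_strings(self, ref, read):
        assert _score(ref, read) == brute_force_alignment_score(ref, read)

    def test_empty_read_rejected(self, plain_amplicon):
        with pytest.raises(InputError):
            bisulfite.align_clone_to_reference("", plain_amplicon)

    def test_reverse_orientation_recovered(self, plain_amplicon):
        from Bio.Seq import Seq

        converted = bisulfite.bisulfite_convert_reference(plain_amplicon.sequence)
        rc = str(Seq(converted).reverse_complement())
        aln = bisulfite.align_clone_to_reference(rc, plain_amplicon)
        assert aln.orientation == "reverse"
        assert aln.score == len(plain_amplicon.sequence)


class TestConversionEfficiency:
    def _amplicon(self):
        # CCGAC: CpG at 1; non-CpG Cs at 0 and 4
        return ReferenceAmplicon("x", "CCGAC", cpg_positions=(1,))

    def test_all_converted(self):
        amp = self._amplicon()
        aln = bisulfite.align_clone_to_reference("TCGAT", amp, try_reverse=False)
        assert bisulfite.conversion_efficiency(aln, amp) == 1.0

    def test_none_converted(self):
        amp = self._amplicon()
        aln = bisulfite.align_clone_to_reference("CCGAC", amp, try_reverse=False)
        assert bisulfite.conversion_efficiency(aln, amp) == 0.0

    def test_fractional(self):
        amp = self._amplicon()
        aln = bisulfite.align_clone_to_reference("TCGAC", amp, try_reverse=False)
        assert bisulfite.conversion_efficiency(aln, amp) == 0.5

    def test_undefined_when_no_non_cpg_c(self):
        amp = ReferenceAmplicon("x", "ACGTA", cpg_positions=(1,))
        aln = bisulfite.align_clone_to_reference("ACGTA", amp, try_reverse=False)
        with pytest.raises(UndefinedEfficiencyError):
            bisulfite.conversion_efficiency(aln, amp)


class TestCallsAndAlleles:
    def test_all_retained_cpgs_are_methylated(self, plain_amplicon):
        aln = bisulfite.align_clone_to_reference(
            plain_amplicon.sequence, plain_amplicon)
        calls = bisulfite.call_clone_methylation(aln, plain_amplicon)
        assert set(calls.values()) == {MethCall.METHYLATED}

    def test_all_converted_cpgs_are_unmethylated(self, plain_amplicon):
        read = bisulfite.bisulfite_convert_reference(plain_amplicon.sequence)
        aln = bisulfite.align_clone_to_reference(read, plain_amplicon)
        calls = bisulfite.call_clone_methylation(aln, plain_amplicon)
        assert set(calls.values()) == {MethCall.UNMETHYLATED}

    @pytest.mark.parametrize("base, expected",
                             [("A", "A"), ("C", "C"), ("T", "C"), ("G", "unassigned")])
    def test_allele_rule_at_snp(self, snp_amplicon, base, expected):
        seq = list(bisulfite.bisulfite_convert_reference(snp_amplicon.sequence))
        seq[snp_amplicon.snp.offset] = base
        aln = bisulfite.align_clone_to_reference(
            "".join(seq), snp_amplicon, try_reverse=False)
        assert bisulfite.assign_allele(aln, snp_amplicon) == expected

    def test_snp_cpg_missing_on_a_allele(self, snp_amplicon):
        seq = list(snp_amplicon.sequence)  # fully methylated clone
        seq[snp_amplicon.snp.offset] = "A"
        aln = bisulfite.align_clone_to_reference(
            "".join(seq), snp_amplicon, try_reverse=False)
        calls = bisulfite.call_clone_methylation(aln, snp_amplicon)
        snp_label = snp_amplicon.cpg_labels[0]
        assert calls[snp_label] == MethCall.MISSING
        assert all(
            calls[lab] == MethCall.METHYLATED
            for lab in snp_amplicon.cpg_labels[1:]
        )


class TestMatrixAndProfiles:
    def _matrix(self, fractions_m, conversions):
        """Hand-built matrix: one CpG 'x', calls from fractions_m."""
        calls = pd.DataFrame({"x": fractions_m},
                             index=[f"c{i}" for i in range(len(fractions_m))])
        qc = pd.DataFrame(
            {"conversion": conversions, "allele": ["C"] * len(fractions_m),
             "score": 0.0, "orientation": "forward"},
            index=calls.index)
        return bisulfite.MethylationMatrix(calls=calls, qc=qc)

    def test_fraction_arithmetic(self):
        mat = self._matrix(["M"] * 3 + ["U"] * 7, [1.0] * 10)
        prof = bisulfite.aggregate_profile(mat)
        assert prof.per_cpg.loc["x", "fraction"] == pytest.approx(0.3)

    def test_low_conversion_clone_excluded(self):
        mat = self._matrix(["M"] * 5 + ["U"] * 5, [0.80] + [1.0] * 9)
        prof = bisulfite.aggregate_profile(mat, min_conversion=0.95)
        assert prof.per_cpg.loc["x", "informative"] == 9
        assert prof.per_cpg.loc["x", "fraction"] == pytest.approx(4 / 9)

    def test_sparse_cpg_absent_not_zero(self):
        mat = self._matrix(["M", "U", ".", ".", "."], [1.0] * 5)
        prof = bisulfite.aggregate_profile(mat, min_informative=3)
        assert "x" not in prof.per_cpg.index

    def test_no_passing_clones_is_an_error(self):
        mat = self._matrix(["M"] * 4, [0.5] * 4)
        with pytest.raises(EmptyProfileError):
            bisulfite.aggregate_profile(mat)

    def test_call_counts_conserved_per_cpg(self, snp_amplicon):
        clones = simulate.simulate_bisulfite_clones(
            snp_amplicon, {"C": [0.5] * 4, "A": [0.5] * 4},
            simulate.CloneSimConfig(n_clones=30, seed=3))
        mat = bisulfite.build_methylation_matrix(
            {c.clone_id: c.read for c in clones}, snp_amplicon)
        for col in mat.calls.columns:
            counts = mat.calls[col].value_counts()
            assert counts.sum() == 30  # M + U + missing per CpG

    def test_matrix_invariant_to_input_order(self, snp_amplicon):
        clones = simulate.simulate_bisulfite_clones(
            snp_amplicon, {"C": [0.6] * 4, "A": [0.2] * 4},
            simulate.CloneSimConfig(n_clones=20, seed=4))
        pairs = [(c.clone_id, c.read) for c in clones]
        m1 = bisulfite.build_methylation_matrix(pairs, snp_amplicon)
        m2 = bisulfite.build_methylation_matrix(pairs[::-1], snp_amplicon)
        pd.testing.assert_frame_equal(m1.calls, m2.calls)


class TestAllelicProfiles:
    def test_identical_alleles_give_unit_ratio(self, snp_amplicon):
        clones = simulate.simulate_bisulfite_clones(
            snp_amplicon, {"C": [0.0, 1, 1, 1], "A": [0.0, 1, 1, 1]},
            simulate.CloneSimConfig(n_clones=40, seed=5,
                                    conversion_efficiency=1.0, error_rate=0.0))
        mat = bisulfite.build_methylation_matrix(
            {c.clone_id: c.read for c in clones}, snp_amplicon)
        allelic = bisulfite.allelic_methylation_ratio(mat, snp_amplicon)
        assert allelic.ratio == pytest.approx(1.0)

    def test_twofold_arithmetic(self, snp_amplicon):
        # deterministic clones: C allele fully methylated, A allele 50%
        clones = simulate.simulate_bisulfite_clones(
            snp_amplicon, {"C": [1.0] * 4, "A": [0.5] * 4},
            simulate.CloneSimConfig(n_clones=120, seed=6,
                                    conversion_efficiency=1.0, error_rate=0.0))
        mat = bisulfite.build_methylation_matrix(
            {c.clone_id: c.read for c in clones}, snp_amplicon)
        allelic = bisulfite.allelic_methylation_ratio(mat, snp_amplicon)
        assert allelic.c_allele.overall_mean == pytest.approx(1.0)
        assert allelic.ratio == pytest.approx(2.0, rel=0.25)
        assert allelic.snp_cpg_fraction == pytest.approx(1.0)

    def test_zero_a_allele_mean_reports_undefined_ratio(self, snp_amplicon):
        clones = simulate.simulate_bisulfite_clones(
            snp_amplicon, {"C": [1.0] * 4, "A": [0.0] * 4},
            simulate.CloneSimConfig(n_clones=40, seed=7,
                                    conversion_efficiency=1.0, error_rate=0.0))
        mat = bisulfite.build_methylation_matrix(
            {c.clone_id: c.read for c in clones}, snp_amplicon)
        allelic = bisulfite.allelic_methylation_ratio(mat, snp_amplicon)
        assert not allelic.ratio_defined

    def test_missing_allele_error_names_it(self, snp_amplicon):
        clones = simulate.simulate_bisulfite_clones(
            snp_amplicon, {"C": [0.5] * 4, "A": [0.5] * 4},
            simulate.CloneSimConfig(
                n_clones=20, seed=8, allele_fractions={"C": 1.0, "A": 0.0}))
        mat = bisulfite.build_methylation_matrix(
            {c.clone_id: c.read for c in clones}, snp_amplicon)
        with pytest.raises(AlleleMissingError, match="'A'"):
            bisulfite.allelic_methylation_ratio(mat, snp_amplicon)


def test_lollipop_has_one_row_per_clone(snp_amplicon):
    clones = simulate.simulate_bisulfite_clones(
        snp_amplicon, {"C": [0.5] * 4, "A": [0.5] * 4},
        simulate.CloneSimConfig(n_clones=5, seed=9))
    mat = bisulfite.build_methylation_matrix(
        {c.clone_id: c.read for c in clones}, snp_amplicon)
    text = bisulfite.format_lollipop(mat)
    assert len(text.splitlines()) == 6  # header + 5 clones
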