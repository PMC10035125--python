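"""Encoder correctness: worked examples, oracle equivalence, invariants."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import subloc as sl
from subloc.errors import LengthError, ValidationError

from conftest import (naive_kmer_vector, naive_pseeiip, naive_pseknc,
                      naive_property_weighted, naive_zc144, naive_zc48,
                      random_dna)


def seq(s: str, sid: str = "s") -> sl.NucleotideSequence:
    return sl.NucleotideSequence(sid, s)


dna = st.text(alphabet="ACGT", min_size=15, max_size=120)


class TestKmer:
    def test_homopolymer(self):
        v = sl.encode_kmer(seq("AAAA"), ks=[2])
        assert v.values[v.schema.names.index("kmer.k2.AA")] == 0.75
        assert np.count_nonzero(v.values) == 1

    def test_worked_example_dinucleotides(self):
        v = sl.encode_kmer(seq("ATAGCATCA"), ks=[2])
        names = v.schema.names
        assert v.values[names.index("kmer.k2.AT")] == pytest.approx(2 / 9)
        assert v.values[names.index("kmer.k2.CA")] == pytest.approx(2 / 9)

    def test_default_dimension_and_blocks(self):
        v = sl.encode_kmer(seq("ACGT" * 10))
        assert len(v.values) == 1360
        assert v.schema.names[0] == "kmer.k2.AA"
        assert v.schema.names[-1] == "kmer.k5.TTTTT"

    def test_k1_available_via_parameter(self):
        v = sl.encode_kmer(seq("AACG"), ks=[1])
        assert len(v.values) == 4
        assert v.values[0] == 0.5  # A frequency

    def test_too_short_raises(self):
        with pytest.raises(LengthError):
            sl.encode_kmer(seq("ACGT"), ks=[5])

    @settings(derandomize=True, max_examples=60)
    @given(dna)
    def test_block_sums_are_window_ratio(self, s):
        v = sl.encode_kmer(seq(s))
        offset = 0
        for k in (2, 3, 4, 5):
            block = v.values[offset:offset + 4 ** k]
            assert block.sum() == pytest.approx((len(s) - k + 1) / len(s),
                                                abs=1e-12)
            offset += 4 ** k


class TestPseKNC:
    def test_default_dimension(self, cfg, tables):
        v = sl.encode_pseknc(seq("ACGT" * 10), cfg, tables.dinuc_standardized)
        assert len(v.values) == 1370

    def test_homopolymer_correlations_vanish(self, cfg, tables):
        v = sl.encode_pseknc(seq("A" * 20), cfg, tables.dinuc_standardized)
        lam_block = v.values[-cfg.lam:]
        assert np.abs(lam_block).max() == 0.0

    def test_weight_zero_reduces_to_frequencies(self, tables):
        cfg0 = sl.PseKNCConfig(weight=0.0)
        s = "ACGTTGCAACGTGGCAACGT"
        v = sl.encode_pseknc(seq(s), cfg0, tables.dinuc_standardized)
        assert np.abs(v.values[-cfg0.lam:]).max() == 0.0
        freqs = v.values[:16]
        from conftest import naive_freqs, words
        expected = [naive_freqs(s, 2)[w] for w in words(2)]
        assert np.allclose(freqs, expected, atol=1e-12)

    def test_requires_standardized_table(self, cfg, tables):
        with pytest.raises(ValidationError, match="standardized"):
            sl.encode_pseknc(seq("ACGT" * 10), cfg, tables.dinuc)

    def test_too_short_for_lambda(self, cfg, tables):
        with pytest.raises(LengthError):
            sl.encode_pseknc(seq("ACGTACGTAC"), cfg,
                             tables.dinuc_standardized)

    def test_matches_naive_transcription(self, cfg, tables):
        rng = np.random.default_rng(11)
        for _ in range(5):
            s = random_dna(rng, int(rng.integers(30, 200)))
            got = sl.encode_pseknc(seq(s), cfg, tables.dinuc_standardized)
            expected = naive_pseknc(s, tables.dinuc_standardized.table)
            assert np.abs(got.values - np.array(expected)).max() < 1e-12


class TestPseEIIP:
    def test_dimension(self):
        assert len(sl.encode_pseeiip(seq("ACGTACGT")).values) == 64

    def test_homopolymer_value(self):
        v = sl.encode_pseeiip(seq("AAAA"))
        assert v.values[v.schema.names.index("eiip.AAA")] == pytest.approx(
            3 * 0.1260)
        assert np.count_nonzero(v.values) == 1

    def test_absent_trinucleotide_is_zero(self):
        v = sl.encode_pseeiip(seq("ACGTACGTACG"))
        assert v.values[v.schema.names.index("eiip.TTT")] == 0.0

    def test_components_reconstruct_from_counts(self):
        rng = np.random.default_rng(3)
        s = random_dna(rng, 90)
        got = sl.encode_pseeiip(seq(s)).values
        assert np.abs(got - np.array(naive_pseeiip(s))).max() < 1e-12


class TestEIIPIndicator:
    def test_worked_example(self):
        got = sl.eiip_indicator(seq("ATAGCATCA"))
        expected = [0.1260, 0.1335, 0.1260, 0.0806, 0.1340, 0.1260, 0.1335,
                    0.1340, 0.1260]
        assert np.allclose(got, expected, atol=1e-15)

    def test_homopolymer_and_length(self):
        assert np.allclose(sl.eiip_indicator(seq("AAAA")), [0.1260] * 4)
        rng = np.random.default_rng(5)
        s = random_dna(rng, 50)
        assert len(sl.eiip_indicator(seq(s))) == 50

    def test_ambiguous_policy(self):
        with pytest.raises(ValidationError):
            sl.eiip_indicator(seq("ACGNT"))
        assert len(sl.eiip_indicator(seq("ACGNT"), policy="skip")) == 4


class TestPropertyWeighted:
    def test_dimensions(self, tables):
        s = seq("ACGTACGTAC")
        assert len(sl.encode_dpcp(s, tables.dinuc).values) == 2368
        assert len(sl.encode_tpcp(s, tables.trinuc).values) == 768

    def test_all_ones_property_recovers_frequencies(self, tmp_path):
        from subloc.properties import DINUCLEOTIDES, TRINUCLEOTIDES
        from conftest import naive_freqs, words
        p = tmp_path / "ones2.tsv"
        p.write_text("property\t" + "\t".join(DINUCLEOTIDES) + "\n"
                     "ones\t" + "\t".join(["1"] * 16) + "\n")
        di = sl.load_dinucleotide_properties(p)
        s = "ATAGCATCAGGATTAC"
        got = sl.encode_dpcp(seq(s), di).values
        assert np.allclose(got, [naive_freqs(s, 2)[w] for w in words(2)],
                           atol=1e-15)
        q = tmp_path / "ones3.tsv"
        q.write_text("property\t" + "\t".join(TRINUCLEOTIDES) + "\n"
                     "ones\t" + "\t".join(["1"] * 64) + "\n")
        tri = sl.load_trinucleotide_properties(q)
        got3 = sl.encode_tpcp(seq(s), tri).values
        assert np.allclose(got3, [naive_freqs(s, 3)[w] for w in words(3)],
                           atol=1e-15)

    def test_absent_word_zeroes_all_properties(self, tables):
        s = "ACACACACAC"  # no TT dinucleotide
        v = sl.encode_dpcp(seq(s), tables.dinuc)
        tt = [i for i, n in enumerate(v.schema.names) if n.endswith(".TT")]
        assert len(tt) == 148
        assert np.abs(v.values[tt]).max() == 0.0

    def test_homopolymer_tpcp(self, tables):
        v = sl.encode_tpcp(seq("AAAAAA"), tables.trinuc)
        nonzero = [n for n, x in zip(v.schema.names, v.values) if x != 0]
        assert nonzero and all(n.endswith(".AAA") for n in nonzero)


class TestZCurve:
    def test_dimensions(self):
        s = seq("ACGTACGTAC")
        assert len(sl.encode_zcurve_independent(s).values) == 48
        assert len(sl.encode_zcurve_phase(s).values) == 144

    def test_polya_saturates_aa_triplet(self):
        v = sl.encode_zcurve_independent(seq("A" * 12))
        names = v.schema.names
        for ax in "xyz":
            assert v.values[names.index(f"zc48.{ax}.AA")] == 1.0
        assert np.count_nonzero(v.values) == 3
        vp = sl.encode_zcurve_phase(seq("A" * 12))
        for ph in (1, 2, 3):
            for ax in "xyz":
                assert vp.values[vp.schema.names.index(
                    f"zc144.p{ph}.{ax}.AA")] == 1.0
        assert np.count_nonzero(vp.values) == 9

    def test_worked_example_at_prefix(self):
        v = sl.encode_zcurve_independent(seq("ATAGCATCA"))
        names = v.schema.names
        assert v.values[names.index("zc48.y.AT")] == pytest.approx(2 / 7)
        assert v.values[names.index("zc48.x.AT")] == 0.0
        assert v.values[names.index("zc48.z.AT")] == 0.0

    @settings(derandomize=True, max_examples=60)
    @given(dna)
    def test_triplet_identity_and_bounds(self, s):
        """x+y+z = 4 p(XYA) - sum_N p(XYN); each axis bounded by the prefix
        mass."""
        v = sl.encode_zcurve_independent(seq(s)).values.reshape(16, 3)
        from conftest import naive_freqs, words
        f = naive_freqs(s, 3)
        for i, xy in enumerate(words(2)):
            total = sum(f[xy + n] for n in "ACGT")
            assert v[i].sum() == pytest.approx(4 * f[xy + "A"] - total,
                                               abs=1e-12)
            assert np.abs(v[i]).max() <= total + 1e-12
            assert total <= 1 + 1e-12

    def test_phase_average_recovers_independent(self):
        """Count-weighted mean of per-phase frequencies equals the
        phase-independent frequencies."""
        rng = np.random.default_rng(17)
        s = random_dna(rng, 60)
        f_all = np.array(naive_zc48(s))
        got = sl.encode_zcurve_independent(seq(s)).values
        assert np.allclose(got, f_all, atol=1e-12)
        n = len(s) - 2
        weights = np.array([len(range(ph, n, 3)) for ph in range(3)]) / n
        per_phase = np.array(naive_zc144(s)).reshape(3, 48)
        assert np.allclose(weights @ per_phase, f_all, atol=1e-12)

    def test_phase_layout_matches_naive(self):
        rng = np.random.default_rng(23)
        s = random_dna(rng, 77)
        got = sl.encode_zcurve_phase(seq(s)).values
        assert np.abs(got - np.array(naive_zc144(s))).max() < 1e-12


class TestAmbiguityPolicy:
    def test_windows_with_n_are_skipped(self):
        # ACGNT: dinucleotide windows AC, CG valid; GN, NT skipped
        v = sl.encode_kmer(seq("ACGNTACG"), ks=[2])
        assert v.values.sum() == pytest.approx(5 / 8)  # 5 valid windows / L

    def test_frequency_encoders_renormalize_over_valid_windows(self, tables):
        v = sl.encode_pseeiip(seq("ACGNTACGA"))
        from conftest import naive_pseeiip
        assert np.abs(v.values - naive_pseeiip("ACGNTACGA")).max() < 1e-12

    def test_strict_policy_rejects(self):
        with pytest.raises(ValidationError, match="strict"):
            sl.encode_kmer(seq("ACGTN" * 3), policy="strict")

    def test_all_ambiguous_errors(self):
        with pytest.raises(LengthError):
            sl.encode_pseeiip(seq("NNNNNN"))


class TestOracleEquivalence:
    """Every frequency-based encoder equals the naive sliding-window counter
    on random sequences, including ones containing ambiguity codes."""

    @pytest.mark.parametrize("alphabet", ["ACGT", "ACGTN"])
    def test_against_naive_counters(self, alphabet, tables):
        rng = np.random.default_rng(42)
        for _ in range(40):
            s = random_dna(rng, int(rng.integers(20, 300)), alphabet)
            if set(s) == {"N"}:
                continue
            nseq = seq(s)
            checks = [
                (sl.encode_kmer(nseq).values, naive_kmer_vector(s)),
                (sl.encode_pseeiip(nseq).values, naive_pseeiip(s)),
                (sl.encode_dpcp(nseq, tables.dinuc).values,
                 naive_property_weighted(s, tables.dinuc.table, 2)),
                (sl.encode_tpcp(nseq, tables.trinuc).values,
                 naive_property_weighted(s, tables.trinuc.table, 3)),
                (sl.encode_zcurve_independent(nseq).values, naive_zc48(s)),
                (sl.encode_zcurve_phase(nseq).values, naive_zc144(s)),
            ]
            for got, expected in checks:
                assert np.abs(got - np.array(expected)).max() < 1e-12


class TestBatteryAssembly:
    def test_group_widths(self, small_corpus, cfg, tables):
        two = sl.build_feature_matrix(small_corpus, ["kmer", "pseknc"], cfg,
                                      tables)
        assert two.data.shape == (len(small_corpus), 2730)
        full = sl.build_feature_matrix(small_corpus,
                                       sl.CANONICAL_GROUPS, cfg, tables)
        assert full.data.shape[1] == 6122

    def test_canonical_group_order(self, small_corpus, cfg, tables):
        fm = sl.build_feature_matrix(small_corpus, ["zcurve", "kmer"], cfg,
                                     tables)
        groups = list(dict.fromkeys(fm.schema.groups))
        assert groups == ["kmer", "zcurve"]

    def test_single_sequence_matrix(self, cfg, tables):
        fm = sl.build_feature_matrix([seq("ACGT" * 10, "only")],
                                     ["kmer"], cfg, tables)
        assert fm.data.shape == (1, 1360)
        assert fm.ids == ("only",)

    def test_short_sequence_named_in_error(self, cfg, tables):
        with pytest.raises(LengthError, match="shorty"):
            sl.build_feature_matrix(
                [seq("ACGT" * 10, "ok"), seq("ACG", "shorty")],
                ["kmer"], cfg, tables)

    def test_encoding_is_deterministic(self, cfg, tables):
        s = seq("ACGTTGCA" * 8)
        a = sl.encode_sequence(s, sl.CANONICAL_GROUPS, cfg, tables)
        b = sl.encode_sequence(s, sl.CANONICAL_GROUPS, cfg, tables)
        assert (a.values == b.values).all()

    def test_csv_round_trip(self, tmp_path, cfg, tables):
        fm = sl.build_feature_matrix([seq("ACGTTGCA" * 4, "r1")],
                                     ["kmer"], cfg, tables)
        path = tmp_path / "features.csv"
        fm.to_csv(path)
        back = sl.FeatureMatrix.from_csv(path, fm.schema)
        assert np.allclose(back.data.to_numpy(), fm.data.to_numpy(),
                           atol=1e-12)
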