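import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwmkit.matrix_model import (
    Alphabet,
    BackgroundModel,
    Pwm,
    SiteAlignment,
    build_dwm,
    build_pwm,
    column_information_content,
    dwm_from_pwm,
    encode,
    extend_alignment_with_flank,
    reverse_complement,
    reverse_complement_seq,
)
from dwmkit.synthetic_data import sample_pwm_sites

from .conftest import random_pwm


class TestAlphabet:
    def test_default_is_dna(self):
        a = Alphabet()
        assert a.symbols == ("A", "C", "G", "T")
        for s in a.symbols:
            assert a.complement[a.complement[s]] == s

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            Alphabet(symbols=("A", "C", "G"))


class TestSiteAlignment:
    def test_rejects_ragged(self):
        with pytest.raises(ValueError, match="length"):
            SiteAlignment(["AAA", "AA"])

    def test_rejects_non_acgt_naming_sequence(self):
        with pytest.raises(ValueError, match="#1.*'N'"):
            SiteAlignment(["ACG", "ANG"])

    def test_empty_needs_length(self):
        with pytest.raises(ValueError):
            SiteAlignment([])
        aln = SiteAlignment([], length=3)
        assert aln.count == 0 and aln.length == 3


class TestBuildPwm:
    def test_aa_tt_example(self, aa_tt_pwm):
        # (n + 1) / (2 + 4) per column
        expected = np.array([[1 / 3, 1 / 6, 1 / 6, 1 / 3]] * 2)
        np.testing.assert_allclose(aa_tt_pwm.probs, expected, atol=1e-15)

    def test_empty_alignment_is_pure_prior(self):
        pwm = build_pwm(SiteAlignment([], length=3), 1.0)
        np.testing.assert_allclose(pwm.probs, 0.25)

    def test_ac_aa_mixture(self):
        aln = SiteAlignment(["AC"] * 50 + ["AA"] * 50)
        pwm = build_pwm(aln, 1.0)
        np.testing.assert_allclose(
            pwm.probs[1], [51 / 104, 51 / 104, 1 / 104, 1 / 104], atol=1e-15
        )

    def test_kappa_convergence_bound(self):
        # with kappa -> 0 the estimate approaches raw frequencies
        rng = np.random.default_rng(7)
        aln = sample_pwm_sites(random_pwm(rng, 5), 400, rng)
        codes = aln.codes()
        raw = np.stack(
            [np.bincount(codes[:, i], minlength=4)[:4] / 400 for i in range(5)]
        )
        for kappa in (1.0, 0.1, 0.01):
            pwm = build_pwm(aln, kappa)
            bound = 4 * kappa / (400 + 4 * kappa)
            assert np.abs(pwm.probs - raw).max() <= bound + 1e-12


class TestBuildDwm:
    def test_aa_tt_pair_entries(self, aa_tt_dwm):
        table = aa_tt_dwm.pair(0, 1)
        assert table[0, 0] == pytest.approx(25 / 162, abs=1e-15)
        assert table[0, 3] == pytest.approx(16 / 162, abs=1e-15)
        assert table.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_product_counts_give_outer_product(self):
        # one copy of each dinucleotide: joint counts equal N * w_i * w_j exactly
        aln = SiteAlignment([a + b for a in "ACGT" for b in "ACGT"])
        dwm = build_dwm(aln, 1.0)
        w = dwm.marginal.probs
        np.testing.assert_allclose(dwm.pair(0, 1), np.outer(w[0], w[1]), atol=1e-15)

    def test_sampling_deviation_within_three_sigma(self):
        rng = np.random.default_rng(11)
        pwm = random_pwm(rng, 6)
        aln = sample_pwm_sites(pwm, 100, rng)
        dwm = build_dwm(aln, 1.0)
        w = dwm.marginal.probs
        n = 100
        for (i, j), table in dwm.pairs.items():
            p = np.outer(w[i], w[j])
            # |pair - w_i w_j| = |m - N p| / (N + 16) <= 3 sqrt(N p (1-p)) / (N + 16)
            bound = 3 * np.sqrt(n * p * (1 - p)) / (n + 16) + 1e-12
            assert np.all(np.abs(table - p) <= bound)

    def test_pure_prior_marginal_consistency(self):
        # for N = 0 the pair tables marginalise exactly to the Pwm columns
        pwm = build_pwm(SiteAlignment([], length=4), 1.0)
        dwm = build_dwm(SiteAlignment([], length=4), 1.0)
        for (i, j), table in dwm.pairs.items():
            np.testing.assert_allclose(table.sum(axis=1), pwm.probs[i], atol=1e-15)
            np.testing.assert_allclose(table.sum(axis=0), pwm.probs[j], atol=1e-15)

    def test_symmetry_convention(self, aa_tt_dwm):
        np.testing.assert_array_equal(aa_tt_dwm.pair(1, 0), aa_tt_dwm.pair(0, 1).T)


class TestExtendAlignmentWithFlank:
    def test_window_arithmetic(self):
        genome = {"seq1": "A" * 20 + "CGCGCG" + "T" * 20}
        aln = extend_alignment_with_flank([("seq1", 20, 26, "+")], genome, flank=10)
        assert aln.sequences == [genome["seq1"][10:36]]

    def test_boundary_sites_dropped(self):
        genome = {"s": "ACGTACGTACGTACGTACGTACGTACGTAC"}  # 30 bp
        aln = extend_alignment_with_flank(
            [("s", 3, 6, "+"), ("s", 12, 15, "+")], genome, flank=10
        )
        assert aln.count == 1 and aln.source_ids == ["s"]
        assert aln.sequences == [genome["s"][2:25]]

    def test_minus_strand_reverse_complemented(self):
        genome = {"s": "AAAACGTTTT"}
        aln = extend_alignment_with_flank([("s", 3, 7, "-")], genome, flank=1)
        assert aln.sequences == [reverse_complement_seq(genome["s"][2:8])]

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError, match="dropped"):
            extend_alignment_with_flank([("s", 0, 3, "+")], {"s": "ACGT"}, flank=5)


class TestInformationContent:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([1, 0, 0, 0], 2.0),
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([0.5, 0.5, 0, 0], 1.0),
        ],
    )
    def test_closed_forms(self, column, expected):
        pwm = Pwm(np.array([column], dtype=float))
        assert column_information_content(pwm, 0) == pytest.approx(expected, abs=1e-12)


class TestReverseComplement:
    def test_pwm_involution_bit_exact(self):
        pwm = random_pwm(np.random.default_rng(3), 9)
        back = reverse_complement(reverse_complement(pwm))
        np.testing.assert_array_equal(back.probs, pwm.probs)

    def test_dwm_involution_bit_exact(self):
        rng = np.random.default_rng(4)
        dwm = build_dwm(sample_pwm_sites(random_pwm(rng, 5), 20, rng), 1.0)
        back = reverse_complement(reverse_complement(dwm))
        for key in dwm.pairs:
            np.testing.assert_array_equal(back.pairs[key], dwm.pairs[key])
        np.testing.assert_array_equal(back.marginal.probs, dwm.marginal.probs)

    def test_uniform_is_palindromic(self):
        pwm = Pwm(np.full((6, 4), 0.25))
        np.testing.assert_array_equal(reverse_complement(pwm).probs, pwm.probs)


class TestDwmFromPwm:
    def test_uniform_gives_sixteenths(self):
        dwm = dwm_from_pwm(Pwm(np.full((3, 4), 0.25)))
        for table in dwm.pairs.values():
            np.testing.assert_allclose(table, 1 / 16, atol=1e-15)

    def test_tables_sum_to_one(self):
        dwm = dwm_from_pwm(random_pwm(np.random.default_rng(5), 8))
        for table in dwm.pairs.values():
            assert table.sum() == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=25, deadline=None)
@given(
    data=st.data(),
    n=st.integers(min_value=1, max_value=30),
    length=st.integers(min_value=2, max_value=8),
)
def test_normalisation_property(data, n, length):
    """Every Pwm row and Dwm pair table sums to 1 for arbitrary alignments."""
    sequences = [
        data.draw(st.text(alphabet="ACGT", min_size=length, max_size=length))
        for _ in range(n)
    ]
    aln = SiteAlignment(sequences)
    pwm = build_pwm(aln, 1.0)
    assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
    dwm = build_dwm(aln, 1.0)
    for table in dwm.pairs.values():
        assert abs(table.sum() - 1.0) < 1e-9


def test_encode_decode_roundtrip():
    assert (encode("ACGTN") == np.array([0, 1, 2, 3, 4])).all()
    assert reverse_complement_seq("ACGTN") == "NACGT"


def test_background_from_sequences():
    bg = BackgroundModel.from_sequences(["AACC", "GGTT"])
    np.testing.assert_allclose(bg.probs, 0.25)
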