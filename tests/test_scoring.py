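import math

import numpy as np
import pytest

from dwmkit.matrix_model import (
    BackgroundModel,
    Dwm,
    Pwm,
    build_dwm,
    dwm_from_pwm,
    encode,
    reverse_complement,
    reverse_complement_seq,
)
from dwmkit.scoring import (
    ScoredSite,
    dwm_log_likelihood,
    log_odds,
    pwm_log_likelihood,
    scan_sequence,
    total_log_odds,
)
from dwmkit.synthetic_data import sample_background, sample_pwm_sites

from .conftest import random_pwm, random_window


def enumerate_dwm_loglik(dwm: Dwm, window: str) -> float:
    """Independent oracle: evaluate u_i and Z_i by direct enumeration."""
    codes = encode(window)
    L = dwm.length
    total = 0.0
    for i in range(L):
        u = {}
        for a in range(4):
            value = dwm.marginal.probs[i, a]
            for j in range(L):
                if j == i:
                    continue
                value *= dwm.pair(i, j)[a, codes[j]] / dwm.marginal.probs[i, a]
            u[a] = value
        z = sum(u.values())
        total += math.log(u[codes[i]] / z)
    return total


class TestPwmLogLikelihood:
    def test_uniform(self):
        pwm = Pwm(np.full((5, 4), 0.25))
        assert pwm_log_likelihood(pwm, "ACGTA") == pytest.approx(5 * math.log(0.25))

    def test_near_deterministic_consensus(self):
        probs = np.full((3, 4), 0.01)
        probs[:, 0] = 0.97
        pwm = Pwm(probs)
        assert pwm_log_likelihood(pwm, "AAA") == pytest.approx(3 * math.log(0.97))

    def test_aa_tt_fixture(self, aa_tt_pwm):
        assert pwm_log_likelihood(aa_tt_pwm, "AA") == pytest.approx(2 * math.log(1 / 3))

    def test_length_mismatch(self, aa_tt_pwm):
        with pytest.raises(ValueError, match="length"):
            pwm_log_likelihood(aa_tt_pwm, "AAA")


class TestDwmLogLikelihood:
    def test_reduces_to_pwm(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pwm = random_pwm(rng, int(rng.integers(2, 9)))
            dwm = dwm_from_pwm(pwm)
            window = random_window(rng, pwm.length)
            got, _ = dwm_log_likelihood(dwm, window)
            assert got == pytest.approx(pwm_log_likelihood(pwm, window), abs=1e-9)

    def test_aa_tt_closed_forms(self, aa_tt_dwm):
        ll_aa, _ = dwm_log_likelihood(aa_tt_dwm, "AA")
        ll_at, _ = dwm_log_likelihood(aa_tt_dwm, "AT")
        assert ll_aa == pytest.approx(2 * math.log(25 / 57), abs=1e-12)
        assert ll_at == pytest.approx(2 * math.log(16 / 57), abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        dwm = build_dwm(sample_pwm_sites(random_pwm(rng, 6), 40, rng), 1.0)
        for _ in range(20):
            window = random_window(rng, 6)
            got, _ = dwm_log_likelihood(dwm, window)
            assert got == pytest.approx(enumerate_dwm_loglik(dwm, window), abs=1e-10)

    def test_unnormalised_over_sequences_but_posteriors_normalised(self, aa_tt_dwm):
        total = 0.0
        for a in "ACGT":
            for b in "ACGT":
                ll, profile = dwm_log_likelihood(aa_tt_dwm, a + b)
                total += math.exp(ll)
                np.testing.assert_allclose(profile.posterior.sum(axis=1), 1.0, atol=1e-9)
                np.testing.assert_allclose(
                    profile.posterior, profile.weights / profile.normalisers[:, None]
                )
        assert abs(total - 1.0) > 1e-3  # the approximation is not normalised

    def test_monotone_in_matching_pair_entry(self):
        # boosting pair(0,1)[s_0, s_1] (renormalised) never lowers the score
        rng = np.random.default_rng(4)
        dwm = build_dwm(sample_pwm_sites(random_pwm(rng, 3), 30, rng), 1.0)
        window = "ACG"
        base, _ = dwm_log_likelihood(dwm, window)
        for boost in (1.1, 1.5, 3.0):
            table = dwm.pairs[(0, 1)].copy()
            table[0, 1] *= boost  # window has A at 0, C at 1
            table /= table.sum()
            boosted = Dwm(
                marginal=dwm.marginal,
                pairs={**{k: v.copy() for k, v in dwm.pairs.items()}, (0, 1): table},
            )
            got, _ = dwm_log_likelihood(boosted, window)
            assert got >= base - 1e-12


class TestLogOdds:
    def test_uniform_model_uniform_background_is_zero(self, uniform_background):
        pwm = Pwm(np.full((4, 4), 0.25))
        for window in ("ACGT", "AAAA", "TTTT"):
            ll = pwm_log_likelihood(pwm, window)
            assert log_odds(ll, window, uniform_background) == pytest.approx(0.0)

    def test_arithmetic(self):
        bg = BackgroundModel(np.array([0.3, 0.2, 0.2, 0.3]))
        ll = 2 * math.log(1 / 3)
        expected = 2 * math.log(1 / 3) - 2 * math.log(0.3)
        assert log_odds(ll, "AA", bg) == pytest.approx(expected, abs=1e-12)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        bg = BackgroundModel(np.array([0.3, 0.2, 0.2, 0.3]))  # complement-symmetric
        pwm = random_pwm(rng, 6)
        for _ in range(20):
            window = random_window(rng, 6)
            fwd = log_odds(pwm_log_likelihood(pwm, window), window, bg)
            rc_window = reverse_complement_seq(window)
            rev = log_odds(
                pwm_log_likelihood(reverse_complement(pwm), rc_window), rc_window, bg
            )
            assert fwd == pytest.approx(rev, abs=1e-9)


class TestScanSequence:
    def test_single_window(self, uniform_background):
        pwm = Pwm(np.full((4, 4), 0.25))
        sites = scan_sequence(pwm, "ACGT", uniform_background)
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (0, 4)

    def test_all_n_sequence_is_empty(self, uniform_background):
        pwm = Pwm(np.full((3, 4), 0.25))
        assert scan_sequence(pwm, "N" * 10, uniform_background) == []

    def test_short_sequence_warns_and_is_empty(self, uniform_background, caplog):
        pwm = Pwm(np.full((5, 4), 0.25))
        with caplog.at_level("WARNING"):
            assert scan_sequence(pwm, "ACG", uniform_background) == []
        assert "shorter" in caplog.text

    def test_planted_consensus_argmax(self, uniform_background):
        consensus = "ACGTAGA"
        probs = np.full((7, 4), 0.01)
        probs[np.arange(7), encode(consensus)] = 0.97
        pwm = Pwm(probs)
        seq = sample_background(uniform_background, 200, seed=9)
        seq = seq[:37] + consensus + seq[44:]
        sites = scan_sequence(pwm, seq, uniform_background, "probe")
        best = max(sites, key=lambda s: s.logodds)
        assert best.start == 37 and best.strand == "+"
        # exhaustive oracle: per-window best-orientation log-odds
        for site in sites:
            window = seq[site.start : site.end]
            fwd = log_odds(pwm_log_likelihood(pwm, window), window, uniform_background)
            rc = reverse_complement_seq(window)
            rev = log_odds(pwm_log_likelihood(pwm, rc), rc, uniform_background)
            assert site.logodds == pytest.approx(max(fwd, rev), abs=1e-9)
            if abs(fwd - rev) > 1e-6:  # tolerate float noise on strand ties
                assert site.strand == ("+" if fwd > rev else "-")

    def test_dwm_scan_matches_single_window_scorer(self, uniform_background):
        rng = np.random.default_rng(6)
        dwm = build_dwm(sample_pwm_sites(random_pwm(rng, 5), 30, rng), 1.0)
        seq = sample_background(uniform_background, 60, seed=10)
        rc_dwm = reverse_complement(dwm)
        for site in scan_sequence(dwm, seq, uniform_background, "s"):
            window = seq[site.start : site.end]
            fwd = log_odds(dwm_log_likelihood(dwm, window)[0], window, uniform_background)
            rev = log_odds(dwm_log_likelihood(rc_dwm, window)[0], window, uniform_background)
            assert site.logodds == pytest.approx(max(fwd, rev), abs=1e-9)


class TestTotalLogOdds:
    def make(self, values):
        return [ScoredSite("s", k, k + 2, "+", v) for k, v in enumerate(values)]

    def test_empty(self):
        assert total_log_odds([]) == 0.0

    def test_sum(self):
        assert total_log_odds(self.make([2.0, -1.0, 0.5])) == pytest.approx(1.5)

    def test_positive_only_flag(self):
        sites = self.make([2.0, -1.0, 0.5])
        assert total_log_odds(sites, positive_only=True) == pytest.approx(2.5)
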