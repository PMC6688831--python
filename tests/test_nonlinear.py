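import math

import numpy as np
import pytest

from neohrv.errors import ParameterError
from neohrv.linear import time_domain
from neohrv.nonlinear import dfa, poincare, prsa, sample_entropy, select_sampen_params
from neohrv.synthetic import gen_white_noise

from conftest import make_window, random_window
from oracles import prsa_bruteforce, sampen_counts_bruteforce


class TestPoincare:
    def test_alternating_series(self):
        r = poincare(make_window([400.0, 420.0] * 100))
        assert r.sd1_ms == pytest.approx(20.0 / math.sqrt(2))
        assert r.sd2_ms == pytest.approx(0.0, abs=1e-9)

    def test_sd1_equals_rmssd_over_sqrt2(self, rng):
        for n in (20, 50, 300):
            w = random_window(rng, n)
            assert poincare(w).sd1_ms == pytest.approx(
                time_domain(w).rmssd_ms / math.sqrt(2), rel=1e-12
            )

    def test_constant_window_degenerate(self):
        r = poincare(make_window([400.0] * 10))
        assert r.sd1_ms == 0.0 and r.sd2_ms == 0.0
        assert np.isnan(r.ratio)


class TestSampleEntropy:
    def test_matches_bruteforce_counts(self, rng):
        for _ in range(10):
            n = int(rng.integers(40, 300))
            w = random_window(rng, n)
            res = sample_entropy(w, m=3, r_frac=0.25)
            r = 0.25 * w.rr_ms.std()
            b, a = sampen_counts_bruteforce(w.rr_ms, 3, r)
            assert (res.matches_m, res.matches_m1) == (b, a)

    def test_periodic_series_zero_entropy(self):
        res = sample_entropy(make_window([400.0, 420.0] * 100), m=3)
        assert res.sampen == pytest.approx(0.0, abs=1e-12)

    def test_shuffling_periodic_series_increases_entropy(self, rng):
        base = np.array([400.0, 420.0, 410.0, 430.0] * 60)
        ref = sample_entropy(make_window(base)).sampen
        for _ in range(20):
            shuffled = rng.permutation(base) + rng.normal(0, 1e-6, base.size)
            assert sample_entropy(make_window(shuffled)).sampen >= ref - 1e-9

    def test_no_matches_gives_nan_not_exception(self, rng):
        # strictly increasing ramp with huge steps: no template matches
        w = make_window(np.linspace(300, 700, 40))
        res = sample_entropy(w, m=3, r_frac=0.01)
        assert np.isnan(res.sampen)


class TestSampEnSelection:
    def test_degenerate_grid_returns_it(self, rng):
        corpus = [random_window(rng, 150) for _ in range(4)]
        m, r, score = select_sampen_params(corpus, m_grid=(3,), r_grid=(0.25,))
        assert (m, r) == (3, 0.25) and score > 0

    def test_efficiency_decreases_in_r(self, rng):
        corpus = [random_window(rng, 200) for _ in range(6)]
        scores = [
            select_sampen_params(corpus, m_grid=(3,), r_grid=(r,))[2]
            for r in (0.1, 0.2, 0.3)
        ]
        assert scores[0] > scores[1] > scores[2]

    def test_near_constant_corpus_prefers_largest_r(self, rng):
        corpus = [
            make_window(400.0 + 0.01 * rng.standard_normal(100)) for _ in range(5)
        ]
        m, r, _ = select_sampen_params(corpus, m_grid=(3,), r_grid=(0.1, 0.2, 0.3))
        assert r == 0.3

    def test_empty_corpus_rejected(self):
        with pytest.raises(ParameterError):
            select_sampen_params([], m_grid=(3,), r_grid=(0.25,))


class TestDFA:
    def test_scale_and_offset_invariance(self, rng):
        x = gen_white_noise(2000, 4)
        a = dfa(x).alpha1
        assert dfa(x + 100.0).alpha1 == pytest.approx(a, abs=1e-6)
        assert dfa(3.5 * x).alpha1 == pytest.approx(a, abs=1e-6)

    def test_too_short_for_alpha1(self):
        assert np.isnan(dfa(gen_white_noise(60, 0)).alpha1)

    def test_alpha2_requires_quarter_length_beyond_44(self):
        assert np.isnan(dfa(gen_white_noise(170, 0)).alpha2)  # N/4 = 42
        assert not np.isnan(dfa(gen_white_noise(400, 0)).alpha2)

    def test_fluctuations_increase_with_box_size(self, rng):
        r = dfa(gen_white_noise(5000, 9))
        assert np.all(np.diff(r.fluctuations) > 0)


class TestPRSA:
    def test_hand_enumerated_example(self):
        r = prsa([400, 410, 405, 415, 410, 420, 415, 425, 420, 430])
        assert r.dc_ms == pytest.approx(2.5)
        assert r.ac_ms == pytest.approx(2.5)
        assert (r.n_dec_anchors, r.n_acc_anchors) == (3, 4)

    def test_strict_alternation_cancels(self):
        r = prsa([400.0, 420.0] * 20)
        assert r.dc_ms == pytest.approx(0.0, abs=1e-12)
        assert r.ac_ms == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_has_no_anchors(self):
        r = prsa([400.0] * 20)
        assert np.isnan(r.dc_ms) and np.isnan(r.ac_ms)
        assert r.n_dec_anchors == 0 and r.n_acc_anchors == 0

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            x = 400 + 20 * rng.standard_normal(int(rng.integers(10, 200)))
            mine = prsa(x)
            dc, ac, ndec, nacc = prsa_bruteforce(x)
            assert mine.dc_ms == pytest.approx(dc, nan_ok=True)
            assert mine.ac_ms == pytest.approx(ac, nan_ok=True)
            assert (mine.n_dec_anchors, mine.n_acc_anchors) == (ndec, nacc)

    def test_time_reversal_swaps_dc_and_ac(self, rng):
        x = 400 + 20 * rng.standard_normal(500)  # ties have measure zero
        fwd, rev = prsa(x), prsa(x[::-1])
        assert rev.dc_ms == pytest.approx(-fwd.ac_ms, abs=1e-9)
        assert rev.ac_ms == pytest.approx(-fwd.dc_ms, abs=1e-9)
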