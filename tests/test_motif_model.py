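"""PWM construction, scoring and the exact score-distribution p-value."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adgscan.motif_model import (
    BackgroundModel,
    PWMMotif,
    build_background,
    build_pwm,
    read_meme,
    score_pvalue,
    score_word,
    word_pvalue,
    write_meme,
)


def enumerate_words(width):
    return ["".join(w) for w in itertools.product("ACGT", repeat=width)]


def brute_force_pvalue(pwm, threshold):
    """Independent oracle: sum background probabilities over all 4^W words
    whose exact score reaches the threshold."""
    bg = pwm.background
    total = 0.0
    for w in enumerate_words(pwm.width):
        if score_word(pwm, w) >= threshold:
            p = 1.0
            for c in w:
                p *= bg[c]
            total += p
    return total


class TestBackground:
    def test_uniform_repeats(self):
        bg = build_background(["ACGT" * 25])
        assert np.allclose(bg.array, 0.25, atol=1e-9)

    def test_plus_one_smoothing(self):
        bg = build_background(["A" * 100])
        assert bg["A"] == pytest.approx(101 / 104)
        assert bg["C"] == pytest.approx(1 / 104)

    def test_concatenation_invariance(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        whole = build_background([seq])
        split = build_background([seq[i : i + 50] for i in range(0, 500, 50)])
        assert np.allclose(whole.array, split.array, atol=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_background([])

    def test_strictly_positive_required(self):
        with pytest.raises(ValueError):
            BackgroundModel((0.5, 0.5, 0.0, 0.0))


class TestBuildPwm:
    def test_identical_sites_zero_pseudocount(self, uniform_bg):
        pwm = build_pwm(["AC", "AC", "AC"], uniform_bg, pseudocount=0.0)
        assert pwm.probs[0, 0] == 1.0 and pwm.probs[1, 1] == 1.0
        assert pwm.consensus_iupac == "AC"

    def test_pseudocount_formula(self, uniform_bg):
        # two sites AC/AT, pseudocount 0.5: P(col2, C) = (1 + 0.125) / 2.5
        pwm = build_pwm(["AC", "AT"], uniform_bg, pseudocount=0.5)
        assert pwm.probs[1, 1] == pytest.approx((1 + 0.5 * 0.25) / 2.5)
        assert pwm.probs[1, 1] == pytest.approx(0.45)

    def test_rejects_bad_input(self, uniform_bg):
        with pytest.raises(ValueError):
            build_pwm(["AC"], uniform_bg)
        with pytest.raises(ValueError):
            build_pwm(["AC", "ACG"], uniform_bg)
        with pytest.raises(ValueError):
            build_pwm(["AN", "AC"], uniform_bg)

    @pytest.mark.parametrize("pc,target", [(1e-9, "empirical"), (1e9, "background")])
    def test_pseudocount_limits(self, uniform_bg, pc, target):
        pwm = build_pwm(["AC", "AC", "AT"], uniform_bg, pseudocount=pc)
        if target == "empirical":
            assert pwm.probs[1, 1] == pytest.approx(2 / 3, abs=1e-6)
        else:
            assert np.allclose(pwm.probs, 0.25, atol=1e-6)


class TestScoreWord:
    def test_uniform_pwm_scores_zero(self, uniform_bg):
        probs = np.full((5, 4), 0.25)
        pwm = PWMMotif("u", probs * 0, probs, uniform_bg, 0.25)
        for w in ["ACGTA", "TTTTT", "GCGCG"]:
            assert score_word(pwm, w) == pytest.approx(0.0)

    def test_argmax_word_is_maximum(self, random_pwms):
        pwm = random_pwms[0]
        best = pwm.consensus
        scores = [score_word(pwm, w) for w in enumerate_words(pwm.width)]
        assert score_word(pwm, best) == pytest.approx(max(scores))

    def test_all_words_match_table_lookup(self, uniform_bg):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(4), size=3)
        pwm = PWMMotif("w3", probs * 0, probs, uniform_bg, 0.25)
        table = np.log2(probs / 0.25)
        for w in enumerate_words(3):
            expected = sum(table[i, "ACGT".index(c)] for i, c in enumerate(w))
            assert score_word(pwm, w) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_errors(self, random_pwms):
        with pytest.raises(ValueError):
            score_word(random_pwms[0], "A" * (random_pwms[0].width + 1))


class TestScorePvalue:
    def test_below_minimum_is_one(self, random_pwms):
        for pwm in random_pwms[:5]:
            lo = min(score_word(pwm, w) for w in enumerate_words(pwm.width))
            assert score_pvalue(pwm, lo - 1.0) == 1.0

    def test_at_maximum_single_argmax(self, uniform_bg):
        # columns with a clear winner: only the argmax word reaches the max
        probs = np.array([[0.7, 0.1, 0.1, 0.1]] * 4)
        pwm = PWMMotif("am", probs * 0, probs, uniform_bg, 0.25)
        top = score_word(pwm, "AAAA")
        assert score_pvalue(pwm, top) == pytest.approx(0.25**4, rel=1e-9)

    def test_matches_brute_force_enumeration(self, random_pwms):
        # thresholds at mid-gaps between achievable scores, with a margin
        # exceeding the lattice resolution, so DP and enumeration agree
        for pwm in random_pwms[:8]:
            words = enumerate_words(pwm.width)
            uniq = np.unique([score_word(pwm, w) for w in words])
            gaps = np.diff(uniq)
            ok = np.nonzero(gaps > 3 * pwm.width * 1e-3)[0]
            for i in (ok[0], ok[len(ok) // 2], ok[-1]):
                t = (uniq[i] + uniq[i + 1]) / 2
                assert score_pvalue(pwm, t) == pytest.approx(
                    brute_force_pvalue(pwm, t), rel=1e-9
                )

    def test_monotone_nonincreasing_in_threshold(self, random_pwms):
        pwm = random_pwms[1]
        ts = np.linspace(-20, 20, 81)
        ps = [score_pvalue(pwm, t) for t in ts]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_granularity_halving_stable(self, random_pwms):
        for pwm in random_pwms[:5]:
            words = enumerate_words(pwm.width)
            uniq = np.unique([score_word(pwm, w) for w in words])
            gaps = np.diff(uniq)
            i = int(np.argmax(gaps))
            t = (uniq[i] + uniq[i + 1]) / 2
            a = score_pvalue(pwm, t, granularity=1e-3)
            b = score_pvalue(pwm, t, granularity=5e-4)
            assert a == pytest.approx(b, rel=1e-6)

    def test_word_pvalue_consistent_with_sf(self, random_pwms):
        pwm = random_pwms[2]
        for w in enumerate_words(pwm.width)[::37]:
            p = word_pvalue(pwm, w)
            assert 0.0 < p <= 1.0

    def test_zero_granularity_errors(self, random_pwms):
        from adgscan.motif_model import ScoreDistribution

        with pytest.raises(ValueError):
            ScoreDistribution.from_pwm(random_pwms[0], 0.0)


@settings(derandomize=True, max_examples=30)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_consensus_iupac_covers_quarter_probability(seed):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(4), size=6)
    pwm = PWMMotif("h", probs * 0, probs, BackgroundModel.uniform(), 0.25)
    code = pwm.consensus_iupac
    from adgscan.motif_model import _IUPAC

    rev = {v: k for k, v in _IUPAC.items()}
    for col, c in enumerate(code):
        covered = rev[c]
        for b in "ACGT":
            if probs[col, "ACGT".index(b)] >= 0.25:
                assert b in covered


def test_meme_roundtrip(tmp_path, uniform_bg):
    pwm = build_pwm(["ACGTAC", "ACGTAT", "ACCTAC"], uniform_bg, motif_id="m1")
    path = tmp_path / "motifs.meme"
    write_meme([pwm], path)
    back = read_meme(path)
    assert len(back) == 1
    assert back[0].motif_id == "m1"
    assert back[0].width == 6
    assert np.allclose(back[0].probs, pwm.probs, atol=1e-5)
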