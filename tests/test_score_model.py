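"""Score distribution DP, thresholds and the joint two-window DP."""

import numpy as np
import pytest

import motifclump as mc
from motifclump.score_model import DEFAULT_GRANULARITY


class TestScoreWord:
    def test_uniform_pfm_uniform_bg_is_zero(self, uniform_bg):
        pfm = mc.PFM(np.full((4, 3), 0.25))
        for w in ["AAA", "ACG", "TTT"]:
            assert mc.score_word(pfm, uniform_bg, w) == pytest.approx(0.0)

    def test_single_column_log2(self, uniform_bg):
        pfm = mc.PFM(np.array([[0.5], [0.25], [0.125], [0.125]]))
        assert mc.score_word(pfm, uniform_bg, "A") == pytest.approx(np.log(2))

    def test_aaa_fixture_score(self, uniform_bg):
        pfm = mc.word_motif("AAA", 0.01)
        assert mc.score_word(pfm, uniform_bg, "AAA") == pytest.approx(
            3 * np.log(0.97 / 0.25)
        )

    def test_order_exceeds_length(self, order2_bg):
        pfm = mc.PFM(np.full((4, 1), 0.25))
        with pytest.raises(ValueError, match="order exceeds"):
            mc.score_word(pfm, order2_bg, "A")


class TestScoreDistribution:
    def test_uniform_point_mass_at_zero(self, uniform_bg):
        pfm = mc.PFM(np.full((4, 4), 0.25))
        dist = mc.score_distribution(pfm, uniform_bg, 0.01)
        assert list(dist.indices) == [0]
        assert dist.probs[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("bg_name", ["uniform_bg", "order1_bg", "order2_bg"])
    def test_matches_exhaustive_enumeration(
        self, request, bg_name, seed, make_random_pfm, oracles
    ):
        bg = request.getfixturevalue(bg_name)
        rng = np.random.default_rng(seed)
        pfm = make_random_pfm(rng, 4)
        dist = mc.score_distribution(pfm, bg, 0.01)
        got = oracles.to_dict(dist)
        want = oracles.score_distribution(pfm, bg, 0.01)
        assert set(got) == {k for k, v in want.items() if v > 0}
        for idx, p in want.items():
            assert got.get(idx, 0.0) == pytest.approx(p, abs=1e-12)

    def test_probabilities_sum_to_one(self, order1_bg, fixtures):
        for pfm in fixtures.values():
            dist = mc.score_distribution(pfm, order1_bg, 0.01)
            assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(dist.probs >= 0)

    def test_rc_pfm_same_distribution_order0(self, uniform_bg, fixtures):
        # exact equality on the same grid: at order 0 the per-position
        # background terms are complement-invariant, so every word maps to
        # the same rounded score as its reverse complement
        for pfm in fixtures.values():
            a = mc.score_distribution(pfm, uniform_bg, 0.01)
            b = mc.score_distribution(
                mc.reverse_complement_pfm(pfm), uniform_bg, 0.01
            )
            assert a.offset == b.offset
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)

    def test_rc_pfm_distribution_higher_order(self, order1_bg, fixtures):
        # for d >= 1 the unrounded distributions coincide but per-position
        # rounding may split atoms across adjacent grid cells; thresholds
        # and attained alphas must still agree at practical levels
        for pfm in fixtures.values():
            a = mc.score_distribution(pfm, order1_bg, 0.01)
            b = mc.score_distribution(
                mc.reverse_complement_pfm(pfm), order1_bg, 0.01
            )
            assert abs(
                float(a.scores @ a.probs) - float(b.scores @ b.probs)
            ) < 2 * 0.01 * pfm.length
            for alpha in (1e-1, 1e-2, 1e-3):
                ta = mc.choose_threshold(a, alpha)
                tb = mc.choose_threshold(b, alpha)
                assert abs(ta.t_index - tb.t_index) <= 2
                assert ta.attained_alpha == pytest.approx(
                    tb.attained_alpha, rel=0.05, abs=1e-9
                )

    def test_granularity_refinement_converges(self, order1_bg, fixtures):
        pfm = fixtures["nonself"]
        coarse = mc.score_distribution(pfm, order1_bg, 0.02)
        fine = mc.score_distribution(pfm, order1_bg, 0.002)
        t = 2.0  # a real score within the support
        tail_c = coarse.tail(int(np.ceil(t / 0.02)))
        tail_f = fine.tail(int(np.ceil(t / 0.002)))
        assert abs(tail_c - tail_f) < 0.01

    def test_invalid_granularity(self, uniform_bg, fixtures):
        with pytest.raises(ValueError):
            mc.score_distribution(fixtures["aaa"], uniform_bg, 0.0)


class TestThreshold:
    def test_alpha_one_gives_min_support(self, uniform_bg, fixtures):
        dist = mc.score_distribution(fixtures["aaa"], uniform_bg, 0.01)
        thr = mc.choose_threshold(dist, 1.0)
        assert thr.t_index == dist.offset
        assert thr.attained_alpha == pytest.approx(1.0)

    def test_monotone_in_alpha(self, order1_bg, fixtures):
        dist = mc.score_distribution(fixtures["nonself"], order1_bg, 0.01)
        alphas = [0.5, 0.1, 0.01, 0.001, 1e-4]
        ts = [mc.choose_threshold(dist, a).t_index for a in alphas]
        assert ts == sorted(ts)

    def test_attained_below_nominal(self, order1_bg, fixtures):
        dist = mc.score_distribution(fixtures["palindrome"], order1_bg, 0.01)
        for a in [0.3, 0.01, 1e-3, 1e-5]:
            thr = mc.choose_threshold(dist, a)
            assert thr.attained_alpha <= a + 1e-15

    def test_exact_word_threshold_aaa(self, uniform_bg, oracles):
        pfm = mc.word_motif("AAA", 0.01)
        dist = mc.score_distribution(pfm, uniform_bg, 0.01)
        thr = mc.choose_threshold(dist, 0.016)  # just above P(AAA) = 1/64
        assert thr.attained_alpha == pytest.approx(1 / 64)
        # exhaustive check: only the word AAA scores at or above t
        hits = [
            codes
            for codes in np.ndindex(4, 4, 4)
            if oracles.word_index(pfm, uniform_bg, list(codes), 0.01) >= thr.t_index
        ]
        assert hits == [(0, 0, 0)]

    def test_alpha_below_smallest_atom_warns(self, uniform_bg, fixtures):
        dist = mc.score_distribution(fixtures["aaa"], uniform_bg, 0.01)
        with pytest.warns(UserWarning, match="no hits"):
            thr = mc.choose_threshold(dist, 1e-12)
        assert thr.attained_alpha == 0.0
        assert thr.t_index > dist.offset + len(dist.probs) - 1

    def test_invalid_alpha(self, uniform_bg, fixtures):
        dist = mc.score_distribution(fixtures["aaa"], uniform_bg, 0.01)
        for a in [0.0, -0.1, 1.5]:
            with pytest.raises(ValueError):
                mc.choose_threshold(dist, a)


class TestJointDistribution:
    @pytest.mark.parametrize("orientation", ["ff", "fr", "rf"])
    def test_marginals_match_1d(self, order1_bg, fixtures, orientation):
        pfm = fixtures["nonself"]
        one_d = mc.score_distribution(pfm, order1_bg, 0.01)
        rc_d = mc.score_distribution(
            mc.reverse_complement_pfm(pfm), order1_bg, 0.01
        )
        jd = mc.joint_score_distribution(pfm, order1_bg, 2, orientation, 0.01)
        assert jd.probs.sum() == pytest.approx(1.0, abs=1e-12)
        m0 = jd.marginal(0)
        m1 = jd.marginal(1)
        ref0 = rc_d if orientation == "rf" else one_d
        ref1 = rc_d if orientation == "fr" else one_d
        for m, ref in [(m0, ref0), (m1, ref1)]:
            assert m.offset == ref.offset
            np.testing.assert_allclose(m.probs, ref.probs, atol=1e-9)

    def test_single_overlap_position_exhaustive(self, uniform_bg, make_random_pfm, oracles):
        # k = M-1: windows overlap in one position, d = 0
        rng = np.random.default_rng(3)
        pfm = make_random_pfm(rng, 3)
        dist = mc.score_distribution(pfm, uniform_bg, 0.01)
        thr = mc.choose_threshold(dist, 0.05)
        jd = mc.joint_score_distribution(pfm, uniform_bg, 2, "ff", 0.01)
        got = jd.joint_tail(thr.t_index)
        want = oracles.joint_tail(pfm, uniform_bg, 2, "ff", 0.01, thr.t_index)
        assert got == pytest.approx(want, abs=1e-12)

    def test_fr_shift0_palindrome_symmetric(self, uniform_bg, fixtures):
        jd = mc.joint_score_distribution(
            fixtures["palindrome"], uniform_bg, 0, "fr", 0.01
        )
        table = {}
        for i0, i1, p in zip(jd.idx0, jd.idx1, jd.probs):
            table[(int(i0), int(i1))] = float(p)
        for (i0, i1), p in table.items():
            assert table.get((i1, i0), 0.0) == pytest.approx(p, abs=1e-12)

    def test_shift_out_of_range(self, uniform_bg, fixtures):
        pfm = fixtures["aaa"]
        with pytest.raises(ValueError):
            mc.joint_score_distribution(pfm, uniform_bg, 0, "ff", 0.01)
        with pytest.raises(ValueError):
            mc.joint_score_distribution(pfm, uniform_bg, 3, "ff", 0.01)
        with pytest.raises(ValueError):
            mc.joint_score_distribution(pfm, uniform_bg, 1, "xx", 0.01)

    def test_word_score_index_consistency(self, order1_bg, fixtures, oracles):
        pfm = fixtures["nonself"]
        rng = np.random.default_rng(8)
        for _ in range(10):
            codes = list(rng.integers(0, 4, size=pfm.length))
            w = "".join("ACGT"[c] for c in codes)
            assert mc.word_score_index(
                pfm, order1_bg, w, DEFAULT_GRANULARITY
            ) == oracles.word_index(pfm, order1_bg, codes, DEFAULT_GRANULARITY)
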