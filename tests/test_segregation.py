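"""Mendelian expectations, exact segregation tests, non-Mendelian flagging."""

import numpy as np
import pytest
from scipy import stats

from rlgsim import (
    IntensityClass,
    LocusObservation,
    flag_non_mendelian,
    mendelian_expectation,
    segregation_test,
)

IC = IntensityClass


class TestMendelianExpectation:
    def test_het_producer_by_nonproducer_f1_is_one_to_one(self):
        probs = mendelian_expectation((True, False), (False, False), "outcross_F1")
        assert probs == {IC.HALF: 0.5, IC.ABSENT: 0.5}

    def test_selfed_heterozygote_is_one_two_one(self):
        probs = mendelian_expectation((True, False), None, "self")
        assert probs == {IC.FULL: 0.25, IC.HALF: 0.5, IC.ABSENT: 0.25}

    def test_homozygote_cross_all_full(self):
        probs = mendelian_expectation((True, True), (True, True), "outcross_F1")
        assert probs == {IC.FULL: 1.0}

    def test_self_with_distinct_parents_rejected(self):
        with pytest.raises(ValueError, match="single parent"):
            mendelian_expectation((True, False), (False, False), "self")


class TestSegregationTest:
    def test_five_to_four_is_perfectly_consistent(self):
        # the NKF1 [MspI] panel: 5 present, 4 absent against 1:1
        p = segregation_test({"present": 5, "absent": 4}, {"present": 0.5, "absent": 0.5})
        assert p == pytest.approx(1.0)

    def test_nine_to_zero_closed_form(self):
        p = segregation_test({"present": 9, "absent": 0}, {"present": 0.5, "absent": 0.5})
        assert p == pytest.approx(2 * 0.5**9)  # 0.00390625

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            segregation_test({"present": 0, "absent": 0}, {"present": 0.5, "absent": 0.5})

    def test_observation_in_impossible_class_gives_zero(self):
        p = segregation_test({IC.FULL: 3, IC.HALF: 1}, {IC.FULL: 1.0})
        assert p == 0.0

    @pytest.mark.parametrize("counts", [(0, 9), (3, 6), (5, 4), (9, 0), (2, 2)])
    def test_multinomial_collapses_to_exact_binomial(self, counts):
        """With two classes the enumeration equals scipy's two-sided binomial."""
        a, b = counts
        n = a + b
        enumerated = sum(
            stats.binom.pmf(k, n, 0.5)
            for k in range(n + 1)
            if stats.binom.pmf(k, n, 0.5) <= stats.binom.pmf(a, n, 0.5) * (1 + 1e-7)
        )
        p = segregation_test({"x": a, "y": b}, {"x": 0.5, "y": 0.5})
        assert p == pytest.approx(enumerated)

    def test_multinomial_enumeration_against_direct_sum(self):
        """Exact multinomial p for 0/9/0 vs 1:2:1, recomputed independently."""
        probs = np.array([0.25, 0.5, 0.25])
        pmf_obs = stats.multinomial(9, probs).pmf([0, 9, 0])
        total = 0.0
        for a in range(10):
            for b in range(10 - a):
                c = 9 - a - b
                pmf = stats.multinomial(9, probs).pmf([a, b, c])
                if pmf <= pmf_obs * (1 + 1e-7):
                    total += pmf
        p = segregation_test(
            {IC.FULL: 0, IC.HALF: 9, IC.ABSENT: 0},
            {IC.FULL: 0.25, IC.HALF: 0.5, IC.ABSENT: 0.25},
        )
        assert p == pytest.approx(total)
        assert pmf_obs == pytest.approx(0.5**9)

    def test_monte_carlo_path_is_seeded_and_close_to_exact(self):
        observed = {IC.FULL: 4, IC.HALF: 14, IC.ABSENT: 7}
        expected = {IC.FULL: 0.25, IC.HALF: 0.5, IC.ABSENT: 0.25}
        p1 = segregation_test(observed, expected, seed=3)
        p2 = segregation_test(observed, expected, seed=3)
        assert p1 == p2  # n=25 > 20 triggers the Monte-Carlo path
        assert 0.0 < p1 < 1.0


class TestFlagNonMendelian:
    def make_obs(self, classes, genotype=(True, False)):
        return LocusObservation("locus", "MspI", classes, genotype)

    def test_all_half_selfed_panel_flagged(self):
        results = flag_non_mendelian([self.make_obs([IC.HALF] * 9)])
        (r,) = results
        assert r.verdict == "non_mendelian_flag"
        assert r.p_value < 0.05
        assert r.test == "exact_multinomial"

    def test_mendelian_looking_panel_not_flagged(self):
        classes = [IC.FULL] * 2 + [IC.HALF] * 5 + [IC.ABSENT] * 2
        (r,) = flag_non_mendelian([self.make_obs(classes)])
        assert r.verdict == "mendelian_consistent"

    def test_homozygous_parent_all_full_not_flagged(self):
        (r,) = flag_non_mendelian([self.make_obs([IC.FULL] * 9, (True, True))])
        assert r.p_value == pytest.approx(1.0)
        assert r.verdict == "mendelian_consistent"

    def test_other_class_excluded_and_counted(self):
        classes = [IC.HALF] * 8 + [IC.OTHER]
        (r,) = flag_non_mendelian([self.make_obs(classes)])
        assert r.n_other == 1
        assert sum(r.observed.values()) == 8

    def test_bh_adjustment_across_loci(self):
        observations = [
            self.make_obs([IC.HALF] * 9),
            self.make_obs([IC.FULL] * 2 + [IC.HALF] * 5 + [IC.ABSENT] * 2),
        ]
        results = flag_non_mendelian(observations)
        ps = [r.p_value for r in results]
        adj = stats.false_discovery_control(np.array(ps), method="bh")
        assert [r.p_adjusted for r in results] == pytest.approx(list(adj))
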