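import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragcycles.dynamics import (Composition, ModelParams, avg_payoffs,
                                 division_probs, division_time,
                                 fragmentation_expectation, growth_step,
                                 neutral_profile)
from fragcycles.games import PayoffMatrix
from fragcycles.lifecycles import LifeCycle, newborn_types

payoff = st.floats(-5, 5, allow_nan=False, allow_infinity=False)
games = st.builds(PayoffMatrix, payoff, payoff, payoff, payoff)
comps = st.tuples(st.integers(0, 7), st.integers(0, 7)).filter(
    lambda t: 1 <= t[0] + t[1] <= 7).map(lambda t: Composition(*t))


class TestAvgPayoffs:
    def test_homogeneous_pair_gets_diagonal(self, pd3):
        # beta is unconstrained here: with j = 0 it never enters the dynamics
        assert avg_payoffs(Composition(2, 0), pd3)[0] == pd3.a

    def test_mixed_pair_gets_cross_payoffs(self, pd3):
        assert avg_payoffs(Composition(1, 1), pd3) == (pd3.b, pd3.c)

    def test_solitary_cells_play_no_game(self, pd3):
        assert avg_payoffs(Composition(1, 0), pd3) == (0.0, 0.0)
        assert avg_payoffs(Composition(0, 1), pd3) == (0.0, 0.0)

    def test_self_interaction_variant(self, pd3):
        # groups include the focal cell's own type; solitary cells still idle
        assert avg_payoffs(Composition(1, 0), pd3, self_interaction=True) == (0.0, 0.0)
        a, b = avg_payoffs(Composition(2, 2), pd3, self_interaction=True)
        assert a == pytest.approx((2 * 1 + 2 * -3) / 4)
        assert b == pytest.approx((2 * 3 + 2 * 0) / 4)


class TestDivisionProbs:
    def test_neutral_is_proportional_to_counts(self, pd3):
        pA, pB = division_probs(Composition(1, 2), pd3, w=0.0)
        assert pA == pytest.approx(1 / 3) and pB == pytest.approx(2 / 3)

    def test_homogeneous_group_is_certain(self, pd3):
        assert division_probs(Composition(3, 0), pd3, w=0.004) == (1.0, 0.0)

    def test_exact_ratio_value(self, pd3):
        # (1,1): alpha = b = -3, beta = c = 3 at w = 0.01
        pA, _ = division_probs(Composition(1, 1), pd3, w=0.01)
        assert pA == pytest.approx(0.97 / 2.00, abs=1e-15)

    def test_too_strong_selection_rejected(self):
        harsh = PayoffMatrix(0, -200, 0, 0)
        with pytest.raises(ValueError, match="i=1, j=1"):
            division_probs(Composition(1, 1), harsh, w=0.01)

    @settings(derandomize=True, max_examples=80)
    @given(comps, games, st.floats(0, 0.01))
    def test_sums_to_one_and_matches_expansion(self, comp, g, w):
        """Exact ratio form: pA + pB = 1, and the first-order expansion
        pA ~ i/n + w ij/n^2 (alpha - beta) agrees to O(w^2)."""
        pA, pB = division_probs(comp, g, w)
        assert pA + pB == pytest.approx(1.0, abs=1e-12)
        i, j, n = comp.i, comp.j, comp.size
        alpha, beta = avg_payoffs(comp, g)
        approx = i / n + w * i * j / n ** 2 * (alpha - beta)
        assert abs(pA - approx) <= 10 * (g.max_abs_payoff ** 2) * w ** 2 + 1e-15


class TestDivisionTime:
    def test_neutral_reduces_to_profile(self, pd3):
        p = ModelParams(m=0.5, w=0.0)
        assert division_time(Composition(2, 1), pd3, p) == pytest.approx(
            neutral_profile(3))

    def test_solitary_time_is_T1(self, pd3):
        p = ModelParams(m=0.5, w=0.3)
        assert division_time(Composition(1, 0), pd3, p) == pytest.approx(math.log(2))

    def test_payoff_cancellation(self, pd3):
        # (1,1) under (1,-3,3,0): i*alpha + j*beta = -3 + 3 = 0
        p = ModelParams(m=0.5, w=0.01)
        assert division_time(Composition(1, 1), pd3, p) == pytest.approx(
            math.log(1.5))

    def test_explicit_profile_list(self, pd3):
        p = ModelParams(m=0.5, w=0.0, time_profile=[1.0, 2.0, 3.0])
        assert division_time(Composition(1, 1), pd3, p) == 2.0
        with pytest.raises(ValueError, match="no entry"):
            division_time(Composition(2, 2), pd3, p)


class TestNeutralProfile:
    def test_values(self):
        assert neutral_profile(1) == pytest.approx(math.log(2))
        assert neutral_profile(3) == pytest.approx(math.log(4 / 3))
        with pytest.raises(ValueError):
            neutral_profile(0)

    @pytest.mark.parametrize("k", range(1, 7))
    def test_doubling_time_is_log2(self, k):
        """The time to grow from k to 2k cells telescopes to ln 2."""
        total = sum(neutral_profile(n) for n in range(k, 2 * k))
        assert total == pytest.approx(math.log(2), abs=1e-14)


class TestGrowthStep:
    def test_symmetric_mixing(self, pd3):
        steps = growth_step(Composition(1, 1), pd3, ModelParams(m=0.5, w=0.0))
        probs = {(s.target.i, s.target.j): s.probability for s in steps}
        assert probs == pytest.approx({(3, 0): 0.125, (2, 1): 0.375,
                                       (1, 2): 0.375, (0, 3): 0.125})

    def test_no_switching_is_deterministic(self, pd3):
        steps = growth_step(Composition(2, 0), pd3, ModelParams(m=0.0, w=0.0))
        assert len(steps) == 1
        assert (steps[0].target, steps[0].probability) == (Composition(3, 0), 1.0)

    def test_solitary_daughter_distribution(self, pd3):
        m = 0.3
        steps = growth_step(Composition(1, 0), pd3, ModelParams(m=m, w=0.002))
        probs = {(s.target.i, s.target.j): s.probability for s in steps}
        assert probs == pytest.approx({(2, 0): (1 - m) ** 2,
                                       (1, 1): 2 * m * (1 - m),
                                       (0, 2): m ** 2})

    @settings(derandomize=True, max_examples=60)
    @given(comps, games, st.floats(0, 1), st.floats(0, 0.01))
    def test_probabilities_sum_to_one(self, comp, g, m, w):
        steps = growth_step(comp, g, ModelParams(m=m, w=w))
        assert sum(s.probability for s in steps) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(comps, games, st.floats(0.05, 0.95), st.floats(0, 0.01))
    def test_exchange_symmetry(self, comp, g, m, w):
        """Relabelling A<->B (and a<->d, b<->c) mirrors every kernel."""
        p = ModelParams(m=m, w=w)
        mirror = Composition(comp.j, comp.i)
        gs = g.swapped()
        assert avg_payoffs(comp, g) == tuple(reversed(avg_payoffs(mirror, gs)))
        assert division_probs(comp, g, w) == pytest.approx(
            tuple(reversed(division_probs(mirror, gs, w))))
        assert division_time(comp, g, p) == pytest.approx(
            division_time(mirror, gs, p))
        probs = {(s.target.i, s.target.j): s.probability
                 for s in growth_step(comp, g, p)}
        mirrored = {(s.target.j, s.target.i): s.probability
                    for s in growth_step(mirror, gs, p)}
        assert probs == pytest.approx(mirrored)


class TestFragmentation:
    def test_equal_split_expectation(self):
        lc = LifeCycle.from_name("2+2")
        e = fragmentation_expectation(Composition(2, 2), lc)
        assert e == pytest.approx([1 / 3, 4 / 3, 1 / 3])

    def test_homogeneous_parent(self):
        lc = LifeCycle.from_name("1+1+1")
        assert fragmentation_expectation(Composition(3, 0), lc) == pytest.approx(
            [3.0, 0.0])
        lc31 = LifeCycle.from_name("3+1")
        e = fragmentation_expectation(Composition(4, 0), lc31)
        types = newborn_types(lc31)
        by_type = dict(zip([(t.size, t.n_A) for t in types], e))
        assert by_type[(3, 3)] == pytest.approx(1.0)
        assert by_type[(1, 1)] == pytest.approx(1.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="size"):
            fragmentation_expectation(Composition(2, 1),
                                      LifeCycle.from_name("2+2"))

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 7), st.sampled_from(
        ["1+1", "2+1", "2+2", "3+1", "2+1+1", "4+3", "3+2+2", "2+2+2"]))
    def test_exact_conservation(self, i, name):
        """Random assignment conserves cells and A-cells identically."""
        lc = LifeCycle.from_name(name)
        i = min(i, lc.M)
        expect = fragmentation_expectation(Composition(i, lc.M - i), lc,
                                           exact=True)
        types = newborn_types(lc)
        assert sum(Fraction(t.size) * e for t, e in zip(types, expect)) == lc.M
        assert sum(Fraction(t.n_A) * e for t, e in zip(types, expect)) == i
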