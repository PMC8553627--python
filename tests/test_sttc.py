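"""Spike-time tiling coefficient: worked values, invariants, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meanet import (SpikeMatrix, SpikeTrain, STTCAnalyzer, ValidationError,
                    coincident_fraction, gen_correlated_trains, sttc_matrix,
                    sttc_pair, tiled_fraction)

from conftest import make_train
from oracles import oracle_coincident_fraction, oracle_sttc, oracle_tiled_fraction


class TestTiledFraction:
    def test_empty_train_tiles_nothing(self):
        assert tiled_fraction(make_train([]), 1.0) == 0.0

    def test_single_central_spike_closed_form(self):
        # tile [T/2 - dt, T/2 + dt] fully inside the window
        assert tiled_fraction(make_train([5.0]), 1.0) == pytest.approx(0.2)

    def test_two_disjoint_tiles(self):
        # T=10, dt=1, spikes {1, 5}: [0,2] u [4,6] -> 0.4
        assert tiled_fraction(make_train([1.0, 5.0]), 1.0) == pytest.approx(0.4)

    def test_overlapping_tiles_merge_not_sum(self):
        # spikes {1, 1.5}: [0,2] u [0.5,2.5] = [0,2.5] -> 0.25
        assert tiled_fraction(make_train([1.0, 1.5]), 1.0) == pytest.approx(0.25)

    def test_clipping_at_window_edges(self):
        # spike at 0.2: tile [-0.8,1.2] clipped to [0,1.2]
        assert tiled_fraction(make_train([0.2]), 1.0) == pytest.approx(0.12)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValidationError):
            tiled_fraction(make_train([1.0]), 0.0)


class TestCoincidentFraction:
    def test_identical_trains_fully_coincident(self):
        a = make_train([1.0, 2.0, 7.5])
        assert coincident_fraction(a, a, 0.5) == 1.0

    def test_worked_half_coincident(self):
        # A={1,5}, B={1.2,8}, dt=1: spike 1 matches 1.2, spike 5 matches nothing
        a, b = make_train([1.0, 5.0]), make_train([1.2, 8.0])
        assert coincident_fraction(a, b, 1.0) == pytest.approx(0.5)

    def test_empty_partner_gives_zero(self):
        assert coincident_fraction(make_train([1.0]), make_train([]), 1.0) == 0.0

    def test_empty_self_is_undefined(self):
        assert math.isnan(coincident_fraction(make_train([]), make_train([1.0]), 1.0))

    def test_window_is_closed(self):
        # |a - b| exactly dt counts
        a, b = make_train([1.0]), make_train([2.0])
        assert coincident_fraction(a, b, 1.0) == 1.0


class TestSTTCPair:
    def test_worked_example(self):
        # T=10, dt=1: T_A=T_B=0.4, P_A=P_B=0.5 -> 0.5*(0.1/0.8)*2 = 0.125
        a, b = make_train([1.0, 5.0]), make_train([1.2, 8.0])
        assert sttc_pair(a, b, 1.0) == pytest.approx(0.125)

    def test_self_comparison_is_one(self):
        a = make_train([1.0, 5.0])
        assert sttc_pair(a, a, 1.0) == pytest.approx(1.0)

    def test_empty_train_is_undefined(self):
        assert math.isnan(sttc_pair(make_train([]), make_train([1.0]), 1.0))
        assert math.isnan(sttc_pair(make_train([1.0]), make_train([]), 1.0))

    def test_zero_denominator_is_undefined_not_zero(self):
        # dt covers the whole window: T=P=1 on both sides -> denominator 0
        a, b = make_train([5.0]), make_train([4.0])
        assert math.isnan(sttc_pair(a, b, 20.0))

    def test_mismatched_durations_rejected(self):
        a = SpikeTrain(np.array([1.0]), 10.0)
        b = SpikeTrain(np.array([1.0]), 20.0)
        with pytest.raises(ValidationError):
            sttc_pair(a, b, 1.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_matches_bruteforce_oracle_and_invariants(self, data):
        """Sweep equals exhaustive enumeration; symmetric; bounded in [-1,1]."""
        duration = data.draw(st.floats(5.0, 50.0))
        dt = data.draw(st.floats(0.05, 3.0))
        def train(label):
            times = data.draw(st.lists(
                st.floats(0.0, duration, exclude_max=True,
                          allow_nan=False, allow_infinity=False),
                max_size=25, unique=True, min_size=0), label=label)
            return SpikeTrain(np.sort(np.array(times, dtype=np.float64)), duration)
        a, b = train("a"), train("b")
        got = sttc_pair(a, b, dt)
        expect = oracle_sttc(a.times, b.times, dt, duration)
        if math.isnan(expect):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expect, abs=1e-12)
            assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12
            assert sttc_pair(b, a, dt) == got


class TestSTTCMatrix:
    def test_identical_trains_give_unit_offdiagonal(self):
        t = [0.5, 2.0, 7.0]
        sm = SpikeMatrix.from_times([t, t, t], duration_s=10.0)
        m = sttc_matrix(sm, 1.0)
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_symmetry_and_unit_diagonal(self, small_matrix):
        m = sttc_matrix(small_matrix, 0.5)
        assert np.array_equal(m.values, m.values.T, equal_nan=True)
        assert m.values[0, 0] == 1.0
        assert math.isnan(m.values[2, 2])  # empty train
        assert np.all(np.isnan(m.values[2, :]))

    def test_matches_pairwise_loop(self):
        sm, _ = gen_correlated_trains(8, 2.0, 0.5, 120.0, seed=7)
        m = sttc_matrix(sm, 0.175)
        for i in range(8):
            for j in range(i + 1, 8):
                expect = sttc_pair(sm[i], sm[j], 0.175)
                assert m.values[i, j] == pytest.approx(expect, nan_ok=True)

    def test_analyzer_transform_equals_function(self, small_matrix):
        m1 = STTCAnalyzer(dt_s=0.5).fit_transform(small_matrix)
        m2 = sttc_matrix(small_matrix, 0.5)
        assert np.array_equal(m1.values, m2.values, equal_nan=True)
        assert m1.spike_matrix is small_matrix

    def test_analyzer_params_roundtrip(self):
        an = STTCAnalyzer(dt_s=0.2)
        assert an.get_params() == {"dt_s": 0.2}
        an.set_params(dt_s=0.3)
        assert an.dt_s == 0.3
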