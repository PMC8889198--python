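"""Deviation-from-IFD metrics and the brute-force equilibrium oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifdsim import (
    FunctionalResponse,
    enumerate_equilibria,
    intake_variance,
    is_ifd,
    matching_slope,
    summarize_batch,
)
from ifdsim.core import RunResult
from ifdsim.metrics import _compositions

TYPE_I = FunctionalResponse("type_I")


class TestIntakeVariance:
    @pytest.mark.parametrize(
        "Q, counts, expected",
        [
            ([10.0, 10.0], [1, 1], 0.0),
            ([12.0, 6.0], [2, 1], 0.0),  # intakes 6 and 6
            ([12.0, 6.0], [1, 1], 9.0),  # population variance of {12, 6}
        ],
    )
    def test_occupied_patch_variance(self, state_factory, Q, counts, expected):
        state = state_factory(Q, counts)
        assert intake_variance(state, TYPE_I) == pytest.approx(expected)

    def test_individual_weighting(self, state_factory):
        # intakes 6 (x2 consumers) and 3 (x1): weighted mean 5, var 2
        state = state_factory([12.0, 3.0], [2, 1])
        assert intake_variance(state, TYPE_I, weight="individual") == pytest.approx(2.0)
        assert intake_variance(state, TYPE_I) == pytest.approx(2.25)

    def test_include_empty_counts_zero_intake(self, state_factory):
        state = state_factory([10.0, 5.0], [1, 0])
        assert intake_variance(state, TYPE_I) == 0.0
        assert intake_variance(state, TYPE_I, include_empty=True) == pytest.approx(25.0)

    def test_error_cases(self, state_factory):
        empty = state_factory([10.0, 5.0], [0, 0])
        with pytest.raises(ValueError):
            intake_variance(empty, TYPE_I)
        state = state_factory([10.0, 5.0], [1, 1])
        with pytest.raises(ValueError):
            intake_variance(state, TYPE_I, weight="banana")


class TestMatchingSlope:
    def test_perfect_input_matching(self, state_factory):
        state = state_factory([16.0, 8.0, 4.0, 2.0], [8, 4, 2, 1])
        assert matching_slope(state) == pytest.approx(1.0)

    def test_uniform_counts_ignore_quality(self, state_factory):
        state = state_factory([16.0, 8.0, 4.0, 2.0], [3, 3, 3, 3])
        assert matching_slope(state) == pytest.approx(0.0)

    def test_against_normal_equations(self, state_factory):
        Q = np.array([16.0, 8.0, 4.0, 2.0])
        counts = np.array([4, 3, 2, 1])
        state = state_factory(Q, counts)
        x, y = np.log(Q), np.log(counts.astype(float))
        # hand-rolled OLS: slope = Sxy / Sxx
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert matching_slope(state) == pytest.approx(slope)

    def test_absent_when_degenerate(self, state_factory):
        assert matching_slope(state_factory([5.0, 5.0], [2, 3])) is None
        assert matching_slope(state_factory([5.0, 7.0], [0, 3])) is None


class TestEnumerateEquilibria:
    @pytest.mark.parametrize(
        "Q, N, expected",
        [
            ([10.0, 10.0], 2, {(1, 1)}),
            ([12.0, 6.0], 3, {(2, 1)}),
            ([12.0, 6.0], 0, {(0, 0)}),
        ],
    )
    def test_known_small_instances(self, Q, N, expected):
        assert enumerate_equilibria(Q, N, TYPE_I) == expected

    def test_guard(self):
        with pytest.raises(ValueError):
            enumerate_equilibria([1.0] * 7, 2)
        with pytest.raises(ValueError):
            enumerate_equilibria([1.0, 2.0], 13)

    @given(
        Q=st.lists(st.floats(0.5, 10.0), min_size=1, max_size=4),
        N=st.integers(1, 8),
    )
    @settings(derandomize=True, max_examples=60)
    def test_pure_equilibrium_always_exists(self, Q, N):
        """This congestion game always has at least one pure equilibrium."""
        assert enumerate_equilibria(Q, N, TYPE_I)

    def test_variance_reducing_moves_never_improve_the_mover(self, state_factory):
        """At an IFD, intake variance can only be reduced by moves that do
        not raise the mover's own intake — equilibria are local minima over
        the moves anyone would actually make."""
        fr = TYPE_I
        Q = [10.0, 4.0, 2.0]
        for N in range(1, 7):
            for counts in enumerate_equilibria(Q, N, fr):
                state = state_factory(Q, counts)
                v0 = intake_variance(state, fr)
                assert is_ifd(state, fr)
                for p in range(len(Q)):
                    if counts[p] == 0:
                        continue
                    for q in range(len(Q)):
                        if q == p:
                            continue
                        nc = list(counts)
                        nc[p] -= 1
                        nc[q] += 1
                        neighbour = state_factory(Q, nc)
                        gain = fr.per_capita(Q[q] / nc[q]) - fr.per_capita(Q[p] / counts[p])
                        if intake_variance(neighbour, fr) < v0 - 1e-12:
                            assert gain <= 1e-12


def test_compositions_cover_the_simplex():
    comps = list(_compositions(4, 3))
    assert len(comps) == 15  # C(4+2, 2)
    assert all(sum(c) == 4 for c in comps)
    assert len(set(comps)) == 15


def _fake_result(time, reason, reached, moves, var=0.0, slope=None):
    return RunResult(
        time_to_stop=time,
        stop_reason=reason,
        reached_true_ifd=reached,
        moves=np.asarray(moves),
        initial_counts=np.array([1, 1]),
        final_counts=np.array([1, 1]),
        quality=np.array([2.0, 1.0]),
        metrics={"intake_variance": var, "matching_slope": slope},
        seed=0,
        events=[],
    )


class TestSummarizeBatch:
    def test_all_true_ifd(self):
        results = [_fake_result(5.0, "true_ifd", True, [1, 0]) for _ in range(4)]
        report, table = summarize_batch(results)
        assert report.proportion_true_ifd == 1.0
        assert report.time_to_ifd == pytest.approx(5.0)
        assert len(table) == 4

    def test_half_reached(self):
        results = [
            _fake_result(5.0, "quiescence", True, [1, 0]),
            _fake_result(9.0, "quiescence", False, [2, 1]),
        ]
        report, table = summarize_batch(results)
        assert report.proportion_true_ifd == 0.5
        assert report.time_to_ifd == pytest.approx(5.0)  # only runs truly at the IFD
        assert report.max_moves_per_consumer == 2
        assert set(table["stop_reason"]) == {"quiescence"}

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            summarize_batch([])

    def test_stop_reason_consistency_enforced(self):
        with pytest.raises(AssertionError):
            _fake_result(5.0, "true_ifd", False, [0])
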