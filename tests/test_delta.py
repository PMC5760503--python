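"""Delta point layer: interval partitioning, Cox-process interval statistics
and the Delta point selection rule."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from deltapoint import (ConfigError, ParameterError, RunLengthState,
                        RunLengthTrajectory, SuspectedChangePoint,
                        conditioned_score, expected_count,
                        integrated_intensity, interval_count_probability,
                        interval_statistics, partition_intervals,
                        select_delta_point)
from deltapoint.delta import IntervalSpec, IntervalStats


def _traj_with_cp_probs(cp_probs, t_start=0):
    """Trajectory whose states carry prescribed change-point masses."""
    states = []
    for k, p in enumerate(cp_probs):
        probs = np.array([p, 1.0 - p])
        with np.errstate(divide="ignore"):  # p=0 -> log prob -inf is fine
            log_probs = np.log(probs)
        states.append(RunLengthState(t=t_start + k + 1,
                                     support=np.array([0, k + 1]),
                                     log_probs=log_probs))
    return RunLengthTrajectory(t_start=t_start, states=states)


def _cp(time, run_length, mass=0.02):
    return SuspectedChangePoint(time=time, run_length=run_length,
                                posterior_mass=mass)


class TestPartitionIntervals:
    def test_span_with_remainder(self):
        ivs = partition_intervals(200, 500, 40)
        assert len(ivs) == 8
        assert [len(iv) for iv in ivs] == [40] * 7 + [20]
        assert ivs[0].start == 200 and ivs[0].end == 240
        assert ivs[-1].start == 480 and ivs[-1].end == 500

    def test_single_interval_when_j_is_span(self):
        ivs = partition_intervals(0, 300, 300)
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end) == (0, 300)

    def test_one_interval_per_step_when_j_is_one(self):
        ivs = partition_intervals(0, 25, 1)
        assert len(ivs) == 25
        assert all(len(iv) == 1 for iv in ivs)

    def test_tiling_is_exact(self):
        ivs = partition_intervals(7, 100, 13)
        assert ivs[0].start == 7
        assert ivs[-1].end == 100
        for a, b in zip(ivs, ivs[1:]):
            assert b.start == a.end

    @settings(derandomize=True, max_examples=60)
    @given(start=st.integers(0, 500), span=st.integers(1, 600),
           j=st.integers(1, 100))
    def test_partition_tiles_any_span_exactly(self, start, span, j):
        """Intervals abut, cover (start, start+span] exactly, and only the
        last may be shorter than j."""
        ivs = partition_intervals(start, start + span, j)
        assert ivs[0].start == start
        assert ivs[-1].end == start + span
        for a, b in zip(ivs, ivs[1:]):
            assert b.start == a.end
        assert all(len(iv) == j for iv in ivs[:-1])
        assert 1 <= len(ivs[-1]) <= j

    def test_invalid_j_rejected(self):
        with pytest.raises(ConfigError):
            partition_intervals(0, 100, 0)


class TestIntervalStatistics:
    def test_mean_of_runlengths(self):
        iv = IntervalSpec(0, 100, 1)
        cps = [_cp(10, 10), _cp(20, 20), _cp(30, 30)]
        assert interval_statistics(cps, iv) == (3, 20.0)

    def test_empty_interval_flagged(self):
        iv = IntervalSpec(50, 60, 1)
        assert interval_statistics([_cp(10, 5)], iv) == (0, None)

    def test_boundaries_half_open_left(self):
        iv = IntervalSpec(10, 20, 1)
        cps = [_cp(10, 1), _cp(11, 2), _cp(20, 3), _cp(21, 4)]
        count, avg = interval_statistics(cps, iv)
        assert count == 2  # 11 and 20 inside; 10 and 21 outside
        assert avg == pytest.approx(2.5)

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            times = np.sort(rng.choice(200, size=12, replace=False))
            cps = [_cp(int(t), int(rng.integers(1, 50))) for t in times]
            lo = int(rng.integers(0, 100))
            iv = IntervalSpec(lo, lo + int(rng.integers(10, 80)), 1)
            inside = [c.run_length for c in cps if iv.start < c.time <= iv.end]
            expected = (len(inside), float(np.mean(inside)) if inside else None)
            assert interval_statistics(cps, iv) == expected


class TestIntegratedIntensity:
    def test_zero_intensity(self):
        traj = _traj_with_cp_probs([0.0] * 10)
        assert integrated_intensity(traj, IntervalSpec(0, 10, 1)) == 0.0

    def test_additivity(self):
        rng = np.random.default_rng(1)
        traj = _traj_with_cp_probs(rng.uniform(0, 0.3, size=30))
        m_ab = integrated_intensity(traj, IntervalSpec(0, 12, 1))
        m_bc = integrated_intensity(traj, IntervalSpec(12, 30, 2))
        m_ac = integrated_intensity(traj, IntervalSpec(0, 30, 1))
        assert m_ab + m_bc == pytest.approx(m_ac, abs=1e-14)

    def test_constant_intensity_closed_form(self):
        h = 0.05
        traj = _traj_with_cp_probs([h] * 40)
        assert integrated_intensity(traj, IntervalSpec(10, 30, 1)) == \
            pytest.approx(h * 20)

    def test_out_of_span_rejected(self):
        traj = _traj_with_cp_probs([0.1] * 10)
        with pytest.raises(ConfigError):
            integrated_intensity(traj, IntervalSpec(5, 15, 1))

    def test_expected_count_equals_integrated_intensity(self):
        rng = np.random.default_rng(2)
        traj = _traj_with_cp_probs(rng.uniform(0, 0.2, size=25))
        for lo, hi in [(0, 25), (3, 9), (10, 24)]:
            iv = IntervalSpec(lo, hi, 1)
            assert expected_count(traj, iv) == integrated_intensity(traj, iv)

    def test_expected_count_linear_in_intensity(self):
        p = np.linspace(0.01, 0.2, 20)
        t1 = _traj_with_cp_probs(p)
        t2 = _traj_with_cp_probs(2 * p)
        iv = IntervalSpec(0, 20, 1)
        assert expected_count(t2, iv) == pytest.approx(2 * expected_count(t1, iv))


class TestIntervalCountProbability:
    def test_empty_process(self):
        assert interval_count_probability(0.0, 0) == 1.0
        assert interval_count_probability(0.0, 3) == 0.0

    def test_closed_form_value(self):
        # m=2, k=3: 8 e^-2 / 6
        assert interval_count_probability(2.0, 3) == \
            pytest.approx(8 * math.exp(-2) / 6, rel=1e-12)
        assert interval_count_probability(2.0, 3) == pytest.approx(0.18045, abs=1e-5)

    def test_normalizes_over_counts(self):
        total = sum(interval_count_probability(3.0, k) for k in range(201))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            interval_count_probability(-0.5, 1)
        with pytest.raises(ParameterError):
            interval_count_probability(1.0, -2)


class TestConditionedScore:
    def _stats(self, count, avg, m):
        return IntervalStats(interval=IntervalSpec(0, 40, 1), count=count,
                             avg_runlength=avg, integrated_intensity=m,
                             count_prob=interval_count_probability(m, count),
                             score=None)

    def test_decreases_as_count_exceeds_intensity(self):
        scores = [conditioned_score(self._stats(c, 25.0, 2.0))
                  for c in (3, 4, 5, 6)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_increases_in_avg_runlength(self):
        scores = [conditioned_score(self._stats(2, avg, 1.5))
                  for avg in (5.0, 10.0, 50.0)]
        assert scores == sorted(scores)

    def test_finite_on_valid_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = self._stats(int(rng.integers(1, 10)),
                            float(rng.uniform(1, 200)),
                            float(rng.uniform(0.01, 5)))
            assert np.isfinite(conditioned_score(s))

    def test_undefined_for_empty_interval(self):
        with pytest.raises(ParameterError):
            conditioned_score(self._stats(0, None, 1.0))


class TestSelectDeltaPoint:
    def _uniform_traj(self, n=500, h=0.018):
        return _traj_with_cp_probs([h] * n)

    def test_single_interval_returns_longest_runlength(self):
        """j = M: the suspected change point with the globally longest run
        length is the Delta point."""
        traj = self._uniform_traj(300)
        cps = [_cp(40, 39), _cp(120, 79), _cp(260, 40)]
        ivs = partition_intervals(0, 300, 300)
        res = select_delta_point(cps, ivs, traj)
        assert res.delta_time == 120
        assert res.delta_runlength == 79

    def test_j_one_reduces_to_pointwise(self):
        """j = 1: every nonempty interval holds exactly one change point and
        selection reduces to the pointwise longest-run criterion."""
        traj = self._uniform_traj(100)
        cps = [_cp(10, 9), _cp(55, 44), _cp(80, 24)]
        ivs = partition_intervals(0, 100, 1)
        stats = [s for s in select_delta_point(cps, ivs, traj).all_stats
                 if s.count >= 1]
        assert all(s.count == 1 for s in stats)
        res = select_delta_point(cps, ivs, traj)
        assert res.delta_time == 55

    def test_lexicographic_rule_by_hand(self):
        """Intervals with (C=3, rbar=5), (C=1, rbar=2), (C=1, rbar=9): the
        third wins and its longest member is the Delta point."""
        traj = self._uniform_traj(120)
        cps = [_cp(5, 4), _cp(15, 6), _cp(25, 5),   # interval (0,40]: C=3
               _cp(50, 2),                           # interval (40,80]: C=1
               _cp(90, 9)]                           # interval (80,120]: C=1
        ivs = partition_intervals(0, 120, 40)
        res = select_delta_point(cps, ivs, traj)
        assert res.selected_interval.start == 80
        assert res.delta_time == 90
        assert res.delta_runlength == 9

    def test_no_changepoints_explicit_result(self):
        traj = self._uniform_traj(50)
        res = select_delta_point([], partition_intervals(0, 50, 10), traj)
        assert not res.found
        assert res.delta_time is None and res.selected_interval is None

    def test_selection_invariant_to_time_shift(self):
        shift = 137
        cps = [_cp(12, 11), _cp(47, 30), _cp(81, 20)]
        traj = self._uniform_traj(100)
        ivs = partition_intervals(0, 100, 25)
        base = select_delta_point(cps, ivs, traj)
        cps_s = [_cp(c.time + shift, c.run_length) for c in cps]
        traj_s = _traj_with_cp_probs([0.018] * 100, t_start=shift)
        ivs_s = partition_intervals(shift, 100 + shift, 25)
        shifted = select_delta_point(cps_s, ivs_s, traj_s)
        assert shifted.delta_time == base.delta_time + shift
        assert shifted.delta_runlength == base.delta_runlength

    def test_refining_j_keeps_isolated_delta_point(self):
        """A single dominant change point isolated by every interval length
        yields the same Delta point for all such j."""
        traj = self._uniform_traj(200)
        cps = [_cp(101, 100), _cp(160, 12)]
        answers = set()
        for j in (200, 100, 50, 25, 10, 1):
            res = select_delta_point(cps, partition_intervals(0, 200, j), traj)
            answers.add(res.delta_time)
        assert answers == {101}

    def test_selected_interval_pareto_undominated(self):
        rng = np.random.default_rng(5)
        traj = self._uniform_traj(200)
        for _ in range(20):
            times = np.sort(rng.choice(np.arange(1, 201), size=8, replace=False))
            cps = [_cp(int(t), int(rng.integers(1, 150))) for t in times]
            res = select_delta_point(cps, partition_intervals(0, 200, 40), traj)
            sel = next(s for s in res.all_stats
                       if s.interval == res.selected_interval)
            for s in res.all_stats:
                if s.count >= 1 and s.interval != sel.interval:
                    assert not (s.count < sel.count
                                and s.avg_runlength > sel.avg_runlength)

    def test_delta_runlength_is_interval_maximum(self):
        traj = self._uniform_traj(100)
        cps = [_cp(12, 5), _cp(25, 30), _cp(33, 8)]
        res = select_delta_point(cps, partition_intervals(0, 100, 40), traj)
        assert res.delta_time == 25
        assert res.delta_runlength == 30
        inside = [c.run_length for c in cps
                  if res.selected_interval.contains(c.time)]
        assert res.delta_runlength == max(inside)
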