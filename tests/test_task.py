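"""Staircase engine: interval bookkeeping, convergence, trial accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discountlab.task import (
    EXPERIENTIAL,
    HYPOTHETICAL,
    Boundary,
    Choice,
    ConfigError,
    SessionError,
    TaskConfig,
    TaskKind,
    TrialRecord,
    enumerate_threshold_sessions,
    extract_indifference_points,
    init_session,
    processing_screen_duration,
    record_choice,
    run_session,
    select_next_trial,
    trials_to_convergence,
)


def threshold_policy(level):
    """Accept the immediate option iff its level index is >= level."""

    def policy(trial):
        return (Choice.IMMEDIATE if trial.presented_level_index >= level
                else Choice.DELAYED)

    return policy


class TestInitSession:
    def test_one_full_interval_per_delay_and_run(self):
        state = init_session(EXPERIENTIAL, seed=0)
        assert len(state.intervals) == 22
        assert all(iv.lo == 0 and iv.hi == 11 and not iv.converged
                   for iv in state.intervals.values())

    def test_hypothetical_grid_gives_14_level_intervals(self):
        state = init_session(HYPOTHETICAL, seed=0)
        assert len(state.intervals) == 22
        assert all(iv.hi == 15 for iv in state.intervals.values())

    def test_same_seed_reproduces_first_trial(self):
        t1 = select_next_trial(init_session(EXPERIENTIAL, seed=3))
        t2 = select_next_trial(init_session(EXPERIENTIAL, seed=3))
        assert (t1.delay, t1.presented_level_index) == (t2.delay, t2.presented_level_index)

    @pytest.mark.parametrize("bad", [
        dict(immediate_values=(0.5, 0.4, 1.0)),            # not increasing
        dict(immediate_values=(0.1, 0.5)),                 # max != delayed
        dict(delays=(5.0, 3.0)),                           # not increasing
        dict(n_runs=0),
        dict(start_pool=(0, 5)),
    ])
    def test_invalid_config_is_rejected(self, bad):
        base = dict(task_kind=TaskKind.EXPERIENTIAL,
                    immediate_values=(0.1, 0.5, 1.0), delayed_value=1.0,
                    delays=(1.0, 5.0), delay_units="seconds", n_runs=2,
                    start_pool=(1, 2))
        with pytest.raises(ConfigError):
            TaskConfig(**{**base, **bad})


class TestBisection:
    def test_first_trial_drawn_from_start_pool(self):
        seen = set()
        for seed in range(40):
            state = init_session(EXPERIENTIAL, seed=seed)
            seen.add(select_next_trial(state).presented_level_index)
        assert seen == {4, 5, 6}

    def test_printed_trace_under_occlusion_axis_mirror(self):
        """The published example runs on the occlusion axis (level 1 = least
        occluded): start [1,10], wait at 5 -> [1,5], next presentation 3.
        On this package's ascending-value axis the identical session is the
        mirror image level <-> 11 - level: wait at presented level 6 narrows
        to the upper half and the next midpoint is the mirror of 3."""
        state = init_session(EXPERIENTIAL, seed=0)
        key = (5, 0)  # the 10-s delay, first run
        iv = state.intervals[key]
        trial = TrialRecord(0, "p1", 10.0, 5, presented_level_index=6,
                            presented_value=0.80, run_index=0)
        record_choice(state, trial, Choice.DELAYED)
        assert (iv.lo, iv.hi) == (6, 11)
        assert iv.midpoint() == 11 - 3

    def test_immediate_choice_lowers_upper_bound(self):
        state = init_session(EXPERIENTIAL, seed=0)
        iv = state.intervals[(0, 0)]
        trial = TrialRecord(0, "p1", 1.0, 0, 5, 0.70, 0)
        record_choice(state, trial, Choice.IMMEDIATE)
        assert (iv.lo, iv.hi) == (0, 5)

    def test_interval_width_never_increases(self):
        state = init_session(EXPERIENTIAL, seed=1)
        widths = {k: iv.width for k, iv in state.intervals.items()}
        policy = threshold_policy(7)
        while not state.complete:
            trial = select_next_trial(state)
            record_choice(state, trial, policy(trial))
            key = (trial.delay_index, trial.run_index)
            assert state.intervals[key].width < widths[key]
            widths[key] = state.intervals[key].width

    def test_recording_on_converged_interval_raises(self):
        state = init_session(EXPERIENTIAL, seed=0)
        iv = state.intervals[(0, 0)]
        iv.lo, iv.hi = 5, 6
        trial = TrialRecord(0, "p1", 1.0, 0, 6, 0.80, 0)
        with pytest.raises(SessionError):
            record_choice(state, trial, Choice.IMMEDIATE)


class TestExtraction:
    @pytest.mark.parametrize("threshold", range(1, 11))
    def test_exact_threshold_recovery_for_every_start_seed(self, threshold):
        """A deterministic threshold agent's indifference point is its
        threshold level, for every delay, run and random start level."""
        for seed in (0, 1, 2):
            _, points = run_session(EXPERIENTIAL, threshold_policy(threshold), seed)
            assert {p.level for p in points} == {threshold}
            assert all(p.value == EXPERIENTIAL.level_value(threshold) for p in points)

    def test_always_delayed_agent_flagged_at_maximum(self):
        _, points = run_session(EXPERIENTIAL, lambda t: Choice.DELAYED, seed=0)
        assert all(p.value == 1.0 and p.at_boundary is Boundary.ALWAYS_DELAYED
                   for p in points)

    def test_always_immediate_agent_flagged_at_minimum(self):
        _, points = run_session(EXPERIENTIAL, lambda t: Choice.IMMEDIATE, seed=0)
        assert all(p.value == 0.13 and p.at_boundary is Boundary.ALWAYS_IMMEDIATE
                   for p in points)

    def test_two_runs_give_two_points_per_delay(self):
        _, points = run_session(EXPERIENTIAL, threshold_policy(6), seed=0)
        assert len(points) == 22
        per_delay = {}
        for p in points:
            per_delay.setdefault(p.delay, []).append(p)
        assert all(len(v) == 2 for v in per_delay.values())

    def test_level_six_maps_to_eighty_percent(self):
        _, points = run_session(EXPERIENTIAL, threshold_policy(6), seed=1)
        assert points[0].value == pytest.approx(0.80)

    def test_extraction_before_convergence_raises(self):
        state = init_session(EXPERIENTIAL, seed=0)
        with pytest.raises(SessionError):
            extract_indifference_points(state)


class TestProcessingScreen:
    def make(self, delays, choices):
        return [TrialRecord(i, "p", d, 0, 5, 0.7, 0, choice=c)
                for i, (d, c) in enumerate(zip(delays, choices))]

    def test_all_delayed_gives_base_five_seconds(self):
        w = self.make([2, 4, 6, 8, 10], [Choice.DELAYED] * 5)
        assert processing_screen_duration(w) == 5.0

    @pytest.mark.parametrize("imm_delays, expected", [
        ({2, 4, 6, 8, 10}, 35.0),
        ({4, 6}, 15.0),
        (set(), 5.0),
    ])
    def test_sums_non_chosen_delays(self, imm_delays, expected):
        delays = [2, 4, 6, 8, 10]
        choices = [Choice.IMMEDIATE if d in imm_delays else Choice.DELAYED
                   for d in delays]
        assert processing_screen_duration(self.make(delays, choices)) == expected

    def test_wrong_window_size_raises(self):
        with pytest.raises(ValueError):
            processing_screen_duration(self.make([1, 2, 4], [Choice.DELAYED] * 3))

    @given(st.lists(st.booleans(), min_size=10, max_size=10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additive_over_disjoint_windows(self, flags):
        delays = [1, 2, 4, 6, 8, 10, 12, 14, 16, 20]
        choices = [Choice.IMMEDIATE if f else Choice.DELAYED for f in flags]
        w = self.make(delays, choices)
        total = processing_screen_duration(w[:5]) + processing_screen_duration(w[5:])
        assert total == 10.0 + sum(d for d, f in zip(delays, flags) if f)


class TestTrialAccounting:
    def test_session_terminates_within_bound(self):
        trials, _ = run_session(EXPERIENTIAL, threshold_policy(7), seed=5)
        assert len(trials) <= 10 * 11 * 2

    def test_cell_counts_depend_only_on_start_and_threshold(self):
        enum = enumerate_threshold_sessions(EXPERIENTIAL)
        assert enum["n_cells"] == 22
        counts = [c for row in enum["table"].values() for c in row.values()]
        assert set(counts) <= {3, 4}

    def test_mean_trials_per_cell_between_three_and_four(self):
        enum = enumerate_threshold_sessions(EXPERIENTIAL)
        assert 3.0 <= enum["mean_trials_per_cell"] <= 4.0

    def test_session_totals_stay_within_enumeration_envelope(self):
        """Every session total lies between the 3-trial and 4-trial per-cell
        extremes (22 cells), and agents switching inside the delay grid mix
        both cell depths rather than pinning either extreme."""
        from discountlab.agents import Agent

        totals = []
        for seed, b in [(0, 1.5), (1, 2.0), (2, 2.5), (3, 3.0)]:
            ag = Agent(model="logistic", a=4.3, b=b, tau=0.0)
            rng = np.random.default_rng(seed)
            trials, _ = run_session(EXPERIENTIAL, ag.policy(EXPERIENTIAL, rng), seed)
            totals.append(len(trials))
        assert all(66 <= t <= 88 for t in totals)
        assert any(t < 88 for t in totals) and any(t > 66 for t in totals)
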