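"""Event detection, the alternation rule, turn exclusion, toe matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitcycles import (
    EventConfig,
    InsufficientCyclesError,
    detect_extrema,
    detect_gait_events,
    enforce_alternation,
    exclude_turn_window,
    match_toe_valleys,
    smooth,
)
from gaitcycles.events import PEAK, VALLEY, GaitEvent


def _ev(kind, time, height):
    return GaitEvent(kind=kind, time=time, height=height)


class TestDetection:
    def test_noiseless_trial_yields_one_cycle_per_truth_cycle(
        self, noiseless_trial
    ):
        trial, gt = noiseless_trial
        for side in ("left", "right"):
            series = detect_gait_events(
                trial.coordinate(f"{side}_heel", "z"),
                trial.sampling_rate,
                side=side,
            )
            assert series.n_cycles == gt.side(side).n_cycles == 5
            # 6 valleys and 5 peaks once trimmed to complete cycles
            kinds = [e.kind for e in series.events]
            assert kinds.count(VALLEY) == 6
            assert kinds.count(PEAK) == 5

    def test_noisy_trial_keeps_cycle_count(self, noisy_trial):
        trial, gt = noisy_trial
        for side in ("left", "right"):
            series = detect_gait_events(
                trial.coordinate(f"{side}_heel", "z"),
                trial.sampling_rate,
                side=side,
            )
            assert series.n_cycles == gt.side(side).n_cycles

    def test_valley_times_match_ground_truth(self, noiseless_trial):
        trial, gt = noiseless_trial
        fs = trial.sampling_rate
        for side in ("left", "right"):
            series = detect_gait_events(
                trial.coordinate(f"{side}_heel", "z"), fs, side=side
            )
            detected = [c.valley_start.time for c in series.cycles]
            detected.append(series.cycles[-1].valley_end.time)
            assert np.allclose(
                detected, gt.side(side).strike_times, atol=1.0 / fs
            )

    def test_flat_signal_raises_insufficient_cycles(self):
        with pytest.raises(InsufficientCyclesError):
            detect_extrema(np.zeros(1000), 100.0)

    def test_detected_peak_heights_match_step_height(self, noiseless_trial):
        trial, gt = noiseless_trial
        series = detect_gait_events(
            trial.coordinate("left_heel", "z"), trial.sampling_rate
        )
        for cyc in series.cycles:
            assert cyc.peak.height == pytest.approx(21.2, abs=0.1)
            assert cyc.valley_start.height == pytest.approx(0.0, abs=0.1)


class TestAlternation:
    def test_extra_peak_between_valleys_removed(self):
        candidates = [
            _ev(VALLEY, 1.0, 0.0),
            _ev(PEAK, 1.3, 18.0),
            _ev(PEAK, 1.5, 12.0),
            _ev(VALLEY, 2.3, 0.0),
        ]
        series = enforce_alternation(candidates)
        assert series.n_cycles == 1
        assert series.cycles[0].peak.time == 1.3

    def test_already_alternating_unchanged(self):
        candidates = [
            _ev(VALLEY, 0.0, 0.0),
            _ev(PEAK, 0.9, 20.0),
            _ev(VALLEY, 1.3, 0.1),
            _ev(PEAK, 2.2, 19.0),
            _ev(VALLEY, 2.6, 0.0),
        ]
        series = enforce_alternation(candidates)
        assert [e.time for e in series.events] == [0.0, 0.9, 1.3, 2.2, 2.6]

    def test_equal_height_peaks_keep_earliest(self):
        candidates = [
            _ev(VALLEY, 0.0, 0.0),
            _ev(PEAK, 0.8, 15.0),
            _ev(PEAK, 1.0, 15.0),
            _ev(VALLEY, 1.3, 0.0),
        ]
        series = enforce_alternation(candidates)
        assert series.cycles[0].peak.time == 0.8

    def test_leading_and_trailing_peaks_trimmed(self):
        candidates = [
            _ev(PEAK, 0.2, 10.0),
            _ev(VALLEY, 0.5, 0.0),
            _ev(PEAK, 1.0, 10.0),
            _ev(VALLEY, 1.5, 0.0),
            _ev(PEAK, 2.0, 10.0),
        ]
        series = enforce_alternation(candidates)
        events = series.events
        assert events[0].kind == VALLEY and events[-1].kind == VALLEY
        assert series.n_cycles == 1

    def test_too_few_valleys_raise(self):
        with pytest.raises(InsufficientCyclesError):
            enforce_alternation([_ev(VALLEY, 0.0, 0.0), _ev(PEAK, 1.0, 5.0)])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(
        st.tuples(
            st.sampled_from([PEAK, VALLEY]),
            st.floats(0.0, 60.0, allow_nan=False),
            st.floats(-5.0, 30.0, allow_nan=False),
        ),
        min_size=0, max_size=40, unique_by=lambda c: c[1],
    ))
    def test_output_always_alternates_and_is_idempotent(self, raw):
        candidates = [_ev(k, t, h) for k, t, h in raw]
        try:
            series = enforce_alternation(candidates)
        except InsufficientCyclesError:
            return
        series.validate()  # alternation + height invariants
        again = enforce_alternation(series.events)
        assert [
            (e.kind, e.time, e.height) for e in again.events
        ] == [(e.kind, e.time, e.height) for e in series.events]


class TestTurnExclusion:
    @pytest.fixture
    def five_cycles(self):
        events = []
        for k in range(6):
            events.append(_ev(VALLEY, float(k), 0.0))
            if k < 5:
                events.append(_ev(PEAK, k + 0.7, 20.0))
        return enforce_alternation(events)

    def test_window_outside_trial_is_identity(self, five_cycles):
        out = exclude_turn_window(five_cycles, (100.0, 110.0))
        assert out.n_cycles == 5

    def test_window_covering_one_cycle_drops_it_whole(self, five_cycles):
        out = exclude_turn_window(five_cycles, (2.1, 2.9))  # cycle 3 of 5
        assert out.n_cycles == 4
        spans = [(c.valley_start.time, c.valley_end.time) for c in out.cycles]
        assert (2.0, 3.0) not in spans
        out.validate()

    def test_window_covering_everything_empties_series(self, five_cycles):
        out = exclude_turn_window(five_cycles, (-1.0, 10.0))
        assert out.n_cycles == 0

    def test_boundary_overlap_drops_both_touching_cycles(self, five_cycles):
        out = exclude_turn_window(five_cycles, (1.9, 2.1))
        assert out.n_cycles == 3


class TestToeMatching:
    def test_toe_valleys_match_ground_truth(self, noiseless_trial):
        trial, gt = noiseless_trial
        fs = trial.sampling_rate
        for side in ("left", "right"):
            series = detect_gait_events(
                trial.coordinate(f"{side}_heel", "z"), fs, side=side
            )
            toe_raw = trial.coordinate(f"{side}_toe", "z")
            toe = match_toe_valleys(
                series, smooth(toe_raw, fs), fs, raw_toe_z=toe_raw
            )
            for t, truth_t in zip(toe.times, gt.side(side).toe_valley_times):
                assert t == pytest.approx(truth_t, abs=1.0 / fs)

    def test_constant_toe_signal_flags_all_cycles(self, noiseless_trial):
        trial, _ = noiseless_trial
        fs = trial.sampling_rate
        series = detect_gait_events(
            trial.coordinate("left_heel", "z"), fs
        )
        toe = match_toe_valleys(series, np.full(trial.n_samples, 3.0), fs)
        assert all(t is None for t in toe.times)
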