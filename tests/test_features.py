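"""Per-cycle parameter arithmetic and condition summaries."""

import numpy as np
import pytest

from gaitcycles import (
    InsufficientCyclesError,
    compute_cycles,
    summarize_condition,
)
from gaitcycles.events import (
    PEAK,
    VALLEY,
    CycleEvents,
    EventSeries,
    GaitEvent,
    ToeValleySet,
)


def _series(triples, side="left"):
    cycles = []
    for v0, p, v1 in triples:
        cycles.append(
            CycleEvents(
                valley_start=GaitEvent(VALLEY, v0[0], v0[1]),
                peak=GaitEvent(PEAK, p[0], p[1]),
                valley_end=GaitEvent(VALLEY, v1[0], v1[1]),
            )
        )
    return EventSeries(side=side, cycles=cycles)


class TestCycleArithmetic:
    def test_single_cycle_durations(self):
        """Valleys at 1.00/2.29 s with the peak at 1.94 s give the
        unassisted-walking means: GCT 1.29, SW 0.35, ST 0.94 s."""
        series = _series([(((1.00), 0.0), (1.94, 21.0), (2.29, 0.0))])
        rec = compute_cycles(series, None, None, fs=100.0)[0]
        assert rec.gct == pytest.approx(1.29)
        assert rec.sw == pytest.approx(0.35)
        assert rec.st == pytest.approx(0.94)
        assert rec.sw + rec.st == rec.gct  # exact identity

    def test_double_support_split_at_toe_valley(self):
        series = _series([((1.00, 0.0), (1.94, 21.0), (2.29, 0.0))])
        toe = ToeValleySet(times=[1.24])
        rec = compute_cycles(series, toe, None, fs=100.0)[0]
        assert rec.ids == pytest.approx(0.24)
        assert rec.tds == pytest.approx(0.70)

    def test_step_height_from_event_heights(self):
        series = _series([((0.0, 1.5), (0.9, 22.7), (1.3, 1.5))])
        rec = compute_cycles(series, None, None, fs=100.0)[0]
        assert rec.sh == pytest.approx(21.2)

    def test_first_cycle_has_no_step_length(self, noiseless_trial):
        trial, _ = noiseless_trial
        from gaitcycles import detect_gait_events

        fs = trial.sampling_rate
        series = detect_gait_events(trial.coordinate("left_heel", "z"), fs)
        recs = compute_cycles(
            series, None, trial.coordinate("left_heel", "x"), fs
        )
        assert recs[0].sl is None and recs[0].vel is None
        for rec in recs[1:]:
            assert rec.sl == pytest.approx(93.0, abs=0.1)
            assert rec.vel * rec.gct == rec.sl  # exact by definition

    def test_misordered_toe_valley_flags_cycle(self):
        series = _series([((1.00, 0.0), (1.94, 21.0), (2.29, 0.0))])
        toe = ToeValleySet(times=[2.00])  # after the peak: negative TDS
        rec = compute_cycles(series, toe, None, fs=100.0)[0]
        assert not rec.valid
        assert "negative_tds" in rec.flags

    def test_missing_toe_valley_flagged_not_fatal(self):
        series = _series([((1.0, 0.0), (1.9, 20.0), (2.3, 0.0))])
        rec = compute_cycles(
            series, ToeValleySet(times=[None]), None, fs=100.0
        )[0]
        assert rec.valid
        assert rec.ids is None and rec.tds is None
        assert "toe_valley_missing" in rec.flags

    def test_empty_series_raises(self):
        with pytest.raises(InsufficientCyclesError):
            compute_cycles(
                EventSeries(side="left", cycles=[]), None, None, 100.0
            )

    def test_time_scaling_property(self):
        """Scaling all event times by a scales durations by a and leaves
        heights untouched."""
        base = [((1.0, 0.0), (1.9, 20.0), (2.3, 0.0)),
                ((2.3, 0.0), (3.2, 20.0), (3.6, 0.0))]
        a = 1.7
        scaled = [
            tuple((t * a, h) for t, h in triple) for triple in base
        ]
        toe_b = ToeValleySet(times=[1.25, 2.55])
        toe_s = ToeValleySet(times=[1.25 * a, 2.55 * a])
        recs_b = compute_cycles(_series(base), toe_b, None, 100.0)
        recs_s = compute_cycles(_series(scaled), toe_s, None, 100.0)
        for rb, rs in zip(recs_b, recs_s):
            for attr in ("gct", "sw", "st", "ids", "tds"):
                assert getattr(rs, attr) == pytest.approx(
                    a * getattr(rb, attr)
                )
            assert rs.sh == pytest.approx(rb.sh)


class TestSummaries:
    def test_identical_records_have_zero_sd(self):
        series = _series(
            [((k, 0.0), (k + 0.9, 20.0), (k + 1.3, 0.0)) for k in (0.0, 1.3, 2.6)]
        )
        # non-contiguous triples are fine: only durations matter here
        recs = compute_cycles(series, None, None, 100.0)
        summary = summarize_condition(recs, "c")
        for stat in summary.stats.values():
            assert stat.sd == pytest.approx(0.0, abs=1e-12)

    def test_phase_ratios_internally_consistent(self, noisy_trial):
        trial, _ = noisy_trial
        from gaitcycles import detect_gait_events, match_toe_valleys, smooth

        fs = trial.sampling_rate
        series = detect_gait_events(trial.coordinate("left_heel", "z"), fs)
        toe_raw = trial.coordinate("left_toe", "z")
        toe = match_toe_valleys(
            series, smooth(toe_raw, fs), fs, raw_toe_z=toe_raw
        )
        recs = compute_cycles(
            series, toe, trial.coordinate("left_heel", "x"), fs
        )
        s = summarize_condition(recs, "c")
        assert s.ratios["ids_st"] == pytest.approx(
            100.0 * s.ratios["ids_gct"] / s.ratios["st_gct"], abs=1e-9
        )
        assert s.ratios["tds_st"] == pytest.approx(
            100.0 * s.ratios["tds_gct"] / s.ratios["st_gct"], abs=1e-9
        )
        assert 0 <= s.ratios["ids_gct"] <= 100

    def test_summary_recovers_generating_values(self):
        """A cohort generated at GCT 1.4 s / 27% swing summarizes back to
        the generating parameters."""
        from gaitcycles import GaitScenario, generate_trial
        from gaitcycles.validation import _extract_records
        from gaitcycles.events import EventConfig

        scenario = GaitScenario(
            n_cycles_per_side=10,
            gct_left=1.4, gct_right=1.4,
            swing_fraction_left=0.27, swing_fraction_right=0.27,
            noise_sd=0.1, seed=21,
        )
        trial, _ = generate_trial(scenario)
        recs, _ = _extract_records(trial, "left", EventConfig())
        s = summarize_condition(recs, "mm")
        assert s.stats["gct"].mean == pytest.approx(1.4, abs=0.01)
        assert s.stats["sw"].mean == pytest.approx(0.27 * 1.4, abs=0.01)
        assert s.stats["sh"].mean == pytest.approx(21.2, abs=0.2)
        assert s.stats["sl"].mean == pytest.approx(93.0, abs=0.5)

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientCyclesError):
            summarize_condition([], "c")
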