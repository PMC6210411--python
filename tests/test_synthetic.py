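"""Generator contracts: determinism, ground-truth arithmetic, invariants."""

import numpy as np
import pytest

from gaitcycles import (
    ConfigurationError,
    GaitScenario,
    generate_trial,
    ground_truth_parameters,
)
from gaitcycles.synthetic import SideTruth, GroundTruth


def test_same_seed_gives_bit_identical_trials():
    scenario = GaitScenario(noise_sd=0.15, seed=99)
    t1, _ = generate_trial(scenario)
    t2, _ = generate_trial(scenario)
    for name in t1.markers:
        assert np.array_equal(t1.markers[name], t2.markers[name])


def test_different_seed_changes_noise():
    a, _ = generate_trial(GaitScenario(noise_sd=0.15, seed=1))
    b, _ = generate_trial(GaitScenario(noise_sd=0.15, seed=2))
    assert not np.array_equal(a.markers["left_heel"], b.markers["left_heel"])


def test_constant_gct_by_construction(noiseless_trial):
    _, gt = noiseless_trial
    for rec in ground_truth_parameters(gt):
        assert rec.gct == pytest.approx(1.29, abs=1e-12)


def test_swing_plus_stance_equals_cycle_exactly(noiseless_trial):
    _, gt = noiseless_trial
    for rec in ground_truth_parameters(gt):
        assert rec.sw + rec.st == rec.gct


def test_heel_z_range_equals_step_height():
    scenario = GaitScenario(
        noise_sd=0.0, step_height_left=20.0, step_height_right=20.0, seed=0
    )
    trial, _ = generate_trial(scenario)
    for side in ("left", "right"):
        z = trial.coordinate(f"{side}_heel", "z")
        # commanded amplitude, up to the sample grid missing the exact apex
        assert np.max(z) - np.min(z) == pytest.approx(20.0, abs=0.05)


def test_event_times_strictly_increasing(noiseless_trial):
    _, gt = noiseless_trial
    for side in ("left", "right"):
        tr = gt.side(side)
        for series in (tr.strike_times, tr.peak_times, tr.toe_valley_times):
            assert np.all(np.diff(series) > 0)


def test_sides_offset_by_half_cycle(noiseless_trial):
    _, gt = noiseless_trial
    offset = gt.right.strike_times[0] - gt.left.strike_times[0]
    assert offset == pytest.approx(0.5 * gt.scenario.gct_right)


def test_truth_gct_from_strike_times():
    """A cycle from strikes at 1.00 s and 2.29 s lasts 1.29 s."""
    truth = SideTruth(
        strike_times=np.array([1.00, 2.29]),
        peak_times=np.array([1.94]),
        toe_valley_times=np.array([1.24]),
        valley_heights=np.zeros(2),
        peak_heights=np.array([21.0]),
        step_length=93.0,
    )
    gt = GroundTruth(left=truth, right=truth, scenario=GaitScenario())
    rec = ground_truth_parameters(gt)[0]
    assert rec.gct == pytest.approx(1.29)
    assert rec.sw == pytest.approx(0.35)
    assert rec.st == pytest.approx(0.94)
    assert rec.ids == pytest.approx(0.24)
    assert rec.tds == pytest.approx(0.70)


def test_symmetric_scenario_gives_identical_sides(noiseless_trial):
    _, gt = noiseless_trial
    recs = ground_truth_parameters(gt)
    left = [r for r in recs if r.side == "left"]
    right = [r for r in recs if r.side == "right"]
    for a, b in zip(left, right):
        assert a.gct == pytest.approx(b.gct)
        assert a.sw == pytest.approx(b.sw)
        assert a.sh == pytest.approx(b.sh)


def test_asymmetric_cycle_times_give_ten_percent_index():
    from gaitcycles import asymmetry_index

    scenario = GaitScenario(gct_left=1.0, gct_right=0.9, noise_sd=0.0, seed=0)
    _, gt = generate_trial(scenario)
    recs = ground_truth_parameters(gt)
    mean = {
        side: np.mean([r.gct for r in recs if r.side == side])
        for side in ("left", "right")
    }
    assert asymmetry_index(mean["left"], mean["right"]) == pytest.approx(10.0)


def test_turn_rotates_heading_but_keeps_vertical_cycling():
    base = GaitScenario(n_cycles_per_side=8, noise_sd=0.0, seed=0)
    turned = GaitScenario(
        n_cycles_per_side=8, noise_sd=0.0, seed=0,
        turn_start=4.0, turn_duration=2.0,
    )
    t0, _ = generate_trial(base)
    t1, _ = generate_trial(turned)
    # identical vertical signal, rotated horizontal path
    assert np.allclose(
        t0.coordinate("left_heel", "z"), t1.coordinate("left_heel", "z")
    )
    x1 = t1.coordinate("left_heel", "x")
    y1 = t1.coordinate("left_heel", "y")
    fs = t1.sampling_rate
    after = int(7.0 * fs)
    # after the 90-degree turn, progression moves along y, not x
    assert abs(x1[-1] - x1[after]) < 5.0
    assert y1[-1] - y1[after] > 20.0
    assert t1.turn_window == (4.0, 6.0)


@pytest.mark.parametrize(
    "field, value",
    [
        ("gct_left", -1.0),
        ("step_height_right", 0.0),
        ("noise_sd", -0.1),
        ("swing_fraction_left", 0.6),
        ("n_cycles_per_side", 0),
        ("turn_duration", 2.0),  # without turn_start
    ],
)
def test_invalid_scenario_names_offending_field(field, value):
    scenario = GaitScenario(**{field: value})
    with pytest.raises(ConfigurationError) as err:
        scenario.validate()
    assert field.split("_")[0] in str(err.value)


def test_phase_budget_must_leave_single_support():
    scenario = GaitScenario(
        swing_fraction_left=0.3, ids_fraction=0.4, tds_fraction=0.4
    )
    with pytest.raises(ConfigurationError):
        scenario.validate()


def test_scenario_roundtrip_via_yaml(tmp_path):
    from gaitcycles import load_scenario

    path = tmp_path / "scenario.yaml"
    path.write_text(
        "gct_left: 1.5\ngct_right: 1.4\nnoise_sd: 0.0\nseed: 7\n"
    )
    scenario = load_scenario(path)
    assert scenario.gct_left == 1.5
    assert scenario.seed == 7
    path.write_text("bogus_field: 1\n")
    with pytest.raises(ConfigurationError, match="bogus_field"):
        load_scenario(path)
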