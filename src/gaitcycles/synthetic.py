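"""Synthetic marker-level walking trials with known ground-truth gait events.

The generator emulates the signal structure the extraction pipeline assumes:
a vertical heel trajectory with exactly one peak (mid/late swing) and one
valley (heel strike) per gait cycle, a vertical toe trajectory whose single
per-cycle valley marks foot-flat a fixed fraction of the cycle after heel
strike, and a horizontal heel coordinate that advances by one step length
per cycle.  Left and right feet alternate half a cycle out of phase.  An
optional turning segment rotates the heading by 90 degrees while vertical
cycling continues, which exercises the turn-exclusion logic downstream.

Every event time and per-cycle parameter is recorded in a ``GroundTruth``
object, so the generator doubles as the oracle for the detection and
feature-extraction modules.

Waveform design
---------------
Each vertical signal is a C1 "bump train": a narrow raised-cosine cup of
depth ``BASIN_DEPTH_CM`` centred on each ground-contact event, a low plateau
between events, and a tall raised-cosine bump (symmetric about its peak) for
the airborne phase.  The cup gives every valley a steep, locally symmetric
basin so that event times remain identifiable to within a sample or two
after smoothing and under realistic marker noise; a perfectly flat stance
would leave the valley position undefined.  The horizontal coordinate holds
still in a window around each heel-z peak so that step length read at the
detected peak equals the commanded value.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError, InsufficientCyclesError
from .features import GaitCycleRecord
from .io import MarkerTrial

# Vertical-waveform shape constants (cm and seconds).  These are properties
# of the emulated kinematics, not tuning knobs of the analysis: the cup gives
# heel strike a well-defined minimum (a heel is never resting perfectly flat
# through stance), the plateau is the small heel clearance during foot-flat.
BASIN_HALFWIDTH_S = 0.10
BASIN_DEPTH_CM = 2.0
TOE_BASIN_HALFWIDTH_S = 0.10
TOE_PLATEAU_CM = 3.0
TOE_BUMP_CM = 8.0
TOE_SWING_FRACTION = 0.25
# Heel-x completes its advance this fraction of a cycle before the heel-z
# peak and holds, so the step length is well defined at the detected peak.
X_HOLD_FRACTION = 0.06
LATERAL_OFFSET_CM = 5.0
FOOT_LENGTH_CM = 15.0


@dataclass(frozen=True)
class GaitScenario:
    """Configuration of one synthetic walking trial.

    Durations in seconds, lengths/heights in cm, fractions of the gait
    cycle dimensionless in (0, 1).  Defaults emulate the unassisted-walking
    condition of a Parkinsonian cohort: 1.29 s cycles, 27% swing, initial
    and terminal double-support fractions of 0.19 and 0.17, ~21 cm stride
    height and ~93 cm stride length.
    """

    sampling_rate: float = 100.0
    n_cycles_per_side: int = 10
    gct_left: float = 1.29
    gct_right: float = 1.29
    swing_fraction_left: float = 0.27
    swing_fraction_right: float = 0.27
    ids_fraction: float = 0.1875
    tds_fraction: float = 0.1688
    step_height_left: float = 21.2
    step_height_right: float = 21.2
    step_length_left: float = 93.0
    step_length_right: float = 93.0
    noise_sd: float = 0.1
    turn_start: float | None = None
    turn_duration: float | None = None
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the offending field."""
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.n_cycles_per_side < 1:
            raise ConfigurationError("n_cycles_per_side must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for side in ("left", "right"):
            gct = getattr(self, f"gct_{side}")
            sw = getattr(self, f"swing_fraction_{side}")
            sh = getattr(self, f"step_height_{side}")
            sl = getattr(self, f"step_length_{side}")
            if gct <= 0:
                raise ConfigurationError(f"gct_{side} must be positive")
            if sh <= 0:
                raise ConfigurationError(f"step_height_{side} must be positive")
            if sl <= 0:
                raise ConfigurationError(f"step_length_{side} must be positive")
            if not 0 < sw < 0.45:
                raise ConfigurationError(
                    f"swing_fraction_{side} must lie in (0, 0.45)"
                )
            if sw + self.ids_fraction + self.tds_fraction >= 1:
                raise ConfigurationError(
                    f"swing_fraction_{side} + ids_fraction + tds_fraction "
                    "must be < 1 (stance must contain both double supports)"
                )
            if sw * gct <= BASIN_HALFWIDTH_S:
                raise ConfigurationError(
                    f"swing_fraction_{side} * gct_{side} must exceed "
                    f"{BASIN_HALFWIDTH_S} s for a resolvable swing bump"
                )
            if TOE_SWING_FRACTION * gct <= TOE_BASIN_HALFWIDTH_S:
                raise ConfigurationError(f"gct_{side} too short for toe model")
            if sh <= BASIN_DEPTH_CM:
                raise ConfigurationError(
                    f"step_height_{side} must exceed the "
                    f"{BASIN_DEPTH_CM} cm stance clearance"
                )
        if not 0 < self.ids_fraction < 1:
            raise ConfigurationError("ids_fraction must lie in (0, 1)")
        if not 0 < self.tds_fraction < 1:
            raise ConfigurationError("tds_fraction must lie in (0, 1)")
        if (self.turn_start is None) != (self.turn_duration is None):
            raise ConfigurationError(
                "turn_start and turn_duration must be given together"
            )
        if self.turn_duration is not None and self.turn_duration <= 0:
            raise ConfigurationError("turn_duration must be positive")
        if self.turn_start is not None and self.turn_start < 0:
            raise ConfigurationError("turn_start must be >= 0")


@dataclass
class SideTruth:
    """Ground-truth event times and heights for one foot."""

    strike_times: np.ndarray          # n_cycles + 1 heel-z valley times, s
    peak_times: np.ndarray            # n_cycles heel-z peak times, s
    toe_valley_times: np.ndarray      # n_cycles toe-z valley times, s
    valley_heights: np.ndarray        # heel-z at strikes, cm
    peak_heights: np.ndarray          # heel-z at peaks, cm
    step_length: float                # commanded per-cycle advance, cm

    @property
    def n_cycles(self) -> int:
        return len(self.strike_times) - 1


@dataclass
class GroundTruth:
    """Event-level truth for a generated trial, one record per side."""

    left: SideTruth
    right: SideTruth
    scenario: GaitScenario

    def side(self, name: str) -> SideTruth:
        if name not in ("left", "right"):
            raise KeyError(name)
        return getattr(self, name)


def _bump_train(
    t: np.ndarray,
    valley_times: np.ndarray,
    peak_times: np.ndarray,
    peak_height: float,
    plateau: float,
    valley_halfwidth: float,
    peak_halfwidth: float,
) -> np.ndarray:
    """C1 piecewise-cosine waveform: cups at valleys, bumps at peaks."""
    z = np.full_like(t, plateau)
    for v in np.atleast_1d(valley_times):
        m = np.abs(t - v) <= valley_halfwidth
        z[m] = plateau * 0.5 * (1.0 - np.cos(np.pi * (t[m] - v) / valley_halfwidth))
    for p in np.atleast_1d(peak_times):
        m = np.abs(t - p) <= peak_halfwidth
        z[m] = plateau + (peak_height - plateau) * 0.5 * (
            1.0 + np.cos(np.pi * (t[m] - p) / peak_halfwidth)
        )
    return z


def _progression(
    t: np.ndarray,
    strike_times: np.ndarray,
    gct: float,
    step_length: float,
    swing_fraction: float,
) -> np.ndarray:
    """Heel forward coordinate: one smooth step-length advance per cycle.

    The advance happens during the rising half of the heel-z bump and
    completes ``X_HOLD_FRACTION`` of a cycle before the heel-z peak; the
    coordinate then holds until the next cycle's lift-off.
    """
    s0 = strike_times[0]
    n = len(strike_times) - 1
    k = np.clip(np.floor((t - s0) / gct), 0, n - 1).astype(int)
    tau = t - (s0 + k * gct)
    ramp_start = (1.0 - 2.0 * swing_fraction) * gct + BASIN_HALFWIDTH_S
    ramp_end = (1.0 - swing_fraction - X_HOLD_FRACTION) * gct
    frac = np.clip((tau - ramp_start) / (ramp_end - ramp_start), 0.0, 1.0)
    frac = 0.5 * (1.0 - np.cos(np.pi * frac))
    return step_length * (k + frac)


def _heading(t: np.ndarray, turn_start: float, turn_duration: float) -> np.ndarray:
    """Heading angle in radians: 0 before the turn, pi/2 after, C1 ramp."""
    u = np.clip((t - turn_start) / turn_duration, 0.0, 1.0)
    return (np.pi / 2.0) * 0.5 * (1.0 - np.cos(np.pi * u))


def _apply_heading(
    prog: np.ndarray, lateral: float, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convert arc-length progression + lateral offset into x/y coordinates."""
    dp = np.diff(prog)
    mid = 0.5 * (theta[:-1] + theta[1:])
    cx = np.concatenate([[0.0], np.cumsum(dp * np.cos(mid))])
    cy = np.concatenate([[0.0], np.cumsum(dp * np.sin(mid))])
    return cx - lateral * np.sin(theta), cy + lateral * np.cos(theta)


def _side_truth(
    scenario: GaitScenario, side: str, first_strike: float
) -> SideTruth:
    gct = getattr(scenario, f"gct_{side}")
    sw = getattr(scenario, f"swing_fraction_{side}")
    n = scenario.n_cycles_per_side
    strikes = first_strike + gct * np.arange(n + 1)
    peaks = strikes[1:] - sw * gct
    toe_valleys = strikes[:-1] + scenario.ids_fraction * gct
    return SideTruth(
        strike_times=strikes,
        peak_times=peaks,
        toe_valley_times=toe_valleys,
        valley_heights=np.zeros(n + 1),
        peak_heights=np.full(n, getattr(scenario, f"step_height_{side}")),
        step_length=getattr(scenario, f"step_length_{side}"),
    )


def generate_trial(
    scenario: GaitScenario,
    trial_id: str = "synthetic",
    subject_id: str = "sim",
    condition: str = "c",
) -> tuple[MarkerTrial, GroundTruth]:
    """Generate one walking trial and its ground truth.

    Identical scenarios (including ``seed``) produce bit-identical output.
    """
    scenario.validate()
    fs = scenario.sampling_rate
    rng = np.random.default_rng(scenario.seed)

    # Lead-in long enough for a full virtual swing bump before the first
    # strike (and after the last), so that the boundary valleys have full
    # prominence; the surplus boundary peaks are trimmed downstream.
    lead = 2.0 * scenario.swing_fraction_left * scenario.gct_left + 0.1
    truth_left = _side_truth(scenario, "left", lead)
    truth_right = _side_truth(
        scenario, "right", lead + 0.5 * scenario.gct_right
    )
    tail = max(
        2.0 * scenario.swing_fraction_left * scenario.gct_left,
        2.0 * scenario.swing_fraction_right * scenario.gct_right,
    )
    t_end = (
        max(truth_left.strike_times[-1], truth_right.strike_times[-1])
        + tail
        + 0.1
    )
    n_samples = int(math.floor(t_end * fs)) + 1
    t = np.arange(n_samples) / fs

    if scenario.turn_start is not None:
        theta = _heading(t, scenario.turn_start, scenario.turn_duration)
    else:
        theta = np.zeros(n_samples)

    markers: dict[str, np.ndarray] = {}
    for side, truth, lateral in (
        ("left", truth_left, LATERAL_OFFSET_CM),
        ("right", truth_right, -LATERAL_OFFSET_CM),
    ):
        gct = getattr(scenario, f"gct_{side}")
        sw = getattr(scenario, f"swing_fraction_{side}")
        sh = getattr(scenario, f"step_height_{side}")
        sl = getattr(scenario, f"step_length_{side}")

        peak_hw = sw * gct - BASIN_HALFWIDTH_S
        virtual_peaks = np.array(
            [
                truth.strike_times[0] - sw * gct,
                truth.strike_times[-1] + sw * gct,
            ]
        )
        heel_z = _bump_train(
            t,
            truth.strike_times,
            np.concatenate([truth.peak_times, virtual_peaks]),
            sh,
            BASIN_DEPTH_CM,
            BASIN_HALFWIDTH_S,
            peak_hw,
        )

        toe_hw = TOE_SWING_FRACTION * gct - TOE_BASIN_HALFWIDTH_S
        toe_peaks = truth.toe_valley_times[1:] - TOE_SWING_FRACTION * gct
        virtual_toe_peaks = np.array(
            [
                truth.toe_valley_times[0] - TOE_SWING_FRACTION * gct,
                truth.toe_valley_times[-1] + TOE_SWING_FRACTION * gct,
            ]
        )
        toe_z = _bump_train(
            t,
            truth.toe_valley_times,
            np.concatenate([toe_peaks, virtual_toe_peaks]),
            TOE_BUMP_CM,
            TOE_PLATEAU_CM,
            TOE_BASIN_HALFWIDTH_S,
            toe_hw,
        )

        prog = _progression(t, truth.strike_times, gct, sl, sw)
        heel_x, heel_y = _apply_heading(prog, lateral, theta)
        toe_x = heel_x + FOOT_LENGTH_CM * np.cos(theta)
        toe_y = heel_y + FOOT_LENGTH_CM * np.sin(theta)

        markers[f"{side}_heel"] = np.column_stack([heel_x, heel_y, heel_z])
        markers[f"{side}_toe"] = np.column_stack([toe_x, toe_y, toe_z])

    if scenario.noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, scenario.noise_sd, markers[name].shape
            )

    turn_window = None
    if scenario.turn_start is not None:
        turn_window = (
            scenario.turn_start,
            scenario.turn_start + scenario.turn_duration,
        )

    trial = MarkerTrial(
        sampling_rate=fs,
        markers=markers,
        condition=condition,
        trial_id=trial_id,
        subject_id=subject_id,
        turn_window=turn_window,
    )
    return trial, GroundTruth(left=truth_left, right=truth_right, scenario=scenario)


def ground_truth_parameters(gt: GroundTruth) -> list[GaitCycleRecord]:
    """Per-cycle parameter records computed from ground-truth event times.

    This is straight arithmetic on the recorded true event times and
    heights (cycle time between consecutive heel strikes, swing from heel
    peak to the following strike, double supports split at the toe valley,
    step length as the per-cycle horizontal advance) and serves as the
    oracle for the detection + extraction pipeline.
    """
    records: list[GaitCycleRecord] = []
    for side in ("left", "right"):
        tr = gt.side(side)
        if tr.n_cycles < 1:
            raise InsufficientCyclesError(
                f"no complete cycle for side {side!r}"
            )
        for k in range(1, tr.n_cycles + 1):
            gct = tr.strike_times[k] - tr.strike_times[k - 1]
            sw = tr.strike_times[k] - tr.peak_times[k - 1]
            ids = tr.toe_valley_times[k - 1] - tr.strike_times[k - 1]
            tds = tr.peak_times[k - 1] - tr.toe_valley_times[k - 1]
            sh = tr.peak_heights[k - 1] - tr.valley_heights[k - 1]
            sl = tr.step_length if k >= 2 else None
            records.append(
                GaitCycleRecord(
                    side=side,
                    cycle_index=k,
                    gct=gct,
                    sw=sw,
                    st=gct - sw,
                    ids=ids,
                    tds=tds,
                    sh=sh,
                    sl=sl,
                    vel=None if sl is None else sl / gct,
                )
            )
    return records


def load_scenario(path) -> GaitScenario:
    """Read a :class:`GaitScenario` from a YAML mapping of its field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("scenario file must contain a mapping")
    known = {f.name for f in dataclasses.fields(GaitScenario)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(
            f"unknown scenario field(s): {', '.join(sorted(unknown))}"
        )
    scenario = GaitScenario(**raw)
    scenario.validate()
    return scenario
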