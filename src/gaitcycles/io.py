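"""Marker-trajectory trial container and CSV round-trip.

The canonical on-disk form is a wide CSV, one row per frame:
``time_s, <marker>_x, <marker>_y, <marker>_z, ...`` preceded by ``#``
header lines carrying trial metadata (sampling rate, units, condition,
identifiers, optional turn window).  Coordinates are cm internally;
files declaring ``units: mm`` are converted on read.

Coordinate convention: z vertical (positive up), x the nominal
progression axis before any turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, TimingError

REQUIRED_MARKERS = ("left_heel", "right_heel", "left_toe", "right_toe")
CONDITION_LABELS = ("c", "ml", "mm", "mh", "w")
_AXES = ("x", "y", "z")


@dataclass
class MarkerTrial:
    """Time-indexed 3D positions for named markers of one walking trial.

    ``markers`` maps a marker name to an ``(n_samples, 3)`` float array of
    x/y/z positions in cm.  ``condition`` is one of the cue-condition
    labels: ``c`` (no assistance), ``w`` (conventional walker), ``ml`` /
    ``mm`` / ``mh`` (motorized walker at low/medium/high speed cue) — or a
    raw trial notation such as ``m03``.
    """

    sampling_rate: float
    markers: dict[str, np.ndarray]
    condition: str = "c"
    trial_id: str = ""
    subject_id: str = ""
    turn_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SchemaError("sampling_rate must be positive")
        lengths = {name: len(arr) for name, arr in self.markers.items()}
        if len(set(lengths.values())) > 1:
            raise SchemaError(f"marker series differ in length: {lengths}")
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise SchemaError(f"marker {name!r} must be (n, 3)")
            self.markers[name] = arr

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.markers.values()))) if self.markers else 0

    @property
    def duration(self) -> float:
        return max(self.n_samples - 1, 0) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def coordinate(self, marker: str, axis: str) -> np.ndarray:
        """One coordinate series, e.g. ``coordinate('left_heel', 'z')``."""
        if marker not in self.markers:
            raise SchemaError(f"missing marker {marker!r}")
        return self.markers[marker][:, _AXES.index(axis)]


@dataclass
class ValidationReport:
    """Per-marker gap accounting and a keep/exclude verdict."""

    gap_counts: dict[str, int]
    longest_gap: int
    duration: float
    verdict: str                      # "keep" | "exclude"
    interpolated_samples: int = 0

    @property
    def keep(self) -> bool:
        return self.verdict == "keep"


def write_trial_csv(trial: MarkerTrial, path, precision: int = 5) -> None:
    """Write a trial in the wide CSV schema (lossless at ``precision``)."""
    if trial.n_samples == 0:
        raise SchemaError("no samples to write")
    cols: dict[str, np.ndarray] = {"time_s": trial.time}
    for name in sorted(trial.markers):
        for j, axis in enumerate(_AXES):
            cols[f"{name}_{axis}"] = trial.markers[name][:, j]
    frame = pd.DataFrame(cols)
    header = [
        "# gaitcycles marker trial",
        f"# sampling_rate_hz: {trial.sampling_rate!r}",
        "# units: cm",
        f"# condition: {trial.condition}",
        f"# trial_id: {trial.trial_id}",
        f"# subject_id: {trial.subject_id}",
    ]
    if trial.turn_window is not None:
        header.append(
            f"# turn_window_s: {trial.turn_window[0]!r},{trial.turn_window[1]!r}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, index=False, float_format=f"%.{precision}f")


def _parse_header(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_trial_csv(path) -> MarkerTrial:
    """Read and validate a wide-schema trial CSV."""
    meta = _parse_header(path)
    frame = pd.read_csv(path, comment="#")
    if "time_s" not in frame.columns:
        raise SchemaError("missing required column 'time_s'")
    if len(frame) == 0:
        raise SchemaError("no samples in file")

    declared_fs = meta.get("sampling_rate_hz")
    time = frame["time_s"].to_numpy(dtype=float)
    if declared_fs is not None:
        fs = float(declared_fs)
    elif len(time) > 1:
        fs = 1.0 / float(np.median(np.diff(time)))
    else:
        raise SchemaError("cannot infer sampling rate from a 1-row file")
    if len(time) > 1:
        dt = np.diff(time)
        if np.any(np.abs(dt - 1.0 / fs) > 0.01 / fs):
            raise TimingError(
                "timestamps deviate from the uniform sample period by >1%"
            )

    scale = 1.0
    units = meta.get("units", "cm").lower()
    if units == "mm":
        scale = 0.1
    elif units != "cm":
        raise SchemaError(f"unsupported units {units!r} (expected cm or mm)")

    marker_names = sorted(
        {
            c.rsplit("_", 1)[0]
            for c in frame.columns
            if c != "time_s" and c.rsplit("_", 1)[-1] in _AXES
        }
    )
    markers: dict[str, np.ndarray] = {}
    for name in set(marker_names) | set(REQUIRED_MARKERS):
        missing = [
            f"{name}_{axis}"
            for axis in _AXES
            if f"{name}_{axis}" not in frame.columns
        ]
        if missing:
            raise SchemaError(
                f"missing required marker column(s) for {name!r}: "
                + ", ".join(missing)
            )
        markers[name] = (
            frame[[f"{name}_{axis}" for axis in _AXES]].to_numpy(dtype=float)
            * scale
        )

    turn_window = None
    if "turn_window_s" in meta:
        a, _, b = meta["turn_window_s"].partition(",")
        turn_window = (float(a), float(b))

    return MarkerTrial(
        sampling_rate=fs,
        markers=markers,
        condition=meta.get("condition", "c"),
        trial_id=meta.get("trial_id", ""),
        subject_id=meta.get("subject_id", ""),
        turn_window=turn_window,
    )


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (half-open) index pairs of consecutive-True runs."""
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts, stops))

def validate_trial(trial: MarkerTrial, max_gap: int = 10) -> tuple[MarkerTrial, ValidationReport]:
    """Gap-check a trial; interpolate short gaps, flag long ones.

    NaN runs of at most ``max_gap`` samples are filled linearly (edge gaps
    by nearest value); any longer run marks the trial ``exclude``, mirroring
    the practice of dropping incomplete recordings.  Report-only: the
    returned trial is a filled copy, the verdict is advisory.
    """
    gap_counts: dict[str, int] = {}
    longest = 0
    filled_total = 0
    new_markers: dict[str, np.ndarray] = {}
    for name, arr in trial.markers.items():
        arr = arr.copy()
        n_gaps = 0
        for j in range(3):
            col = arr[:, j]
            runs = _nan_runs(np.isnan(col))
            n_gaps += len(runs)
            for start, stop in runs:
                longest = max(longest, stop - start)
                if stop - start <= max_gap:
                    idx = np.flatnonzero(~np.isnan(col))
                    if len(idx) == 0:
                        continue
                    col[start:stop] = np.interp(
                        np.arange(start, stop), idx, col[idx]
                    )
                    filled_total += stop - start
            arr[:, j] = col
        gap_counts[name] = n_gaps
        new_markers[name] = arr
    verdict = "keep" if longest <= max_gap else "exclude"
    report = ValidationReport(
        gap_counts=gap_counts,
        longest_gap=longest,
        duration=trial.duration,
        verdict=verdict,
        interpolated_samples=filled_total,
    )
    filled = MarkerTrial(
        sampling_rate=trial.sampling_rate,
        markers=new_markers,
        condition=trial.condition,
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        turn_window=trial.turn_window,
    )
    return filled, report
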