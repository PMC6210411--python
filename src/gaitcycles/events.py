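"""Gait-event detection from vertical heel and toe marker signals.

Heel strikes appear as valleys and mid/late-swing as peaks of the heel-z
signal.  Detection is coarse-to-fine: candidates come from the heavily
smoothed signal (robust cycle segmentation), then each event is re-located
on a lightly smoothed copy of the raw signal and given a sub-sample time
and a noise-averaged height by a local parabola fit.  The heavy smoothing
kernel spans a large fraction of a cycle and displaces the extrema of an
asymmetric waveform; the refinement step removes that bias.

Turning-phase artifacts are handled in two layers, mirroring the analysis
this package implements: an alternation rule keeps only the highest peak
between two valleys and the lowest valley between two peaks, and cycles
overlapping an explicitly supplied turn window are dropped whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema, peak_prominences

from .errors import ConfigurationError, InsufficientCyclesError
from .smoothing import SmoothingConfig, smooth

PEAK = "peak"
VALLEY = "valley"


@dataclass(frozen=True)
class GaitEvent:
    kind: str                  # "peak" | "valley"
    time: float                # s
    height: float              # cm
    index: int | None = None   # sample index in the source signal


@dataclass(frozen=True)
class EventConfig:
    """Detection thresholds.

    ``min_prominence_cm`` (2 cm) sits far below the smallest plausible
    step height (~10 cm) and above marker noise; ``neighborhood_samples``
    is the one-sided comparison window for local extrema.  The refinement
    radius bounds how far an event may move between the heavily smoothed
    and lightly smoothed signals.
    """

    min_prominence_cm: float = 2.0
    neighborhood_samples: int = 10
    toe_min_prominence_cm: float = 1.0
    refine_radius_samples: int = 15
    refine_window_samples: int = 9
    fit_halfwidth_samples: int = 3
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)


@dataclass
class CycleEvents:
    """One complete gait cycle: valley -> peak -> valley."""

    valley_start: GaitEvent
    peak: GaitEvent
    valley_end: GaitEvent

    def validate(self) -> None:
        if not (self.valley_start.time < self.peak.time < self.valley_end.time):
            raise ValueError("cycle events out of order")
        if self.peak.height <= max(
            self.valley_start.height, self.valley_end.height
        ):
            raise ValueError("peak height must exceed neighboring valleys")


@dataclass
class EventSeries:
    """Ordered gait cycles for one foot.

    Consecutive cycles usually share their boundary valley; after turn
    exclusion the series may contain gaps, in which case a cycle's
    ``valley_start`` is a fresh event rather than the predecessor's
    ``valley_end``.
    """

    side: str
    cycles: list[CycleEvents]

    def validate(self) -> None:
        prev_end = -np.inf
        for cyc in self.cycles:
            cyc.validate()
            if cyc.valley_start.time < prev_end:
                raise ValueError("cycles overlap or are unordered")
            prev_end = cyc.valley_end.time

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def events(self) -> list[GaitEvent]:
        """Flattened event list; shared boundary valleys appear once."""
        out: list[GaitEvent] = []
        for cyc in self.cycles:
            if not out or out[-1].time < cyc.valley_start.time:
                out.append(cyc.valley_start)
            out.append(cyc.peak)
            out.append(cyc.valley_end)
        return out

    def contiguous_with_previous(self, i: int) -> bool:
        """True when cycle ``i`` shares its start valley with cycle i-1."""
        if i == 0:
            return False
        return (
            self.cycles[i].valley_start.time
            == self.cycles[i - 1].valley_end.time
        )


@dataclass
class ToeValleySet:
    """Per-cycle toe-z valley (foot-flat) times; ``None`` = not found."""

    times: list[float | None]


def _candidate_extrema(
    x: np.ndarray, fs: float, min_prominence: float, neighborhood: int
) -> list[GaitEvent]:
    """All interior local extrema with the requested prominence.

    Plateau extrema are collapsed to their first sample.  Does not raise
    on sparse results; callers decide whether that is an error.
    """
    if neighborhood < 1:
        raise ConfigurationError("neighborhood_samples must be >= 1")
    if min_prominence < 0:
        raise ConfigurationError("min_prominence_cm must be >= 0")
    events: list[GaitEvent] = []
    for kind, sig in ((PEAK, x), (VALLEY, -x)):
        (idx,) = argrelextrema(
            sig, np.greater_equal, order=neighborhood, mode="clip"
        )
        idx = idx[(idx > 0) & (idx < len(x) - 1)]
        if len(idx) == 0:
            continue
        # collapse runs of equal-height neighbours (plateaus) to the first
        keep = np.concatenate(
            [[True], ~((np.diff(idx) <= neighborhood)
                       & (sig[idx[1:]] == sig[idx[:-1]]))]
        )
        idx = idx[keep]
        # plateau interiors satisfy >= both ways; require a true extremum
        idx = idx[(sig[idx] > sig[np.maximum(idx - 1, 0)])
                  | (sig[idx] > sig[np.minimum(idx + 1, len(x) - 1)])]
        if len(idx) == 0:
            continue
        with warnings.catch_warnings():
            # zero-prominence plateau artifacts are filtered just below
            warnings.simplefilter("ignore")
            prom = peak_prominences(sig, idx)[0]
        idx = idx[prom >= min_prominence]
        events.extend(
            GaitEvent(kind=kind, time=i / fs, height=x[i], index=int(i))
            for i in idx
        )
    events.sort(key=lambda e: (e.time, e.kind))
    return events


def detect_extrema(
    smoothed: np.ndarray,
    fs: float,
    min_prominence: float = 2.0,
    neighborhood: int = 10,
) -> list[GaitEvent]:
    """Peak/valley candidates on a smoothed heel-z signal.

    Raises :class:`InsufficientCyclesError` when fewer than two valleys
    survive the prominence filter (no complete cycle can exist).
    """
    events = _candidate_extrema(
        np.asarray(smoothed, dtype=float), fs, min_prominence, neighborhood
    )
    if sum(e.kind == VALLEY for e in events) < 2:
        raise InsufficientCyclesError(
            "fewer than 2 valleys detected; no complete gait cycle"
        )
    return events


def _parabola_vertex(
    raw: np.ndarray, i: int, halfwidth: int
) -> tuple[float, float]:
    """Sub-sample vertex (offset in samples, value) of a local LS parabola."""
    lo = max(i - halfwidth, 0)
    hi = min(i + halfwidth + 1, len(raw))
    u = np.arange(lo, hi) - i
    y = raw[lo:hi]
    if len(u) < 3:
        return 0.0, float(raw[i])
    a, b, c = np.polyfit(u, y, 2)
    if abs(a) < 1e-12:
        return 0.0, float(raw[i])
    offset = float(np.clip(-b / (2.0 * a), -2.0, 2.0))
    return offset, float(a * offset**2 + b * offset + c)


def refine_events(
    candidates: list[GaitEvent],
    raw: np.ndarray,
    fs: float,
    config: EventConfig | None = None,
) -> list[GaitEvent]:
    """Re-locate candidate events on the raw signal.

    Each event is moved to the extremum of a lightly smoothed copy of the
    raw signal within ``refine_radius_samples``, then assigned a sub-sample
    time and height from a parabola fitted to the raw samples around it.
    """
    if config is None:
        config = EventConfig()
    raw = np.asarray(raw, dtype=float)
    light = smooth(
        raw,
        fs,
        SmoothingConfig(window_samples=config.refine_window_samples),
    )
    refined: list[GaitEvent] = []
    seen: set[tuple[str, int]] = set()
    for ev in candidates:
        i0 = ev.index if ev.index is not None else int(round(ev.time * fs))
        lo = max(i0 - config.refine_radius_samples, 1)
        hi = min(i0 + config.refine_radius_samples + 1, len(raw) - 1)
        if hi <= lo:
            continue
        window = light[lo:hi]
        i1 = lo + (
            int(np.argmax(window)) if ev.kind == PEAK else int(np.argmin(window))
        )
        if (ev.kind, i1) in seen:
            continue
        seen.add((ev.kind, i1))
        offset, value = _parabola_vertex(raw, i1, config.fit_halfwidth_samples)
        refined.append(
            GaitEvent(kind=ev.kind, time=(i1 + offset) / fs,
                      height=value, index=i1)
        )
    refined.sort(key=lambda e: (e.time, e.kind))
    return refined


def enforce_alternation(
    candidates: list[GaitEvent], side: str = "left"
) -> EventSeries:
    """Reduce candidates to strictly alternating valley/peak cycles.

    Between two valleys only the highest peak survives; between two peaks
    only the lowest valley (ties keep the earliest).  Leading and trailing
    events are trimmed so the series starts and ends with a valley.
    Idempotent: a valid alternating series passes through unchanged.
    """
    ordered = sorted(candidates, key=lambda e: e.time)
    selected: list[GaitEvent] = []
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and ordered[j].kind == ordered[i].kind:
            j += 1
        run = ordered[i:j]
        if run[0].kind == PEAK:
            best = max(run, key=lambda e: (e.height, -e.time))
        else:
            best = min(run, key=lambda e: (e.height, e.time))
        selected.append(best)
        i = j

    # drop peaks not exceeding both neighbours (degenerate after selection)
    changed = True
    while changed:
        changed = False
        for k, ev in enumerate(selected):
            if ev.kind != PEAK:
                continue
            neighbours = [
                e for e in (selected[k - 1] if k > 0 else None,
                            selected[k + 1] if k + 1 < len(selected) else None)
                if e is not None
            ]
            if neighbours and ev.height <= max(e.height for e in neighbours):
                higher = max(
                    (e for e in neighbours), key=lambda e: e.height
                )
                selected.remove(ev)
                if len(neighbours) == 2:
                    selected.remove(higher)
                changed = True
                break

    while selected and selected[0].kind != VALLEY:
        selected.pop(0)
    while selected and selected[-1].kind != VALLEY:
        selected.pop()
    if sum(e.kind == VALLEY for e in selected) < 2:
        raise InsufficientCyclesError(
            "alternation left fewer than 2 valleys; no complete cycle"
        )
    cycles = [
        CycleEvents(
            valley_start=selected[k],
            peak=selected[k + 1],
            valley_end=selected[k + 2],
        )
        for k in range(0, len(selected) - 2, 2)
    ]
    series = EventSeries(side=side, cycles=cycles)
    series.validate()
    return series


def exclude_turn_window(
    series: EventSeries, turn_window: tuple[float, float]
) -> EventSeries:
    """Drop whole cycles whose span overlaps the turn window."""
    start, end = turn_window
    if not start < end:
        raise ConfigurationError("turn window start must precede its end")
    kept = [
        cyc
        for cyc in series.cycles
        if cyc.valley_end.time <= start or cyc.valley_start.time >= end
    ]
    out = EventSeries(side=series.side, cycles=kept)
    out.validate()
    return out


def match_toe_valleys(
    series: EventSeries,
    toe_z: np.ndarray,
    fs: float,
    raw_toe_z: np.ndarray | None = None,
    config: EventConfig | None = None,
) -> ToeValleySet:
    """Assign each heel cycle the nearest toe-z valley after heel strike.

    The search window is [valley_start, peak]; a cycle with no toe valley
    inside its window is flagged ``None`` (its double-support split is
    then unavailable downstream).
    """
    if config is None:
        config = EventConfig()
    candidates = _candidate_extrema(
        np.asarray(toe_z, dtype=float),
        fs,
        config.toe_min_prominence_cm,
        config.neighborhood_samples,
    )
    valleys = [e for e in candidates if e.kind == VALLEY]
    if raw_toe_z is not None and valleys:
        valleys = [
            e for e in refine_events(valleys, raw_toe_z, fs, config)
            if e.kind == VALLEY
        ]
    times: list[float | None] = []
    half_sample = 0.5 / fs
    for cyc in series.cycles:
        in_window = [
            v.time
            for v in valleys
            if cyc.valley_start.time - half_sample <= v.time <= cyc.peak.time
        ]
        if not in_window:
            times.append(None)
        else:
            anchor = cyc.valley_start.time
            times.append(min(in_window, key=lambda tv: abs(tv - anchor)))
    return ToeValleySet(times=times)


def detect_gait_events(
    heel_z_raw: np.ndarray,
    fs: float,
    side: str = "left",
    config: EventConfig | None = None,
    turn_window: tuple[float, float] | None = None,
) -> EventSeries:
    """Full heel-event chain: smooth, detect, refine, alternate, exclude."""
    if config is None:
        config = EventConfig()
    heel_z_raw = np.asarray(heel_z_raw, dtype=float)
    smoothed = smooth(heel_z_raw, fs, config.smoothing)
    candidates = detect_extrema(
        smoothed, fs, config.min_prominence_cm, config.neighborhood_samples
    )
    refined = refine_events(candidates, heel_z_raw, fs, config)
    series = enforce_alternation(refined, side=side)
    if turn_window is not None:
        series = exclude_turn_window(series, turn_window)
    return series
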