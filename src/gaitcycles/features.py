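"""Per-cycle spatiotemporal gait parameters and condition-level summaries.

For cycle ``k`` delimited by heel-z valleys at times ``tV(k-1)`` and
``tV(k)`` with the intervening peak at ``tP(k)`` (height ``zP``), the toe-z
valley at ``tVto``, and the heel forward coordinate ``x``:

====================  =================================================
gait cycle time       ``GCT = tV(k) - tV(k-1)``
swing time            ``SW  = tV(k) - tP(k)``
stance time           ``ST  = GCT - SW``
initial double supp.  ``IDS = tVto - tV(k-1)``
terminal double supp. ``TDS = tP(k) - tVto``
step height           ``SH  = zP(k) - zV(k-1)``  (heights, not times)
step length           ``SL  = x(tP(k)) - x(tP(k-1))``
velocity              ``Vel = SL / GCT``
====================  =================================================

The first cycle of a contiguous run has no step length (it needs the
previous peak).  A cycle with a negative computed duration is flagged
invalid rather than clamped.  Condition summaries report mean and sample
SD per parameter, and phase ratios computed on condition means
(``mean(IDS)/mean(GCT) * 100`` etc.), so the ratio table is internally
consistent: ``IDS/ST = (IDS/GCT) / (ST/GCT)`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientCyclesError
from .events import EventSeries, ToeValleySet

PARAMETERS = ("gct", "sw", "st", "ids", "tds", "sh", "sl", "vel")
RATIO_KEYS = ("st_gct", "ids_gct", "tds_gct", "ids_st", "tds_st")


@dataclass
class GaitCycleRecord:
    """Spatiotemporal parameters of one gait cycle for one side.

    Durations in s, heights/lengths in cm, velocity in cm/s.  ``ids``,
    ``tds`` are ``None`` when the cycle's toe valley was not found;
    ``sl``/``vel`` are ``None`` for the first cycle of a contiguous run.
    """

    side: str
    cycle_index: int
    gct: float
    sw: float
    st: float
    ids: float | None
    tds: float | None
    sh: float
    sl: float | None
    vel: float | None
    valid: bool = True
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ParamStat:
    mean: float
    sd: float
    n: int


@dataclass
class ConditionSummary:
    """Mean +- SD of each parameter plus phase ratios for one condition."""

    label: str
    n_cycles: int
    stats: dict[str, ParamStat]
    ratios: dict[str, float]


def _window_mean(x: np.ndarray, fs: float, t: float, halfwidth: int) -> float:
    i = int(round(t * fs))
    lo = max(i - halfwidth, 0)
    hi = min(i + halfwidth + 1, len(x))
    return float(np.mean(x[lo:hi]))


def compute_cycles(
    series: EventSeries,
    toe_valleys: ToeValleySet | None,
    heel_x: np.ndarray | None,
    fs: float,
    x_window_samples: int = 4,
) -> list[GaitCycleRecord]:
    """Per-cycle records from detected events.

    ``heel_x`` is the raw forward coordinate; the position at a peak is
    averaged over ``+-x_window_samples`` samples to suppress marker noise
    (the window is small against the near-stationary hold around the
    heel-z peak).  Pass ``toe_valleys=None`` or ``heel_x=None`` to skip
    the double-support split or the spatial parameters respectively.
    """
    if series.n_cycles == 0:
        raise InsufficientCyclesError("empty event series")
    heel_x = None if heel_x is None else np.asarray(heel_x, dtype=float)
    records: list[GaitCycleRecord] = []
    prev_peak_x: float | None = None
    for i, cyc in enumerate(series.cycles):
        flags: list[str] = []
        gct = cyc.valley_end.time - cyc.valley_start.time
        sw = cyc.valley_end.time - cyc.peak.time
        st = gct - sw
        sh = cyc.peak.height - cyc.valley_start.height

        ids = tds = None
        if toe_valleys is not None:
            tvo = toe_valleys.times[i]
            if tvo is None:
                flags.append("toe_valley_missing")
            else:
                ids = tvo - cyc.valley_start.time
                tds = cyc.peak.time - tvo

        sl = vel = None
        if heel_x is not None:
            peak_x = _window_mean(heel_x, fs, cyc.peak.time, x_window_samples)
            if prev_peak_x is not None and series.contiguous_with_previous(i):
                sl = peak_x - prev_peak_x
                vel = sl / gct
            prev_peak_x = peak_x

        valid = True
        for name, value in (("gct", gct), ("sw", sw), ("st", st),
                            ("ids", ids), ("tds", tds)):
            if value is not None and value < 0:
                flags.append(f"negative_{name}")
                valid = False
        if sh <= 0:
            flags.append("nonpositive_sh")
            valid = False

        records.append(
            GaitCycleRecord(
                side=series.side,
                cycle_index=i + 1,
                gct=gct, sw=sw, st=st, ids=ids, tds=tds,
                sh=sh, sl=sl, vel=vel,
                valid=valid, flags=tuple(flags),
            )
        )
    return records


def _values(records: list[GaitCycleRecord], param: str) -> np.ndarray:
    vals = [getattr(r, param) for r in records if r.valid]
    return np.array([v for v in vals if v is not None], dtype=float)


def summarize_condition(
    records: list[GaitCycleRecord], label: str
) -> ConditionSummary:
    """Pool per-cycle records of one condition into means, SDs and ratios."""
    valid = [r for r in records if r.valid]
    if not valid:
        raise InsufficientCyclesError(
            f"no valid cycles to summarize for condition {label!r}"
        )
    stats: dict[str, ParamStat] = {}
    for param in PARAMETERS:
        vals = _values(valid, param)
        if len(vals) == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        stats[param] = ParamStat(mean=float(np.mean(vals)), sd=sd, n=len(vals))

    ratios: dict[str, float] = {}
    mean_gct = stats["gct"].mean
    mean_st = stats["st"].mean
    ratios["st_gct"] = 100.0 * mean_st / mean_gct
    if "ids" in stats:
        ratios["ids_gct"] = 100.0 * stats["ids"].mean / mean_gct
        ratios["ids_st"] = 100.0 * stats["ids"].mean / mean_st
    if "tds" in stats:
        ratios["tds_gct"] = 100.0 * stats["tds"].mean / mean_gct
        ratios["tds_st"] = 100.0 * stats["tds"].mean / mean_st
    return ConditionSummary(
        label=label, n_cycles=len(valid), stats=stats, ratios=ratios
    )


def records_to_frame(
    records: list[GaitCycleRecord],
    subject: str = "",
    trial: str = "",
    condition: str = "",
) -> pd.DataFrame:
    """One row per cycle, the package's canonical tabular output."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject": subject,
                "trial": trial,
                "condition": condition,
                "side": r.side,
                "k": r.cycle_index,
                "gct_s": r.gct,
                "sw_s": r.sw,
                "st_s": r.st,
                "ids_s": r.ids,
                "tds_s": r.tds,
                "sh_cm": r.sh,
                "sl_cm": r.sl,
                "vel_cm_s": r.vel,
                "valid": r.valid,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def summary_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Condition summary table: one row per parameter, columns per condition."""
    rows = []
    for param in PARAMETERS:
        row: dict[str, object] = {"parameter": param}
        for s in summaries:
            st = s.stats.get(param)
            row[f"{s.label}_mean"] = None if st is None else st.mean
            row[f"{s.label}_sd"] = None if st is None else st.sd
        rows.append(row)
    return pd.DataFrame(rows)


def ratios_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Phase-ratio table (percent): rows ST/GCT, IDS/GCT, TDS/GCT, IDS/ST, TDS/ST."""
    rows = []
    for key in RATIO_KEYS:
        row: dict[str, object] = {"ratio": key}
        for s in summaries:
            row[s.label] = s.ratios.get(key)
        rows.append(row)
    return pd.DataFrame(rows)
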