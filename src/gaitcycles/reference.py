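"""Published reference summaries for PD gait under haptic speed cues.

These tables are the group-level results of a six-subject motion-capture
study of Parkinson's disease gait, comparing walking without assistance
(``c``), with a conventional rolling walker (``w``), and with a motorized
walker delivering low/medium/high haptic speed cues (``ml``/``mm``/``mh``).
The underlying recordings are not public; the printed summaries serve here
as inputs for internal-consistency checks of the summary arithmetic and as
realistic targets for synthetic scenarios.

All durations are seconds, lengths/heights cm, velocity cm/s, ratios and
asymmetry indices percent.
"""

from __future__ import annotations

import pandas as pd

CONDITIONS = ("c", "w", "ml", "mm", "mh")

# mean, sd per parameter per condition
PARAMETER_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "gct": {"c": (1.29, 0.25), "w": (1.34, 0.21), "ml": (1.68, 0.28),
            "mm": (1.40, 0.20), "mh": (1.31, 0.13)},
    "sw":  {"c": (0.35, 0.05), "w": (0.39, 0.06), "ml": (0.43, 0.10),
            "mm": (0.38, 0.06), "mh": (0.38, 0.06)},
    "st":  {"c": (0.94, 0.22), "w": (0.95, 0.20), "ml": (1.25, 0.28),
            "mm": (1.02, 0.17), "mh": (0.94, 0.10)},
    "ids": {"c": (0.24, 0.69), "w": (0.24, 0.11), "ml": (0.28, 0.14),
            "mm": (0.22, 0.01), "mh": (0.21, 0.06)},
    "tds": {"c": (0.22, 0.03), "w": (0.22, 0.12), "ml": (0.25, 0.13),
            "mm": (0.21, 0.13), "mh": (0.21, 0.05)},
    "sl":  {"c": (92.98, 1.24), "w": (70.61, 27.70), "ml": (49.72, 12.58),
            "mm": (68.59, 11.86), "mh": (74.76, 12.11)},
    "sh":  {"c": (21.19, 3.14), "w": (20.78, 3.40), "ml": (14.52, 4.09),
            "mm": (19.02, 3.31), "mh": (21.08, 2.97)},
    "vel": {"c": (75.28, 12.99), "w": (65.89, 17.36), "ml": (29.24, 7.94),
            "mm": (52.80, 10.56), "mh": (67.33, 11.67)},
}

# phase ratios in percent of the gait cycle / of stance
PHASE_RATIOS: dict[str, dict[str, float]] = {
    "st_gct":  {"c": 72.76, "ml": 74.40, "mm": 73.10, "mh": 71.53, "w": 70.98},
    "ids_gct": {"c": 18.75, "ml": 16.78, "mm": 15.66, "mh": 15.72, "w": 17.48},
    "tds_gct": {"c": 16.88, "ml": 14.94, "mm": 15.09, "mh": 16.18, "w": 16.59},
    "ids_st":  {"c": 25.77, "ml": 22.56, "mm": 21.43, "mh": 21.98, "w": 24.63},
    "tds_st":  {"c": 22.45, "ml": 20.08, "mm": 20.65, "mh": 22.62, "w": 23.37},
}

# asymmetry indices in percent; the published "<0.1" cells are stored as
# their bound with the flag below
ASYMMETRY: dict[str, dict[str, float]] = {
    "gct": {"c": 6.7, "ml": 0.56, "mm": 0.1, "mh": 0.1, "w": 0.53},
    "sh":  {"c": 5.7, "ml": -3.99, "mm": 3.46, "mh": 2.12, "w": 1.48},
    "sl":  {"c": -1.8, "ml": -2.10, "mm": 1.44, "mh": 1.33, "w": -3.25},
    "vel": {"c": 3.4, "ml": -9.50, "mm": 1.48, "mh": 2.03, "w": -2.75},
}
ASYMMETRY_UPPER_BOUNDS = {("gct", "mm"), ("gct", "mh")}


def parameter_summary_frame() -> pd.DataFrame:
    rows = []
    for param, cols in PARAMETER_SUMMARY.items():
        row: dict[str, object] = {"parameter": param}
        for cond, (mean, sd) in cols.items():
            row[f"{cond}_mean"] = mean
            row[f"{cond}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)


def phase_ratio_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [{"ratio": k, **v} for k, v in PHASE_RATIOS.items()]
    )


def double_support_reduction(
    ratios: dict[str, dict[str, float]] | None = None,
    cond_a: str = "c",
    cond_b: str = "mm",
) -> dict[str, float]:
    """IDS/GCT and TDS/GCT reduction from condition ``a`` to ``b``.

    On the published ratios the default pair (unassisted vs. motorized
    walker, medium cue) gives 3.09 and 1.79 points, an overall 4.88-point
    drop in double support as a share of the gait cycle.
    """
    if ratios is None:
        ratios = PHASE_RATIOS
    ids = ratios["ids_gct"][cond_a] - ratios["ids_gct"][cond_b]
    tds = ratios["tds_gct"][cond_a] - ratios["tds_gct"][cond_b]
    return {"ids_gct": ids, "tds_gct": tds, "total": ids + tds}


def derived_stance_ratios(
    ratios: dict[str, dict[str, float]] | None = None,
) -> dict[str, dict[str, float]]:
    """IDS/ST and TDS/ST implied by the */GCT rows.

    ``IDS/ST = (IDS/GCT) / (ST/GCT) * 100``; the published table satisfies
    this for every column except ``c``'s TDS/ST cell, a known internal
    inconsistency of the source (16.88 / 72.76 gives 23.20, not 22.45).
    """
    if ratios is None:
        ratios = PHASE_RATIOS
    out: dict[str, dict[str, float]] = {"ids_st": {}, "tds_st": {}}
    for cond in ratios["st_gct"]:
        st = ratios["st_gct"][cond]
        out["ids_st"][cond] = 100.0 * ratios["ids_gct"][cond] / st
        out["tds_st"][cond] = 100.0 * ratios["tds_gct"][cond] / st
    return out


def stance_identity_residuals(
    summary: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> dict[str, float]:
    """``mean GCT - mean SW - mean ST`` per condition.

    Zero up to the rounding of the printed two-decimal means (each column
    is within +-0.015 s, the half-ulp budget of three rounded values).
    """
    if summary is None:
        summary = PARAMETER_SUMMARY
    return {
        cond: summary["gct"][cond][0]
        - summary["sw"][cond][0]
        - summary["st"][cond][0]
        for cond in summary["gct"]
    }
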