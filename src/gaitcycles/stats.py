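"""Condition-comparison statistics and per-trial reporting.

Per-cycle parameter values are pooled per condition; normality is screened
with the Shapiro-Wilk test (flagged at p <= 0.05, never auto-switched to a
nonparametric test) and condition pairs are compared with a two-sided
two-sample t-test at alpha = 0.05.  Welch's unequal-variance form is the
default; a pooled-variance option exists for strict reproduction of
classical analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SampleSizeError
from .features import GaitCycleRecord


@dataclass
class ComparisonResult:
    parameter: str
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    normality_p_a: float
    normality_p_b: float
    normality_flag: bool          # True when either group looks non-normal
    t_statistic: float
    p_value: float
    alpha: float
    equal_var: bool

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def test_normality(samples) -> float:
    """Shapiro-Wilk p-value; small p (< ~0.05) flags non-normality.

    A constant sample has no meaningful distribution shape; it is reported
    as p = 0.0 (maximally flagged) rather than an error.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        raise SampleSizeError(
            f"normality test needs n >= 3, got n = {len(x)}"
        )
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def _extract(records, parameter: str) -> np.ndarray:
    if len(records) and isinstance(records[0], GaitCycleRecord):
        vals = [
            getattr(r, parameter)
            for r in records
            if r.valid and getattr(r, parameter) is not None
        ]
        return np.asarray(vals, dtype=float)
    return np.asarray(records, dtype=float)


def compare_conditions(
    records_a,
    records_b,
    parameter: str = "gct",
    alpha: float = 0.05,
    equal_var: bool = False,
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-sided two-sample t-test on per-cycle values of one parameter.

    Accepts lists of :class:`GaitCycleRecord` or plain numeric sequences.
    """
    a = _extract(records_a, parameter)
    b = _extract(records_b, parameter)
    if len(a) < 2 or len(b) < 2:
        raise SampleSizeError(
            f"t-test needs n >= 2 per group, got {len(a)} and {len(b)}"
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    p_a = test_normality(a) if len(a) >= 3 else float("nan")
    p_b = test_normality(b) if len(b) >= 3 else float("nan")
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return ComparisonResult(
        parameter=parameter,
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        normality_p_a=p_a,
        normality_p_b=p_b,
        normality_flag=(p_a <= 0.05) or (p_b <= 0.05),
        t_statistic=t,
        p_value=p,
        alpha=alpha,
        equal_var=equal_var,
    )


def trial_sort_key(trial: str) -> tuple[int, int]:
    """Deterministic cue-speed ordering of trial notations.

    Unassisted first, then motorized-walker trials in increasing trial /
    cue-speed order (m01, m02, ..., ml, mm, mh), then the conventional
    walker.  Unknown labels sort last alphabetically (stable).
    """
    if trial == "c":
        return (0, 0)
    if trial.startswith("m") and trial[1:].isdigit():
        return (1, int(trial[1:]))
    speed_order = {"ml": 100, "mm": 101, "mh": 102}
    if trial in speed_order:
        return (1, speed_order[trial])
    if trial == "w":
        return (2, 0)
    return (3, sum(ord(ch) for ch in trial))


def per_trial_report(
    records_by_trial: dict[str, dict[str, list[GaitCycleRecord]]],
) -> pd.DataFrame:
    """Per-(trial, side) mean and variance of gait cycle time.

    ``records_by_trial`` maps trial notation -> side -> cycle records.
    Rows are ordered by cue-speed trial notation, supporting adaptation
    analyses (variance decline across early motorized-walker trials).
    Empty sides are omitted with a warning.
    """
    rows = []
    for trial in sorted(records_by_trial, key=trial_sort_key):
        for side in ("left", "right"):
            recs = [
                r for r in records_by_trial[trial].get(side, []) if r.valid
            ]
            if not recs:
                warnings.warn(
                    f"trial {trial!r}: no valid cycles for side {side!r}",
                    stacklevel=2,
                )
                continue
            gct = np.array([r.gct for r in recs])
            rows.append(
                {
                    "trial": trial,
                    "side": side,
                    "n_cycles": len(gct),
                    "gct_mean_s": float(np.mean(gct)),
                    "gct_var_s2": float(np.var(gct, ddof=1))
                    if len(gct) > 1
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)
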