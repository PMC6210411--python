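"""Bilateral gait symmetry via the asymmetry index.

For a gait parameter X measured on the left (XL) and right (XR) side,

    Ia = (XL - XR) / max(XL, XR) * 100

in percent: 0 means perfect bilateral symmetry, positive values a larger
left side, negative a larger right side, and |Ia| <= 100 always.  Indices
are computed on per-side condition means of GCT, SH, SL and Vel over
straight-walking (turn-excluded) cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError
from .features import ConditionSummary

ASYMMETRY_PARAMETERS = ("gct", "sh", "sl", "vel")


def asymmetry_index(x_left: float, x_right: float) -> float:
    """Asymmetry index in percent for one positive-valued parameter pair."""
    if x_left <= 0 or x_right <= 0:
        raise DomainError(
            "asymmetry index requires positive inputs, got "
            f"({x_left!r}, {x_right!r})"
        )
    return (x_left - x_right) / max(x_left, x_right) * 100.0


@dataclass
class AsymmetryTable:
    """Ia per condition per parameter; ``None`` where a side is missing."""

    values: dict[str, dict[str, float | None]]  # condition -> param -> Ia

    def to_frame(self) -> pd.DataFrame:
        rows = []
        conditions = list(self.values)
        for param in ASYMMETRY_PARAMETERS:
            row: dict[str, object] = {"parameter": f"ia_{param}"}
            for cond in conditions:
                row[cond] = self.values[cond].get(param)
            rows.append(row)
        return pd.DataFrame(rows)


def asymmetry_table(
    side_summaries: dict[str, tuple[ConditionSummary | None, ConditionSummary | None]],
) -> AsymmetryTable:
    """Apply the index to per-side condition means.

    ``side_summaries`` maps a condition label to its (left, right) summary
    pair; a missing side leaves that condition's cells ``None``.
    """
    out: dict[str, dict[str, float | None]] = {}
    for cond, (left, right) in side_summaries.items():
        cells: dict[str, float | None] = {}
        for param in ASYMMETRY_PARAMETERS:
            if (
                left is None
                or right is None
                or param not in left.stats
                or param not in right.stats
            ):
                cells[param] = None
                continue
            cells[param] = asymmetry_index(
                left.stats[param].mean, right.stats[param].mean
            )
        out[cond] = cells
    return AsymmetryTable(values=out)
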