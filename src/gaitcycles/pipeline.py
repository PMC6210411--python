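"""End-to-end orchestration: simulate/load -> smooth -> detect -> extract
-> summarize -> compare -> report.

A single :class:`RunConfig` (YAML-backed) drives a fully deterministic run:
every source of randomness derives from one seed, outputs are written with
fixed float formatting, and the log accounts for every cycle in the input
(used, turn-excluded, or flagged) so the exclusion behaviour is auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, GaitError, InsufficientCyclesError
from .events import EventConfig, detect_gait_events, match_toe_valleys
from .features import (
    GaitCycleRecord,
    compute_cycles,
    ratios_to_frame,
    records_to_frame,
    summarize_condition,
    summary_to_frame,
)
from .io import MarkerTrial, read_trial_csv, validate_trial
from .smoothing import SmoothingConfig, smooth
from .stats import compare_conditions, per_trial_report
from .symmetry import asymmetry_table
from .synthetic import GaitScenario, generate_trial

# motorized-walker trial notation -> cue-speed condition
TRIAL_CONDITION_MAP = {
    "m01": "ml", "m02": "ml",
    "m03": "mm", "m04": "mm", "m05": "mm",
    "m06": "mh", "m07": "mh",
}


def condition_for_trial(notation: str) -> str:
    """Map a trial notation (c, m01..m07, w, ...) to its condition label."""
    return TRIAL_CONDITION_MAP.get(notation, notation)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``scenarios`` (condition label -> :class:`GaitScenario`) for a
    simulated cohort, or ``trial_paths`` pointing at marker CSVs; both may
    be combined.  ``seed`` re-seeds every scenario deterministically.
    """

    out_dir: str = "gait_out"
    seed: int = 0
    alpha: float = 0.05
    max_gap_samples: int = 10
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("c", "mm"), ("c", "mh"), ("c", "w")]
    )
    compare_parameters: tuple[str, ...] = (
        "gct", "sw", "st", "ids", "tds", "sl", "sh", "vel"
    )
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    events: EventConfig = field(default_factory=EventConfig)
    scenarios: dict[str, GaitScenario] = field(default_factory=dict)
    trial_paths: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("run config must be a mapping")
        kwargs: dict = {}
        for key in ("out_dir", "seed", "alpha", "max_gap_samples"):
            if key in raw:
                kwargs[key] = raw[key]
        if "comparisons" in raw:
            kwargs["comparisons"] = [tuple(p) for p in raw["comparisons"]]
        if "smoothing" in raw:
            kwargs["smoothing"] = SmoothingConfig(**raw["smoothing"])
        if "events" in raw:
            ev = dict(raw["events"])
            if "smoothing" in ev:
                ev["smoothing"] = SmoothingConfig(**ev["smoothing"])
            elif "smoothing" in raw:
                ev["smoothing"] = SmoothingConfig(**raw["smoothing"])
            kwargs["events"] = EventConfig(**ev)
        elif "smoothing" in raw:
            kwargs["events"] = EventConfig(
                smoothing=SmoothingConfig(**raw["smoothing"])
            )
        if "scenarios" in raw:
            kwargs["scenarios"] = {
                label: GaitScenario(**fields)
                for label, fields in raw["scenarios"].items()
            }
        if "trial_paths" in raw:
            missing = [p for p in raw["trial_paths"] if not Path(p).exists()]
            if missing:
                raise ConfigurationError(
                    f"trial file(s) not found: {', '.join(missing)}"
                )
            kwargs["trial_paths"] = list(raw["trial_paths"])
        return cls(**kwargs)


@dataclass
class TrialResult:
    trial: MarkerTrial
    condition: str
    records: dict[str, list[GaitCycleRecord]]     # side -> records
    n_detected: dict[str, int]
    n_turn_excluded: dict[str, int]
    n_flagged: dict[str, int]


@dataclass
class PipelineResult:
    cycles: pd.DataFrame
    summaries: pd.DataFrame
    ratios: pd.DataFrame
    asymmetry: pd.DataFrame
    comparisons: pd.DataFrame
    per_trial: pd.DataFrame
    log_lines: list[str]
    out_dir: Path | None = None


def _reseeded(scenario: GaitScenario, run_seed: int, index: int) -> GaitScenario:
    child = int(
        np.random.SeedSequence([run_seed, index]).generate_state(1)[0]
        % (2**31 - 1)
    )
    return dataclasses.replace(scenario, seed=child)


def analyze_trial(
    trial: MarkerTrial, config: RunConfig
) -> TrialResult:
    """Detect events and extract cycle records for both feet of one trial."""
    records: dict[str, list[GaitCycleRecord]] = {}
    n_detected: dict[str, int] = {}
    n_excl: dict[str, int] = {}
    n_flag: dict[str, int] = {}
    for side in ("left", "right"):
        stage = f"trial {trial.trial_id!r} side {side}"
        try:
            heel_z = trial.coordinate(f"{side}_heel", "z")
            series = detect_gait_events(
                heel_z, trial.sampling_rate, side=side, config=config.events
            )
            n_detected[side] = series.n_cycles
            if trial.turn_window is not None:
                from .events import exclude_turn_window

                series = exclude_turn_window(series, trial.turn_window)
            n_excl[side] = n_detected[side] - series.n_cycles
            if series.n_cycles == 0:
                raise InsufficientCyclesError("all cycles turn-excluded")
            toe_raw = trial.coordinate(f"{side}_toe", "z")
            toe_smoothed = smooth(
                toe_raw, trial.sampling_rate, config.events.smoothing
            )
            toe_valleys = match_toe_valleys(
                series,
                toe_smoothed,
                trial.sampling_rate,
                raw_toe_z=toe_raw,
                config=config.events,
            )
            heel_x = trial.coordinate(f"{side}_heel", "x")
            recs = compute_cycles(
                series, toe_valleys, heel_x, trial.sampling_rate
            )
        except GaitError as exc:
            raise type(exc)(f"[{stage}] {exc}") from exc
        records[side] = recs
        n_flag[side] = sum(not r.valid for r in recs)
    return TrialResult(
        trial=trial,
        condition=condition_for_trial(trial.condition),
        records=records,
        n_detected=n_detected,
        n_turn_excluded=n_excl,
        n_flagged=n_flag,
    )


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write the artifact set."""
    log: list[str] = [f"seed={config.seed} alpha={config.alpha}"]

    trials: list[MarkerTrial] = []
    for i, (label, scenario) in enumerate(sorted(config.scenarios.items())):
        scenario = _reseeded(scenario, config.seed, i)
        trial, _ = generate_trial(
            scenario, trial_id=f"sim_{label}", subject_id="sim",
            condition=label,
        )
        trials.append(trial)
        log.append(f"simulated trial {trial.trial_id!r} condition {label!r}")
    for path in config.trial_paths:
        trial = read_trial_csv(path)
        trials.append(trial)
        log.append(f"loaded trial {trial.trial_id!r} from {path}")
    if not trials:
        raise ConfigurationError(
            "run config defines neither scenarios nor trial_paths"
        )

    results: list[TrialResult] = []
    for trial in trials:
        filled, report = validate_trial(trial, config.max_gap_samples)
        if not report.keep:
            log.append(
                f"trial {trial.trial_id!r} EXCLUDED: gap of "
                f"{report.longest_gap} samples exceeds {config.max_gap_samples}"
            )
            continue
        if report.interpolated_samples:
            log.append(
                f"trial {trial.trial_id!r}: interpolated "
                f"{report.interpolated_samples} samples"
            )
        res = analyze_trial(filled, config)
        for side in ("left", "right"):
            used = sum(r.valid for r in res.records[side])
            log.append(
                f"trial {trial.trial_id!r} {side}: "
                f"{res.n_detected[side]} cycles detected = {used} used + "
                f"{res.n_turn_excluded[side]} turn-excluded + "
                f"{res.n_flagged[side]} flagged"
            )
        results.append(res)

    cycle_frames = [
        records_to_frame(
            res.records[side],
            subject=res.trial.subject_id,
            trial=res.trial.trial_id,
            condition=res.condition,
        )
        for res in results
        for side in ("left", "right")
    ]
    cycles = pd.concat(cycle_frames, ignore_index=True)

    by_condition: dict[str, list[GaitCycleRecord]] = {}
    by_condition_side: dict[str, dict[str, list[GaitCycleRecord]]] = {}
    by_trial: dict[str, dict[str, list[GaitCycleRecord]]] = {}
    for res in results:
        for side in ("left", "right"):
            by_condition.setdefault(res.condition, []).extend(
                res.records[side]
            )
            by_condition_side.setdefault(res.condition, {}).setdefault(
                side, []
            ).extend(res.records[side])
            by_trial.setdefault(res.trial.condition, {}).setdefault(
                side, []
            ).extend(res.records[side])

    summaries = []
    for label in sorted(by_condition):
        summaries.append(summarize_condition(by_condition[label], label))
        log.append(
            f"condition {label!r}: {summaries[-1].n_cycles} pooled cycles"
        )
    summary_frame = summary_to_frame(summaries)
    ratio_frame = ratios_to_frame(summaries)

    side_pairs = {}
    for label, sides in sorted(by_condition_side.items()):
        pair = []
        for side in ("left", "right"):
            recs = sides.get(side, [])
            pair.append(
                summarize_condition(recs, label) if any(
                    r.valid for r in recs
                ) else None
            )
        side_pairs[label] = tuple(pair)
    asym_frame = asymmetry_table(side_pairs).to_frame()

    comp_rows = []
    for a, b in config.comparisons:
        if a not in by_condition or b not in by_condition:
            log.append(f"comparison {a} vs {b} skipped: condition missing")
            continue
        for param in config.compare_parameters:
            try:
                r = compare_conditions(
                    by_condition[a], by_condition[b], param,
                    alpha=config.alpha, label_a=a, label_b=b,
                )
            except GaitError as exc:
                log.append(f"comparison {a} vs {b} {param}: {exc}")
                continue
            comp_rows.append(
                {
                    "parameter": param, "a": a, "b": b,
                    "n_a": r.n_a, "n_b": r.n_b,
                    "t": r.t_statistic, "p": r.p_value,
                    "significant": r.significant,
                    "normality_flag": r.normality_flag,
                }
            )
    comparisons = pd.DataFrame(comp_rows)
    per_trial = per_trial_report(by_trial)

    out_dir = None
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fmt = "%.6f"
        cycles.to_csv(out_dir / "cycles.csv", index=False, float_format=fmt)
        summary_frame.to_csv(
            out_dir / "condition_summary.csv", index=False, float_format=fmt
        )
        ratio_frame.to_csv(
            out_dir / "phase_ratios.csv", index=False, float_format=fmt
        )
        asym_frame.to_csv(
            out_dir / "asymmetry.csv", index=False, float_format=fmt
        )
        comparisons.to_csv(
            out_dir / "comparisons.csv", index=False, float_format=fmt
        )
        per_trial.to_csv(
            out_dir / "per_trial_gct.csv", index=False, float_format=fmt
        )
        (out_dir / "run.log").write_text("\n".join(log) + "\n")

    return PipelineResult(
        cycles=cycles,
        summaries=summary_frame,
        ratios=ratio_frame,
        asymmetry=asym_frame,
        comparisons=comparisons,
        per_trial=per_trial,
        log_lines=log,
        out_dir=out_dir,
    )
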