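"""End-to-end analysis: kinematics -> segmentation -> classification -> stats.

``analyze_trajectory`` classifies one trial; ``analyze`` processes many
and builds the summary report; ``run_pipeline`` is the file-level entry
used by the command line (reads trajectory CSVs, writes events/turns
CSV, summary JSON and a run manifest). Outputs are a pure function of
(inputs, config): rerunning with the same manifest reproduces them
byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .arena import LightSpot
from .classification import TrialResult, TurnEvent, classify_trial, compute_heading_angle
from .config import Config
from .io import (events_frame, read_trajectory_csv, turns_frame,
                 write_manifest, write_summary_json)
from .kinematics import Trajectory, compute_kinematics
from .segmentation import segment_trajectory
from .stats import SummaryReport, summarize

log = logging.getLogger("lightcast")


@dataclass
class AnalysisResult:
    trials: list[TrialResult] = field(default_factory=list)
    report: SummaryReport | None = None
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def light_related_turns(self) -> list[TurnEvent]:
        return [t for tr in self.trials for t in tr.turns if t.light_related]


def analyze_trajectory(traj: Trajectory, spot: LightSpot, cfg: Config) -> TrialResult:
    """Classify one trial: stops, casts, turns, relatedness, success."""
    kin = compute_kinematics(traj, cfg)
    stops, casts = segment_trajectory(kin, cfg)
    return classify_trial(traj, kin, stops, casts, spot, cfg)


def analyze(trajectories: list[Trajectory], spot: LightSpot,
            cfg: Config | None = None) -> AnalysisResult:
    """Classify many trials and summarize light-related turns.

    A failing trial is reported in ``errors`` and skipped; the rest are
    still processed.
    """
    cfg = cfg or Config()
    result = AnalysisResult()
    heading_first: list[tuple[float, float]] = []
    heading_second: list[tuple[float, float]] = []
    for traj in trajectories:
        try:
            trial = analyze_trajectory(traj, spot, cfg)
        except Exception as exc:  # keep processing remaining trials
            log.warning("trial %s failed: %s", traj.trial_id, exc)
            result.errors[traj.trial_id] = str(exc)
            continue
        result.trials.append(trial)
        for turn in trial.turns:
            if not turn.light_related:
                continue
            angle = compute_heading_angle(traj, spot, turn.stop_start_frame)
            heading_first.append((angle, turn.casts[0].amplitude))
            if turn.n_casts >= 2:
                heading_second.append((angle, turn.casts[1].amplitude))
    result.report = summarize(result.light_related_turns, result.trials,
                              heading_pairs=(heading_first, heading_second))
    return result


def run_pipeline(trajectory_paths: list[str | Path], spot: LightSpot,
                 cfg: Config, out_dir: str | Path,
                 seed: int | None = None) -> AnalysisResult:
    """File-level pipeline: read CSVs, analyze, write all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trajectories = []
    errors: dict[str, str] = {}
    for p in sorted(map(str, trajectory_paths)):
        try:
            trajectories.append(read_trajectory_csv(p, cfg))
        except Exception as exc:
            log.warning("could not read %s: %s", p, exc)
            errors[Path(p).name] = str(exc)
    result = analyze(trajectories, spot, cfg)
    result.errors.update(errors)

    events_frame(result.trials).to_csv(out / "events.csv", index=False,
                                       float_format="%.6f")
    turns_frame(result.trials).to_csv(out / "turns.csv", index=False,
                                      float_format="%.6f")
    write_summary_json(out / "summary.json", result.report.to_dict())
    counts = {
        "trials": len(result.trials),
        "stops": sum(len(tr.stops) for tr in result.trials),
        "casts": sum(len(tr.casts) for tr in result.trials),
        "turns": sum(len(tr.turns) for tr in result.trials),
        "light_related_turns": len(result.light_related_turns),
    }
    warnings = [f"{k}: {v}" for k, v in sorted(result.errors.items())]
    if not trajectories:
        warnings.append("no input trajectories found; report is empty")
    write_manifest(out / "manifest.json", cfg,
                   inputs=[str(p) for p in trajectory_paths],
                   counts=counts, seed=seed, warnings=warnings)
    return result
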