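"""Tidy-CSV serialization of trial logs and JSON sidecars for configurations."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .task_simulator import AgentParams, TaskConfig, TrialRecord

__all__ = [
    "trials_to_frame",
    "write_trials_csv",
    "read_trials_csv",
    "write_sidecar",
    "read_sidecar",
]

_SAMPLE_COLS = ["t", "hand_x", "hand_y", "cursor_x", "cursor_y", "target_x"]


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """One row per sample: subject, trial, phase, sample columns, metadata."""
    parts = []
    for r in records:
        n = r.t.size
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(r.subject_id, n),
                    "trial_index": np.repeat(r.trial_index, n),
                    "phase": np.repeat(r.phase, n),
                    "t": r.t,
                    "hand_x": r.hand_x,
                    "hand_y": r.hand_y,
                    "cursor_x": r.cursor_x,
                    "cursor_y": r.cursor_y,
                    "target_x": r.target_x,
                    "target_speed": np.repeat(r.target_speed_cmps, n),
                    "direction": np.repeat(r.target_direction, n),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_trials_csv(records: list[TrialRecord], path: str | Path) -> None:
    trials_to_frame(records).to_csv(path, index=False, float_format="%.9g")


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    records = []
    for (sid, idx), grp in df.groupby(["subject_id", "trial_index"], sort=True):
        grp = grp.sort_values("t")
        records.append(
            TrialRecord(
                subject_id=str(sid),
                trial_index=int(idx),
                phase=str(grp["phase"].iloc[0]),
                target_speed_cmps=float(grp["target_speed"].iloc[0]),
                target_direction=int(grp["direction"].iloc[0]),
                t=grp["t"].to_numpy(dtype=float),
                hand_x=grp["hand_x"].to_numpy(dtype=float),
                hand_y=grp["hand_y"].to_numpy(dtype=float),
                cursor_x=grp["cursor_x"].to_numpy(dtype=float),
                cursor_y=grp["cursor_y"].to_numpy(dtype=float),
                target_x=grp["target_x"].to_numpy(dtype=float),
            )
        )
    records.sort(key=lambda r: (r.subject_id, r.trial_index))
    return records


def write_sidecar(path: str | Path, cfg: TaskConfig, agents: list[AgentParams]) -> None:
    payload = {
        "task": dataclasses.asdict(cfg),
        "agents": [dataclasses.asdict(a) for a in agents],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_sidecar(path: str | Path) -> tuple[TaskConfig, list[AgentParams]]:
    payload = json.loads(Path(path).read_text())
    task = payload["task"]
    task["target_speeds_cmps"] = tuple(task["target_speeds_cmps"])
    task["occlusion_window_cm"] = tuple(task["occlusion_window_cm"])
    cfg = TaskConfig(**task)
    agents = [AgentParams(**a) for a in payload["agents"]]
    return cfg, agents
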