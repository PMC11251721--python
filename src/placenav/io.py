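"""Trajectory/metric file formats and run configuration.

Trajectories travel as flat CSV — one row per sample, grouped by trial and
time-sorted — with a ``# placenav-trajectory-csv v<major>.<minor>`` version
stamp on the first line.  Readers reject files stamped with a newer major
version.  Configuration round-trips through JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import Session, Trial
from .environment import ArenaConfig, build_main_arena

__all__ = [
    "SCHEMA_VERSION",
    "TRAJECTORY_COLUMNS",
    "TrajectoryFormatError",
    "write_trajectories",
    "read_trajectories",
    "write_metrics",
    "RunConfig",
]

log = logging.getLogger("placenav")

SCHEMA_VERSION = (1, 0)
_STAMP_PREFIX = "# placenav-trajectory-csv v"

TRAJECTORY_COLUMNS = [
    "session_id",
    "subject_id",
    "condition",
    "trial_id",
    "start_direction_deg",
    "t_s",
    "x_m",
    "y_m",
    "scene_dir_deg",
    "outcome",
]

_OUTCOME_TOKENS = {"high", "low", "timeout"}


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (schema, ordering or token errors)."""


def sessions_to_frame(sessions) -> pd.DataFrame:
    rows = []
    for sess in sessions:
        for tr in sess.trials:
            n = len(tr)
            rows.append(
                pd.DataFrame(
                    {
                        "session_id": [sess.session_id] * n,
                        "subject_id": [sess.subject_id] * n,
                        "condition": [sess.condition] * n,
                        "trial_id": [tr.trial_id] * n,
                        "start_direction_deg": [tr.start_direction] * n,
                        "t_s": tr.t,
                        "x_m": tr.x,
                        "y_m": tr.y,
                        "scene_dir_deg": tr.scene_dir,
                        "outcome": [tr.outcome] * n,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_trajectories(sessions, path) -> None:
    """Write sessions to a version-stamped trajectory CSV."""
    path = Path(path)
    frame = sessions_to_frame(sessions)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_STAMP_PREFIX}{SCHEMA_VERSION[0]}.{SCHEMA_VERSION[1]}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def _check_version(path: Path) -> None:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first.startswith(_STAMP_PREFIX):
        return  # unstamped files are accepted as current-version
    try:
        major = int(first[len(_STAMP_PREFIX):].split(".")[0])
    except ValueError as exc:
        raise TrajectoryFormatError(f"unparsable version stamp: {first!r}") from exc
    if major > SCHEMA_VERSION[0]:
        raise TrajectoryFormatError(
            f"file schema v{major} is newer than supported v{SCHEMA_VERSION[0]}"
        )


def read_trajectories(path, config: ArenaConfig | None = None) -> list:
    """Read a trajectory CSV back into :class:`Session` objects.

    ``config`` supplies the reward schedule used to reattach per-trial
    reward drops from the outcome token (defaults to the main arena).
    """
    path = Path(path)
    _check_version(path)
    if config is None:
        config = build_main_arena()
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise TrajectoryFormatError(f"missing columns: {missing}")
    if frame.empty:
        log.warning("trajectory file %s contains a header but no samples", path)
        return []

    bad = set(frame["outcome"].unique()) - _OUTCOME_TOKENS
    if bad:
        raise TrajectoryFormatError(f"unknown outcome tokens: {sorted(bad)}")

    sessions = []
    for session_id, sf in frame.groupby("session_id", sort=False):
        trials = []
        for trial_id, tf in sf.groupby("trial_id", sort=False):
            t = tf["t_s"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                first_row = int(tf.index[np.argmax(np.diff(t) <= 0)]) + 2
                raise TrajectoryFormatError(
                    f"non-monotone time in session {session_id!r} trial {trial_id} "
                    f"(near line {first_row})"
                )
            outcome = str(tf["outcome"].iloc[0])
            drops = (
                config.zone(outcome).reward_drops
                if outcome in ("high", "low") and any(z.label == outcome for z in config.zones)
                else 0
            )
            trials.append(
                Trial(
                    trial_id=int(trial_id),
                    start_direction=float(tf["start_direction_deg"].iloc[0]),
                    t=t,
                    x=tf["x_m"].to_numpy(float),
                    y=tf["y_m"].to_numpy(float),
                    scene_dir=tf["scene_dir_deg"].to_numpy(float),
                    outcome=outcome,
                    reward_drops=drops,
                    session_id=str(session_id),
                    condition=str(tf["condition"].iloc[0]),
                )
            )
        sessions.append(
            Session(
                trials=trials,
                subject_id=str(sf["subject_id"].iloc[0]),
                condition=str(sf["condition"].iloc[0]),
                session_id=str(session_id),
            )
        )
    return sessions


def write_metrics(metric_records, path) -> None:
    """Write per-trial metric records as a flat, version-stamped CSV."""
    frame = pd.DataFrame([asdict(m) if not isinstance(m, dict) else m for m in metric_records])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_STAMP_PREFIX}{SCHEMA_VERSION[0]}.{SCHEMA_VERSION[1]}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, JSON round-trippable."""

    environment: dict = field(default_factory=dict)   # arena overrides
    agents: dict = field(default_factory=dict)        # condition -> param overrides
    analysis: dict = field(default_factory=dict)      # n_perm, alpha, thresholds...
    output_dir: str = "."

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls(**json.loads(s))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(indent=2), encoding="utf-8")
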