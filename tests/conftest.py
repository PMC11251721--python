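import math

import numpy as np
import pytest

from placenav.agents import Session, Trial
from placenav.environment import build_main_arena, build_probe_arena, point_at


@pytest.fixture(scope="session")
def main_arena():
    return build_main_arena()


@pytest.fixture(scope="session")
def probe_arena():
    return build_probe_arena()


def make_trial(points, dt=1.0 / 60.0, scene=None, outcome="high",
               start_direction=270.0, trial_id=0, **kwargs):
    """Build a Trial from explicit waypoints (list of (x, y))."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    t = np.arange(n) * dt
    if scene is None:
        scene = np.full(n, start_direction)
    return Trial(
        trial_id=trial_id,
        start_direction=start_direction,
        t=t,
        x=pts[:, 0],
        y=pts[:, 1],
        scene_dir=np.asarray(scene, dtype=float) % 360.0,
        outcome=outcome,
        reward_drops={"high": 12, "low": 2}.get(outcome, 0),
        **kwargs,
    )


def straight_ray_trial(angle_deg, end_radius=0.70, n=200, outcome=None,
                       start_direction=None, **kwargs):
    """A straight run from the arena center out to ``end_radius`` at a
    fixed arena-frame angle; scene direction constant at that angle."""
    radii = np.linspace(0.0, end_radius, n)
    pts = [point_at(angle_deg, r) for r in radii]
    if outcome is None:
        from placenav.environment import circular_deviation
        if end_radius >= 0.62 and circular_deviation(angle_deg, 180.0) <= 30.0:
            outcome = "high"
        elif end_radius >= 0.62 and circular_deviation(angle_deg, 0.0) <= 30.0:
            outcome = "low"
        else:
            outcome = "timeout"
    return make_trial(
        pts,
        scene=np.full(n, angle_deg),
        outcome=outcome,
        start_direction=start_direction if start_direction is not None else angle_deg,
        **kwargs,
    )


def resample_trial(trial, factor=10):
    """Linear densification of a trial's samples by an integer factor."""
    t_new = np.interp(
        np.linspace(0, len(trial.t) - 1, (len(trial.t) - 1) * factor + 1),
        np.arange(len(trial.t)),
        trial.t,
    )
    def dense(v):
        return np.interp(t_new, trial.t, v)
    return Trial(
        trial_id=trial.trial_id,
        start_direction=trial.start_direction,
        t=t_new,
        x=dense(trial.x),
        y=dense(trial.y),
        scene_dir=dense(trial.scene_dir),
        outcome=trial.outcome,
        reward_drops=trial.reward_drops,
        side=trial.side,
    )


def make_session(trials, subject_id="r0", condition="expert", day=0):
    return Session(trials=list(trials), subject_id=subject_id,
                   condition=condition, day=day, session_id=f"{subject_id}-d{day}")
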