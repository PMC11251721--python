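"""Per-trial behavioral measures extracted from raw trajectories.

The two directional indices are positional angles of boundary-crossing
points, not instantaneous headings:

* **departing direction (DD)** — arena-frame angle of the point where the
  trajectory first crosses the departure circle from inside to outside;
* **perimeter-crossing direction (PCD)** — angle of the first
  inside-to-outside crossing of the unmarked perimeter boundary that
  shares the reward zones' inner edge.

Crossing points are linearly interpolated in Cartesian space between the
bracketing samples.  Deviations are smallest absolute differences from the
high-value zone center (180 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .agents import Trial
from .environment import (
    ArenaConfig,
    WALL_MARGIN,
    angle_of,
    circular_deviation,
)

__all__ = [
    "TrialMetrics",
    "SceneRotationTrace",
    "UndefinedMetricError",
    "departing_direction",
    "dd_deviation",
    "perimeter_crossings",
    "perimeter_crossing_direction",
    "pcd_deviation",
    "scene_rotation_trace",
    "first_turn_direction",
    "path_lengths",
    "classify_probe_trial",
    "compute_trial_metrics",
]

HIGH_ZONE_CENTER = 180.0


class UndefinedMetricError(ValueError):
    """A metric's precondition is not met (e.g. the boundary is never crossed)."""


@dataclass
class TrialMetrics:
    """Flat record of all per-trial measures.

    PCD fields are ``None`` on trials that never reach the perimeter;
    ``excess_travel_distance`` is ``None`` on timeout trials.
    """

    trial_id: int
    outcome: str
    departing_direction: float | None
    dd_deviation: float | None
    perimeter_crossing_direction: float | None
    pcd_deviation: float | None
    n_perimeter_crossings: int
    travel_distance: float
    excess_travel_distance: float | None
    latency: float
    mean_speed: float  # cm/s
    first_turn: str    # "cw" | "ccw" | "none"
    n_wall_bumps: int = 0


@dataclass
class SceneRotationTrace:
    """Unwrapped scene direction vs normalized distance to the DC exit."""

    normalized_distance: np.ndarray  # nondecreasing, [0, 1]
    scene_direction: np.ndarray      # deg, unwrapped, clockwise-positive


def _radial_crossings(trial: Trial, radius: float) -> list[tuple[int, float, float]]:
    """Inside-to-outside crossings of a circle of the given radius.

    Returns (index of the sample before the crossing, crossing angle in
    deg, interpolation fraction).  Outside-to-inside transitions are
    ignored.  The crossing point solves |p_i + s (p_{i+1} - p_i)| = radius
    exactly on the Cartesian segment.
    """
    x, y = trial.x, trial.y
    r = np.hypot(x, y)
    out = []
    inside = r < radius
    idx = np.nonzero(inside[:-1] & ~inside[1:])[0]
    for i in idx:
        p = np.array([x[i], y[i]])
        d = np.array([x[i + 1] - x[i], y[i + 1] - y[i]])
        a = d @ d
        b = 2.0 * (p @ d)
        c = p @ p - radius * radius
        if a == 0.0:
            continue
        disc = b * b - 4 * a * c
        s = (-b + math.sqrt(max(disc, 0.0))) / (2 * a)
        s = min(max(s, 0.0), 1.0)
        pt = p + s * d
        out.append((int(i), angle_of((pt[0], pt[1])), float(s)))
    return out


def departing_direction(trial: Trial, config: ArenaConfig) -> float:
    """Angle of the first inside-to-outside departure-circle crossing."""
    crossings = _radial_crossings(trial, config.departure_circle_radius)
    if not crossings:
        raise UndefinedMetricError(
            f"trial {trial.trial_id}: trajectory never leaves the departure circle"
        )
    return crossings[0][1]


def dd_deviation(trial: Trial, config: ArenaConfig) -> float:
    """Deviation of the DD from the high-value zone center, in [0, 180]."""
    return circular_deviation(departing_direction(trial, config), HIGH_ZONE_CENTER)


def perimeter_crossings(trial: Trial, config: ArenaConfig) -> list[tuple[int, float]]:
    """All inside-to-outside perimeter crossings as (sample index, angle)."""
    return [(i, ang) for i, ang, _ in _radial_crossings(trial, config.perimeter_radius)]


def perimeter_crossing_direction(trial: Trial, config: ArenaConfig) -> float:
    """Angle of the first perimeter crossing."""
    crossings = perimeter_crossings(trial, config)
    if not crossings:
        raise UndefinedMetricError(
            f"trial {trial.trial_id}: trajectory never crosses the perimeter"
        )
    return crossings[0][1]


def pcd_deviation(trial: Trial, config: ArenaConfig) -> float:
    """Deviation of the PCD from the high-value zone center, in [0, 180]."""
    return circular_deviation(
        perimeter_crossing_direction(trial, config), HIGH_ZONE_CENTER
    )


def unwrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Minimal-jump unwrapping of a degree sequence (no step exceeds 180)."""
    return np.unwrap(np.asarray(angles, dtype=float), period=360.0)


def scene_rotation_trace(trial: Trial, config: ArenaConfig) -> SceneRotationTrace:
    """Scene direction over normalized path length from start to DC exit.

    The abscissa is cumulative traveled distance up to the departure-circle
    exit, normalized to [0, 1]; the ordinate is the unwrapped scene
    direction (clockwise-positive, so counterclockwise turns decrease it).
    """
    crossings = _radial_crossings(trial, config.departure_circle_radius)
    if not crossings:
        raise UndefinedMetricError(
            f"trial {trial.trial_id}: trajectory never leaves the departure circle"
        )
    i_exit, _, s = crossings[0]
    end = i_exit + 1
    seg = np.hypot(np.diff(trial.x[: end + 1]), np.diff(trial.y[: end + 1]))
    # truncate the final segment at the interpolated crossing point
    seg[-1] *= s
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    norm = cum / total if total > 0 else cum
    scene = unwrap_degrees(trial.scene_dir[: end + 1])
    return SceneRotationTrace(normalized_distance=norm, scene_direction=scene)


def first_turn_direction(trial: Trial, threshold: float = 10.0) -> str:
    """Direction of the first scene-direction excursion beyond threshold.

    Clockwise-positive convention: a positive excursion of the unwrapped
    scene direction is a clockwise body turn.
    """
    scene = unwrap_degrees(trial.scene_dir)
    exc = scene - scene[0]
    beyond = np.nonzero(np.abs(exc) > threshold)[0]
    if len(beyond) == 0:
        return "none"
    return "cw" if exc[beyond[0]] > 0 else "ccw"


def _shortest_path_length(trial: Trial, config: ArenaConfig) -> float:
    if config.task == "probe":
        beacon = config.beacon_positions[trial.side or "right"]
        sx, sy = config.start_position
        return max(
            math.hypot(beacon[0] - sx, beacon[1] - sy) - config.reward_zone_radius, 0.0
        )
    return config.perimeter_radius


def path_lengths(trial: Trial, config: ArenaConfig):
    """(travel_distance m, excess m or None, latency s, mean_speed cm/s).

    Travel distance sums segment lengths from start to the final sample
    (zone entry, or the timeout point for timeout trials).  Excess is the
    travel distance minus the shortest path to the zone actually entered;
    it is ``None`` on timeouts.  Mean speed covers the full interval,
    including any post-bump recovery pauses.
    """
    travel = float(np.sum(np.hypot(np.diff(trial.x), np.diff(trial.y))))
    latency = float(trial.t[-1] - trial.t[0])
    if trial.outcome == "timeout":
        excess = None
    else:
        excess = max(travel - _shortest_path_length(trial, config), 0.0)
    mean_speed = (travel / latency * 100.0) if latency > 0 else 0.0
    return travel, excess, latency, mean_speed


def wall_contacts(trial: Trial, config: ArenaConfig) -> np.ndarray:
    """Indices of samples touching the arena wall (within the bump margin)."""
    r = np.hypot(trial.x, trial.y)
    return np.nonzero(r >= config.arena_radius - WALL_MARGIN - 1e-9)[0]


def classify_probe_trial(trial: Trial, config: ArenaConfig) -> str:
    """``direct_hit`` iff the beacon zone was reached without wall contact."""
    if config.task != "probe":
        raise ValueError("classify_probe_trial requires a probe arena config")
    if trial.outcome == "timeout":
        return "failed"
    if len(wall_contacts(trial, config)) > 0:
        return "failed"
    return "direct_hit"


def compute_trial_metrics(trial: Trial, config: ArenaConfig) -> TrialMetrics:
    """Assemble the full metric record for one trial.

    DD/PCD are ``None`` when undefined (the trial never crossed the
    respective boundary) rather than raising, so timeout trials survive
    aggregation.
    """
    try:
        dd = departing_direction(trial, config)
        ddd = circular_deviation(dd, HIGH_ZONE_CENTER)
    except UndefinedMetricError:
        dd = ddd = None
    crossings = perimeter_crossings(trial, config)
    if crossings:
        pcd = crossings[0][1]
        pcdd = circular_deviation(pcd, HIGH_ZONE_CENTER)
    else:
        pcd = pcdd = None
    travel, excess, latency, speed = path_lengths(trial, config)
    return TrialMetrics(
        trial_id=trial.trial_id,
        outcome=trial.outcome,
        departing_direction=dd,
        dd_deviation=ddd,
        perimeter_crossing_direction=pcd,
        pcd_deviation=pcdd,
        n_perimeter_crossings=len(crossings),
        travel_distance=travel,
        excess_travel_distance=excess,
        latency=latency,
        mean_speed=speed,
        first_turn=first_turn_direction(trial),
        n_wall_bumps=trial.n_wall_bumps,
    )
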