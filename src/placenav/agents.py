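"""Synthetic navigation agents.

Generates trajectory sessions that reproduce the qualitative behavioral
regimes of the task — novice (no scene alignment, straight runs along the
start direction), expert (counterclockwise scene alignment onto the
high-value zone, direct runs), dMUS (noisier alignment, wall bumps near
the goal, mostly successful recovery) and iMUS (poor alignment, occasional
low-value targeting, disorganized recovery) — plus a beacon-homing agent
for the object-guided probe task.

All numeric generative parameters are package defaults chosen to produce
the documented qualitative orderings; they are not estimates fit to any
animal data, and every one is configurable.

Randomness is counter-based: each trial draws from a fresh generator
seeded by ``(session_seed, trial_index)``, so sessions are reproducible
and trials independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .environment import (
    ArenaConfig,
    WALL_MARGIN,
    arena_to_math,
    circular_deviation,
    point_at,
    zone_membership,
)

__all__ = [
    "AgentParams",
    "Trial",
    "Session",
    "default_params",
    "simulate_trial",
    "simulate_session",
    "simulate_probe_trial",
    "simulate_probe_session",
]

CONDITIONS = ("novice", "expert", "dMUS", "iMUS", "probe")

#: In-place scene rotation rate during start alignment, deg/s.
ROTATION_SPEED = 90.0
#: Alignment tolerance ending the rotation phase, deg.
ALIGN_TOLERANCE = 5.0
#: Pause inserted after a wall bump, s.
BUMP_RECOVERY_DURATION = 1.0
#: Hard floor on the per-trial running speed, m/s.
SPEED_FLOOR = 0.05


@dataclass(frozen=True)
class AgentParams:
    """Condition-specific generative parameters.

    ``kappa_align`` concentrates the sampled departure goal angle around
    the chosen zone center; ``kappa_run`` concentrates each step heading
    around the current target; ``math.inf`` for either means noise-free.
    """

    condition: str
    kappa_align: float = 0.0
    p_low_target: float = 0.0
    kappa_run: float = 8.0
    rotate_at_start: bool = False
    p_reorient_success: float = 0.0
    speed_mean: float = 0.15
    speed_sd: float = 0.03
    turn_bias: str = "none"  # "ccw" | "cw" | "none"

    def __post_init__(self):
        if self.kappa_align < 0 or self.kappa_run < 0:
            raise ValueError("concentration parameters must be >= 0")
        for p in (self.p_low_target, self.p_reorient_success):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.turn_bias not in ("ccw", "cw", "none"):
            raise ValueError(f"unknown turn_bias {self.turn_bias!r}")


_DEFAULTS = {
    "novice": AgentParams(
        condition="novice",
        rotate_at_start=False,
        kappa_align=0.0,
        p_low_target=0.0,
        kappa_run=30.0,
        p_reorient_success=0.0,
    ),
    "expert": AgentParams(
        condition="expert",
        rotate_at_start=True,
        turn_bias="ccw",
        kappa_align=50.0,
        p_low_target=0.0,
        kappa_run=100.0,
        p_reorient_success=0.9,
    ),
    "dMUS": AgentParams(
        condition="dMUS",
        rotate_at_start=True,
        turn_bias="ccw",
        kappa_align=8.0,
        p_low_target=0.0,
        kappa_run=25.0,
        p_reorient_success=0.65,
    ),
    "iMUS": AgentParams(
        condition="iMUS",
        rotate_at_start=True,
        turn_bias="ccw",
        kappa_align=1.5,
        p_low_target=0.2,
        kappa_run=10.0,
        p_reorient_success=0.3,
    ),
    "probe": AgentParams(
        condition="probe",
        rotate_at_start=False,
        kappa_align=60.0,
        kappa_run=100.0,
    ),
}


def default_params(condition: str, **overrides) -> AgentParams:
    """Default generative parameters for a recognized condition."""
    if condition not in _DEFAULTS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return replace(_DEFAULTS[condition], **overrides)


@dataclass
class Trial:
    """One simulated navigation episode."""

    trial_id: int
    start_direction: float
    t: np.ndarray          # s, strictly increasing
    x: np.ndarray          # m
    y: np.ndarray          # m
    scene_dir: np.ndarray  # deg, arena frame, [0, 360)
    outcome: str           # "high" | "low" | "timeout"
    reward_drops: int
    session_id: str = ""
    condition: str = ""
    side: str | None = None       # probe trials only
    n_wall_bumps: int = 0

    def __len__(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class Session:
    """An ordered collection of trials from one subject on one day."""

    trials: list
    subject_id: str = "synthetic"
    condition: str = ""
    day: int = 0
    session_id: str = ""

    def __len__(self) -> int:
        return len(self.trials)


def _vm_noise(rng: np.random.Generator, kappa: float) -> float:
    """A von Mises(0, kappa) draw in degrees; 0 for infinite concentration."""
    if math.isinf(kappa):
        return 0.0
    return math.degrees(rng.vonmises(0.0, kappa))


def _heading_unit(angle_deg: float) -> tuple[float, float]:
    a = math.radians(arena_to_math(angle_deg))
    return (math.cos(a), math.sin(a))


def _angle_towards(src: tuple[float, float], dst: tuple[float, float]) -> float:
    dx, dy = dst[0] - src[0], dst[1] - src[1]
    return (-math.degrees(math.atan2(dy, dx))) % 360.0


def _trial_speed(rng: np.random.Generator, params: AgentParams) -> float:
    # truncated normal via rejection; floor guarantees forward progress
    for _ in range(1000):
        v = rng.normal(params.speed_mean, params.speed_sd)
        if v >= SPEED_FLOOR:
            return v
    return SPEED_FLOOR


def _rotation_samples(
    start_direction: float,
    goal_angle: float,
    turn_bias: str,
    sample_rate: float,
    start_pos: tuple[float, float],
) -> tuple[list, float]:
    """In-place scene rotation from the start direction toward the goal.

    Returns the samples generated (excluding the initial one) and the end
    time.  The scene angle moves at ROTATION_SPEED in the bias direction
    (ccw decreases the clockwise-positive arena angle) until within
    ALIGN_TOLERANCE of the goal, then snaps to the goal angle.
    """
    dt = 1.0 / sample_rate
    step = ROTATION_SPEED * dt
    if turn_bias == "ccw":
        sweep = (start_direction - goal_angle) % 360.0
        sign = -1.0
    elif turn_bias == "cw":
        sweep = (goal_angle - start_direction) % 360.0
        sign = 1.0
    else:
        diff = (goal_angle - start_direction + 180.0) % 360.0 - 180.0
        sweep = abs(diff)
        sign = 1.0 if diff >= 0 else -1.0

    samples = []
    t = 0.0
    angle = start_direction
    remaining = sweep
    while remaining > ALIGN_TOLERANCE:
        advance = min(step, remaining)
        angle = (angle + sign * advance) % 360.0
        remaining -= advance
        t += dt
        samples.append((t, start_pos[0], start_pos[1], angle))
    if samples:
        # snap the final alignment onto the goal
        t += dt
        samples.append((t, start_pos[0], start_pos[1], goal_angle % 360.0))
    return samples, t


def simulate_trial(
    params: AgentParams,
    config: ArenaConfig,
    start_direction: float,
    seed,
    trial_id: int = 0,
    session_id: str = "",
) -> Trial:
    """Simulate one main-task trial.

    Phase 1 (agents with ``rotate_at_start``): the scene rotates in place,
    in the ``turn_bias`` direction, onto a goal angle drawn as the chosen
    zone center plus von Mises(0, kappa_align) noise; the goal zone is the
    low-value zone with probability ``p_low_target``, else high-value.

    Phase 2: forward steps of ``speed / sample_rate`` along the current
    target heading plus von Mises(0, kappa_run) noise.  Hitting the wall
    records a bump, pauses 1 s, then reorients toward the goal with
    probability ``p_reorient_success`` (uniformly at random otherwise).
    The trial ends on reward-zone entry or at ``config.trial_timeout``.

    Deterministic given ``seed``.
    """
    if not any(math.isclose(start_direction, d) for d in config.start_directions):
        raise ValueError(
            f"start direction {start_direction} not in {config.start_directions}"
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.sample_rate
    start = config.start_position

    goal_label = "low" if rng.random() < params.p_low_target else "high"
    goal_zone = config.zone(goal_label)
    goal_angle = (goal_zone.center_angle + _vm_noise(rng, params.kappa_align)) % 360.0
    goal_point = point_at(
        goal_zone.center_angle, 0.5 * (goal_zone.inner_radius + goal_zone.outer_radius)
    )

    samples = [(0.0, start[0], start[1], start_direction % 360.0)]
    if params.rotate_at_start:
        rot, t = _rotation_samples(
            start_direction, goal_angle, params.turn_bias, config.sample_rate, start
        )
        samples.extend(rot)
        target = goal_angle
    else:
        t = 0.0
        target = start_direction

    speed = _trial_speed(rng, params)
    step_len = speed * dt
    x, y = start
    bump_limit = config.arena_radius - WALL_MARGIN
    outcome = "timeout"
    reward_drops = 0
    n_bumps = 0

    while t < config.trial_timeout:
        heading = (target + _vm_noise(rng, params.kappa_run)) % 360.0
        ux, uy = _heading_unit(heading)
        x, y = x + step_len * ux, y + step_len * uy
        r = math.hypot(x, y)
        bumped = r >= bump_limit
        if bumped:
            x, y = x * bump_limit / r, y * bump_limit / r
        t += dt
        samples.append((t, x, y, heading))

        label = zone_membership((x, y), config)
        if label != "none":
            outcome = label
            reward_drops = config.zone(label).reward_drops
            break

        if bumped:
            n_bumps += 1
            # recovery pause at the wall
            pause_steps = int(round(BUMP_RECOVERY_DURATION * config.sample_rate))
            for _ in range(pause_steps):
                t += dt
                samples.append((t, x, y, heading))
                if t >= config.trial_timeout:
                    break
            if rng.random() < params.p_reorient_success:
                target = _angle_towards((x, y), goal_point)
            else:
                target = rng.uniform(0.0, 360.0)

    arr = np.array(samples)
    return Trial(
        trial_id=trial_id,
        start_direction=start_direction % 360.0,
        t=arr[:, 0],
        x=arr[:, 1],
        y=arr[:, 2],
        scene_dir=arr[:, 3] % 360.0,
        outcome=outcome,
        reward_drops=reward_drops,
        session_id=session_id,
        condition=params.condition,
        n_wall_bumps=n_bumps,
    )


def balanced_start_directions(
    directions, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Pseudorandom start order: shuffled balanced blocks of the options."""
    directions = np.asarray(directions, dtype=float)
    k = len(directions)
    out = []
    remaining = n_trials
    while remaining > 0:
        block = rng.permutation(directions)
        out.append(block[: min(k, remaining)])
        remaining -= k
    return np.concatenate(out)[:n_trials]


def simulate_session(
    params: AgentParams,
    config: ArenaConfig,
    n_trials: int,
    seed,
    subject_id: str = "synthetic",
    day: int = 0,
    session_id: str | None = None,
) -> Session:
    """Simulate a session of ``n_trials`` main-task trials.

    Start directions are drawn as shuffled balanced blocks of the six
    options, so any ``n_trials`` divisible by six is exactly balanced.
    Per-trial seeds derive from ``(seed, trial_index)``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if session_id is None:
        session_id = f"{subject_id}-{params.condition}-d{day}"
    order_rng = np.random.default_rng([int(seed), 0xD1CE])
    dirs = balanced_start_directions(config.start_directions, n_trials, order_rng)
    trials = [
        simulate_trial(
            params,
            config,
            d,
            seed=[int(seed), i],
            trial_id=i,
            session_id=session_id,
        )
        for i, d in enumerate(dirs)
    ]
    return Session(
        trials=trials,
        subject_id=subject_id,
        condition=params.condition,
        day=day,
        session_id=session_id,
    )


def simulate_probe_trial(
    params: AgentParams,
    config: ArenaConfig,
    side: str,
    seed,
    trial_id: int = 0,
    session_id: str = "",
) -> Trial:
    """Simulate one beacon-homing probe trial.

    The agent aims at the beacon once, with von Mises(0, kappa_align)
    aiming error, then runs with von Mises(0, kappa_run) per-step heading
    noise; a large aiming error drives it into the wall before the zone.
    After a wall bump it re-aims directly at the (visible) beacon.  Left
    trials are exact mirror images of the right-frame simulation about
    the start-heading axis, so mirrored seeds yield mirror-symmetric
    trajectories.
    """
    if config.task != "probe":
        raise ValueError("probe trials require a probe arena config")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.sample_rate
    start = config.start_position
    beacon = config.beacon_positions["right"]  # simulate in the right frame
    zone_r = config.reward_zone_radius
    bump_limit = config.arena_radius - WALL_MARGIN

    speed = _trial_speed(rng, params)
    step_len = speed * dt
    x, y = start
    t = 0.0
    samples = [(0.0, x, y, config.start_directions[0])]
    outcome = "timeout"
    reward_drops = 0
    n_bumps = 0
    target = (_angle_towards(start, beacon) + _vm_noise(rng, params.kappa_align)) % 360.0

    while t < config.trial_timeout:
        heading = (target + _vm_noise(rng, params.kappa_run)) % 360.0
        ux, uy = _heading_unit(heading)
        x, y = x + step_len * ux, y + step_len * uy
        r = math.hypot(x, y)
        if r >= bump_limit:
            x, y = x * bump_limit / r, y * bump_limit / r
            n_bumps += 1
            target = _angle_towards((x, y), beacon)  # beacon stays visible
        t += dt
        samples.append((t, x, y, heading))
        if math.hypot(x - beacon[0], y - beacon[1]) <= zone_r:
            outcome = "high"
            reward_drops = 12
            break

    arr = np.array(samples)
    xs, ys, scenes = arr[:, 1], arr[:, 2], arr[:, 3]
    if side == "left":
        xs = -xs
        scenes = (180.0 - scenes) % 360.0
    return Trial(
        trial_id=trial_id,
        start_direction=config.start_directions[0],
        t=arr[:, 0],
        x=xs,
        y=ys,
        scene_dir=scenes % 360.0,
        outcome=outcome,
        reward_drops=reward_drops,
        session_id=session_id,
        condition=params.condition,
        side=side,
        n_wall_bumps=n_bumps,
    )


def simulate_probe_session(
    params: AgentParams,
    config: ArenaConfig,
    n_trials: int,
    seed,
    subject_id: str = "synthetic",
    day: int = 0,
) -> Session:
    """A probe session with pseudorandomly balanced left/right trials."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    session_id = f"{subject_id}-probe-d{day}"
    order_rng = np.random.default_rng([int(seed), 0xBEAC])
    sides = ["left", "right"]
    order = [
        s
        for block in range(-(-n_trials // 2))
        for s in order_rng.permutation(sides)
    ][:n_trials]
    trials = [
        simulate_probe_trial(
            params, config, side, seed=[int(seed), i], trial_id=i, session_id=session_id
        )
        for i, side in enumerate(order)
    ]
    return Session(
        trials=trials,
        subject_id=subject_id,
        condition=params.condition,
        day=day,
        session_id=session_id,
    )
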