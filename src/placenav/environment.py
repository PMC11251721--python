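"""Arena geometry, reward zones and task constants.

Two task layouts are supported:

* the **main** place-preference task — a circular arena with a central
  start position, two hidden annular-sector reward zones of unequal value
  (high at 180 deg, low at 0 deg), a small departure circle around the
  start and an unmarked perimeter boundary that shares the zones' inner
  edge;
* the **probe** (object-guided) task — the same arena without peripheral
  landmarks, a fixed south-periphery start and a flickering beacon that
  spawns left or right of the start heading, rewarded inside a 0.4 m disc.

Angle convention
----------------
Arena-frame angles are measured **clockwise from East** in degrees, in
``[0, 360)``.  Under this convention North = 270, NE = 315, South = 90 and
NW = 225.  The conversion to/from the standard counterclockwise math
convention is a sign flip: ``arena = (-math) % 360``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

__all__ = [
    "RewardZone",
    "ArenaConfig",
    "build_main_arena",
    "build_probe_arena",
    "angle_of",
    "point_at",
    "circular_deviation",
    "zone_membership",
    "arena_to_math",
    "math_to_arena",
    "WALL_MARGIN",
]

#: Radial margin (m) inside the arena wall at which a wall bump is registered.
WALL_MARGIN = 0.02

#: The six start directions of the main task: N, NE, SE, S, SW, NW.
MAIN_START_DIRECTIONS = (270.0, 315.0, 45.0, 90.0, 135.0, 225.0)


class ArenaConfigError(ValueError):
    """Raised for unknown override keys or violated geometric invariants."""


def arena_to_math(angle_deg: float) -> float:
    """Convert a clockwise-from-east arena angle to a ccw math angle."""
    return (-angle_deg) % 360.0


def math_to_arena(angle_deg: float) -> float:
    """Convert a ccw math angle to a clockwise-from-east arena angle."""
    return (-angle_deg) % 360.0


@dataclass(frozen=True)
class RewardZone:
    """An annular-sector reward zone.

    Attributes
    ----------
    label : str
        Either ``"high"`` or ``"low"``.
    center_angle : float
        Zone-center angle, degrees in the arena frame.
    angular_halfwidth : float
        Half angular extent, degrees.
    inner_radius, outer_radius : float
        Radial span in meters.
    reward_drops : int
        Drops of honey water dispensed on arrival.
    drop_volume : float
        Volume per drop, microliters.
    """

    label: str
    center_angle: float
    angular_halfwidth: float = 30.0
    inner_radius: float = 0.62
    outer_radius: float = 0.78
    reward_drops: int = 0
    drop_volume: float = 12.0

    def contains(self, radius: float, angle_deg: float) -> bool:
        """True iff the polar point lies in this annular sector."""
        if not (self.inner_radius <= radius <= self.outer_radius):
            return False
        return circular_deviation(angle_deg, self.center_angle) <= self.angular_halfwidth

    @property
    def reward_volume(self) -> float:
        """Total reward volume dispensed per arrival (μl)."""
        return self.reward_drops * self.drop_volume


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and task constants for one arena layout."""

    task: str = "main"  # "main" | "probe"
    arena_radius: float = 0.8
    start_position: tuple[float, float] = (0.0, 0.0)
    departure_circle_radius: float = 0.10
    perimeter_radius: float = 0.62
    zones: tuple[RewardZone, ...] = ()
    start_directions: tuple[float, ...] = MAIN_START_DIRECTIONS
    iti_still_duration: float = 5.0
    iti_speed_threshold: float = 1.0  # cm/s
    trial_timeout: float = 120.0
    sample_rate: float = 60.0
    # probe-task extras
    has_landmarks: bool = True
    reward_zone_radius: float | None = None
    beacon_positions: dict | None = None

    def zone(self, label: str) -> RewardZone:
        for z in self.zones:
            if z.label == label:
                return z
        raise KeyError(f"no zone labeled {label!r}")

    def validate(self) -> "ArenaConfig":
        if not (self.departure_circle_radius < self.perimeter_radius < self.arena_radius):
            raise ArenaConfigError(
                "require departure_circle_radius < perimeter_radius < arena_radius, "
                f"got {self.departure_circle_radius}, {self.perimeter_radius}, "
                f"{self.arena_radius}"
            )
        for d in self.start_directions:
            if not (0.0 <= d < 360.0):
                raise ArenaConfigError(f"start direction {d} outside [0, 360)")
            for z in self.zones:
                if math.isclose(d, z.center_angle):
                    raise ArenaConfigError(
                        f"start direction {d} coincides with {z.label}-zone center"
                    )
        if self.task == "main":
            if len(self.start_directions) != 6:
                raise ArenaConfigError("main task requires exactly 6 start directions")
            for z in self.zones:
                if not math.isclose(z.inner_radius, self.perimeter_radius):
                    raise ArenaConfigError(
                        "perimeter boundary must share every zone's inner radius"
                    )
        for z in self.zones:
            if z.outer_radius >= self.arena_radius:
                raise ArenaConfigError(
                    f"{z.label} zone outer radius reaches the arena wall"
                )
        return self

    # JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["zones"] = [asdict(z) for z in self.zones]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaConfig":
        d = dict(d)
        d["zones"] = tuple(RewardZone(**z) for z in d.get("zones", ()))
        d["start_position"] = tuple(d.get("start_position", (0.0, 0.0)))
        d["start_directions"] = tuple(d.get("start_directions", ()))
        return cls(**d).validate()

    @classmethod
    def from_json(cls, s: str) -> "ArenaConfig":
        return cls.from_dict(json.loads(s))


def _default_main_zones() -> tuple[RewardZone, RewardZone]:
    high = RewardZone(label="high", center_angle=180.0, reward_drops=12)
    low = RewardZone(label="low", center_angle=0.0, reward_drops=2)
    return (high, low)


_ZONE_OVERRIDE_KEYS = {
    "angular_halfwidth", "inner_radius", "outer_radius", "reward_drops", "drop_volume",
}


def build_main_arena(overrides: dict | None = None) -> ArenaConfig:
    """Build the default main-task arena, applying recognized overrides.

    Defaults: 1.6 m diameter arena, center start, 0.10 m departure-circle
    radius, 0.62 m perimeter radius, high zone at 180 deg (12 drops) and
    low zone at 0 deg (2 drops), six start directions.

    Parameters
    ----------
    overrides : dict, optional
        Top-level ``ArenaConfig`` field overrides, plus ``"high_zone"`` /
        ``"low_zone"`` sub-dicts for per-zone overrides.

    Raises
    ------
    ArenaConfigError
        On an unrecognized key or a violated geometric invariant.
    """
    overrides = dict(overrides or {})
    zone_overrides = {
        "high": overrides.pop("high_zone", {}),
        "low": overrides.pop("low_zone", {}),
    }
    zones = []
    for z in _default_main_zones():
        zo = dict(zone_overrides[z.label])
        unknown = set(zo) - _ZONE_OVERRIDE_KEYS
        if unknown:
            raise ArenaConfigError(f"unknown {z.label}_zone override keys: {sorted(unknown)}")
        zones.append(replace(z, **zo))

    cfg = ArenaConfig(task="main", zones=tuple(zones))
    known = set(cfg.__dataclass_fields__) - {"task", "zones"}
    unknown = set(overrides) - known
    if unknown:
        raise ArenaConfigError(f"unknown override keys: {sorted(unknown)}")
    if "start_directions" in overrides:
        overrides["start_directions"] = tuple(overrides["start_directions"])
    # zones inherit a changed perimeter radius unless explicitly overridden
    if "perimeter_radius" in overrides:
        pr = overrides["perimeter_radius"]
        cfg = replace(
            cfg,
            zones=tuple(
                z if zone_overrides[z.label].get("inner_radius") is not None
                else replace(z, inner_radius=pr)
                for z in cfg.zones
            ),
        )
    return replace(cfg, **overrides).validate()


#: Probe-task layout constants (positions in m, arena frame).
PROBE_START = (0.0, -0.7)          # south periphery
PROBE_START_DIRECTION = 270.0      # facing North, toward the center
PROBE_BEACON_RADIUS = 0.5          # beacon distance from arena center
PROBE_BEACON_ANGLES = {"left": 225.0, "right": 315.0}  # symmetric about heading


def build_probe_arena() -> ArenaConfig:
    """Build the object-guided probe-task arena.

    No peripheral landmarks; fixed south-periphery start heading north;
    two mirror-symmetric beacon spawn positions; reward zone is a
    0.4 m-radius disc around the spawned beacon; 60 s trial timeout.
    """
    beacons = {
        side: point_at(ang, PROBE_BEACON_RADIUS)
        for side, ang in PROBE_BEACON_ANGLES.items()
    }
    return ArenaConfig(
        task="probe",
        start_position=PROBE_START,
        start_directions=(PROBE_START_DIRECTION,),
        trial_timeout=60.0,
        has_landmarks=False,
        reward_zone_radius=0.4,
        beacon_positions=beacons,
        zones=(),
    ).validate()


def angle_of(point: tuple[float, float], config: ArenaConfig | None = None) -> float:
    """Arena-frame angle of ``point`` about the arena center.

    Measured clockwise from East, in degrees in ``[0, 360)``.

    Raises
    ------
    ValueError
        If the point coincides with the arena center.
    """
    x, y = point
    if x == 0.0 and y == 0.0:
        raise ValueError("angle undefined at the arena center")
    return math_to_arena(math.degrees(math.atan2(y, x)))


def point_at(angle_deg: float, radius: float) -> tuple[float, float]:
    """Cartesian point at the given arena-frame angle and radius."""
    a = math.radians(arena_to_math(angle_deg))
    return (radius * math.cos(a), radius * math.sin(a))


def circular_deviation(a: float, b: float) -> float:
    """Smallest absolute angular difference between two angles, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def zone_membership(point: tuple[float, float], config: ArenaConfig) -> str:
    """Classify a point as inside the ``high`` zone, ``low`` zone or ``none``.

    Raises
    ------
    ValueError
        If the point lies outside the arena.
    """
    x, y = point
    r = math.hypot(x, y)
    if r > config.arena_radius + 1e-12:
        raise ValueError(f"point at radius {r:.3f} m is outside the arena")
    if r == 0.0:
        return "none"
    ang = angle_of(point)
    for z in config.zones:
        if z.contains(r, ang):
            return z.label
    return "none"
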