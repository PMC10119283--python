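"""Frame-based simulation of the boat-docking trial world.

The world is a circular grid (radius 3.82 visual-degree units) in which a
cursor is piloted from a start (S) to a goal (G).  A cursor can accelerate
along one of three fixed headings, 2*pi/3 apart.  Every throttled frame burns
one unit from a 360-unit fuel tank and adds a fixed speed increment along the
pressed heading; velocity persists when no throttle is down (frictionless
point mass, forward-Euler at 60 Hz).  A trial ends at the first of four
terminal events: a successful dock (entering a 0.479-radius disc around G at
speed <= 1.920/s), leaving the grid, arriving too fast, or running out of
fuel.  Reward is the proportion of fuel conserved on a dock, 0 otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "CursorSpec",
    "SGPair",
    "WorldConfig",
    "ExecutionTrace",
    "TrialOutcome",
    "SkillMeasures",
    "State",
    "OutOfFuelError",
    "UnterminatedTraceError",
    "congruent_cursor",
    "incongruent_cursor",
    "sample_sg",
    "step_dynamics",
    "run_schedule",
    "adjudicate",
    "compute_skill",
]

# Headings in radians; pi/2 is the upward vertical.
CONGRUENT_HEADINGS = (7 * math.pi / 6, math.pi / 2, 11 * math.pi / 6)
INCONGRUENT_HEADINGS = (5 * math.pi / 6, math.pi / 6, 3 * math.pi / 2)


class OutOfFuelError(RuntimeError):
    """Raised when a throttle is requested with an empty fuel tank."""


class UnterminatedTraceError(RuntimeError):
    """Raised when a bounded trace ends without any terminal event."""


@dataclass(frozen=True)
class CursorSpec:
    """A cursor's three displacement headings and congruency label.

    ``throttle_map`` maps finger names to heading indices; ties between
    simultaneous presses are resolved upstream by fixed finger priority
    (index > middle > ring).
    """

    label: str  # "congruent" | "incongruent"
    headings: tuple[float, float, float]
    throttle_map: tuple[str, str, str] = ("index", "middle", "ring")

    def __post_init__(self) -> None:
        if self.label not in ("congruent", "incongruent"):
            raise ValueError(f"unknown cursor label {self.label!r}")
        h = np.sort(np.mod(self.headings, 2 * math.pi))
        gaps = np.diff(np.concatenate([h, [h[0] + 2 * math.pi]]))
        if not np.allclose(gaps, 2 * math.pi / 3, atol=1e-9):
            raise ValueError("cursor headings must be mutually 2*pi/3 apart")

    @property
    def unit_vectors(self) -> np.ndarray:
        """(3, 2) array of unit displacement vectors, one per heading."""
        a = np.asarray(self.headings)
        return np.stack([np.cos(a), np.sin(a)], axis=1)


def congruent_cursor() -> CursorSpec:
    return CursorSpec("congruent", CONGRUENT_HEADINGS)


def incongruent_cursor() -> CursorSpec:
    return CursorSpec("incongruent", INCONGRUENT_HEADINGS)


@dataclass(frozen=True)
class WorldConfig:
    """World constants; defaults reproduce the task's stated geometry.

    ``accel_per_frame`` is a package convention (the original acceleration
    dynamics are not published): 0.032 means exactly 1 s of continuous
    throttle reaches the dock speed limit of 1.920/s.
    """

    fuel_units: int = 360
    frame_rate: float = 60.0
    grid_radius: float = 3.82
    perimeter_margin: float = 0.320
    min_sg_separation: float = 0.957
    dock_radius: float = 0.479
    dock_speed_limit: float = 1.920
    accel_per_frame: float = 0.032
    # Wall-time horizon the route planner must dock within (seconds);
    # defaults to the same 6-s window that bounds throttle time.  Without
    # some horizon the fuel-minimal plan degenerates to "throttle once and
    # coast forever" and lambda would not depend on distance.
    route_time_limit_s: float = 6.0

    def __post_init__(self) -> None:
        for name in (
            "fuel_units", "frame_rate", "grid_radius", "perimeter_margin",
            "min_sg_separation", "dock_radius", "dock_speed_limit",
            "accel_per_frame", "route_time_limit_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def max_throttle_seconds(self) -> float:
        """Total throttle time available per trial (fuel / frame rate)."""
        return self.fuel_units / self.frame_rate


@dataclass(frozen=True)
class SGPair:
    """A start-goal pair inside the grid."""

    start: tuple[float, float]
    goal: tuple[float, float]
    grid_radius: float = 3.82

    @property
    def displacement(self) -> np.ndarray:
        return np.asarray(self.goal) - np.asarray(self.start)

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.displacement))

    @property
    def direction_rad(self) -> float:
        d = self.displacement
        if not d.any():
            raise ValueError("zero-length SG vector has no direction")
        return float(math.atan2(d[1], d[0]) % (2 * math.pi))

    def is_admissible(self, config: WorldConfig) -> bool:
        rmax = config.grid_radius - config.perimeter_margin
        return (
            np.linalg.norm(self.start) <= rmax
            and np.linalg.norm(self.goal) <= rmax
            and self.distance >= config.min_sg_separation
        )


def sample_sg(rng: np.random.Generator, config: WorldConfig = WorldConfig()) -> SGPair:
    """Draw an SG pair uniformly over the admissible region.

    Rejection sampling: both points uniform in the disc of radius
    ``grid_radius - perimeter_margin``, rejected until their separation is at
    least ``min_sg_separation``.
    """
    rmax = config.grid_radius - config.perimeter_margin
    while True:
        pts = rng.uniform(-rmax, rmax, size=(2, 2))
        if np.any(np.linalg.norm(pts, axis=1) > rmax):
            continue
        if np.linalg.norm(pts[1] - pts[0]) < config.min_sg_separation:
            continue
        return SGPair(tuple(pts[0]), tuple(pts[1]), config.grid_radius)


@dataclass(frozen=True)
class State:
    pos: tuple[float, float]
    vel: tuple[float, float]
    fuel: int


def step_dynamics(
    state: State,
    throttle: Optional[int],
    cursor: CursorSpec,
    config: WorldConfig = WorldConfig(),
) -> State:
    """Advance one frame: throttle adds a speed increment and burns fuel.

    If ``throttle`` is a heading index, velocity gains ``accel_per_frame``
    along that heading and fuel drops by 1; position then advances by
    velocity / frame_rate.  Unthrottled frames leave velocity and fuel
    unchanged (frictionless coasting).
    """
    vx, vy = state.vel
    fuel = state.fuel
    if throttle is not None:
        if fuel <= 0:
            raise OutOfFuelError("throttle requested with empty tank")
        a = config.accel_per_frame
        ang = cursor.headings[throttle]
        vx += a * math.cos(ang)
        vy += a * math.sin(ang)
        fuel -= 1
    x = state.pos[0] + vx / config.frame_rate
    y = state.pos[1] + vy / config.frame_rate
    return State((x, y), (vx, vy), fuel)


@dataclass
class ExecutionTrace:
    """Per-frame record of one action-execution period.

    ``throttle`` holds the heading index pressed on each frame, -1 when no
    throttle was down.  Frame 0 is the trial start (cursor at rest on S).
    """

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    throttle: np.ndarray
    fuel: np.ndarray

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame, "x": self.x, "y": self.y,
                "vx": self.vx, "vy": self.vy,
                "throttle": self.throttle, "fuel": self.fuel,
            }
        )


@dataclass(frozen=True)
class TrialOutcome:
    kind: str  # dock | out_of_gas | left_grid | too_fast
    reward: float
    terminal_frame: int

    def __post_init__(self) -> None:
        if self.kind not in ("dock", "out_of_gas", "left_grid", "too_fast"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if not (0.0 <= self.reward <= 1.0):
            raise ValueError("reward must lie in [0, 1]")
        if self.reward > 0 and self.kind != "dock":
            raise ValueError("only docks yield reward")


@dataclass(frozen=True)
class SkillMeasures:
    reward: float
    direction_changes: int
    temporal_skill: Optional[float]  # None when the goal disc was never crossed


def _terminal_event(
    pos: np.ndarray, speed: float, inside_dock_prev: bool, inside_dock: bool,
    fuel: int, config: WorldConfig,
) -> Optional[str]:
    """Adjudicate one frame.  Dock/too-fast fire on *entering* the goal disc."""
    if inside_dock and not inside_dock_prev:
        # relative tolerance: "no greater than" is inclusive, and speed is a
        # float accumulation of per-frame increments
        ok = speed <= config.dock_speed_limit * (1 + 1e-9)
        return "dock" if ok else "too_fast"
    if np.hypot(pos[0], pos[1]) > config.grid_radius:
        return "left_grid"
    if fuel <= 0:
        return "out_of_gas"
    return None


def run_schedule(
    schedule: Iterable[Optional[int]],
    sg: SGPair,
    cursor: CursorSpec,
    config: WorldConfig = WorldConfig(),
) -> ExecutionTrace:
    """Execute a throttle schedule from rest at S; stop at the first terminal
    event (or at schedule end).

    The schedule yields a heading index (0..2) or None per frame.  The trace
    includes frame 0 (initial state) through the terminal frame.
    """
    goal = np.asarray(sg.goal)
    state = State(tuple(sg.start), (0.0, 0.0), config.fuel_units)
    frames = [0]
    xs = [state.pos[0]]; ys = [state.pos[1]]
    vxs = [0.0]; vys = [0.0]
    throttles = [-1]
    fuels = [config.fuel_units]
    inside_prev = np.hypot(*(np.asarray(state.pos) - goal)) <= config.dock_radius
    k = 0
    for thr in schedule:
        k += 1
        state = step_dynamics(state, thr, cursor, config)
        frames.append(k)
        xs.append(state.pos[0]); ys.append(state.pos[1])
        vxs.append(state.vel[0]); vys.append(state.vel[1])
        throttles.append(-1 if thr is None else thr)
        fuels.append(state.fuel)
        pos = np.asarray(state.pos)
        inside = np.hypot(*(pos - goal)) <= config.dock_radius
        speed = math.hypot(*state.vel)
        if _terminal_event(pos, speed, inside_prev, inside, state.fuel, config):
            break
        inside_prev = inside
    return ExecutionTrace(
        np.asarray(frames), np.asarray(xs), np.asarray(ys),
        np.asarray(vxs), np.asarray(vys),
        np.asarray(throttles), np.asarray(fuels),
    )


def adjudicate(
    trace: ExecutionTrace, sg: SGPair, config: WorldConfig = WorldConfig()
) -> TrialOutcome:
    """Classify a terminated trace into one of the four trial outcomes.

    Dock iff the goal disc is entered at speed <= the limit (inclusive, per
    "no greater than"); reward = fuel conserved / tank size on a dock, else 0.
    Raises :class:`UnterminatedTraceError` if no terminal event occurs.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    goal = np.asarray(sg.goal)
    dist = np.hypot(trace.x - goal[0], trace.y - goal[1])
    inside = dist <= config.dock_radius
    speed = trace.speed
    prev_inside = np.concatenate([[inside[0]], inside[:-1]])
    entered = inside & ~prev_inside  # frame 0 is never an entry
    for i in range(1, len(trace)):
        if entered[i]:
            if speed[i] <= config.dock_speed_limit * (1 + 1e-9):
                reward = trace.fuel[i] / config.fuel_units
                return TrialOutcome("dock", float(reward), int(trace.frame[i]))
            return TrialOutcome("too_fast", 0.0, int(trace.frame[i]))
        if np.hypot(trace.x[i], trace.y[i]) > config.grid_radius:
            return TrialOutcome("left_grid", 0.0, int(trace.frame[i]))
        if trace.fuel[i] <= 0:
            return TrialOutcome("out_of_gas", 0.0, int(trace.frame[i]))
    raise UnterminatedTraceError(
        "no terminal event in bounded trace; extend or abort"
    )


def compute_skill(
    trace: ExecutionTrace, sg: SGPair, config: WorldConfig = WorldConfig()
) -> SkillMeasures:
    """Per-trial skill measures from a terminated trace.

    direction_changes counts adjacent-distinct transitions over the sequence
    of throttled frames; temporal_skill = (v_max - v_final) / SG distance and
    is defined only when the goal disc was crossed (dock or too_fast).
    """
    outcome = adjudicate(trace, sg, config)
    pressed = trace.throttle[trace.throttle >= 0]
    changes = int(np.sum(np.diff(pressed) != 0)) if len(pressed) > 1 else 0
    temporal: Optional[float] = None
    if outcome.kind in ("dock", "too_fast"):
        speed = trace.speed
        i_final = int(np.searchsorted(trace.frame, outcome.terminal_frame))
        v_final = speed[i_final]
        v_max = speed[: i_final + 1].max()
        temporal = float((v_max - v_final) / sg.distance)
    return SkillMeasures(outcome.reward, changes, temporal)
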