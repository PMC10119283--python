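"""Trialwise cursor-suitability scores: spatial heuristic vs route planning.

Two continuous scores enumerate how well each cursor suits a start-goal (SG)
pair:

* the *heuristic offset* — the smallest wrapped angular distance (degrees)
  between the SG direction and the incongruent cursor's three headings.  It
  ranges over [0, 60]: 0 means the SG lies on an incongruent heading, 60 on a
  congruent heading, and 30 is the indifference point.

* the *route-planning score* — the difference in projected reward between the
  fuel-optimal route flown with the congruent cursor and with the incongruent
  cursor, where projected reward is (360 - lambda) / 360 and lambda is the
  number of throttled frames in the optimal plan.  Positive values favour the
  congruent cursor; 0 is the indifference point.

The optimal-route search enumerates a candidate family of plans that is
consistent-by-construction with the world simulator: single-heading plans
whose ray passes within the dock radius of the goal, two-segment plans using
the unique nonnegative decomposition of the SG displacement onto a pair of
cursor headings (full stop at the turn point, braking realised by alternating
the cursor's other two throttles), and m-fold zig-zags of the same two
headings when both two-segment turn points would leave the grid, and
"blended" plans that interleave pulses of the two decomposition headings so
the net velocity points straight along the chord.  Every plan must dock
within a wall-time horizon (``WorldConfig.route_time_limit_s``, default the
6-s trial window), which is what makes faster displacement more fuel
efficient: covering a longer path inside the window demands higher peak
speed, hence more throttled frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .world import (
    CursorSpec,
    ExecutionTrace,
    SGPair,
    State,
    WorldConfig,
    adjudicate,
    congruent_cursor,
    incongruent_cursor,
    step_dynamics,
)

__all__ = [
    "RouteLeg",
    "RoutePlan",
    "RouteUnsolvableError",
    "DifficultyBinning",
    "heuristic_offset",
    "appropriate_cursor",
    "optimal_route",
    "route_planning_score",
    "make_difficulty_bins",
    "fly_plan",
]

# Fraction of the dock radius used as an aiming margin by the planner; the
# slack absorbs frame quantisation and braking drift so plans replay cleanly.
_AIM_MARGIN = 0.80
_WAYPOINT_MARGIN = 0.06  # keep turn points this far inside the grid edge
_MAX_ZIGZAG_PAIRS = 8
_MAX_STOP_ACCEL = 150  # peak-speed cap (frames of accel) for legs ending in a stop


class RouteUnsolvableError(RuntimeError):
    """No candidate plan docks under the given configuration."""


def heuristic_offset(sg: SGPair, incongruent: Optional[CursorSpec] = None) -> float:
    """Angular offset (degrees) between the SG direction and the nearest
    incongruent heading, wrapped to [0, 180] before the minimum.

    By the interleaved cursor geometry the result lies in [0, 60].
    """
    if incongruent is None:
        incongruent = incongruent_cursor()
    theta = sg.direction_rad  # raises on zero-length SG
    diffs = [
        abs((theta - h + math.pi) % (2 * math.pi) - math.pi)
        for h in incongruent.headings
    ]
    # the interleaved geometry bounds the minimum by 60 deg; clamp float eps
    return min(max(math.degrees(min(diffs)), 0.0), 60.0)


def appropriate_cursor(offset_deg: float) -> str:
    """State-appropriate cursor from the offset: incongruent below 30,
    congruent above 30, indeterminate exactly at the boundary."""
    if offset_deg < 30.0:
        return "incongruent"
    if offset_deg > 30.0:
        return "congruent"
    return "indeterminate"


@dataclass(frozen=True)
class RouteLeg:
    heading_index: int
    length: float
    accel_frames: int
    stop: bool  # True: ends with a full brake; False: coasts into the dock


@dataclass(frozen=True)
class BlendLeg:
    """Interleaved thrust on two headings whose integer pulse counts sum to a
    net velocity along the SG chord; the cursor then coasts into the dock.

    Geometrically a straight-line flight (the thrust-phase wander around the
    chord is a fraction of the dock radius), so it is always inside the grid;
    it is the fuel-efficient realisation of a "zig-zag" route when full-stop
    turns would exhaust the tank.
    """

    heading_i: int
    heading_j: int
    pulses_i: int
    pulses_j: int

    @property
    def accel_frames(self) -> int:
        return self.pulses_i + self.pulses_j


@dataclass(frozen=True)
class RoutePlan:
    cursor_label: str
    legs: tuple[RouteLeg, ...]
    lam: int  # total throttled frames
    projected_reward: float
    segmentation: str  # "single" | "multiple"
    est_frames: int  # closed-form wall-time estimate

    @property
    def n_legs(self) -> int:
        return len(self.legs)


def _acc_dist(a, A: float, fps: float):
    """Distance covered while accelerating for ``a`` frames from rest."""
    a = np.asarray(a, dtype=float)
    return A * a * (a + 1) / (2.0 * fps)


def _brk_dist(a, A: float, fps: float):
    """Distance covered while braking from speed a*A over 2a frames at A/2."""
    a = np.asarray(a, dtype=float)
    return A * a * (2 * a - 1) / (2.0 * fps)


def _leg_times(
    L: float,
    a_grid: np.ndarray,
    A: float,
    fps: float,
    stop: bool,
    accel_cap: Optional[float] = None,
) -> np.ndarray:
    """Wall-time (frames) to fly a leg of length L for each accel count, or
    +inf where the accel count cannot realise the leg.

    ``accel_cap`` bounds the distance covered during the accel phase of a
    final (coast-into-dock) leg so the goal disc is always entered while
    coasting, keeping the replayed throttle count equal to the planned one.
    """
    v = a_grid * A
    if stop:
        travel = _acc_dist(a_grid, A, fps) + _brk_dist(a_grid, A, fps)
        coast = np.ceil((L - travel) * fps / v)
        t = a_grid + coast + 2 * a_grid
        t = np.where(travel <= L, t, np.inf)
    else:
        d_acc = _acc_dist(a_grid, A, fps)
        coast = np.maximum(np.ceil((L - d_acc) * fps / v), 0.0)
        t = a_grid + coast
        cap = L if accel_cap is None else min(L, accel_cap)
        t = np.where(d_acc <= cap, t, np.inf)
    return t


def _blended_candidate(
    sg: SGPair,
    cursor: CursorSpec,
    config: WorldConfig,
    decomp: tuple[int, int, float, float],
) -> Optional[RoutePlan]:
    """Minimal-fuel blended-heading plan (see :class:`BlendLeg`)."""
    i, j, ci, cj = decomp
    units = cursor.unit_vectors
    A, fps = config.accel_per_frame, config.frame_rate
    T_max = int(config.route_time_limit_s * fps)
    aim = _AIM_MARGIN * config.dock_radius
    d = sg.displacement
    w = ci / (ci + cj)
    limit = config.dock_speed_limit
    for n in range(2, config.fuel_units):
        best = None
        for a_i in {math.floor(w * n), math.ceil(w * n)}:
            a_j = n - a_i
            if a_i < 1 or a_j < 1:
                continue
            v = A * (a_i * units[i] + a_j * units[j])
            sp = float(np.linalg.norm(v))
            if sp > limit * (1 - 1e-9) or sp <= 0:
                continue
            vhat = v / sp
            t_proj = float(d @ vhat)
            if t_proj <= 0:
                continue
            miss = float(np.linalg.norm(d - t_proj * vhat))
            if miss > aim:
                continue
            L_entry = t_proj - math.sqrt(aim * aim - miss * miss)
            r = config.dock_radius
            true_entry = t_proj - math.sqrt(max(r * r - miss * miss, 0.0))
            p_thrust = sp * (n + 1) / (2 * fps)  # ramp-up displacement
            if p_thrust > true_entry - 0.05:
                continue
            t = n + max(math.ceil((L_entry - p_thrust) * fps / sp), 0)
            if t > T_max:
                continue
            if best is None or miss < best[1]:
                best = ((a_i, a_j), miss, t)
        if best is not None:
            (a_i, a_j), _, t = best
            leg = BlendLeg(i, j, a_i, a_j)
            return RoutePlan(
                cursor.label, (leg,), n,
                (config.fuel_units - n) / config.fuel_units,
                "multiple", int(t),
            )
    return None


def _heading_pair_decomposition(
    d: np.ndarray, units: np.ndarray
) -> Optional[tuple[int, int, float, float]]:
    """Unique nonnegative 2-vector decomposition of displacement d onto a
    pair of the cursor's headings, if one exists."""
    best = None
    for i in range(3):
        for j in range(i + 1, 3):
            M = np.column_stack([units[i], units[j]])
            try:
                c = np.linalg.solve(M, d)
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            if c[0] >= -1e-12 and c[1] >= -1e-12:
                best = (i, j, max(c[0], 0.0), max(c[1], 0.0))
    return best


def _single_heading_candidates(
    sg: SGPair, cursor: CursorSpec, config: WorldConfig
) -> list[RoutePlan]:
    d = sg.displacement
    units = cursor.unit_vectors
    A, fps = config.accel_per_frame, config.frame_rate
    T_max = int(config.route_time_limit_s * fps)
    a_max = int(config.dock_speed_limit // A)
    aim = _AIM_MARGIN * config.dock_radius
    out: list[RoutePlan] = []
    for i in range(3):
        t_proj = float(d @ units[i])
        if t_proj <= 0:
            continue
        miss = float(np.linalg.norm(d - t_proj * units[i]))
        if miss > aim:
            continue
        L_entry = t_proj - math.sqrt(aim * aim - miss * miss)
        if L_entry <= 0:
            continue
        r = config.dock_radius
        true_entry = t_proj - math.sqrt(max(r * r - miss * miss, 0.0))
        a_grid = np.arange(1, a_max + 1)
        times = _leg_times(L_entry, a_grid, A, fps, stop=False,
                           accel_cap=true_entry - 0.05)
        ok = np.nonzero(times <= T_max)[0]
        if ok.size == 0:
            continue
        a = int(a_grid[ok[0]])  # smallest feasible accel count = smallest lambda
        leg = RouteLeg(i, L_entry, a, stop=False)
        out.append(
            RoutePlan(
                cursor.label, (leg,), a, (config.fuel_units - a) / config.fuel_units,
                "single", int(times[ok[0]]),
            )
        )
    return out


def _legged_candidate(
    sg: SGPair,
    cursor: CursorSpec,
    config: WorldConfig,
    legs_geom: Sequence[tuple[int, float]],
) -> Optional[RoutePlan]:
    """Best plan for a fixed leg geometry (heading index, length per leg);
    all legs but the last end with a full stop.  Returns None if infeasible
    within the trial window."""
    A, fps = config.accel_per_frame, config.frame_rate
    T_max = int(config.route_time_limit_s * fps)
    a_max = int(config.dock_speed_limit // A)  # arrival-speed cap, final leg
    # intermediate legs brake to a stop, so their peak speed may exceed the
    # dock limit; cap the accel grid where braking distance outgrows the leg
    a_stop = np.arange(1, _MAX_STOP_ACCEL + 1)
    n_stop = len(legs_geom) - 1
    stop_times = np.zeros(a_stop.shape)
    for _, L in legs_geom[:-1]:
        stop_times = stop_times + _leg_times(L, a_stop, A, fps, stop=True)
    L_final = legs_geom[-1][1] - _AIM_MARGIN * config.dock_radius
    if L_final <= 0:
        return None
    fin_times = _leg_times(
        L_final, np.arange(1, a_max + 1), A, fps, stop=False,
        accel_cap=legs_geom[-1][1] - config.dock_radius - 0.05,
    )
    a_fin = np.arange(1, a_max + 1)
    # lambda(a_s, a_f) = 3 * n_stop * a_s + a_f, subject to total time <= T_max
    total = stop_times[:, None] + fin_times[None, :]
    lam = 3 * n_stop * a_stop[:, None] + a_fin[None, :]
    feasible = (total <= T_max) & (lam < config.fuel_units)
    if not feasible.any():
        return None
    lam_f = np.where(feasible, lam, np.iinfo(np.int64).max)
    idx = np.unravel_index(np.argmin(lam_f), lam_f.shape)
    a_s, a_f = int(a_stop[idx[0]]), int(a_fin[idx[1]])
    legs = tuple(
        RouteLeg(h, L, a_s, stop=True) for h, L in legs_geom[:-1]
    ) + (RouteLeg(legs_geom[-1][0], L_final, a_f, stop=False),)
    lam_best = 3 * n_stop * a_s + a_f
    return RoutePlan(
        cursor.label, legs, lam_best,
        (config.fuel_units - lam_best) / config.fuel_units,
        "multiple", int(total[idx]),
    )


def _waypoints_inside(
    start: np.ndarray,
    legs_geom: Sequence[tuple[int, float]],
    units: np.ndarray,
    config: WorldConfig,
) -> bool:
    pos = start.astype(float).copy()
    rmax = config.grid_radius - _WAYPOINT_MARGIN
    for h, L in legs_geom[:-1]:
        pos = pos + L * units[h]
        if np.linalg.norm(pos) > rmax:
            return False
    return True


def optimal_route(
    sg: SGPair,
    cursor: CursorSpec,
    config: WorldConfig = WorldConfig(),
    validate: bool = False,
) -> RoutePlan:
    """Fuel-optimal plan for one cursor on one SG (minimal throttled frames
    among the candidate family, subject to docking within the trial window).

    With ``validate=True`` the returned plan is replayed through the world
    simulator and must dock; see :func:`fly_plan`.
    """
    d = sg.displacement
    units = cursor.unit_vectors
    candidates = _single_heading_candidates(sg, cursor, config)
    decomp = _heading_pair_decomposition(d, units)
    if decomp is not None:
        i, j, ci, cj = decomp
        if ci > 1e-9 and cj > 1e-9:
            blend = _blended_candidate(sg, cursor, config, decomp)
            if blend is not None:
                candidates.append(blend)
            start = np.asarray(sg.start)
            for order in (((i, ci), (j, cj)), ((j, cj), (i, ci))):
                if not _waypoints_inside(start, order, units, config):
                    continue
                cand = _legged_candidate(sg, cursor, config, order)
                if cand is not None:
                    candidates.append(cand)
            if not any(c.segmentation == "multiple" for c in candidates):
                # both turn points exit the grid: zig-zag the decomposition
                for m in range(2, _MAX_ZIGZAG_PAIRS + 1):
                    zig = []
                    for _ in range(m):
                        zig += [(i, ci / m), (j, cj / m)]
                    if not _waypoints_inside(start, zig, units, config):
                        continue
                    cand = _legged_candidate(sg, cursor, config, zig)
                    if cand is not None:
                        candidates.append(cand)
                        break
    if not candidates:
        raise RouteUnsolvableError(
            f"no candidate plan docks for SG {sg.start}->{sg.goal} "
            f"with the {cursor.label} cursor (unsolvable under config)"
        )
    candidates.sort(key=lambda p: (p.lam, p.n_legs, p.est_frames))
    best = candidates[0]
    if validate:
        trace = fly_plan(best, sg, cursor, config)
        outcome = adjudicate(trace, sg, config)
        if outcome.kind != "dock":
            raise RouteUnsolvableError(
                f"plan replay failed with outcome {outcome.kind}"
            )
        lam_flown = int(np.sum(trace.throttle >= 0))
        if lam_flown != best.lam:  # pragma: no cover - consistency guard
            raise RouteUnsolvableError(
                f"replayed lambda {lam_flown} != planned {best.lam}"
            )
    return best


def fly_plan(
    plan: RoutePlan,
    sg: SGPair,
    cursor: CursorSpec,
    config: WorldConfig = WorldConfig(),
) -> ExecutionTrace:
    """Closed-loop replay of a route plan through the world dynamics.

    Stop legs accelerate for the planned frame count, coast until the
    remaining along-heading distance equals the braking distance, then brake
    by alternating the cursor's other two throttles (net reverse acceleration
    accel/2, lateral components cancelling over frame pairs).  The final leg
    accelerates and coasts into the goal disc.
    """
    A, fps = config.accel_per_frame, config.frame_rate
    goal = np.asarray(sg.goal)
    state = State(tuple(sg.start), (0.0, 0.0), config.fuel_units)
    frames = [0]; xs = [state.pos[0]]; ys = [state.pos[1]]
    vxs = [0.0]; vys = [0.0]; throttles = [-1]; fuels = [state.fuel]
    units = cursor.unit_vectors
    k = 0
    hard_cap = 4 * config.fuel_units  # safety bound on wall frames

    def push(thr: Optional[int]) -> None:
        nonlocal state, k
        state = step_dynamics(state, thr, cursor, config)
        k += 1
        frames.append(k)
        xs.append(state.pos[0]); ys.append(state.pos[1])
        vxs.append(state.vel[0]); vys.append(state.vel[1])
        throttles.append(-1 if thr is None else thr)
        fuels.append(state.fuel)

    def in_dock() -> bool:
        return bool(np.hypot(*(np.asarray(state.pos) - goal)) <= config.dock_radius)

    waypoint = np.asarray(sg.start, dtype=float)
    for leg in plan.legs:
        if isinstance(leg, BlendLeg):
            # interleave pulses of the two headings (largest-remainder order)
            ai, n = leg.pulses_i, leg.accel_frames
            for f in range(n):
                thr = (
                    leg.heading_i
                    if (f + 1) * ai // n > f * ai // n
                    else leg.heading_j
                )
                push(thr)
            while not in_dock():
                push(None)
                if k > hard_cap:
                    break
            continue
        h, a = leg.heading_index, leg.accel_frames
        u = units[h]
        if leg.stop:
            waypoint = waypoint + leg.length * u
            for _ in range(a):
                push(h)
            d_brk = float(_brk_dist(a, A, fps))
            v = a * A
            while (waypoint - np.asarray(state.pos)) @ u > d_brk + v / fps:
                push(None)
                if k > hard_cap:
                    return _to_trace(frames, xs, ys, vxs, vys, throttles, fuels)
            others = [o for o in range(3) if o != h]
            for b in range(2 * a):
                push(others[b % 2])
        else:
            for _ in range(a):
                push(h)
                if in_dock():
                    return _to_trace(frames, xs, ys, vxs, vys, throttles, fuels)
            while not in_dock():
                push(None)
                if k > hard_cap:
                    break
    return _to_trace(frames, xs, ys, vxs, vys, throttles, fuels)


def _to_trace(frames, xs, ys, vxs, vys, throttles, fuels) -> ExecutionTrace:
    return ExecutionTrace(
        np.asarray(frames), np.asarray(xs), np.asarray(ys),
        np.asarray(vxs), np.asarray(vys),
        np.asarray(throttles), np.asarray(fuels),
    )


def route_planning_score(
    sg: SGPair,
    config: WorldConfig = WorldConfig(),
    cursors: Optional[tuple[CursorSpec, CursorSpec]] = None,
    validate: bool = False,
) -> tuple[float, RoutePlan, RoutePlan]:
    """Route-planning score = congruent projected reward - incongruent
    projected reward, with the two optimal plans."""
    if cursors is None:
        cursors = (congruent_cursor(), incongruent_cursor())
    cong, incong = cursors
    plan_c = optimal_route(sg, cong, config, validate=validate)
    plan_i = optimal_route(sg, incong, config, validate=validate)
    return plan_c.projected_reward - plan_i.projected_reward, plan_c, plan_i


@dataclass(frozen=True)
class DifficultyBinning:
    """Shared 5-bin difficulty partition of a pooled score distribution.

    Bin 1 holds the most incongruent-suited trials, bin 5 the most
    congruent-suited; bin 3 straddles the indifference point (offset 30 /
    route score 0).  Edges are pooled quantiles so per-bin counts are
    maximally equal across the cohort.
    """

    kind: str  # "offset" | "route"
    edges: tuple[float, ...]
    n_bins: int = 5

    def assign(self, scores) -> np.ndarray:
        """Map scores to bin indices 1..n_bins."""
        return np.searchsorted(np.asarray(self.edges), np.asarray(scores),
                               side="left") + 1


def make_difficulty_bins(scores, kind: str, n_bins: int = 5) -> DifficultyBinning:
    """Quantile bin edges pooled over the cohort (interior quantiles
    0.2, 0.4, 0.6, 0.8 for the default five bins)."""
    scores = np.asarray(scores, dtype=float)
    if np.unique(scores).size < n_bins:
        raise ValueError("need at least n_bins distinct scores")
    qs = np.arange(1, n_bins) / n_bins
    edges = tuple(np.quantile(scores, qs))
    binning = DifficultyBinning(kind, edges, n_bins)
    counts = np.bincount(binning.assign(scores), minlength=n_bins + 1)[1:]
    target = len(scores) / n_bins
    if counts.max() - counts.min() > max(2, 0.1 * target):
        warnings.warn(
            f"heavy ties prevent bin parity (counts {counts.tolist()})",
            stacklevel=2,
        )
    return binning
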