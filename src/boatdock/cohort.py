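"""Synthetic participants with known strategy, decision parameters and
skill dynamics — the pipeline's ground-truth oracle.

Each agent carries drift-diffusion parameters drawn from truncated normals
centred on published group-level values (heuristic, route-planner or
nonplanner profile), a per-cursor execution-skill profile (baseline
direction-change rate, temporal-skill mean/sd, linear and logarithmic
run-trend coefficients) and a catastrophic-error probability.  A session
mirrors the task structure: 360 choice trials in six runs of 60, SGs drawn
uniformly under the grid constraints, per-trial drift set by the difficulty
bin of the agent's own strategy score, and choices/RTs generated by
simulating the diffusion process.

Execution is generated statistically (Poisson direction changes, Gaussian
temporal skill) rather than by a closed-loop control policy: downstream
analyses consume only the skill measures.  Reward ties to skill through a
deterministic map — the optimal-route reward of the chosen cursor times an
exponential penalty in excess direction changes and temporal-skill deficit —
so reward, spatial and temporal skill covary the way the task couples them.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_ddm
from .strategy import (
    RoutePlan,
    appropriate_cursor,
    heuristic_offset,
    make_difficulty_bins,
    optimal_route,
)
from .world import WorldConfig, congruent_cursor, incongruent_cursor, sample_sg

__all__ = [
    "SkillProfile",
    "AgentSpec",
    "CohortSpec",
    "GROUP_DDM_MEANS",
    "make_agent",
    "simulate_session",
    "simulate_cohort",
    "ideal_direction_changes",
]

# Group-level DDM profiles (means) and between-agent spreads used by the
# generator; means follow the published group posteriors.
GROUP_DDM_MEANS = {
    "heuristic": dict(mu1=0.046, mu2=0.073, B=0.125, bC=0.070, t0=0.780),
    "route": dict(mu1=0.029, mu2=0.058, B=0.151, bC=0.147, t0=0.811),
    "null": dict(mu1=0.0, mu2=0.0, B=0.106, bC=0.267, t0=0.522),
}
GROUP_DDM_SPREADS = dict(mu1=0.010, mu2=0.012, B=0.020, bC=0.080, t0=0.100)
GROUP_CATASTROPHIC = {"heuristic": 0.118, "route": 0.128, "null": 0.178}

# Baseline direction-change rates per group x cursor (counts per trial) and
# temporal-skill means; anchored to the published collapsed group values.
_SPATIAL_RATES = {
    ("heuristic", "congruent"): 1.53,
    ("heuristic", "incongruent"): 1.58,
    ("route", "congruent"): 1.52,
    ("route", "incongruent"): 1.76,
    ("null", "congruent"): 1.60,
    ("null", "incongruent"): 1.85,
}
_TEMPORAL_MEANS = {
    ("heuristic", "congruent"): 0.671,
    ("heuristic", "incongruent"): 0.710,
    ("route", "congruent"): 0.690,
    ("route", "incongruent"): 0.677,
    ("null", "congruent"): 0.650,
    ("null", "incongruent"): 0.640,
}

# Reward map constants: reward = optimal reward * exp(-K_SPATIAL * excess
# direction changes - K_TEMPORAL * max(0, TEMPORAL_TARGET - temporal)).
K_SPATIAL = 0.15
K_TEMPORAL = 1.5
TEMPORAL_TARGET = 0.9


@dataclass(frozen=True)
class SkillProfile:
    """Execution-skill generator for one cursor.

    Trends are coefficients on the z-scored linear and logarithmic run
    regressors (runs 1..6); negative spatial trends mean fewer direction
    changes late in the session (learning).
    """

    spatial_log_rate: float
    spatial_trend_lin: float = 0.0
    spatial_trend_log: float = -0.10
    temporal_mean: float = 0.68
    temporal_sd: float = 0.25
    temporal_trend_lin: float = 0.0
    temporal_trend_log: float = 0.0


@dataclass(frozen=True)
class AgentSpec:
    agent_id: str
    strategy: str  # heuristic | route | null
    ddm: DDMParams
    skills: dict  # cursor label -> SkillProfile
    catastrophic_p: float
    seg_rt_penalty: float
    seed: int

    def __post_init__(self) -> None:
        if self.strategy not in ("heuristic", "route", "null"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "null" and (self.ddm.mu1 != 0 or self.ddm.mu2 != 0):
            raise ValueError("null strategy requires mu1 = mu2 = 0")
        if not (0 <= self.catastrophic_p < 1):
            raise ValueError("catastrophic_p must lie in [0, 1)")

    def to_manifest(self) -> dict:
        d = {
            "agent_id": self.agent_id,
            "strategy": self.strategy,
            "ddm": {k: getattr(self.ddm, k) for k in
                    ("mu1", "mu2", "B", "bC", "t0", "sigma")},
            "skills": {c: asdict(s) for c, s in self.skills.items()},
            "catastrophic_p": self.catastrophic_p,
            "seg_rt_penalty": self.seg_rt_penalty,
            "seed": self.seed,
        }
        return d


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout; defaults reproduce the session shape of the task
    (six runs of 60 choice trials)."""

    group_sizes: tuple = (("heuristic", 10), ("route", 10), ("null", 10))
    n_runs: int = 6
    trials_per_run: int = 60
    master_seed: int = 0
    world: WorldConfig = WorldConfig()

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    @property
    def n_agents(self) -> int:
        return sum(n for _, n in self.group_sizes)


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(min(max(mean, lo + 1e-6), hi - 1e-6))


def make_agent(
    strategy: str,
    rng: np.random.Generator,
    agent_id: str = "agent",
    seed: int = 0,
    overrides: Optional[dict] = None,
) -> AgentSpec:
    """Draw an agent of the given strategy.

    DDM parameters come from truncated normals centred on the group profile
    (respecting 0 <= mu1 <= mu2, B > 0, |bC| < 1, t0 >= 0); ``overrides``
    (field name -> value, e.g. ``{"ddm": ..., "seg_rt_penalty": 0.5}``) are
    applied last and re-validated.
    """
    m = GROUP_DDM_MEANS[strategy]
    s = GROUP_DDM_SPREADS
    if strategy == "null":
        mu1 = mu2 = 0.0
    else:
        mu2 = _trunc_normal(rng, m["mu2"], s["mu2"], 1e-4, 0.5)
        mu1 = _trunc_normal(rng, min(m["mu1"], mu2), s["mu1"], 0.0, mu2)
    ddm = DDMParams(
        mu1, mu2,
        _trunc_normal(rng, m["B"], s["B"], 0.02, 1.0),
        _trunc_normal(rng, m["bC"], s["bC"], -0.95, 0.95),
        _trunc_normal(rng, m["t0"], s["t0"], 0.05, 3.0),
    )
    skills = {}
    for cursor in ("congruent", "incongruent"):
        base = _SPATIAL_RATES[(strategy, cursor)] * math.exp(rng.normal(0, 0.10))
        skills[cursor] = SkillProfile(
            spatial_log_rate=math.log(base),
            spatial_trend_log=-0.10,
            temporal_mean=_TEMPORAL_MEANS[(strategy, cursor)] + rng.normal(0, 0.03),
            temporal_sd=0.25,
            # the route group uniquely learns in the temporal domain
            temporal_trend_log=0.04 if strategy == "route" else 0.0,
        )
    spec = AgentSpec(
        agent_id=agent_id,
        strategy=strategy,
        ddm=ddm,
        skills=skills,
        catastrophic_p=float(np.clip(
            rng.normal(GROUP_CATASTROPHIC[strategy], 0.02), 0.0, 0.5)),
        # route planners pay an extra planning cost on multi-segment
        # congruent-suited trials (drives the segmentation RT interaction)
        seg_rt_penalty=0.30 if strategy == "route" else 0.0,
        seed=seed,
    )
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def ideal_direction_changes(plan: RoutePlan) -> int:
    """Turn count of an optimal plan: 0 for a single heading, 1 for a
    blended (chord-following) plan, legs - 1 for explicit dog-legs."""
    if plan.segmentation == "single":
        return 0
    return max(plan.n_legs - 1, 1)


def _run_trend(profile: SkillProfile, kind: str, n_runs: int) -> np.ndarray:
    x = np.arange(1, n_runs + 1, dtype=float)
    zlin = (x - x.mean()) / x.std()
    lx = np.log(x)
    zlog = (lx - lx.mean()) / lx.std()
    if kind == "spatial":
        return profile.spatial_trend_lin * zlin + profile.spatial_trend_log * zlog
    return profile.temporal_trend_lin * zlin + profile.temporal_trend_log * zlog


def simulate_session(
    agent: AgentSpec,
    cohort: CohortSpec = CohortSpec(),
) -> pd.DataFrame:
    """Simulate one agent's full session; returns a trial table.

    Difficulty bins used for the drifts are the within-session quantile bins
    of the agent's own strategy score (the analysis pipeline later replaces
    the bin columns with cohort-pooled binnings).  Unsolvable SGs are
    resampled and counted in ``df.attrs["resampled_sgs"]``.
    """
    rng = np.random.default_rng(agent.seed)
    cfg = cohort.world
    n = cohort.n_trials
    cursors = {"congruent": congruent_cursor(), "incongruent": incongruent_cursor()}

    records = []
    plans: list[dict] = []
    resampled = 0
    while len(records) < n:
        sg = sample_sg(rng, cfg)
        try:
            plan_c = optimal_route(sg, cursors["congruent"], cfg)
            plan_i = optimal_route(sg, cursors["incongruent"], cfg)
        except Exception:
            resampled += 1
            continue
        off = heuristic_offset(sg)
        score = plan_c.projected_reward - plan_i.projected_reward
        records.append((sg, off, score))
        plans.append({"congruent": plan_c, "incongruent": plan_i})

    offsets = np.array([r[1] for r in records])
    scores = np.array([r[2] for r in records])
    own = offsets if agent.strategy == "heuristic" else scores
    if agent.strategy == "null":
        drifts = np.zeros(n)
        own_bins = np.full(n, 3)
    else:
        own_bins = make_difficulty_bins(
            own, "offset" if agent.strategy == "heuristic" else "route"
        ).assign(own)
        drifts = agent.ddm.drift_for_bin(own_bins)

    choice, rt, censored = simulate_ddm(agent.ddm, drifts, rng)
    runs = np.repeat(np.arange(1, cohort.n_runs + 1), cohort.trials_per_run)

    rows = []
    for i, (sg, off, score) in enumerate(records):
        cursor = "congruent" if choice[i] else "incongruent"
        appr = appropriate_cursor(off)
        plan_appr = plans[i]["congruent" if appr != "incongruent" else "incongruent"]
        segmentation = plan_appr.segmentation
        rt_i = rt[i]
        if (
            agent.seg_rt_penalty > 0
            and appr == "congruent"
            and segmentation == "multiple"
        ):
            rt_i += agent.seg_rt_penalty
        run = int(runs[i])
        prof = agent.skills[cursor]
        sp_trend = _run_trend(prof, "spatial", cohort.n_runs)[run - 1]
        tm_trend = _run_trend(prof, "temporal", cohort.n_runs)[run - 1]
        n_changes = int(rng.poisson(math.exp(prof.spatial_log_rate + sp_trend)))
        temporal = max(float(rng.normal(prof.temporal_mean + tm_trend,
                                        prof.temporal_sd)), 0.0)
        plan_chosen = plans[i][cursor]
        ideal = ideal_direction_changes(plan_chosen)
        if rng.uniform() < agent.catastrophic_p:
            outcome = ("out_of_gas", "left_grid", "too_fast")[rng.integers(3)]
            reward = 0.0
            temporal_out = temporal if outcome == "too_fast" else np.nan
        else:
            outcome = "dock"
            excess = max(0, n_changes - ideal)
            penalty = math.exp(
                -K_SPATIAL * excess
                - K_TEMPORAL * max(0.0, TEMPORAL_TARGET - temporal)
            )
            reward = float(np.clip(plan_chosen.projected_reward * penalty, 0.0, 1.0))
            temporal_out = temporal
        rows.append({
            "participant_id": agent.agent_id,
            "run": run,
            "trial_index": i,
            "start_x": sg.start[0], "start_y": sg.start[1],
            "goal_x": sg.goal[0], "goal_y": sg.goal[1],
            "cursor_chosen": cursor,
            "rt_seconds": float(rt_i),
            "outcome": outcome,
            "reward_proportion": reward,
            "direction_changes": n_changes,
            "temporal_skill": temporal_out,
            "offset_deg": off,
            "route_score": score,
            "bin_offset": 0,  # filled with pooled binnings downstream
            "bin_route": 0,
            "appropriate_cursor": appr,
            "segmentation": segmentation,
            "ideal_direction_changes": ideal,
        })
    df = pd.DataFrame(rows)
    df.attrs["resampled_sgs"] = resampled
    return df


def simulate_cohort(
    cohort: CohortSpec = CohortSpec(),
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort; returns the pooled trial table (with
    cohort-pooled difficulty binnings in ``bin_offset`` / ``bin_route``) and
    a ground-truth manifest.

    Agent seeds derive from the master seed via ``SeedSequence.spawn``, so
    the cohort is bitwise-reproducible and agents are independent.
    """
    ss = np.random.SeedSequence(cohort.master_seed)
    agent_seeds = ss.spawn(cohort.n_agents + 1)
    draw_rng = np.random.default_rng(agent_seeds[-1])
    frames = []
    manifest = {"master_seed": cohort.master_seed, "agents": []}
    idx = 0
    for strategy, size in cohort.group_sizes:
        for j in range(size):
            seed = int(agent_seeds[idx].generate_state(1)[0] % (2**31))
            agent = make_agent(
                strategy, draw_rng,
                agent_id=f"{strategy[0]}{j:02d}", seed=seed,
            )
            frames.append(simulate_session(agent, cohort))
            manifest["agents"].append(agent.to_manifest())
            idx += 1
    table = pd.concat(frames, ignore_index=True)
    off_bins = make_difficulty_bins(table["offset_deg"].to_numpy(), "offset")
    route_bins = make_difficulty_bins(table["route_score"].to_numpy(), "route")
    table["bin_offset"] = off_bins.assign(table["offset_deg"].to_numpy())
    table["bin_route"] = route_bins.assign(table["route_score"].to_numpy())
    manifest["binning"] = {
        "offset_edges": list(off_bins.edges),
        "route_edges": list(route_bins.edges),
    }
    manifest["resampled_sgs"] = int(sum(f.attrs.get("resampled_sgs", 0) for f in frames))
    return table, manifest
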