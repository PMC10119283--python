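"""Trial-table I/O, configuration and the end-to-end run.

The interchange format is a plain CSV (one row per trial, UTF-8, comma
delimited, '.' decimal) with a mandatory header.  The stages are:

    simulate -> score -> fit/classify -> analyze -> report

Every random draw derives from the seeds in :class:`RunConfig`, so a full
report is reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import bayes, cohort as cohort_mod, ddm as ddm_mod, strategy, world

logger = logging.getLogger("boatdock")

__all__ = [
    "REQUIRED_COLUMNS",
    "RunConfig",
    "SchemaError",
    "read_trials",
    "write_trials",
    "validate_trials",
    "score_trials",
    "classify_cohort",
    "analyze_cohort",
    "run_pipeline",
]

REQUIRED_COLUMNS = [
    "participant_id", "run", "trial_index",
    "start_x", "start_y", "goal_x", "goal_y",
    "cursor_chosen", "rt_seconds", "outcome",
    "reward_proportion", "direction_changes", "temporal_skill",
    "offset_deg", "route_score", "bin_offset", "bin_route",
    "appropriate_cursor", "segmentation",
]

_CURSORS = {"congruent", "incongruent"}
_OUTCOMES = {"dock", "out_of_gas", "left_grid", "too_fast"}


class SchemaError(ValueError):
    """Trial-table schema violation; lists the offending rows/columns."""


@dataclass
class RunConfig:
    """End-to-end run configuration (serialisable as plain ``key = value``
    text)."""

    seed: int = 0
    heuristic_n: int = 10
    route_n: int = 10
    null_n: int = 10
    n_runs: int = 6
    trials_per_run: int = 60
    n_restarts: int = 20
    draws_per_chain: int = 10_000
    hdi_mass: float = 0.94
    out_dir: str = "results"

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise SchemaError(f"unknown config key {key!r}")
            caster = float if types[key] == "float" else (
                str if types[key] == "str" else int)
            kwargs[key] = caster(value)
        return cls(**kwargs)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema; raises
    :class:`SchemaError` naming offending columns/rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    bad = df.index[df["rt_seconds"] <= 0].tolist()
    if bad:
        raise SchemaError(f"rt_seconds must be > 0; offending rows {bad[:10]}")
    bad = df.index[
        (df["reward_proportion"] < 0) | (df["reward_proportion"] > 1)
    ].tolist()
    if bad:
        raise SchemaError(f"reward_proportion outside [0,1]; rows {bad[:10]}")
    bad = df.index[~df["cursor_chosen"].isin(_CURSORS)].tolist()
    if bad:
        raise SchemaError(f"unknown cursor_chosen; rows {bad[:10]}")
    bad = df.index[~df["outcome"].isin(_OUTCOMES)].tolist()
    if bad:
        raise SchemaError(f"unknown outcome; rows {bad[:10]}")
    null_required = df["outcome"].isin(["out_of_gas", "left_grid"])
    bad = df.index[null_required & df["temporal_skill"].notna()].tolist()
    if bad:
        raise SchemaError(
            f"temporal_skill must be null for out_of_gas/left_grid; rows {bad[:10]}"
        )
    bad = df.index[~null_required & df["temporal_skill"].isna()].tolist()
    if bad:
        raise SchemaError(
            f"temporal_skill missing on a threshold-crossing trial; rows {bad[:10]}"
        )
    return df


def read_trials(path) -> pd.DataFrame:
    """Load and validate a TrialRecord CSV."""
    df = pd.read_csv(path, encoding="utf-8")
    return validate_trials(df)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a validated trial table; write -> read round-trips."""
    validate_trials(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def score_trials(
    df: pd.DataFrame, config: world.WorldConfig = world.WorldConfig()
) -> pd.DataFrame:
    """(Re)compute the strategy-score columns from the SG coordinates:
    offset_deg, route_score, pooled difficulty bins, appropriate_cursor and
    segmentation."""
    df = df.copy()
    cong, incong = world.congruent_cursor(), world.incongruent_cursor()
    offsets, scores, segs = [], [], []
    for row in df.itertuples():
        sg = world.SGPair((row.start_x, row.start_y), (row.goal_x, row.goal_y),
                          config.grid_radius)
        off = strategy.heuristic_offset(sg, incong)
        plan_c = strategy.optimal_route(sg, cong, config)
        plan_i = strategy.optimal_route(sg, incong, config)
        offsets.append(off)
        scores.append(plan_c.projected_reward - plan_i.projected_reward)
        appr = strategy.appropriate_cursor(off)
        segs.append((plan_i if appr == "incongruent" else plan_c).segmentation)
    df["offset_deg"] = offsets
    df["route_score"] = scores
    df["appropriate_cursor"] = [strategy.appropriate_cursor(o) for o in offsets]
    df["segmentation"] = segs
    off_b = strategy.make_difficulty_bins(df["offset_deg"].to_numpy(), "offset")
    route_b = strategy.make_difficulty_bins(df["route_score"].to_numpy(), "route")
    df["bin_offset"] = off_b.assign(df["offset_deg"].to_numpy())
    df["bin_route"] = route_b.assign(df["route_score"].to_numpy())
    return df


def classify_cohort(
    df: pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 20,
    maxiter: int = 800,
) -> tuple[pd.DataFrame, dict]:
    """Classify every participant by the five-model AICc comparison.

    Returns a per-participant classification table and the full
    :class:`~boatdock.ddm.ClassificationResult` objects.
    """
    rows, results = [], {}
    ss = np.random.SeedSequence(seed)
    for child, (pid, sub) in zip(
        ss.spawn(df["participant_id"].nunique()),
        df.groupby("participant_id", observed=True, sort=True),
    ):
        res = ddm_mod.classify_participant(
            sub["rt_seconds"].to_numpy(),
            (sub["cursor_chosen"] == "congruent").to_numpy(),
            sub["bin_offset"].to_numpy(),
            sub["bin_route"].to_numpy(),
            np.random.default_rng(child),
            n_restarts=n_restarts,
            maxiter=maxiter,
        )
        results[pid] = res
        best = res.fits[res.best_model]
        rows.append({
            "participant_id": pid,
            "label": res.label,
            "best_model": res.best_model,
            "aicc_best": best.aicc,
            "aicc_null": res.fits["null"].aicc,
            "mu1": best.params.mu1, "mu2": best.params.mu2,
            "B": best.params.B, "bC": best.params.bC, "t0": best.params.t0,
            "sensitivity": res.sensitivity if res.sensitivity is not None else np.nan,
            "d2_heuristic": res.d2["heuristic"],
            "d2_route": res.d2["route"],
            "tie": res.tie,
        })
        logger.info("classified %s -> %s", pid, res.label)
    return pd.DataFrame(rows), results


def _median_rt_by_segmentation(df: pd.DataFrame, labels: dict) -> pd.DataFrame:
    sub = df[(df["appropriate_cursor"] == "congruent")
             & df["participant_id"].map(labels).isin(["heuristic", "route"])]
    med = (
        sub.groupby(["participant_id", "segmentation"], observed=True)["rt_seconds"]
        .median().rename("median_rt").reset_index()
    )
    med["group"] = med["participant_id"].map(labels)
    return med


def analyze_cohort(
    df: pd.DataFrame,
    labels: dict,
    sampler: bayes.SamplerConfig = bayes.SamplerConfig(),
    hdi_mass: float = 0.94,
) -> dict:
    """Group-level Bayesian analyses of a classified cohort.

    ``labels`` maps participant_id -> group.  Returns a nested dict of
    posterior summaries, credible comparisons, time-on-task labels and the
    segmentation ANOVA.
    """
    import warnings

    df = df.copy()
    df["_group"] = df["participant_id"].map(labels)
    sizes = pd.Series(labels).value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(
            f"groups with < 2 participants dropped from group-level models: {small}",
            stacklevel=2,
        )
        labels = {p: g for p, g in labels.items() if g not in small}
        df = df[df["participant_id"].isin(labels)]
        df = df.copy()
    by_p = df.groupby("participant_id", observed=True)
    pids = list(by_p.groups)
    glab = [labels[p] for p in pids]

    det = df[df["appropriate_cursor"] != "indeterminate"]
    appro = det.groupby("participant_id", observed=True).apply(
        lambda s: int((s["cursor_chosen"] == s["appropriate_cursor"]).sum()),
        include_groups=False,
    )
    out: dict = {"groups": dict(zip(pids, glab))}
    out["summary"] = {
        "appropriate": bayes.summary_binomial(
            appro.loc[pids].to_numpy(),
            det.groupby("participant_id", observed=True).size().loc[pids].to_numpy(),
            groups=glab, mass=hdi_mass, config=sampler,
        ),
        "congruent": bayes.summary_binomial(
            by_p.apply(lambda s: int((s["cursor_chosen"] == "congruent").sum()),
                       include_groups=False).loc[pids].to_numpy(),
            by_p.size().loc[pids].to_numpy(),
            groups=glab, mass=hdi_mass, config=sampler,
        ),
        "catastrophic": bayes.summary_binomial(
            by_p.apply(lambda s: int((s["outcome"] != "dock").sum()),
                       include_groups=False).loc[pids].to_numpy(),
            by_p.size().loc[pids].to_numpy(),
            groups=glab, mass=hdi_mass, config=sampler,
        ),
        "median_rt": bayes.summary_gaussian(
            by_p["rt_seconds"].median().loc[pids].to_numpy(),
            groups=glab, mass=hdi_mass, config=sampler,
        ),
    }

    # hierarchical choice model: appropriate choices per run
    n_runs = int(df["run"].max())
    y = np.zeros((len(pids), n_runs))
    t = np.zeros((len(pids), n_runs))
    for i, p in enumerate(pids):
        s = det[det["participant_id"] == p]
        for r in range(1, n_runs + 1):
            sr = s[s["run"] == r]
            t[i, r - 1] = len(sr)
            y[i, r - 1] = int((sr["cursor_chosen"] == sr["appropriate_cursor"]).sum())
    out["choice_by_run"] = bayes.hier_binomial_choice(
        y, t, glab, mass=hdi_mass, config=sampler
    )

    # hierarchical skill models
    out["reward"] = bayes.hier_gaussian_skill(
        df, "reward_proportion", labels, mass=hdi_mass, config=sampler,
        value_scale=360.0, report_scale=360.0,
    )
    out["temporal"] = bayes.hier_gaussian_skill(
        df, "temporal_skill", labels, mass=hdi_mass, config=sampler,
    )
    out["spatial"] = bayes.hier_poisson_spatial(
        df, labels, mass=hdi_mass, config=sampler
    )
    out["time_on_task"] = {
        measure: {
            key: bayes.time_on_task(draws, mass=hdi_mass)
            for key, draws in out[measure].runwise_draws.items()
            if draws.shape[0] == 6
        }
        for measure in ("reward", "temporal", "spatial")
    }

    med = _median_rt_by_segmentation(df, labels)
    if med["participant_id"].nunique() >= 4 and med["group"].nunique() == 2:
        out["segmentation_anova"] = bayes.segmentation_anova(med)
    else:
        out["segmentation_anova"] = None
    return out


def _tidy_posteriors(analysis: dict) -> pd.DataFrame:
    rows = []
    for model in ("reward", "temporal", "spatial"):
        res = analysis[model]
        for (g, c, r), s in res.runwise.items():
            rows.append((model, g, c, str(r), s.mean, *s.hdi))
        for (g, c), s in res.collapsed.items():
            rows.append((model, g, c, "collapsed", s.mean, *s.hdi))
    for (g, r), s in analysis["choice_by_run"]["theta"].items():
        rows.append(("choice", g, "both", str(r), s.mean, *s.hdi))
    for name, d in analysis["summary"].items():
        for g, s in d.items():
            rows.append((name, g, "both", "all", s.mean, *s.hdi))
    return pd.DataFrame(
        rows, columns=["model", "group", "cursor", "run", "mean", "hdi_lo", "hdi_hi"]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Single-command end-to-end run: simulate a cohort, score, classify,
    analyze and write the report bundle to ``config.out_dir``.

    Emits: cohort CSV, manifest JSON, classification CSV, tidy posterior
    CSV, time-on-task labels, a recovery scorecard and a run log.
    """
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed = {config.seed}"]

    spec = cohort_mod.CohortSpec(
        group_sizes=(
            ("heuristic", config.heuristic_n),
            ("route", config.route_n),
            ("null", config.null_n),
        ),
        n_runs=config.n_runs,
        trials_per_run=config.trials_per_run,
        master_seed=config.seed,
    )
    stage = "simulate"
    try:
        table, manifest = cohort_mod.simulate_cohort(spec)
        write_trials(table, out_dir / "cohort.csv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log_lines.append(f"simulate: {len(table)} trials, "
                         f"{manifest['resampled_sgs']} SGs resampled")

        stage = "classify"
        cls, _ = classify_cohort(
            table, seed=config.seed + 1, n_restarts=config.n_restarts
        )
        cls.to_csv(out_dir / "classification.csv", index=False)
        truth = {a["agent_id"]: a["strategy"] for a in manifest["agents"]}
        want = {"heuristic": "heuristic", "route": "route", "null": "nonplanner"}
        hits = [want[truth[r.participant_id]] == r.label for r in cls.itertuples()]
        recovery = float(np.mean(hits))
        log_lines.append(f"classify: recovery {recovery:.3f}")

        stage = "analyze"
        labels = dict(zip(cls["participant_id"], cls["label"]))
        sampler = bayes.SamplerConfig(
            draws_per_chain=config.draws_per_chain, seed=config.seed + 2
        )
        analysis = analyze_cohort(table, labels,
                                  sampler=sampler, hdi_mass=config.hdi_mass)
        _tidy_posteriors(analysis).to_csv(out_dir / "posteriors.csv", index=False)
        tot_rows = [
            {"measure": m, "group": g, "cursor": c,
             "label": eff.label,
             "beta_lin": eff.beta_lin.mean, "beta_log": eff.beta_log.mean}
            for m, d in analysis["time_on_task"].items()
            for (g, c), eff in d.items()
        ]
        pd.DataFrame(tot_rows).to_csv(out_dir / "time_on_task.csv", index=False)

        stage = "report"
        report = {
            "seed": config.seed,
            "n_trials": int(len(table)),
            "recovery": recovery,
            "group_counts": cls["label"].value_counts().to_dict(),
            "resampled_sgs": manifest["resampled_sgs"],
            "design_flags": {
                "route_time_limit_s": spec.world.route_time_limit_s,
                "accel_per_frame": spec.world.accel_per_frame,
                "hdi_mass": config.hdi_mass,
                "draws_per_chain": config.draws_per_chain,
                "n_restarts": config.n_restarts,
            },
            "runtime_s": round(time.time() - t_start, 1),
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
        log_lines.append(f"done in {report['runtime_s']} s")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        return {"report": report, "classification": cls, "analysis": analysis,
                "table": table, "manifest": manifest}
    except Exception as err:
        (out_dir / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED at stage {stage}: {err}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
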