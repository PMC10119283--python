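"""Drift-diffusion modelling of action selection.

A Wiener process with drift ``mu``, diffusion noise ``sigma = 0.1`` (fixed
scaling), absorbing boundaries ``+B`` (congruent choice) and ``-B``
(incongruent choice) and start point ``bC * B`` models the deliberation
between the two cursors; response time is first-passage time plus a
nondecision offset ``t0``.

Five candidate models are fitted per participant with the quantile
("chi-square") method: the trial set is split into five difficulty levels by
either the heuristic-offset or the route-planning binning, levels map onto
signed drifts ``(-mu2, -mu1, 0, +mu1, +mu2)``, and the objective is the
binned multinomial negative log-likelihood of choice frequencies and RT
quantile-bin counts (bins bounded by the 10/30/50/70/90% RT quantiles of
each choice's distribution per level).  Candidates: heuristic and route
models with one (``mu1 = mu2``) or two free drifts, plus a zero-drift null.
Participants are labelled heuristic / route / nonplanner by minimum AICc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "SIGMA",
    "DDMParams",
    "ModelSpec",
    "MODEL_SPECS",
    "ObservedBins",
    "FitResult",
    "ClassificationResult",
    "ddm_choice_probability",
    "wiener_fpt_cdf",
    "simulate_ddm",
    "bin_observed",
    "fit_objective",
    "chi_square_statistic",
    "fit_ddm",
    "aicc",
    "sensitivity",
    "classify_participant",
    "crossvalidate_classification",
]

SIGMA = 0.1  # fixed diffusion scaling parameter
_PROB_FLOOR = 1e-10
_DRIFT_SIGNS = np.array([-1.0, -1.0, 0.0, 1.0, 1.0])  # bins 1..5 -> +/- mu
_DRIFT_WHICH = np.array([2, 1, 0, 1, 2])  # 0: none, 1: mu1, 2: mu2


class SeriesConvergenceError(RuntimeError):
    """First-passage series failed to reach the requested tolerance."""


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters.

    ``mu1`` is the high-difficulty drift magnitude, ``mu2`` the
    low-difficulty one, constrained ``0 <= mu1 <= mu2``.  ``B > 0`` is the
    boundary, ``bC`` in (-1, 1) the congruency bias (start point ``bC*B``),
    ``t0 >= 0`` the nondecision time in seconds.
    """

    mu1: float
    mu2: float
    B: float
    bC: float
    t0: float
    sigma: float = SIGMA

    def __post_init__(self) -> None:
        if not (0 <= self.mu1 <= self.mu2):
            raise ValueError("require 0 <= mu1 <= mu2")
        if self.B <= 0:
            raise ValueError("require B > 0")
        if not (-1 < self.bC < 1):
            raise ValueError("require -1 < bC < 1")
        if self.t0 < 0:
            raise ValueError("require t0 >= 0")

    def drift_for_bin(self, bin_index) -> np.ndarray:
        """Signed drift for difficulty bins 1..5: (-mu2, -mu1, 0, mu1, mu2)."""
        b = np.asarray(bin_index) - 1
        mags = np.array([0.0, self.mu1, self.mu2])
        return _DRIFT_SIGNS[b] * mags[_DRIFT_WHICH[b]]


def _scaled(params: DDMParams, drift: float) -> tuple[float, float, float]:
    """Scale to unit diffusion: boundary separation a, start z, drift v."""
    s = params.sigma
    return 2 * params.B / s, params.B * (1 + params.bC) / s, drift / s


def ddm_choice_probability(params: DDMParams, drift: float) -> float:
    """Probability of absorbing at the congruent (+B) boundary.

    Closed form for a Wiener process with drift on [0, a] starting at z:
    ``P = (1 - exp(-2 v z)) / (1 - exp(-2 v a))``; ``z / a`` at zero drift.
    """
    a, z, v = _scaled(params, drift)
    if abs(v) < 1e-12:
        return z / a
    # expm1 keeps precision for small exponents
    num = -math.expm1(-2 * v * z)
    den = -math.expm1(-2 * v * a)
    return num / den


def wiener_fpt_cdf(
    params: DDMParams,
    drift: float,
    t,
    tol: float = 1e-8,
    max_terms: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Defective first-passage CDFs at the congruent (+B) and incongruent
    (-B) boundaries, evaluated at decision times ``t`` (seconds, excluding
    nondecision time).

    Uses the large-time eigenfunction series of the absorbed-mass tail,
    truncated adaptively to ``tol``; raises
    :class:`SeriesConvergenceError` when the requested tolerance is not
    reachable within ``max_terms``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    a, z, v = _scaled(params, drift)
    p_upper = ddm_choice_probability(params, drift)
    # reflection: hitting +B from z with drift v == hitting 0 from a-z with -v
    f_up = _defective_cdf_lower(a, a - z, -v, p_upper, t, tol, max_terms)
    f_lo = _defective_cdf_lower(a, z, v, 1.0 - p_upper, t, tol, max_terms)
    return f_up, f_lo


def _defective_cdf_lower(
    a: float, z: float, v: float, p_abs: float, t: np.ndarray,
    tol: float, max_terms: int,
) -> np.ndarray:
    """P(hit lower boundary 0 by time t) for unit-diffusion Wiener on [0, a]
    starting at z with drift v; ``p_abs`` is the t -> inf limit."""
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    tmin = tp.min()
    # series term k decays as exp(-k^2 pi^2 t / (2 a^2)); bound the truncation
    k_needed = int(a / math.pi * math.sqrt(2.0 * max(math.log(1.0 / tol), 1.0) / tmin)) + 10
    if k_needed > max_terms:
        raise SeriesConvergenceError(
            f"need {k_needed} terms for t={tmin:.2e} at tol={tol:.0e} "
            f"(a={a:.3f}); increase tol or the term cap"
        )
    k = np.arange(1, k_needed + 1)
    beta = 0.5 * (v * v + (k * math.pi / a) ** 2)
    coef = k * np.sin(k * math.pi * z / a) / beta
    log_pref = math.log(math.pi) - 2 * math.log(a) - v * z
    # tail(t) = pref * sum_k coef_k * exp(-beta_k t)
    expo = np.exp(-beta[None, :] * tp[:, None] + log_pref)
    tail = expo @ coef
    out[pos] = np.clip(p_abs - tail, 0.0, 1.0)
    return out


def simulate_ddm(
    params: DDMParams,
    drift,
    rng: np.random.Generator,
    n: Optional[int] = None,
    dt: float = 0.001,
    t_max: float = 60.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euler-Maruyama simulation of choices and RTs.

    ``drift`` may be a scalar (with ``n`` draws) or an array of per-trial
    drifts.  Returns ``(choice_congruent, rt, censored)``; RTs include
    ``t0``.  Paths still unabsorbed at ``t_max`` are flagged censored and
    assigned ``t_max + t0``.
    """
    drift = np.atleast_1d(np.asarray(drift, dtype=float))
    if n is not None and drift.size == 1:
        drift = np.full(n, drift[0])
    m = drift.size
    x = np.full(m, params.bC * params.B)
    rt = np.full(m, np.nan)
    choice = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)
    sq = params.sigma * math.sqrt(dt)
    n_steps = int(round(t_max / dt))
    for step in range(1, n_steps + 1):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        x[idx] += drift[idx] * dt + sq * rng.standard_normal(idx.size)
        hit_up = x[idx] >= params.B
        hit_lo = x[idx] <= -params.B
        done = hit_up | hit_lo
        if np.any(done):
            d = idx[done]
            choice[d] = hit_up[done]
            rt[d] = step * dt + params.t0
            active[d] = False
    censored = active.copy()
    rt[censored] = t_max + params.t0
    return choice, rt, censored


@dataclass
class ObservedBins:
    """Choice and RT-quantile bin counts per difficulty level.

    ``levels`` maps a level index to a dict with, per choice (True =
    congruent), either ``("binned", edges, counts)`` — six counts bounded by
    that choice's 10/30/50/70/90% RT quantiles — or ``("collapsed", count)``
    for sparse cells (< ``min_per_cell`` trials).
    """

    levels: dict
    n_trials: int
    min_per_cell: int


def bin_observed(
    rts: np.ndarray,
    choices: np.ndarray,
    level_index: np.ndarray,
    n_levels: int = 5,
    min_per_cell: int = 12,
) -> ObservedBins:
    """Bin choices/RTs into the quantile-method cells, per difficulty level."""
    rts = np.asarray(rts, dtype=float)
    choices = np.asarray(choices, dtype=bool)
    level_index = np.asarray(level_index)
    levels: dict = {}
    for lev in range(1, n_levels + 1):
        sel = level_index == lev
        if not np.any(sel):
            warnings.warn(f"difficulty level {lev} has no trials; dropped",
                          stacklevel=2)
            continue
        per_choice = {}
        for ch in (True, False):
            r = rts[sel & (choices == ch)]
            if r.size == 0:
                continue
            if r.size < min_per_cell:
                per_choice[ch] = ("collapsed", r.size)
            else:
                edges = np.quantile(r, [0.1, 0.3, 0.5, 0.7, 0.9])
                counts = np.histogram(r, np.concatenate([[-np.inf], edges, [np.inf]]))[0]
                per_choice[ch] = ("binned", edges, counts)
        levels[lev] = per_choice
    return ObservedBins(levels, int(len(rts)), min_per_cell)


@dataclass(frozen=True)
class ModelSpec:
    """One of the five candidate models."""

    family: str  # "heuristic" | "route" | "null"
    drift_count: int  # 0, 1 or 2

    @property
    def k(self) -> int:
        """Free-parameter count: B, bC, t0 plus the drifts."""
        return 3 + self.drift_count

    @property
    def name(self) -> str:
        if self.family == "null":
            return "null"
        return f"{self.family}_{self.drift_count}"


MODEL_SPECS = (
    ModelSpec("heuristic", 2),
    ModelSpec("heuristic", 1),
    ModelSpec("route", 2),
    ModelSpec("route", 1),
    ModelSpec("null", 0),
)


def _cell_logprobs(params: DDMParams, observed: ObservedBins):
    """Yield (count, predicted probability) pairs over all cells."""
    pooled = len(observed.levels) == 1 and 1 in observed.levels
    for lev, per_choice in observed.levels.items():
        # a pooled (single-level) structure carries no difficulty signal
        drift = 0.0 if pooled else float(params.drift_for_bin(lev))
        p_up = ddm_choice_probability(params, drift)
        for ch, cell in per_choice.items():
            p_choice = p_up if ch else 1.0 - p_up
            if cell[0] == "collapsed":
                yield cell[1], p_choice
            else:
                edges, counts = cell[1], cell[2]
                tt = np.maximum(edges - params.t0, 0.0)
                f_up, f_lo = wiener_fpt_cdf(params, drift, tt)
                f = f_up if ch else f_lo
                cum = np.concatenate([[0.0], f, [p_choice]])
                probs = np.diff(cum)
                for c, p in zip(counts, probs):
                    yield c, p


def fit_objective(
    params: DDMParams, observed: ObservedBins, spec: Optional[ModelSpec] = None
) -> float:
    """Binned multinomial negative log-likelihood (up to the multinomial
    constant), floored at probability 1e-10 so it stays finite everywhere."""
    nll = 0.0
    for c, p in _cell_logprobs(params, observed):
        nll -= c * math.log(max(p, _PROB_FLOOR))
    return nll


def chi_square_statistic(params: DDMParams, observed: ObservedBins) -> float:
    """Pearson chi-square over the same cells, for comparability with the
    classical quantile-fitting criterion."""
    level_n = {
        lev: sum(c[1] if c[0] == "collapsed" else int(np.sum(c[2]))
                 for c in per.values())
        for lev, per in observed.levels.items()
    }
    chi2 = 0.0
    pooled = len(observed.levels) == 1 and 1 in observed.levels
    for lev, per_choice in observed.levels.items():
        drift = 0.0 if pooled else float(params.drift_for_bin(lev))
        p_up = ddm_choice_probability(params, drift)
        n_lev = level_n[lev]
        for ch, cell in per_choice.items():
            p_choice = p_up if ch else 1.0 - p_up
            if cell[0] == "collapsed":
                pairs = [(cell[1], p_choice)]
            else:
                edges, counts = cell[1], cell[2]
                tt = np.maximum(edges - params.t0, 0.0)
                f_up, f_lo = wiener_fpt_cdf(params, drift, tt)
                f = f_up if ch else f_lo
                probs = np.diff(np.concatenate([[0.0], f, [p_choice]]))
                pairs = list(zip(counts, probs))
            for c, p in pairs:
                e = n_lev * max(p, _PROB_FLOOR)
                chi2 += (c - e) ** 2 / e
    return chi2


def _theta_to_params(theta: np.ndarray, spec: ModelSpec) -> DDMParams:
    """Unconstrained optimiser coordinates -> constrained parameters.

    log B, atanh bC, log t0; two-drift: log mu2 and a logistic share putting
    mu1 = mu2 * expit(share); one-drift: log mu (mu1 = mu2)."""
    B = math.exp(theta[0])
    bC = math.tanh(theta[1])
    t0 = math.exp(theta[2])
    if spec.drift_count == 0:
        mu1 = mu2 = 0.0
    elif spec.drift_count == 1:
        mu1 = mu2 = math.exp(theta[3])
    else:
        mu2 = math.exp(theta[3])
        mu1 = mu2 * expit(theta[4])
    return DDMParams(mu1, mu2, B, bC, t0)


def aicc(ll: float, k: int, n: int) -> float:
    """AICc = -2 LL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("sample too small for AICc")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    spec: ModelSpec
    params: DDMParams
    objective: float  # binned negative log-likelihood
    ll: float
    aicc: float
    chi_square: float
    n_trials: int
    n_restarts: int
    restart_objectives: np.ndarray


def fit_ddm(
    rts: np.ndarray,
    choices: np.ndarray,
    level_index: np.ndarray,
    spec: ModelSpec,
    rng: np.random.Generator,
    n_restarts: int = 20,
    maxiter: int = 800,
    min_per_cell: int = 12,
) -> FitResult:
    """Fit one candidate model by multi-start Nelder-Mead on transformed
    parameters.

    The null model is fitted on a single pooled level (it predicts no
    difficulty structure); heuristic/route models use the supplied five-level
    assignment.
    """
    rts = np.asarray(rts, dtype=float)
    choices = np.asarray(choices, dtype=bool)
    n = len(rts)
    if n < 50:
        warnings.warn(f"only {n} trials; fits may be unstable", stacklevel=2)
    if spec.drift_count == 0:
        level_index = np.ones(n, dtype=int)
        observed = bin_observed(rts, choices, level_index, n_levels=1,
                                min_per_cell=min_per_cell)
    else:
        observed = bin_observed(rts, choices, level_index,
                                min_per_cell=min_per_cell)

    def objective(theta: np.ndarray) -> float:
        try:
            params = _theta_to_params(theta, spec)
        except (ValueError, OverflowError):
            return 1e12
        try:
            return fit_objective(params, observed, spec)
        except SeriesConvergenceError:
            return 1e12

    min_rt = max(float(np.min(rts)), 1e-3)
    best = None
    restart_vals = []
    for _ in range(n_restarts):
        theta0 = [
            math.log(0.12) + 0.4 * rng.standard_normal(),
            0.3 * rng.standard_normal(),
            math.log(min_rt * rng.uniform(0.3, 0.9)),
        ]
        if spec.drift_count >= 1:
            theta0.append(math.log(0.06) + 0.5 * rng.standard_normal())
        if spec.drift_count == 2:
            theta0.append(1.0 + rng.standard_normal())
        res = minimize(
            objective, np.asarray(theta0), method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3},
        )
        restart_vals.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"all {n_restarts} restarts failed for {spec.name}: "
            f"objectives {restart_vals}"
        )
    params = _theta_to_params(best.x, spec)
    ll = -best.fun
    return FitResult(
        spec, params, float(best.fun), float(ll),
        aicc(ll, spec.k, n), chi_square_statistic(params, observed),
        n, n_restarts, np.asarray(restart_vals),
    )


def sensitivity(params: DDMParams) -> float:
    """Sensitivity S = (mu1 + mu2) / (2 B (1 + |bC|))."""
    return (params.mu1 + params.mu2) / (2 * params.B * (1 + abs(params.bC)))


@dataclass
class ClassificationResult:
    label: str  # heuristic | route | nonplanner
    fits: dict  # model name -> FitResult
    sensitivity: Optional[float]
    d2: dict  # family -> residual deviance vs null
    best_model: str
    tie: bool


def classify_participant(
    rts: np.ndarray,
    choices: np.ndarray,
    offset_bins: np.ndarray,
    route_bins: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int = 20,
    maxiter: int = 800,
) -> ClassificationResult:
    """Fit all five candidate models and label the participant by minimum
    AICc (one-drift variants count toward their family; the null wins ->
    nonplanner)."""
    fits = {}
    for spec in MODEL_SPECS:
        levels = offset_bins if spec.family == "heuristic" else route_bins
        fits[spec.name] = fit_ddm(
            rts, choices, levels, spec, rng,
            n_restarts=n_restarts, maxiter=maxiter,
        )
    scores = {name: f.aicc for name, f in fits.items()}
    best_score = min(scores.values())
    winners = [name for name, s in scores.items() if s == best_score]
    tie_families = {fits[w].spec.family for w in winners}
    tie = len(tie_families) > 1
    if tie:  # break by smaller k
        winners.sort(key=lambda w: fits[w].spec.k)
    best_model = min(scores, key=lambda w: (scores[w], fits[w].spec.k))
    family = fits[best_model].spec.family
    label = "nonplanner" if family == "null" else family
    ll_null = fits["null"].ll
    d2 = {
        fam: 2.0 * (max(fits[f"{fam}_1"].ll, fits[f"{fam}_2"].ll) - ll_null)
        for fam in ("heuristic", "route")
    }
    s = sensitivity(fits[best_model].params) if label != "nonplanner" else None
    return ClassificationResult(label, fits, s, d2, best_model, tie)


def _heldout_ll(
    params: DDMParams, rts, choices, levels, spec: ModelSpec, min_per_cell: int
) -> float:
    if spec.drift_count == 0:
        observed = bin_observed(rts, choices, np.ones(len(rts), dtype=int),
                                n_levels=1, min_per_cell=min_per_cell)
    else:
        observed = bin_observed(rts, choices, levels,
                                min_per_cell=min_per_cell)
    return -fit_objective(params, observed, spec)


def crossvalidate_classification(
    rts: np.ndarray,
    choices: np.ndarray,
    offset_bins: np.ndarray,
    route_bins: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int = 10,
    maxiter: int = 800,
) -> dict:
    """Twofold cross-validation: random half-split stratified by the
    offset-difficulty bin; each fold is fitted on one half and labelled by
    held-out binned log-likelihood on the other half.

    Returns fold labels and whether they agree."""
    rts = np.asarray(rts, dtype=float)
    choices = np.asarray(choices, dtype=bool)
    offset_bins = np.asarray(offset_bins)
    route_bins = np.asarray(route_bins)
    n = len(rts)
    if n < 100:
        raise ValueError("need >= 100 trials for twofold cross-validation")
    half = np.zeros(n, dtype=bool)
    for lev in np.unique(offset_bins):
        idx = np.nonzero(offset_bins == lev)[0]
        rng.shuffle(idx)
        half[idx[: len(idx) // 2]] = True
    labels = []
    for train in (half, ~half):
        test = ~train
        fold_fits = {}
        for spec in MODEL_SPECS:
            levels = offset_bins if spec.family == "heuristic" else route_bins
            fit = fit_ddm(rts[train], choices[train], levels[train], spec,
                          rng, n_restarts=n_restarts, maxiter=maxiter)
            fold_fits[spec.name] = _heldout_ll(
                fit.params, rts[test], choices[test], levels[test], spec,
                min_per_cell=12,
            )
        best = max(fold_fits, key=fold_fits.get)
        fam = best.split("_")[0]
        labels.append("nonplanner" if fam == "null" else fam)
    return {
        "fold_labels": labels,
        "agree": labels[0] == labels[1],
        "split_first_half": half,
    }
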