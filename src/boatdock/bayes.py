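"""Summary and hierarchical Bayesian group analyses.

The models mirror a standard behavioural-analysis stack:

* summary models pool per-participant summaries — a Beta(1,1)-binomial for
  choice proportions (conjugate, sampled exactly) and a Gaussian with
  mu ~ N(0, 10), Sigma ~ HalfNormal(10) on z-scored values;
* hierarchical models summarise trialwise measures inside each participant
  and constrain participant-level parameters with group-by-run(-by-cursor)
  hyperpriors: a Beta-hyperprior binomial for state-appropriate choice, a
  Gaussian with log-scale likelihood noise for reward/temporal skill, and a
  log-link Poisson for direction changes;
* deterministic per-draw least squares on runwise posterior draws estimates
  linear and logarithmic time-on-task (learning) trends;
* credible effects require the minimum-width highest-density interval (HDI,
  default mass 0.94) of a posterior — or of a difference of posteriors — to
  exclude the reference value.

Posteriors that are not conjugate are sampled with the affine-invariant
ensemble sampler (emcee); walkers are grouped into four pseudo-chains for
split-R-hat convergence checks (tolerance 1.01).  Hierarchical cells that
share no parameters — distinct group-by-run(-by-cursor) combinations — are
sampled independently, which is exact for these models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln

__all__ = [
    "SamplerConfig",
    "PosteriorSummary",
    "CredibleComparison",
    "TimeOnTaskEffect",
    "ConvergenceError",
    "hdi",
    "split_rhat",
    "summary_binomial",
    "summary_gaussian",
    "hier_binomial_choice",
    "hier_gaussian_skill",
    "hier_poisson_spatial",
    "time_on_task",
    "nonparametric_tot",
    "segmentation_anova",
]

RHAT_TOL = 1.01


class ConvergenceError(RuntimeError):
    """Sampler diagnostics failed (carries the offending R-hat values)."""


@dataclass(frozen=True)
class SamplerConfig:
    """Kept-draw budget: ``chains * draws_per_chain`` samples after an equal
    tuning run.  The default follows the 4 x 10,000 contract; ``reduced()``
    is a 4 x 1,000 mode for quick runs."""

    chains: int = 4
    draws_per_chain: int = 10_000
    seed: int = 0

    @classmethod
    def reduced(cls, seed: int = 0) -> "SamplerConfig":
        return cls(chains=4, draws_per_chain=1_000, seed=seed)

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws_per_chain


def hdi(draws, mass: float = 0.94) -> tuple[float, float]:
    """Minimum-width (highest-density) credible interval.

    Shortest contiguous window containing ``ceil(mass * n)`` sorted draws;
    ties resolve to the leftmost window.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty draws")
    m = int(math.ceil(mass * n))
    m = min(max(m, 1), n)
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))  # argmin takes the first (leftmost) tie
    return float(x[i]), float(x[i + m])


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for draws shaped
    (n_chains, n_draws)."""
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2:
        raise ValueError("expected (chains, draws)")
    n = c.shape[1] // 2
    halves = np.concatenate([c[:, :n], c[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    B = n * means.var(ddof=1)
    W = halves.var(axis=1, ddof=1).mean()
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


@dataclass
class PosteriorSummary:
    """Named posterior draws with expectation, HDI and diagnostics."""

    name: str
    draws: np.ndarray  # flattened over chains
    mean: float
    hdi: tuple[float, float]
    hdi_mass: float
    rhat: float
    n_divergences: int = 0

    @classmethod
    def from_chains(
        cls, name: str, chains: np.ndarray, mass: float = 0.94
    ) -> "PosteriorSummary":
        flat = np.asarray(chains, dtype=float).reshape(-1)
        return cls(
            name, flat, float(flat.mean()), hdi(flat, mass), mass,
            split_rhat(np.asarray(chains)),
        )

    def transformed(self, fn: Callable, name: Optional[str] = None) -> "PosteriorSummary":
        d = fn(self.draws)
        return PosteriorSummary(
            name or self.name, d, float(np.mean(d)), hdi(d, self.hdi_mass),
            self.hdi_mass, self.rhat, self.n_divergences,
        )

    def excludes(self, value: float) -> bool:
        lo, hi = self.hdi
        return value < lo or value > hi


@dataclass
class CredibleComparison:
    """Difference of two posteriors, A - B; credible iff the HDI of the
    difference distribution excludes 0 (never judged by HDI overlap)."""

    name: str
    draws: np.ndarray
    mean: float
    hdi: tuple[float, float]
    credible: bool

    @classmethod
    def of(
        cls,
        a: PosteriorSummary,
        b: PosteriorSummary,
        mass: float = 0.94,
        name: Optional[str] = None,
    ) -> "CredibleComparison":
        k = min(a.draws.size, b.draws.size)
        d = a.draws[:k] - b.draws[:k]
        lo, hi = hdi(d, mass)
        return cls(
            name or f"{a.name}-{b.name}", d, float(d.mean()), (lo, hi),
            not (lo <= 0.0 <= hi),
        )


# ---------------------------------------------------------------------------
# ensemble-sampler plumbing


def _run_ensemble(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init_center: np.ndarray,
    init_scale: np.ndarray,
    config: SamplerConfig,
    seed: int,
    step_factor: int = 1,
) -> np.ndarray:
    """Sample a log-posterior with emcee; returns (chains, draws, ndim).

    Walkers are initialised around ``init_center``, burn for as many steps
    as are kept, and are grouped into ``config.chains`` pseudo-chains.
    """
    ndim = len(init_center)
    nw = max(2 * ndim + 2, 16)
    nw += (-nw) % (2 * config.chains)  # divisible into chain groups, even
    # kept steps: enough for the draw budget and for mixing (ensemble
    # autocorrelation grows with dimension)
    steps = max(int(math.ceil(config.total_draws / nw)), 20 * ndim, 100)
    steps *= step_factor
    # decorrelate kept draws; low-dimensional targets are cheap to thin hard
    thin = 8 if ndim <= 4 else 4
    rng = np.random.default_rng(seed)
    p0 = init_center[None, :] + init_scale[None, :] * rng.standard_normal(
        (nw, ndim)
    )
    lp0 = log_prob(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while np.any(bad) and tries < 100:
        p0[bad] = init_center[None, :] + 0.1 * init_scale[None, :] * (
            rng.standard_normal((int(bad.sum()), ndim))
        )
        lp0 = log_prob(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    if np.any(bad):
        raise ConvergenceError("could not initialise walkers in finite-density region")
    moves = [
        (emcee.moves.DEMove(), 0.8),
        (emcee.moves.DESnookerMove(), 0.2),
    ]
    sampler = emcee.EnsembleSampler(nw, ndim, log_prob, vectorize=True,
                                    moves=moves)
    sampler._random = np.random.RandomState(seed % (2**31))
    state = sampler.run_mcmc(p0, steps * thin, progress=False)  # burn-in
    sampler.reset()
    # thin_by runs steps * thin proposals and stores every thin-th
    sampler.run_mcmc(state, steps, progress=False, thin_by=thin)
    chain = sampler.get_chain()  # (steps, nw, ndim)
    chain = np.moveaxis(chain, 1, 0)  # (nw, steps, ndim)
    per = nw // config.chains
    grouped = chain.reshape(config.chains, per * steps, ndim)
    return grouped


def _check_rhat(grouped: np.ndarray, context: str) -> np.ndarray:
    rhats = np.array(
        [split_rhat(grouped[:, :, d]) for d in range(grouped.shape[2])]
    )
    if np.any(rhats > RHAT_TOL):
        raise ConvergenceError(
            f"{context}: split R-hat {rhats.max():.4f} > {RHAT_TOL}"
        )
    return rhats


def _sample_checked(
    log_prob: Callable[[np.ndarray], np.ndarray],
    init_center: np.ndarray,
    init_scale: np.ndarray,
    config: SamplerConfig,
    seed: int,
    context: str,
    check_dims: int = 1,
    derive: Optional[Callable[[np.ndarray], np.ndarray]] = None,
):
    """Sample and verify split R-hat on the first ``check_dims`` coordinates
    and, optionally, on a derived (chains, draws) quantity — the posterior
    actually reported.  Slow-mixing targets are retried with 4x and 16x
    longer chains before raising :class:`ConvergenceError`."""
    last: Optional[ConvergenceError] = None
    for factor in (1, 4, 16):
        grouped = _run_ensemble(
            log_prob, init_center, init_scale, config,
            seed=seed + factor, step_factor=factor,
        )
        try:
            _check_rhat(grouped[:, :, :check_dims], context)
            if derive is None:
                return grouped
            derived = derive(grouped)
            r = split_rhat(derived)
            if r > RHAT_TOL:
                raise ConvergenceError(
                    f"{context}: derived-posterior R-hat {r:.4f} > {RHAT_TOL}"
                )
            return grouped, derived
        except ConvergenceError as err:
            last = err
    raise last


def _grid2d_draws(
    log_post: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    config: SamplerConfig,
    seed: int,
    coarse: tuple[int, int] = (120, 100),
    fine: tuple[int, int] = (400, 300),
) -> tuple[np.ndarray, np.ndarray]:
    """Draw iid posterior samples of a smooth 2-D density by adaptive grid
    integration: a coarse pass brackets the high-density region, a fine grid
    is normalised there, and draws are jittered within grid cells.

    ``log_post(X, Y)`` must broadcast over arrays.  Returns two
    (chains, draws_per_chain) arrays.  Exact up to grid resolution; draws
    are independent, so convergence diagnostics are trivially clean.
    """
    def mesh(xr, yr, nx, ny):
        x = np.linspace(xr[0], xr[1], nx)
        y = np.linspace(yr[0], yr[1], ny)
        X, Y = np.meshgrid(x, y, indexing="ij")
        return x, y, log_post(X, Y)

    x, y, lp = mesh(x_range, y_range, *coarse)
    lp_max = np.nanmax(lp)
    keep = np.argwhere(lp > lp_max - 30.0)
    xi_lo, yi_lo = keep.min(axis=0)
    xi_hi, yi_hi = keep.max(axis=0)
    pad_x = (x[1] - x[0]) * 2
    pad_y = (y[1] - y[0]) * 2
    xr = (x[xi_lo] - pad_x, x[xi_hi] + pad_x)
    yr = (y[yi_lo] - pad_y, y[yi_hi] + pad_y)
    x, y, lp = mesh(xr, yr, *fine)
    lp = lp - np.nanmax(lp)
    p = np.exp(np.nan_to_num(lp, nan=-np.inf))
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(p.size, size=config.total_draws, p=p.ravel())
    ix, iy = np.unravel_index(idx, p.shape)
    dx, dy = x[1] - x[0], y[1] - y[0]
    xs = x[ix] + rng.uniform(-dx / 2, dx / 2, idx.size)
    ys = y[iy] + rng.uniform(-dy / 2, dy / 2, idx.size)
    shape = (config.chains, config.draws_per_chain)
    return xs.reshape(shape), ys.reshape(shape)


def _half_normal_logpdf(x, sigma: float):
    return np.where(
        x > 0, -0.5 * (x / sigma) ** 2 - math.log(sigma) + 0.5 * math.log(2 / math.pi),
        -np.inf,
    )


def _half_student_t_logpdf(x, nu: float, sigma: float):
    return np.where(
        x > 0,
        -0.5 * (nu + 1) * np.log1p(x * x / (nu * sigma * sigma)),
        -np.inf,
    )


# ---------------------------------------------------------------------------
# summary models


def summary_binomial(
    y,
    t,
    groups: Optional[Sequence] = None,
    mass: float = 0.94,
    config: SamplerConfig = SamplerConfig(),
) -> dict:
    """Pooled (or per-group) binomial proportion with a Beta(1,1) prior.

    The posterior is conjugate — Beta(1 + sum(y), 1 + sum(t - y)) — and is
    sampled exactly.  Returns {group: PosteriorSummary}; the pooled variant
    uses the single key "all".
    """
    y = np.asarray(y, dtype=int)
    t = np.asarray(t, dtype=int)
    if np.any(y < 0) or np.any(y > t):
        raise ValueError("require 0 <= y <= t elementwise")
    labels = np.asarray(groups) if groups is not None else np.array(["all"] * len(y))
    rng = np.random.default_rng(config.seed)
    out = {}
    for g in pd.unique(labels):
        sel = labels == g
        a = 1 + int(y[sel].sum())
        b = 1 + int((t[sel] - y[sel]).sum())
        chains = rng.beta(a, b, size=(config.chains, config.draws_per_chain))
        out[g] = PosteriorSummary.from_chains(f"theta[{g}]", chains, mass)
    return out


def summary_gaussian(
    values,
    groups: Optional[Sequence] = None,
    mass: float = 0.94,
    config: SamplerConfig = SamplerConfig(),
) -> dict:
    """Gaussian summary model on z-scored values: y ~ N(mu, Sigma) with
    mu ~ N(0, 10), Sigma ~ HalfNormal(10).

    Values are z-scored across *all* participants before fitting; reported
    ``mu`` posteriors are transformed back to natural units.  Returns
    {group: PosteriorSummary}.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(groups) if groups is not None else np.array(["all"] * len(v))
    center, scale = float(np.mean(v)), float(np.std(v))
    if scale == 0:
        scale = 1.0
    z = (v - center) / scale
    out = {}
    for gi, g in enumerate(pd.unique(labels)):
        zg = z[labels == g]
        if zg.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 values")

        n_g = zg.size
        m_g, ss_g = float(zg.mean()), float(np.sum((zg - zg.mean()) ** 2))

        def log_post(MU, LOGSIG, n_g=n_g, m_g=m_g, ss_g=ss_g):
            SIG = np.exp(LOGSIG)
            lp = -0.5 * (MU / 10) ** 2 + _half_normal_logpdf(SIG, 10) + LOGSIG
            ll = -n_g * LOGSIG - 0.5 * (ss_g + n_g * (m_g - MU) ** 2) / SIG**2
            return lp + ll

        mu_chains, _ = _grid2d_draws(
            log_post, (-12.0, 12.0), (-6.0, 4.0), config,
            seed=config.seed + 1000 + gi,
        )
        summ = PosteriorSummary.from_chains(f"mu[{g}]", mu_chains, mass)
        out[g] = summ.transformed(lambda d: center + scale * d)
    return out


# ---------------------------------------------------------------------------
# hierarchical models


def hier_binomial_choice(
    y: np.ndarray,
    t: np.ndarray,
    groups: Sequence,
    mass: float = 0.94,
    config: SamplerConfig = SamplerConfig(),
    chance: float = 0.5,
) -> dict:
    """Hierarchical binomial model of per-run choice counts.

    ``y`` and ``t`` are (participants, runs) arrays; each participant's
    run-wise proportion theta_{n,r} gets a Beta(alpha_{g,r}, beta_{g,r})
    hyperprior with HalfStudentT(10, 10) priors on alpha and beta.  The
    participant-level thetas are marginalised analytically (beta-binomial),
    so each group-by-run cell is an exact independent 2-parameter posterior.
    Group-level deterministic draws theta_{g,r} = alpha / (alpha + beta).

    Returns ``{"theta": {(g, r): PosteriorSummary},
    "above_chance": {(g, r): bool}, "first_credible_run": {g: run or None}}``.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    labels = np.asarray(groups)
    n_runs = y.shape[1]
    theta: dict = {}
    above: dict = {}
    for gi, g in enumerate(pd.unique(labels)):
        sel = labels == g
        for r in range(n_runs):
            yy, tt = y[sel, r], t[sel, r]
            keep = tt > 0
            if not np.all(keep):
                warnings.warn(
                    f"group {g} run {r + 1}: {int((~keep).sum())} empty cells dropped",
                    stacklevel=2,
                )
            yy, tt = yy[keep], tt[keep]

            def log_post(LGT, LOGNU, yy=yy, tt=tt):
                # parameterised by (logit mean, log concentration); priors
                # stay HalfStudentT(10, 10) on alpha and beta (plus Jacobian)
                th = 1.0 / (1.0 + np.exp(-LGT))
                nu = np.exp(LOGNU)
                a, b = th * nu, (1 - th) * nu
                jac = 2 * LOGNU + np.log(th) + np.log1p(-th)
                lp = (
                    _half_student_t_logpdf(a, 10, 10)
                    + _half_student_t_logpdf(b, 10, 10)
                    + jac
                )
                ll = np.zeros_like(a)
                for yi, ti in zip(yy, tt):
                    ll += betaln(a + yi, b + ti - yi) - betaln(a, b)
                return lp + ll

            lgt_chains, _ = _grid2d_draws(
                log_post, (-7.0, 7.0), (-2.0, 9.0), config,
                seed=config.seed + 7919 * gi + 13 * r,
            )
            th = 1.0 / (1.0 + np.exp(-lgt_chains))
            s = PosteriorSummary.from_chains(f"theta[{g},run{r + 1}]", th, mass)
            theta[(g, r + 1)] = s
            above[(g, r + 1)] = s.excludes(chance) and s.mean > chance
    first = {}
    for g in pd.unique(labels):
        runs = [r for r in range(1, n_runs + 1) if above[(g, r)]]
        first[g] = runs[0] if runs else None
    return {"theta": theta, "above_chance": above, "first_credible_run": first}


def _cell_stats(df: pd.DataFrame, value_col: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-participant sufficient statistics (n, mean, sum of squared
    deviations) for the trials in one group-by-run-by-cursor cell."""
    gb = df.groupby("participant_id", observed=True)[value_col]
    n = gb.count().to_numpy(dtype=float)
    mean = gb.mean().to_numpy(dtype=float)
    ss = gb.apply(lambda s: float(np.sum((s - s.mean()) ** 2))).to_numpy(dtype=float)
    return n, mean, ss


@dataclass
class HierSkillResult:
    """Runwise, collapsed and per-draw posteriors from a hierarchical skill
    model; ``runwise_draws[(g, c)]`` is a (6, K) array feeding the
    time-on-task regression."""

    runwise: dict
    collapsed: dict
    runwise_draws: dict
    participant_level: dict
    hdi_mass: float


def hier_gaussian_skill(
    trials: pd.DataFrame,
    measure: str,
    groups: dict,
    mass: float = 0.94,
    config: SamplerConfig = SamplerConfig(),
    value_scale: float = 1.0,
    report_scale: float = 1.0,
) -> HierSkillResult:
    """Hierarchical Gaussian model of a trialwise skill measure.

    y_{n,r,c} ~ N(xbar_{n,r,c}, exp(sigma_{n,r,c})) per trial, with
    xbar ~ N(mu_{g,r,c}, Sigma_{g,r,c}) and sigma ~ N(phi_{g,r,c},
    psi_{g,r,c}); mu, phi ~ N(0, 10) and Sigma, psi ~ HalfNormal(10).
    Cells are sampled independently (they share no parameters).

    ``value_scale`` multiplies the stored measure before fitting (reward is
    stored as a proportion but fitted on the 0-360 fuel scale);
    ``report_scale`` divides reported posteriors back.  ``groups`` maps
    participant_id -> group label.  Rows with a missing measure are dropped.
    """
    df = trials.dropna(subset=[measure]).copy()
    df["_y"] = df[measure].astype(float) * value_scale
    df["_g"] = df["participant_id"].map(groups)
    # the N(0, 10) / HalfNormal(10) priors are uninformed *relative to a
    # standardised scale*; fit on grand z-scores and back-transform (affine,
    # exact) so the priors never fight the raw units
    center = float(df["_y"].mean())
    spread = float(df["_y"].std()) or 1.0
    # a numerically constant measure needs no sampling at all
    degenerate_all = spread < 1e-4 * max(1.0, abs(center))
    df["_z"] = (df["_y"] - center) / spread
    back = lambda d: (center + spread * d) / report_scale
    runwise, collapsed, runwise_draws, participant_level = {}, {}, {}, {}
    runs = sorted(df["run"].unique())
    cell_i = 0
    for g in sorted(df["_g"].dropna().unique()):
        for c in sorted(df["cursor_chosen"].unique()):
            per_run = {}
            for r in runs:
                cell = df[(df["_g"] == g) & (df["cursor_chosen"] == c) & (df["run"] == r)]
                if cell.empty:
                    warnings.warn(f"empty cell ({g},{c},run{r}); dropped",
                                  stacklevel=2)
                    continue
                n_i, m_i, ss_i = _cell_stats(cell, "_z")
                np_ = len(n_i)
                if degenerate_all:
                    # the measure is numerically constant across the whole
                    # table: the group mean is the cell constant
                    # (point-mass posterior)
                    const = np.full((config.chains, config.draws_per_chain),
                                    float(m_i.mean()))
                    per_run[r] = PosteriorSummary.from_chains(
                        f"mu[{g},{c},run{r}]", const, mass
                    ).transformed(back)
                    participant_level[(g, c, r)] = (
                        cell["participant_id"].drop_duplicates().to_numpy(),
                        back(np.tile(m_i, (const.size, 1))),
                    )
                    cell_i += 1
                    continue
                scale_guess = max(float(np.sqrt((ss_i.sum() + 1e-6) / max(n_i.sum() - np_, 1))), 1e-3)
                TAU2 = 100.0  # variance of the N(0, 10) priors

                # per-participant log-noise latents s_i are integrated out on
                # a fixed grid around their likelihood peak; the sampled
                # target is the 4-D hyperposterior (mu, log Sigma, phi,
                # log psi), which the ensemble sampler mixes well even for
                # very small cells
                K = 61
                s_grids, lik_grids = [], []
                for i in range(np_):
                    s_hat = 0.5 * math.log(max(ss_i[i] / max(n_i[i], 1), 1e-8))
                    half = max(8.0 / math.sqrt(max(n_i[i], 2)), 3.0)
                    s_k = np.linspace(s_hat - half, s_hat + half, K)
                    lik = -(n_i[i] - 1) * s_k - 0.5 * ss_i[i] * np.exp(-2 * s_k)
                    s_grids.append(s_k)
                    lik_grids.append(lik + math.log(s_k[1] - s_k[0]))
                s_grid = np.stack(s_grids)        # (n, K)
                lik_grid = np.stack(lik_grids)    # (n, K), includes log ds

                def log_prob(theta, n_i=n_i, m_i=m_i, s_grid=s_grid,
                             lik_grid=lik_grid, np_=np_):
                    mu, logSig = theta[:, 0], theta[:, 1]
                    phi, logpsi = theta[:, 2], theta[:, 3]
                    with np.errstate(all="ignore"):
                        Sig2 = np.exp(2 * logSig)
                        psi = np.exp(logpsi)
                        lp = (
                            -0.5 * mu**2 / TAU2
                            + _half_normal_logpdf(np.exp(logSig), 10) + logSig
                            - 0.5 * phi**2 / TAU2
                            + _half_normal_logpdf(psi, 10) + logpsi
                        )
                        # star2: (W, n, K) variance of m_i around mu
                        star2 = (Sig2[:, None, None]
                                 + np.exp(2 * s_grid)[None, :, :] / n_i[None, :, None])
                        terms = (
                            lik_grid[None, :, :]
                            - 0.5 * np.log(2 * math.pi * star2)
                            - 0.5 * (m_i[None, :, None] - mu[:, None, None]) ** 2 / star2
                            - 0.5 * ((s_grid[None, :, :] - phi[:, None, None])
                                     / psi[:, None, None]) ** 2
                            - np.log(psi)[:, None, None]
                        )
                        tmax = terms.max(axis=2)
                        ll = tmax + np.log(np.exp(terms - tmax[:, :, None]).sum(axis=2))
                        out = lp + ll.sum(axis=1)
                    out[~np.isfinite(out)] = -np.inf
                    out[np.max(np.abs(theta), axis=1) > 25] = -np.inf
                    return out

                init = np.array([
                    float(m_i.mean()),
                    math.log(max(float(m_i.std()), scale_guess / 4, 1e-3)),
                    math.log(scale_guess),
                    math.log(0.5),
                ])
                scale0 = np.array([0.3, 0.3, 0.3, 0.3])
                grouped = _sample_checked(
                    log_prob, init, scale0, config,
                    seed=config.seed + 104729 + 17 * cell_i,
                    context=f"hier_gaussian[{g},{c},run{r}]", check_dims=1,
                )
                cell_i += 1
                per_run[r] = PosteriorSummary.from_chains(
                    f"mu[{g},{c},run{r}]", grouped[:, :, 0], mass,
                ).transformed(back)
                # participant means: draw s_i from its grid conditional, then
                # xbar_i conjugately given (mu, Sigma, s_i)
                flat = grouped.reshape(-1, 4)
                prng = np.random.default_rng(config.seed + 556 + cell_i)
                mu_f = flat[:, 0]
                Sig2_f = np.exp(2 * flat[:, 1])
                phi_f, psi_f = flat[:, 2], np.exp(flat[:, 3])
                xbar_cols = []
                for i in range(np_):
                    star2 = Sig2_f[:, None] + np.exp(2 * s_grid[i])[None, :] / n_i[i]
                    t = (lik_grid[i][None, :]
                         - 0.5 * np.log(star2)
                         - 0.5 * (m_i[i] - mu_f[:, None]) ** 2 / star2
                         - 0.5 * ((s_grid[i][None, :] - phi_f[:, None])
                                  / psi_f[:, None]) ** 2)
                    t = t - t.max(axis=1, keepdims=True)
                    w = np.exp(t)
                    w /= w.sum(axis=1, keepdims=True)
                    pick = (np.cumsum(w, axis=1)
                            < prng.uniform(size=(len(flat), 1))).sum(axis=1)
                    s_i = s_grid[i][pick.clip(0, K - 1)]
                    sd2 = np.exp(2 * s_i)
                    prec = n_i[i] / sd2 + 1.0 / Sig2_f
                    mean_x = (n_i[i] * m_i[i] / sd2 + mu_f / Sig2_f) / prec
                    xbar_cols.append(
                        mean_x + prng.standard_normal(len(flat)) / np.sqrt(prec)
                    )
                participant_level[(g, c, r)] = (
                    cell["participant_id"].drop_duplicates().to_numpy(),
                    back(np.column_stack(xbar_cols)),
                )
            if not per_run:
                continue
            present = [r for r in runs if r in per_run]
            K = min(per_run[r].draws.size for r in present)
            Y = np.stack([per_run[r].draws[:K] for r in present], axis=0)
            runwise_draws[(g, c)] = Y
            runwise.update({(g, c, r): per_run[r] for r in per_run})
            coll = Y.mean(axis=0)  # per-draw mean over runs (linear collapse)
            collapsed[(g, c)] = PosteriorSummary(
                f"mu[{g},{c},collapsed]", coll, float(coll.mean()),
                hdi(coll, mass), mass,
                float(max(per_run[r].rhat for r in present)),
            )
    return HierSkillResult(runwise, collapsed, runwise_draws, participant_level, mass)


def hier_poisson_spatial(
    trials: pd.DataFrame,
    groups: dict,
    normalise: str = "raw",
    ideal_col: str = "ideal_direction_changes",
    mass: float = 0.94,
    config: SamplerConfig = SamplerConfig(),
) -> HierSkillResult:
    """Hierarchical log-link Poisson model of direction-change counts.

    y_{n,r,c} ~ Poisson(exp(xbar_{n,r,c})) per trial with
    xbar ~ N(mu_{g,r,c}, Sigma_{g,r,c}); mu ~ N(0, 10), Sigma ~
    HalfNormal(10).  Reported posteriors are exp-transformed back to the
    count scale.

    ``normalise="choice_normalised"`` fits observed minus ideal direction
    changes (the optimal plan's turn count for the chosen cursor); because
    adjusted counts can be negative, the cohort-wide minimum is added before
    the fit and subtracted from the exp-adjusted posteriors afterwards.
    """
    if normalise not in ("raw", "choice_normalised"):
        raise ValueError("normalise must be 'raw' or 'choice_normalised'")
    df = trials.copy()
    df["_g"] = df["participant_id"].map(groups)
    shift = 0.0
    if normalise == "choice_normalised":
        adj = df["direction_changes"].astype(float) - df[ideal_col].astype(float)
        shift = float(max(0.0, -adj.min()))
        if shift > 0:
            warnings.warn(
                f"choice-normalised counts shifted by +{shift:g} before the "
                "Poisson fit (negative adjusted counts); the shift is removed "
                "from reported posteriors",
                stacklevel=2,
            )
        df["_y"] = adj + shift
    else:
        df["_y"] = df["direction_changes"].astype(float)
    runwise, collapsed, runwise_draws, participant_level = {}, {}, {}, {}
    runs = sorted(df["run"].unique())
    cell_i = 0
    for g in sorted(df["_g"].dropna().unique()):
        for c in sorted(df["cursor_chosen"].unique()):
            per_run = {}
            for r in runs:
                cell = df[(df["_g"] == g) & (df["cursor_chosen"] == c) & (df["run"] == r)]
                if cell.empty:
                    warnings.warn(f"empty cell ({g},{c},run{r}); dropped",
                                  stacklevel=2)
                    continue
                gb = cell.groupby("participant_id", observed=True)["_y"]
                n_i = gb.count().to_numpy(dtype=float)
                sum_i = gb.sum().to_numpy(dtype=float)
                np_ = len(n_i)

                # participant latents are integrated out by Gauss-Hermite
                # quadrature (the Poisson x Gaussian integrand is
                # log-concave), leaving an exact 2-D posterior in
                # (mu, log Sigma) that the ensemble sampler handles easily
                gh_x, gh_w = np.polynomial.hermite_e.hermegauss(41)
                log_gh_w = np.log(gh_w / math.sqrt(2 * math.pi))

                def log_post(MU, LOGSIG, n_i=n_i, sum_i=sum_i):
                    with np.errstate(all="ignore"):
                        SIG = np.exp(LOGSIG)
                        lp = (
                            -0.5 * (MU / 10) ** 2
                            + _half_normal_logpdf(SIG, 10) + LOGSIG
                        )
                        # quadrature nodes: (..., participants, gh nodes)
                        x = MU[..., None, None] + SIG[..., None, None] * gh_x
                        terms = (
                            log_gh_w
                            + sum_i[:, None] * x
                            - n_i[:, None] * np.exp(x)
                        )
                        tmax = terms.max(axis=-1)
                        ll = tmax + np.log(
                            np.exp(terms - tmax[..., None]).sum(axis=-1)
                        )
                        out = lp + ll.sum(axis=-1)
                    return np.nan_to_num(out, nan=-np.inf, posinf=-np.inf)

                rate = max(float(sum_i.sum() / n_i.sum()), 0.05)
                lo = min(math.log(rate) - 8.0, -4.0)
                hi = max(math.log(rate) + 6.0, 4.0)
                mu_chains, logsig_chains = _grid2d_draws(
                    log_post, (lo, hi), (-7.0, 3.5), config,
                    seed=config.seed + 224737 + 17 * cell_i,
                )
                cell_i += 1
                per_run[r] = PosteriorSummary.from_chains(
                    f"rate[{g},{c},run{r}]",
                    np.exp(mu_chains) - shift, mass,
                )
                # participant log-rates re-drawn from the quadrature grid of
                # their conditional given each (mu, Sigma) draw
                prng = np.random.default_rng(config.seed + 777 + cell_i)
                mu_f = mu_chains.reshape(-1)
                Sig_f = np.exp(logsig_chains.reshape(-1))
                flat = mu_f[:, None]  # length reference for draws below
                x = mu_f[:, None] + Sig_f[:, None] * gh_x[None, :]
                xbar_cols = []
                for i in range(np_):
                    t = (log_gh_w[None, :] + sum_i[i] * x - n_i[i] * np.exp(x))
                    t = t - t.max(axis=1, keepdims=True)
                    w = np.exp(t)
                    w /= w.sum(axis=1, keepdims=True)
                    cum = np.cumsum(w, axis=1)
                    u = prng.uniform(size=(len(flat), 1))
                    pick = (cum < u).sum(axis=1).clip(0, len(gh_x) - 1)
                    xbar_cols.append(x[np.arange(len(flat)), pick])
                xbar_flat = np.column_stack(xbar_cols)
                participant_level[(g, c, r)] = (
                    cell["participant_id"].drop_duplicates().to_numpy(),
                    np.exp(xbar_flat) - shift,
                )
            if not per_run:
                continue
            present = [r for r in runs if r in per_run]
            K = min(per_run[r].draws.size for r in present)
            Y = np.stack([per_run[r].draws[:K] for r in present], axis=0)
            runwise_draws[(g, c)] = Y
            runwise.update({(g, c, r): per_run[r] for r in per_run})
            coll = Y.mean(axis=0)
            collapsed[(g, c)] = PosteriorSummary(
                f"rate[{g},{c},collapsed]", coll, float(coll.mean()),
                hdi(coll, mass), mass,
                float(max(per_run[r].rhat for r in present)),
            )
    return HierSkillResult(runwise, collapsed, runwise_draws, participant_level, mass)


def _tot_design(n_runs: int = 6) -> np.ndarray:
    """Design matrix: intercept, z-scored linear and z-scored logarithmic
    run regressors."""
    x = np.arange(1, n_runs + 1, dtype=float)
    zlin = (x - x.mean()) / x.std()
    lx = np.log(x)
    zlog = (lx - lx.mean()) / lx.std()
    return np.column_stack([np.ones(n_runs), zlin, zlog])


@dataclass
class TimeOnTaskEffect:
    """Per-draw least-squares time-on-task trends across the six runs.

    ``label`` follows the precedence rule: logarithmic whenever the
    logarithmic coefficient is credible, else linear, else none.
    """

    beta_lin: PosteriorSummary
    beta_log: PosteriorSummary
    label: str

    @property
    def credible_lin(self) -> bool:
        return self.beta_lin.excludes(0.0)

    @property
    def credible_log(self) -> bool:
        return self.beta_log.excludes(0.0)


def time_on_task(runwise_draws: np.ndarray, mass: float = 0.94) -> TimeOnTaskEffect:
    """Exact per-draw least squares of runwise posterior draws on the
    time-on-task design; ``runwise_draws`` has shape (6, K)."""
    Y = np.asarray(runwise_draws, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != 6:
        raise ValueError("expected (6, K) runwise draws")
    X = _tot_design(6)
    B = np.linalg.solve(X.T @ X, X.T @ Y)  # (3, K), exact per draw
    # snap float residue to exact zeros (constant Y must give beta == 0, and
    # a zero-width posterior at 1e-15 would spuriously "exclude" zero)
    B[np.abs(B) < 1e-10 * max(1.0, float(np.abs(Y).max()))] = 0.0
    b_lin = PosteriorSummary(
        "beta_lin", B[1], float(B[1].mean()), hdi(B[1], mass), mass, 1.0
    )
    b_log = PosteriorSummary(
        "beta_log", B[2], float(B[2].mean()), hdi(B[2], mass), mass, 1.0
    )
    if b_log.excludes(0.0):
        label = "logarithmic"
    elif b_lin.excludes(0.0):
        label = "linear"
    else:
        label = "none"
    return TimeOnTaskEffect(b_lin, b_log, label)


def nonparametric_tot(
    medians: np.ndarray,
    groups: Sequence,
    mass: float = 0.94,
    config: SamplerConfig = SamplerConfig(),
    alpha: float = 0.05,
) -> dict:
    """Participant-level nonparametric time-on-task analysis.

    ``medians`` is (participants, 6): each participant's run-wise posterior
    medians for one cursor.  Two separate simple regressions (z-scored
    linear; z-scored logarithmic) are fitted per participant; a participant
    is an improver ("time-on-task positive") if either slope's 95% CI
    excludes 0.  Improver proportions are compared between groups with the
    conjugate Beta(1,1)-binomial and the credible-difference rule.
    """
    M = np.asarray(medians, dtype=float)
    labels = np.asarray(groups)
    if M.ndim != 2 or M.shape[1] != 6:
        raise ValueError("expected (participants, 6) medians")
    X = _tot_design(6)
    flags = np.zeros(M.shape[0], dtype=bool)
    tcrit = stats.t.ppf(1 - alpha / 2, df=6 - 2)
    for i in range(M.shape[0]):
        y = M[i]
        for col in (1, 2):
            Xi = X[:, [0, col]]
            beta, res, *_ = np.linalg.lstsq(Xi, y, rcond=None)
            resid = y - Xi @ beta
            s2 = float(resid @ resid) / (6 - 2)
            se = math.sqrt(s2 * np.linalg.inv(Xi.T @ Xi)[1, 1])
            if se == 0.0:
                continue
            if abs(beta[1]) / se > tcrit:
                flags[i] = True
    uniq = list(pd.unique(labels))
    posteriors = summary_binomial(
        [int(flags[labels == g].sum()) for g in uniq],
        [int((labels == g).sum()) for g in uniq],
        groups=uniq, mass=mass, config=config,
    )
    comparisons = {}
    for i, g1 in enumerate(uniq):
        for g2 in uniq[i + 1 :]:
            comparisons[(g1, g2)] = CredibleComparison.of(
                posteriors[g1], posteriors[g2], mass
            )
    return {
        "improver": flags,
        "proportions": posteriors,
        "comparisons": comparisons,
    }


def segmentation_anova(data: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-way mixed ANOVA of median RT: group (between) by route
    segmentation (within), with Tukey-corrected single-vs-multiple
    contrasts inside each group.

    ``data`` needs columns participant_id, group, segmentation
    ("single"/"multiple") and median_rt, one row per participant x
    segmentation cell; participants missing a cell are excluded (flagged).
    """
    import pingouin as pg

    df = data.copy()
    cell_counts = df.groupby("participant_id", observed=True)["segmentation"].nunique()
    complete = cell_counts[cell_counts == 2].index
    excluded = sorted(set(df["participant_id"]) - set(complete))
    if excluded:
        warnings.warn(f"excluded participants missing a cell: {excluded}",
                      stacklevel=2)
        df = df[df["participant_id"].isin(complete)]
    aov = pg.mixed_anova(
        data=df, dv="median_rt", within="segmentation",
        subject="participant_id", between="group",
    )
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    # Tukey-corrected cell contrasts: paired single-vs-multiple differences
    # per group, pooled error variance across groups (emmeans convention,
    # studentized-range reference with k = 4 cells).
    wide = df.pivot_table(index=["participant_id", "group"],
                          columns="segmentation", values="median_rt").reset_index()
    wide["diff"] = wide["multiple"] - wide["single"]
    groups_ = sorted(wide["group"].unique())
    n_g = {g: int((wide["group"] == g).sum()) for g in groups_}
    ss = sum(
        float(np.sum((wide.loc[wide["group"] == g, "diff"]
                      - wide.loc[wide["group"] == g, "diff"].mean()) ** 2))
        for g in groups_
    )
    df_err = sum(n_g.values()) - len(groups_)
    s2 = ss / df_err
    contrasts = {}
    for g in groups_:
        d = float(wide.loc[wide["group"] == g, "diff"].mean())
        se = math.sqrt(s2 / n_g[g])
        tstat = d / se if se > 0 else np.inf
        p_tukey = float(stats.studentized_range.sf(abs(tstat) * math.sqrt(2), 4, df_err))
        contrasts[g] = {
            "mean_diff": d, "t": tstat, "df": df_err, "p_tukey": p_tukey,
            "significant": p_tukey < alpha,
        }
    return {
        "anova": aov,
        "interaction_F": float(inter["F"]),
        "interaction_df": (int(inter["DF1"]), int(inter["DF2"])),
        "interaction_p": float(inter[p_col]),
        "contrasts": contrasts,
        "excluded": excluded,
    }
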