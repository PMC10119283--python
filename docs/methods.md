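# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package, in the order the pipeline uses them.

## Trial world

The world is a frictionless point-mass simulation on a circular grid
(radius 3.82, in abstract visual-angle units; no screen/pixel model). Every
throttled frame adds a fixed speed increment `accel_per_frame` along the
pressed heading and burns one fuel unit from a 360-unit tank; unthrottled
frames leave velocity unchanged. Positions advance by forward-Euler at
60 Hz, frame 0 being the trial start. The published task defers its exact
acceleration law to unavailable supplementary material; the frictionless
constant-increment law is this package's own realisation of the stated
qualitative contract — throttle time burns fuel linearly but grows
displacement quadratically, and arrival speed is a real control problem.
The default `accel_per_frame = 0.032` is a convention chosen so that
exactly 1 s of continuous throttle reaches the 1.920/s dock speed limit; it
is configurable and nothing downstream depends on the specific value.

Docking is adjudicated on *entering* the 0.479-radius goal disc: a dock if
speed ≤ 1.920/s (inclusive, with a 1e−9 relative tolerance because speed is
a float accumulation), too-fast otherwise; leaving the grid or draining the
tank end the trial first. At most one throttle registers per frame; ties
resolve by fixed finger priority (index > middle > ring). Start–goal pairs
are drawn by rejection sampling, uniform over the admissible region (both
points ≥ 0.320 inside the perimeter, centres ≥ 0.957 apart).

Skill measures per trial: reward = fuel conserved / 360 on a dock, else 0;
spatial skill = count of adjacent-distinct throttle identities over the
throttled frames; temporal skill = (v_max − v_final) / SG distance, defined
only when the goal disc was crossed (docks and too-fast arrivals) and
reported as missing otherwise, never as zero.

## Optimal routes and the two suitability scores

The heuristic offset is the minimum wrapped angular distance (degrees)
between the SG direction and the incongruent cursor's three headings,
clamped to [0, 60]; the congruent cursor's suitability is implied by
60 − offset. State-appropriateness: incongruent below 30°, congruent above,
indeterminate exactly at 30° (excluded from appropriateness tallies;
measure-zero under continuous sampling).

The route-planning score is the congruent-minus-incongruent difference in
projected optimal-route reward, where an optimal route minimises throttled
frames λ over a candidate family that is consistent-by-construction with
the simulator:

* **single-heading plans** whenever a heading ray from S passes within the
  dock radius of G (an aiming margin of 0.8 × the dock radius absorbs frame
  quantisation) — accelerate, then coast into the disc;
* **two-segment plans** from the unique nonnegative decomposition of the SG
  displacement onto a pair of cursor headings, flown in either order with a
  full stop at the turn point; braking alternates the cursor's other two
  throttles, giving reverse acceleration of half a unit with lateral
  components cancelling over frame pairs (a geometric consequence of the
  120° spacing);
* **blended plans** that interleave integer pulse counts of the two
  decomposition headings (largest-remainder order) so the net velocity
  points straight along the chord, then coast into the disc;
* an m-fold zig-zag fallback of the decomposition when both two-segment
  turn points would leave the grid.

Plans must dock within a wall-time horizon, by default the same 6-s window
that bounds throttle time. The horizon is what couples fuel to distance:
without it the fuel-minimal plan degenerates to "throttle once and coast
forever" and λ would not depend on the SG at all. With blended plans every
admissible SG is solvable inside the horizon (0 failures in 2,000 sampled
SGs), arrival speed never exceeds the dock limit by construction, and the
replayed plan reproduces λ exactly — the search uses closed-form phase
arithmetic, and replay through the simulator is the validation oracle.

λ is searched at 1-frame granularity, so the route score has 1/360
resolution. Near the 30° indifference point this quantisation produces
exact score ties (≈ 4% of trials, score exactly 0) but no strict sign
disagreements with the offset rule; the published ±0.35 score range is not
reproduced (it depends on the unpublished dynamics) and is not needed —
difficulty bins are quantile-based, so only the score's ordering matters.
Segmentation class: "single" iff the optimal plan uses one heading. The
per-trial segmentation column refers to the optimal plan of the
state-appropriate cursor. Ideal direction changes (for choice-normalised
spatial skill) are the plan's turn count: 0 for single-heading plans, 1 for
blends, legs − 1 for explicit dog-legs.

Difficulty bins use pooled cohort quantiles (0.2, 0.4, 0.6, 0.8) shared
across participants; bin 1 is most incongruent-suited, bin 5 most
congruent-suited, bin 3 straddles the indifference point. Offsets are
continuous, so parity is exact; route scores are discrete and parity is
approximate, with a warning reporting achieved counts.

## Decision model and classification

The drift–diffusion model fixes σ = 0.1 and constrains 0 ≤ μ₁ ≤ μ₂, B > 0,
−1 < b_C < 1, t₀ ≥ 0. Choice probabilities use the closed-form absorption
probability; first-passage CDFs use the large-time eigenfunction series of
the absorbed-mass tail, truncated adaptively to 1e−8 with an error raised
if the tolerance is unreachable. Verification: total absorbed mass and the
boundary split agree with the closed form to 1e−6 across random parameter
draws, and simulated quantiles (Euler–Maruyama at 1-ms steps) match the
numerical CDF.

Fitting uses the quantile ("chi-square") method: per difficulty level and
choice, six RT bins bounded by that choice's own 10/30/50/70/90% quantiles;
cells with fewer than 12 trials collapse to a single frequency cell. The
objective is the binned multinomial negative log-likelihood (probability
floor 1e−10), asymptotically equivalent to the chi-square criterion and the
basis for AICc with n = trial count; the Pearson chi-square statistic is
also reported. The null model carries no difficulty structure, so its
observed bins use a single pooled level — the heuristic and route models
keep their own five-level partitions, exactly as the families are meant to
be compared. Optimisation is multi-start Nelder–Mead (default 20 restarts;
recovery experiments use 4–5, since restarts converge to a common optimum
on these objectives) on transformed coordinates: log B, atanh b_C, log t₀,
log μ₂ and a logistic share for μ₁/μ₂.

Classification takes the minimum AICc across the five models; one-drift
variants count toward their family, ties break toward fewer parameters and
are flagged. Residual deviance is D₂ = 2(LL_family_best − LL_null) per
participant. Twofold cross-validation splits trials in half stratified by
offset-difficulty bin, fits on one half and labels each fold by held-out
binned log-likelihood.

At the published heuristic-group parameter means (μ₁ = 0.046, μ₂ = 0.073,
B = 0.125, b_C = 0.070) the sensitivity S evaluates to 0.445, whereas the
published group value is 0.447 — the latter is the posterior expectation of
a nonlinear function, not the function of the posterior means. The package
documents this gap rather than asserting the two equal.

## Bayesian layer

All models follow the same contract: 4 chains × 10,000 kept draws
(a 4 × 1,000 reduced mode serves quick runs), HDI mass 0.94 by default
(configurable to 0.95), credibility = the minimum-width HDI of a posterior
(or of a difference of posteriors, never HDI overlap) excluding the
reference value, and split-chain R-hat ≤ 1.01 (the idealised "R̂ not
greater than 1" is unattainable in finite samples).

Posterior computation is chosen per model structure rather than by a single
sampler:

* the summary binomial (Beta(1,1) prior) is conjugate and sampled exactly;
* 2-D marginal posteriors — the summary Gaussian in (μ, log Σ); the
  hierarchical binomial's group-by-run (logit mean, log concentration)
  after analytically marginalising participant rates into a beta-binomial;
  and the hierarchical Poisson's (μ, log Σ) after integrating participant
  log-rates by 41-node Gauss–Hermite quadrature — are integrated on an
  adaptive grid (coarse pass brackets the mass, fine 400 × 300 grid is
  normalised there) and sampled iid with within-cell jitter. This is exact
  to grid resolution, deterministic, and immune to the funnel geometry that
  defeats random-walk samplers on small cells;
* the hierarchical Gaussian skill model reduces to a 4-D hyperposterior
  (μ, log Σ, φ, log ψ) by marginalising participant means analytically and
  integrating participant log-noises on fixed per-participant grids; that
  4-D target is sampled with the emcee ensemble sampler
  (differential-evolution moves, walkers grouped into four pseudo-chains,
  thinned, with automatic 4× and 16× longer reruns if R-hat exceeds 1.01).

Participant-level draws (needed for the nonparametric temporal-skill
follow-up) are reconstructed conjugately, or drawn from their quadrature
grids, given each kept hyperdraw. Hierarchical cells over distinct
group × run(× cursor) combinations share no parameters, so sampling them
independently is exact. Divergence counts are identically zero for these
samplers.

Scale conventions: the hierarchical Gaussian fits on grand z-scores — the
N(0, 10)/HalfNormal(10) priors are uninformed only relative to a
standardised scale, and fitting raw 0–360 fuel units under them would let
the prior overwhelm the likelihood — and transforms posteriors back
(affine, exact). Reward is scaled to 0–360 before standardisation and
reported as a proportion; temporal skill is fitted and reported in natural
units (the published group values are natural-scale). Time-on-task betas
are reported on the same scale as the reported posteriors. A measure that
is numerically constant across the table short-circuits to its point-mass
posterior. Choice-normalised spatial counts can be negative after
subtracting ideal turns; the cohort-minimum shift is added before the
Poisson fit and removed from the exp-adjusted posteriors, with a prominent
warning.

Trial inclusion: reward models include all trials (catastrophic errors
contribute 0); temporal-skill models include only threshold-crossing
trials; spatial models include all trials. Groups with fewer than two
participants are dropped from group-level models with a warning.

Time-on-task effects solve b = (XᵀX)⁻¹XᵀY exactly per posterior draw, with
X = [1, z-scored (1..6), z-scored (ln 1..ln 6)]; coefficients below 1e−10
of the draw scale snap to exact zeros so constant input yields exactly zero
betas. A credible logarithmic trend takes precedence over a linear one.
The nonparametric follow-up runs two separate per-participant OLS fits
(linear; logarithmic) on runwise posterior medians, flags a participant as
an improver if either 95% CI excludes zero, and compares group improver
proportions with the conjugate binomial and the credible-difference rule.

The segmentation check is a two-way mixed ANOVA (group between, single- vs
multiple-segment within) of median RT on congruent-suited trials, with
Tukey-corrected single-vs-multiple contrasts per group: paired differences,
error variance pooled across groups (df = N − number of groups), and the
studentized-range reference with k = 4 cells — the emmeans convention.

## Synthetic cohort

Agents carry DDM parameters drawn from truncated normals centred on the
published group-level values (heuristic: μ₁ 0.046, μ₂ 0.073, B 0.125,
b_C 0.070, t₀ 0.780 s; route: 0.029/0.058/0.151/0.147/0.811; nonplanner:
zero drifts, B 0.106, b_C 0.267, t₀ 0.522), with spreads of roughly 0.01 on
drifts, 0.02 on B, 0.08 on b_C and 0.1 s on t₀ — magnitudes a
between-participant distribution of these parameters plausibly has.
Sessions reproduce the task structure: 360 choice trials in six runs of 60,
SGs sampled uniformly, per-trial drift set by the difficulty bin of the
agent's own strategy score (within-session quantile bins at generation
time; the analysis pipeline re-bins with pooled cohort edges). Choices and
RTs come from simulating the diffusion process at 1-ms steps.

Execution is generated statistically rather than by a closed-loop control
policy (downstream analyses consume only the skill measures): spatial
counts from a log-link Poisson with baseline rates near the published
collapsed values (≈ 1.5 congruent, 1.6–1.85 incongruent, worse for
non-heuristic groups on the incongruent cursor) and a logarithmic learning
trend (−0.10 on the z-scored log-run regressor); temporal skill from a
Gaussian (means ≈ 0.64–0.71, trial SD 0.25) with a logarithmic improvement
(+0.04) for route agents only, mirroring the temporal-domain learning that
distinguishes that group. Reward ties deterministically to skill:
optimal-route reward × exp(−0.15 × excess direction changes − 1.5 ×
max(0, 0.9 − temporal skill)), clipped to [0, 1] and zeroed on catastrophic
trials (per-agent probability ≈ 0.12–0.18 by group). Route agents pay an
additional 0.30 s planning cost on multiple-segment congruent-suited
trials, which reproduces the group × segmentation RT interaction.
Per-agent seeds derive from the master seed via `SeedSequence.spawn`, so
cohorts are bitwise-reproducible. Unsolvable SGs would be resampled and
counted; none occur under the default configuration.

What passing tests on this cohort do and do not show: the generator
reproduces the *structure* real data would have (difficulty-modulated
drifts, skill-coupled reward, run trends, a segmentation cost), not human
motor-noise spectra, fatigue, or the real cohort's parameter covariance —
so recovery results certify the pipeline's correctness, not effect sizes in
human data.

## Problem sizes used in the checks

Parameter recovery uses 20 replicates of 2,000-trial sessions (tolerances:
B within 0.02, drifts within 0.01, t₀ within 0.05 s, required in ≥ 90% of
replicates). Classification recovery uses one default 30-agent cohort
(10 per strategy, 360 trials each, 4 fit restarts), requiring ≥ 80% correct
family labels overall and ≥ 90% nonplanner recovery for null agents.
Bayesian-layer checks run in the reduced 4 × 1,000 draw mode against the
conjugate Beta closed form, a fine-grid density-threshold HDI oracle on
Beta(2, 5), and exact column-space inputs for the time-on-task regression.
The end-to-end pipeline test uses an eight-agent cohort with 180 trials per
agent and reduced draws.

## Known limitations

* The acceleration law, optimal-route family and 6-s planning horizon are
  this package's own realisation of an under-specified task; λ values and
  the route-score range are internally consistent but not comparable in
  magnitude to the original implementation.
* The route score's 1-frame resolution leaves exact ties near the
  indifference point; binwise analyses are unaffected.
* With very small groups (two or three participants) the hierarchical
  posteriors are prior-dominated and heavy-tailed — exp-adjusted Poisson
  means can be very large honestly; analyses are intended for group sizes
  in the published range (≈ 14–20).
* The quantile-method objective compares models across different cell
  partitions (heuristic vs route binnings), as the original comparison
  does; the multinomial constants differ slightly between partitions.
* Cross-validated classification and the nonparametric follow-up are
  implemented but not exercised at the published cohort's scale in the
  default test run.
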