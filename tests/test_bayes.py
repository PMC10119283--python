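"""Bayesian layer: HDI, conjugate oracles, hierarchical models, trends."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boatdock.bayes import (
    CredibleComparison,
    PosteriorSummary,
    SamplerConfig,
    hdi,
    hier_binomial_choice,
    hier_gaussian_skill,
    hier_poisson_spatial,
    nonparametric_tot,
    segmentation_anova,
    split_rhat,
    summary_binomial,
    summary_gaussian,
    time_on_task,
)
from boatdock.bayes import _tot_design

REDUCED = SamplerConfig.reduced(seed=9)


class TestHdi:
    def test_point_mass_zero_width(self):
        lo, hi = hdi(np.full(5000, 3.2))
        assert lo == hi == 3.2

    def test_standard_normal_symmetric_interval(self, rng):
        draws = rng.standard_normal(200_000)
        lo, hi = hdi(draws, 0.94)
        # symmetric density: HDI matches the central interval +-1.881
        z = stats.norm.ppf(0.97)
        assert lo == pytest.approx(-z, abs=0.05)
        assert hi == pytest.approx(z, abs=0.05)

    def test_beta25_matches_density_threshold_oracle(self, rng):
        draws = rng.beta(2, 5, 400_000)
        lo, hi = hdi(draws, 0.94)
        # oracle: lower the density threshold on a fine grid until the
        # enclosed mass reaches 0.94; the HDI is that level set
        grid = np.linspace(0, 1, 20_001)
        pdf = stats.beta.pdf(grid, 2, 5)
        order = np.argsort(pdf)[::-1]
        cdf_mass = np.cumsum(pdf[order]) / pdf.sum()
        inside = order[: int(np.searchsorted(cdf_mass, 0.94)) + 1]
        assert lo == pytest.approx(grid[inside].min(), abs=0.01)
        assert hi == pytest.approx(grid[inside].max(), abs=0.01)

    def test_mass_contained(self, rng):
        draws = rng.gamma(3, 1, 50_000)
        lo, hi = hdi(draws, 0.94)
        frac = np.mean((draws >= lo) & (draws <= hi))
        assert frac == pytest.approx(0.94, abs=0.005)


class TestSplitRhat:
    def test_iid_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 4000))
        assert split_rhat(chains) < 1.01

    def test_shifted_chain_detected(self, rng):
        chains = rng.standard_normal((4, 4000))
        chains[0] += 3.0
        assert split_rhat(chains) > 1.2


class TestSummaryBinomial:
    def test_conjugate_closed_form(self):
        out = summary_binomial([7], [10], config=REDUCED)["all"]
        a, b = 8, 4
        assert out.mean == pytest.approx(a / (a + b), abs=3 * 0.13 / 63)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert out.draws.var() == pytest.approx(var, rel=0.1)

    def test_all_failures(self):
        out = summary_binomial([0, 0], [50, 50], config=REDUCED)["all"]
        assert out.mean == pytest.approx(1 / 102, abs=0.005)

    def test_group_coverage(self, rng):
        hits = 0
        for rep in range(20):
            cfg = SamplerConfig.reduced(seed=rep)
            truth = {"a": 0.72, "b": 0.68, "c": 0.49}
            y, t, g = [], [], []
            for name, th in truth.items():
                for _ in range(12):
                    y.append(int(rng.binomial(360, th)))
                    t.append(360)
                    g.append(name)
            out = summary_binomial(y, t, groups=g, config=cfg)
            if all(out[k].hdi[0] <= truth[k] <= out[k].hdi[1] for k in truth):
                hits += 1
        assert hits >= 18


class TestSummaryGaussian:
    def test_recovers_mean_in_natural_units(self, rng):
        vals = rng.normal(1.7, 0.8, 19)
        out = summary_gaussian(vals, config=REDUCED)["all"]
        assert out.mean == pytest.approx(vals.mean(), abs=0.15)
        assert out.hdi[0] < vals.mean() < out.hdi[1]

    def test_identical_groups_not_credibly_different(self, rng):
        vals = rng.normal(2.0, 0.5, 30)
        out = summary_gaussian(
            np.concatenate([vals, vals]),
            groups=["a"] * 30 + ["b"] * 30, config=REDUCED,
        )
        comp = CredibleComparison.of(out["a"], out["b"])
        assert not comp.credible

    def test_single_value_group_errors(self):
        with pytest.raises(ValueError):
            summary_gaussian([1.0, 2.0], groups=["a", "b"], config=REDUCED)


class TestHierBinomial:
    def test_ramping_group_credible_earlier(self, rng):
        t = np.full((16, 6), 60)
        theta_fast = np.linspace(0.55, 0.85, 6)
        theta_flat = np.full(6, 0.5)
        y = np.vstack(
            [rng.binomial(60, theta_fast) for _ in range(8)]
            + [rng.binomial(60, theta_flat) for _ in range(8)]
        )
        res = hier_binomial_choice(y, t, ["fast"] * 8 + ["flat"] * 8,
                                   config=REDUCED)
        assert res["first_credible_run"]["fast"] is not None
        assert res["first_credible_run"]["flat"] is None
        th = res["theta"][("fast", 6)]
        assert 0 < th.mean < 1

    def test_chance_group_never_credible(self, rng):
        t = np.full((10, 6), 60)
        y = rng.binomial(60, 0.5, size=(10, 6))
        res = hier_binomial_choice(y, t, ["g"] * 10, config=REDUCED)
        assert all(not v for v in res["above_chance"].values())


def _skill_frame(rng, group_means, n_per=8, sd=0.1, n_trials=20, runs=6,
                 participant_sd=0.02):
    rows = []
    for g, gm in group_means.items():
        for p in range(n_per):
            pm = rng.normal(gm, participant_sd)
            for r in range(1, runs + 1):
                for c in ("congruent", "incongruent"):
                    for v in rng.normal(pm, sd, n_trials):
                        rows.append((f"{g}{p}", r, c, v))
    df = pd.DataFrame(
        rows, columns=["participant_id", "run", "cursor_chosen", "value"]
    )
    labels = {f"{g}{p}": g for g in group_means for p in range(n_per)}
    return df, labels


class TestHierGaussian:
    def test_constant_measure_recovered_exactly(self, rng):
        df, labels = _skill_frame(rng, {"a": 0.6}, n_per=4, sd=1e-9,
                                  n_trials=10, participant_sd=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hier_gaussian_skill(df, "value", labels, config=REDUCED)
        for s in res.runwise.values():
            assert s.mean == pytest.approx(0.6, abs=0.01)
        assert res.collapsed[("a", "congruent")].mean == pytest.approx(0.6, abs=0.01)

    def test_collapse_is_linear(self, rng):
        df, labels = _skill_frame(rng, {"a": 0.5}, n_per=5)
        res = hier_gaussian_skill(df, "value", labels, config=REDUCED)
        runmeans = [res.runwise[("a", "congruent", r)].mean for r in range(1, 7)]
        assert np.mean(runmeans) == pytest.approx(
            res.collapsed[("a", "congruent")].mean, abs=0.01
        )

    def test_group_gap_detected(self, rng):
        df, labels = _skill_frame(rng, {"hi": 0.60, "lo": 0.45}, n_per=8)
        res = hier_gaussian_skill(df, "value", labels, config=REDUCED)
        comp = CredibleComparison.of(
            res.collapsed[("hi", "incongruent")],
            res.collapsed[("lo", "incongruent")],
        )
        assert comp.credible and comp.mean > 0


class TestHierPoisson:
    def test_rate_coverage(self, rng):
        rows = []
        for p in range(10):
            for r in range(1, 7):
                for c in ("congruent", "incongruent"):
                    for v in rng.poisson(1.5, 20):
                        rows.append((f"p{p}", r, c, v))
        df = pd.DataFrame(rows, columns=["participant_id", "run",
                                         "cursor_chosen", "direction_changes"])
        labels = {f"p{p}": "g" for p in range(10)}
        res = hier_poisson_spatial(df, labels, config=REDUCED)
        s = res.collapsed[("g", "congruent")]
        # the exp-adjusted collapsed rate must track the realised sample
        # rate of this dataset (and sit near the generating 1.5)
        emp = df.loc[df.cursor_chosen == "congruent", "direction_changes"].mean()
        assert s.hdi[0] - 0.02 < emp < s.hdi[1] + 0.02
        assert s.mean == pytest.approx(1.5, abs=0.25)

    def test_choice_normalised_identity_when_ideal_zero(self, rng):
        rows = []
        for p in range(6):
            for r in range(1, 7):
                for v in rng.poisson(1.2, 15):
                    rows.append((f"p{p}", r, "congruent", v, 0))
        df = pd.DataFrame(rows, columns=["participant_id", "run",
                                         "cursor_chosen", "direction_changes",
                                         "ideal_direction_changes"])
        labels = {f"p{p}": "g" for p in range(6)}
        raw = hier_poisson_spatial(df, labels, normalise="raw", config=REDUCED)
        adj = hier_poisson_spatial(df, labels, normalise="choice_normalised",
                                   config=REDUCED)
        assert raw.collapsed[("g", "congruent")].mean == pytest.approx(
            adj.collapsed[("g", "congruent")].mean, abs=0.05
        )


class TestTimeOnTask:
    def test_constant_draws_give_exact_zero(self):
        Y = np.full((6, 500), 2.5)
        eff = time_on_task(Y)
        assert np.all(eff.beta_lin.draws == 0)
        assert np.all(eff.beta_log.draws == 0)
        assert eff.label == "none"

    def test_exact_linear_recovery(self):
        X = _tot_design(6)
        Y = (1.0 + 0.7 * X[:, 1])[:, None] * np.ones((1, 200))
        eff = time_on_task(Y)
        assert np.allclose(eff.beta_lin.draws, 0.7)
        assert np.allclose(eff.beta_log.draws, 0.0, atol=1e-12)
        assert eff.label == "linear"

    def test_log_trend_with_noise_labelled_logarithmic(self, rng):
        X = _tot_design(6)
        Y = (2.0 - 0.5 * X[:, 2])[:, None] + rng.normal(0, 0.05, (6, 4000))
        eff = time_on_task(Y)
        assert eff.credible_log
        assert eff.label == "logarithmic"


class TestNonparametricTot:
    def test_flat_vs_ramping_participants(self, rng):
        M = np.vstack(
            [np.linspace(2.0, 1.2, 6) + rng.normal(0, 0.02, 6)
             for _ in range(10)]
            + [np.full(6, 1.6) + rng.normal(0, 0.02, 6) for _ in range(14)]
        )
        res = nonparametric_tot(M, ["up"] * 10 + ["flat"] * 14, config=REDUCED)
        lab = np.array(["up"] * 10 + ["flat"] * 14)
        assert res["improver"][lab == "up"].sum() >= 9
        assert res["improver"][lab == "flat"].sum() <= 3
        assert res["comparisons"][("up", "flat")].credible

    def test_group_proportion_contrast(self, rng):
        # mirrors a 10/19 vs 0/14 improver split
        hits = 0
        for rep in range(20):
            cfg = SamplerConfig.reduced(seed=100 + rep)
            out = summary_binomial([10, 0], [19, 14], groups=["a", "b"],
                                   config=cfg)
            comp = CredibleComparison.of(out["a"], out["b"])
            if comp.credible:
                hits += 1
        assert hits >= 18


class TestSegmentationAnova:
    def _frame(self, rng, route_slow):
        rows = []
        for g, n, slow in [("heuristic", 14, 0.0), ("route", 19, route_slow)]:
            for p in range(n):
                base = rng.normal(1.8, 0.3)
                rows.append((f"{g}{p}", g, "single", base + rng.normal(0, 0.08)))
                rows.append((f"{g}{p}", g, "multiple",
                             base + slow + rng.normal(0, 0.08)))
        return pd.DataFrame(rows, columns=["participant_id", "group",
                                           "segmentation", "median_rt"])

    def test_identical_cells_give_null_interaction(self, rng):
        df = self._frame(rng, 0.0)
        res = segmentation_anova(df)
        assert res["interaction_p"] > 0.01

    def test_textbook_f_on_balanced_toy(self):
        # 2 groups x 2 participants, known cell values; closed-form mixed
        # ANOVA interaction F = MS_interaction / MS_error(within)
        df = pd.DataFrame({
            "participant_id": ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"],
            "group": ["A", "A", "A", "A", "B", "B", "B", "B"],
            "segmentation": ["single", "multiple"] * 4,
            "median_rt": [1.0, 1.2, 1.1, 1.5, 1.0, 1.8, 1.1, 2.1],
        })
        res = segmentation_anova(df)
        diffs = {"A": [0.2, 0.4], "B": [0.8, 1.0]}
        grand = np.mean(sum(diffs.values(), []))
        ss_inter = sum(2 * (np.mean(v) - grand) ** 2 for v in diffs.values()) / 2
        ss_err = sum((x - np.mean(v)) ** 2 for v in diffs.values() for x in v) / 2
        f_expected = (ss_inter / 1) / (ss_err / 2)
        assert res["interaction_F"] == pytest.approx(f_expected, rel=1e-6)

    def test_route_only_slowdown_recovered(self, rng):
        df = self._frame(rng, 0.35)
        res = segmentation_anova(df)
        assert res["interaction_p"] < 0.05
        assert res["contrasts"]["route"]["significant"]
        assert not res["contrasts"]["heuristic"]["significant"]
        assert res["interaction_df"] == (1, 31)

    def test_incomplete_participant_excluded(self, rng):
        df = self._frame(rng, 0.35)
        df = df.drop(df.index[0])  # heuristic0 now misses the "single" cell
        with pytest.warns(UserWarning, match="excluded"):
            res = segmentation_anova(df)
        assert "heuristic0" in res["excluded"]
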