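"""Rejection, regression adjustment, model choice and demographic fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from paraconv.abc_inference import (
    DEMOG_STAT_NAMES,
    PosteriorSummary,
    PriorSpec,
    fit_demography,
    model_choice,
    posterior_summary,
    regression_adjust,
    rejection,
    run_simulations,
    sample_priors,
    summarize,
)


class TestPriors:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec({"C": (2.0, 1.0)})

    def test_empty_draw(self):
        spec = PriorSpec({"C": (0.0, 20.0)})
        assert len(sample_priors(spec, 0, seed=1)) == 0

    def test_moments_and_uniformity(self):
        spec = PriorSpec({"C": (0.0, 20.0)})
        draws = sample_priors(spec, 100_000, seed=2)["C"]
        assert draws.mean() == pytest.approx(10.0, abs=0.1)
        stat = kstest((draws / 20.0).to_numpy(), "uniform")
        assert stat.pvalue > 0.01

    def test_reproducible_by_seed(self):
        spec = PriorSpec({"C": (0.0, 5.0), "lambda_tract": (50.0, 500.0)})
        a = sample_priors(spec, 100, seed=3)
        b = sample_priors(spec, 100, seed=3)
        pd.testing.assert_frame_equal(a, b)


def _toy_table(rng, n=20, stats=("s1", "s2")):
    table = pd.DataFrame({"C": rng.uniform(0, 10, n)})
    for s in stats:
        table[s] = rng.normal(size=n)
    return table


class TestRejection:
    def test_exact_match_retained_first(self):
        rng = np.random.default_rng(4)
        table = _toy_table(rng)
        obs = table[["s1", "s2"]].iloc[7].to_numpy()
        post = rejection(obs, table, k=5, stat_names=("s1", "s2"))
        assert post.delta[0] == 0.0
        assert post.retained["C"].iloc[0] == table["C"].iloc[7]

    def test_retain_all(self):
        rng = np.random.default_rng(5)
        table = _toy_table(rng)
        post = rejection(np.zeros(2), table, k=len(table), stat_names=("s1", "s2"))
        assert len(post.retained) == len(table)

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(6)
        table = _toy_table(rng, n=20)
        obs = np.array([0.3, -0.2])
        post = rejection(obs, table, k=5, stat_names=("s1", "s2"))
        z = table[["s1", "s2"]].to_numpy()
        sd = z.std(axis=0)
        d = np.sqrt((((z - obs) / sd) ** 2).sum(axis=1))
        expected = table.iloc[np.argsort(d, kind="stable")[:5]]["C"].to_numpy()
        assert np.allclose(post.retained["C"].to_numpy(), expected)

    def test_zero_variance_statistic_dropped(self):
        rng = np.random.default_rng(7)
        table = _toy_table(rng)
        table["s2"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            post = rejection(np.array([0.0, 1.0]), table, k=5, stat_names=("s1", "s2"))
        assert len(post.retained) == 5

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(8)
        table = _toy_table(rng)
        with pytest.raises(ValueError):
            rejection(np.zeros(2), table, k=50, stat_names=("s1", "s2"))


class TestRegressionAdjustment:
    def test_identity_when_stats_equal_observed(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {"C": rng.uniform(0, 10, 30), "s1": np.ones(30), "s2": rng.normal(size=30)}
        )
        table.loc[:9, "s2"] = 0.5  # ten rows exactly at the observed stats
        obs = np.array([1.0, 0.5])
        post = rejection(obs, table, k=10, stat_names=("s1", "s2"))
        post = regression_adjust(post, obs, table, stat_names=("s1", "s2"))
        assert np.allclose(
            post.adjusted["C"].to_numpy(), post.retained["C"].to_numpy()
        )

    def test_noiseless_linear_relation_collapses(self):
        # param = 2 * stat exactly: adjusted draws all equal 2 * observed
        rng = np.random.default_rng(10)
        s = rng.uniform(0, 5, 40)
        table = pd.DataFrame({"C": 2 * s, "s1": s})
        obs = np.array([1.7])
        post = rejection(obs, table, k=20, stat_names=("s1",))
        post = regression_adjust(post, obs, table, stat_names=("s1",))
        assert np.allclose(post.adjusted["C"].to_numpy(), 3.4, atol=1e-8)

    def test_clamped_to_prior_support(self):
        rng = np.random.default_rng(11)
        s = rng.uniform(0, 5, 40)
        table = pd.DataFrame({"C": 2 * s + rng.normal(0, 0.1, 40), "s1": s})
        prior = PriorSpec({"C": (0.0, 4.0)})
        post = rejection(np.array([4.0]), table, k=20, stat_names=("s1",))
        post = regression_adjust(post, np.array([4.0]), table, prior=prior, stat_names=("s1",))
        assert post.adjusted["C"].max() <= 4.0


class TestPosteriorSummary:
    def test_point_mass(self):
        mode, ci = posterior_summary(np.full(100, 3.3))
        assert mode == 3.3 and ci == (3.3, 3.3)

    def test_gaussian_recovery(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(5, 1, 10_000)
        mode, ci = posterior_summary(draws, support=(0, 10))
        assert mode == pytest.approx(5.0, abs=0.2)
        assert ci[0] == pytest.approx(norm.ppf(0.025, 5, 1), abs=0.1)
        assert ci[1] == pytest.approx(norm.ppf(0.975, 5, 1), abs=0.1)

    def test_uniform_central_interval(self):
        rng = np.random.default_rng(13)
        draws = rng.uniform(0, 1, 20_000)
        _, ci = posterior_summary(draws, support=(0, 1))
        assert ci[0] == pytest.approx(0.025, abs=0.01)
        assert ci[1] == pytest.approx(0.975, abs=0.01)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            posterior_summary(np.arange(10))


class TestModelChoice:
    def test_duplicate_tables_give_bf_near_one(self):
        rng = np.random.default_rng(14)
        table = _toy_table(rng, n=200)
        bf, lb = model_choice(np.zeros(2), table, table.copy(), k=50, stat_names=("s1", "s2"))
        assert not lb
        assert 0.5 < bf < 2.0

    def test_observed_only_near_m2(self):
        rng = np.random.default_rng(15)
        m1 = _toy_table(rng, n=100)
        m2 = m1.copy()
        m2[["s1", "s2"]] += 100.0
        bf, lb = model_choice(np.array([100.0, 100.0]), m1, m2, k=10, stat_names=("s1", "s2"))
        assert lb and bf == 10.0

    def test_invalid_k(self):
        rng = np.random.default_rng(16)
        t = _toy_table(rng)
        with pytest.raises(ValueError):
            model_choice(np.zeros(2), t, t, k=0, stat_names=("s1", "s2"))


class TestRunSimulations:
    def test_row_count_and_determinism(self):
        spec = PriorSpec({"C": (0.0, 2.0), "lambda_tract": (50.0, 200.0)})
        params = sample_priors(spec, 10, seed=17)
        fixed = {"n_A": 5, "n_B": 4, "L": 200, "theta": 0.01, "t_dup": 1.0}
        t1 = run_simulations(params, fixed, seed=18)
        t2 = run_simulations(params, fixed, seed=18)
        assert len(t1) == 10
        pd.testing.assert_frame_equal(t1, t2)

    def test_mean_s_increases_with_theta(self):
        spec = PriorSpec({"t_dup": (0.5, 1.0)})
        params = sample_priors(spec, 40, seed=19)
        stats = ("S_A", "pi_A")
        fixed = {"n_A": 8, "n_B": 0, "L": 500}
        lo = run_simulations(params, dict(fixed, theta=0.005), stat_names=stats, seed=20)
        hi = run_simulations(params, dict(fixed, theta=0.02), stat_names=stats, seed=20)
        assert hi["S_A"].mean() > lo["S_A"].mean()


class TestDemographyFit:
    PRIORS = PriorSpec({"theta": (0.001, 0.03), "f": (1.0, 20.0), "t_exp": (0.0, 1.0)})

    def test_simulated_panel_parameters_within_ci(self):
        # observed = statistics of one simulated panel; its own generating
        # parameters must fall inside the 95% credibility intervals
        from paraconv.synthetic_data import reference_panel

        truth = dict(theta=0.012, growth_factor=6.0, t_exp=0.4)
        obs = reference_panel(n=10, L=800, n_loci=8, seed=21, **truth)
        post = fit_demography(obs, self.PRIORS, n_sims=1500, k=75, n=10, L=800, seed=22)
        lo, hi = post.ci95["theta"]
        assert lo <= truth["theta"] <= hi

    def test_fixed_growth_leaves_expansion_time_flat(self):
        # with f pinned to 1 the expansion time is unidentifiable, so its
        # posterior should look like the prior (wide central interval)
        from paraconv.synthetic_data import reference_panel

        priors = PriorSpec({"theta": (0.001, 0.03), "f": (1.0, 1.0001), "t_exp": (0.0, 1.0)})
        obs = reference_panel(theta=0.01, growth_factor=1.0, t_exp=0.0,
                              n=8, L=500, n_loci=6, seed=23)
        post = fit_demography(obs, priors, n_sims=800, k=100, n=8, L=500, seed=24)
        lo, hi = post.ci95["t_exp"]
        assert hi - lo > 0.6  # close to the prior's 0.95 width

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValueError):
            fit_demography([(5, 0.01, 0.1)], self.PRIORS, 100, 10, n=8, L=500)
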