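import math

import numpy as np
import pytest
from scipy import stats

from smallcrt.errors import ConfigurationError, NumericalError
from smallcrt.simulator import (
    DISTRIBUTIONS,
    Scenario,
    draw_cluster_effects,
    draw_cluster_sizes,
    enumerate_grid,
    generate_trial,
    generate_trial_arrays,
    grid_to_frame,
    icc_to_sigma2,
    sigma2_to_icc,
    solve_effect_size,
)


class TestIccConversion:
    @pytest.mark.parametrize(
        "icc,expected",
        [(0.0, 0.0), (0.5, math.pi**2 / 3), (0.1, 0.36554)],
    )
    def test_values(self, icc, expected):
        assert icc_to_sigma2(icc) == pytest.approx(expected, abs=5e-6)

    @pytest.mark.parametrize("icc", [0.001, 0.01, 0.05, 0.1, 0.9])
    def test_round_trip(self, icc):
        assert sigma2_to_icc(icc_to_sigma2(icc)) == pytest.approx(icc, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ConfigurationError):
            icc_to_sigma2(1.0)


class TestClusterSizes:
    def test_common_size(self, rng):
        sizes = draw_cluster_sizes(8, 10, 0.0, rng)
        assert np.all(sizes == 10)

    def test_minimum_is_two(self, rng):
        sizes = draw_cluster_sizes(5000, 10, 0.8, rng)
        assert sizes.min() >= 2

    def test_negative_binomial_moments(self):
        """Sample mean within 1% of the target mean and sample CV within
        2% of the target CV at 1e5 clusters (the parameterisation gives
        E[m] = mbar and Var[m] = (cv*mbar)^2 exactly)."""
        rng = np.random.default_rng(4242)
        sizes = draw_cluster_sizes(100_000, 50, 0.8, rng)
        assert sizes.mean() == pytest.approx(50, rel=0.01)
        cv = sizes.std(ddof=1) / sizes.mean()
        assert cv == pytest.approx(0.8, rel=0.02)

    def test_infeasible_parameterisation(self, rng):
        # variance (cv*mean)^2 = 4 <= mean - 2 = 8
        with pytest.raises(ConfigurationError, match="mean - 2"):
            draw_cluster_sizes(8, 10, 0.2, rng)


class TestClusterEffects:
    @pytest.mark.parametrize("dist", DISTRIBUTIONS)
    def test_zero_variance(self, dist, rng):
        u = draw_cluster_effects(100, dist, 0.0, rng)
        assert np.all(u == 0)

    @pytest.mark.parametrize("dist", DISTRIBUTIONS)
    def test_moments(self, dist):
        """Mean 0 and variance sigma_b2 within 3 Monte-Carlo SEs at 1e6."""
        rng = np.random.default_rng(77)
        sigma_b2 = 0.36554
        u = draw_cluster_effects(1_000_000, dist, sigma_b2, rng)
        n = u.size
        mean_se = math.sqrt(sigma_b2 / n)
        assert abs(u.mean()) < 3 * mean_se
        kurt = stats.kurtosis(u, fisher=False)
        var_se = u.var() * math.sqrt((kurt - 1) / n)
        assert abs(u.var(ddof=1) - sigma_b2) < 3 * var_se

    def test_gamma_skewness(self):
        """The shifted/scaled Gamma(2,1) keeps skewness 2/sqrt(2)."""
        rng = np.random.default_rng(5)
        u = draw_cluster_effects(1_000_000, "gamma", 1.0, rng)
        assert stats.skew(u) == pytest.approx(math.sqrt(2.0), abs=0.02)

    def test_uniform_bounds(self, rng):
        sigma_b2 = 0.5
        u = draw_cluster_effects(100_000, "uniform", sigma_b2, rng)
        half = math.sqrt(3 * sigma_b2)
        assert u.min() >= -half and u.max() <= half

    def test_unknown_distribution(self, rng):
        with pytest.raises(ConfigurationError):
            draw_cluster_effects(10, "cauchy", 1.0, rng)


class TestEffectSize:
    def test_monotone_in_clusters(self):
        ors = [
            solve_effect_size(
                Scenario(nc, 50, 0.0, 0.3, 0.05, "null")
            )
            for nc in (8, 12, 20, 30)
        ]
        assert all(a >= b for a, b in zip(ors, ors[1:]))

    def test_grid_range(self):
        """Solved odds ratios approximately reproduce the published span
        (roughly 1.1 to 11.5); the exact bounds depend on unpublished
        internals of the original power calculation."""
        ors = [
            solve_effect_size(Scenario(nc, ms, cv, p, icc, "null"))
            for nc in (8, 30)
            for ms in (10, 1000)
            for cv in (0.0, 0.8)
            for p in (0.10, 0.30)
            for icc in (0.001, 0.1)
        ]
        assert 1.05 <= min(ors) <= 1.25
        assert 8.0 <= max(ors) <= 12.5

    def test_infeasible(self):
        # 4 clusters of 2 with huge ICC cannot reach 80% power with OR <= 100
        with pytest.raises(NumericalError):
            solve_effect_size(Scenario(4, 2, 0.0, 0.3, 0.1, "null"), or_max=1.5)

    def test_powered_scenario_reaches_nominal_power(self):
        """Monte-Carlo self-consistency: the solved effect size gives the
        best estimator roughly the targeted 80% power."""
        from smallcrt.evaluation import run_grid

        base = Scenario(30, 50, 0.0, 0.3, 0.01, "null", seed=3)
        scen = base.with_effect(solve_effect_size(base))
        df = run_grid([scen], ["CL-UNW"], reps=2000, master_seed=12)
        assert 70.0 <= float(df.rejection_pct.iloc[0]) <= 90.0


class TestGenerateTrial:
    def test_deterministic(self):
        scen = Scenario(12, 50, 0.5, 0.3, 0.05, 2.0, "normal", seed=9)
        d1 = generate_trial(scen, np.random.default_rng(42))
        d2 = generate_trial(scen, np.random.default_rng(42))
        assert d1 == d2

    def test_arm_layout(self, rng):
        scen = Scenario(8, 10, 0.0, 0.3, 0.01, "null")
        data = generate_trial(scen, rng)
        assert data.clusters_per_arm() == (4, 4)

    def test_law_of_large_numbers(self):
        """With no clustering and no effect, the pooled event proportion
        approaches the control prevalence in both arms (1e6 observations)."""
        scen = Scenario(1000, 1000, 0.0, 0.3, 0.0, "null")
        rng = np.random.default_rng(10)
        arm, sizes, events = generate_trial_arrays(scen, 1, rng)
        for a in (0, 1):
            p = events[0][arm == a].sum() / sizes[0][arm == a].sum()
            assert p == pytest.approx(0.3, abs=0.002)

    def test_cluster_log_odds_variance(self):
        """Taylor-expansion oracle: with large common clusters the variance
        of the cluster log odds is sigma_b2 + E[1/(p(1-p)m)]."""
        scen = Scenario(30, 1000, 0.0, 0.3, 0.1, "null", "normal")
        rng = np.random.default_rng(2024)
        _, sizes, events = generate_trial_arrays(scen, 2000, rng)
        s = np.log((events + 0.5) / (sizes - events + 0.5))
        expected = icc_to_sigma2(0.1) + 1.0 / (0.3 * 0.7 * 1000)
        assert s.var(ddof=1) == pytest.approx(expected, rel=0.05)

    def test_dataset_invariants_fuzz(self, rng):
        for _ in range(50):
            scen = Scenario(
                n_clusters=int(rng.choice([8, 12, 20, 30])),
                mean_size=float(rng.choice([10, 50])),
                cv_size=float(rng.choice([0.0, 0.5, 0.8])),
                control_prevalence=float(rng.uniform(0.05, 0.5)),
                icc=float(rng.uniform(0, 0.2)),
                effect="null" if rng.random() < 0.5 else float(rng.uniform(1, 5)),
                effect_distribution=str(rng.choice(list(DISTRIBUTIONS))),
            )
            data = generate_trial(scen, rng)
            assert data.n == scen.n_clusters
            assert np.all(data.events >= 0) and np.all(data.events <= data.size)
            assert np.all(data.size >= 2)


class TestGrid:
    def test_factorial_counts(self):
        grid = enumerate_grid(master_seed=0, solve_powered=False)
        assert len(grid) == 1728
        assert sum(s.is_null for s in grid) == 864

    def test_filter_counts(self):
        small_low = enumerate_grid(
            master_seed=0, mean_size=[10.0], control_prevalence=[0.10],
            effects=("powered",), solve_powered=False,
        )
        assert len(small_low) == 144
        cv_half_null = enumerate_grid(
            master_seed=0, cv_size=[0.5], effects=("null",)
        )
        assert len(cv_half_null) == 288

    def test_seeds_reproducible_and_stable_under_filtering(self):
        full = enumerate_grid(master_seed=7, effects=("null",))
        sub = enumerate_grid(master_seed=7, n_clusters=[12], effects=("null",))
        by_key = {
            (s.n_clusters, s.mean_size, s.cv_size, s.control_prevalence,
             s.icc, s.effect_distribution): s.seed
            for s in full
        }
        for s in sub:
            key = (s.n_clusters, s.mean_size, s.cv_size, s.control_prevalence,
                   s.icc, s.effect_distribution)
            assert s.seed == by_key[key]

    def test_frame_round_trip(self):
        grid = enumerate_grid(master_seed=0, n_clusters=[8], mean_size=[10.0],
                              effects=("null",))
        frame = grid_to_frame(grid)
        assert len(frame) == len(grid)
        assert set(frame.columns) >= {"n_clusters", "icc", "sigma_b2", "seed"}


def test_scenario_validation():
    with pytest.raises(ConfigurationError):
        Scenario(9, 10, 0.0, 0.3, 0.05, "null")  # odd cluster count
    with pytest.raises(ConfigurationError):
        Scenario(8, 10, 0.0, 0.3, 0.05, -2.0)  # negative odds ratio
    with pytest.raises(ConfigurationError):
        Scenario(8, 10, 0.0, 0.3, 0.05, "null", "weibull")
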