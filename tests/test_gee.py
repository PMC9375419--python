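import math

import numpy as np
import pytest
from scipy.linalg import fractional_matrix_power

from smallcrt.errors import ConfigurationError
from smallcrt.evaluation import marginal_truth
from smallcrt.gee import SandwichSpec, fit_gee, gee_analysis, gee_test, sandwich
from smallcrt.simulator import Scenario, generate_trial, generate_trial_arrays
from smallcrt.trial_data import TrialDataset

from conftest import make_trial


def brute_force_sandwich(fit, correction, fg_bound=0.75):
    """Assemble the sandwich from explicit individual-level m x m matrices
    (the formulas as printed, with no collapsing)."""
    mu = fit.mu
    alpha = fit.alpha_hat
    bread = fit.v_model
    meat = np.zeros((2, 2))
    for c in range(fit.n_clusters):
        m = int(fit.size[c])
        w = mu[c] * (1 - mu[c])
        x = np.array([1.0, float(fit.arm[c])])
        D = np.tile(w * x, (m, 1))  # d mu_i / d beta', m x 2
        Vw = w * ((1 - alpha) * np.eye(m) + alpha * np.ones((m, m)))
        Vw_inv = np.linalg.inv(Vw)
        y = np.zeros(m)
        y[: int(fit.events[c])] = 1.0
        r = y - mu[c]
        if correction == "none":
            g = D.T @ Vw_inv @ r
            meat += np.outer(g, g)
        elif correction == "KC":
            A = fractional_matrix_power(
                np.eye(m) - D @ fit.v_model @ D.T @ Vw_inv, -0.5
            ).real
            g = D.T @ Vw_inv @ A @ r
            meat += np.outer(g, g)
        elif correction == "FG":
            Q = D.T @ Vw_inv @ D @ fit.v_model
            a = np.diag(1.0 / np.sqrt(1.0 - np.minimum(fg_bound, np.diag(Q))))
            g = a @ D.T @ Vw_inv @ r
            meat += np.outer(g, g)
    return bread @ meat @ bread


class TestFit:
    def test_independence_is_pooled_logistic(self):
        """With an arm-only covariate, the independence GEE solution is the
        pooled-counts log odds ratio (closed-form oracle)."""
        for seed in (1, 7, 13):
            data = make_trial(seed)
            fit = fit_gee(data, "independence")
            y, m, a = data.events, data.size, data.arm
            e0, M0 = y[a == 0].sum(), m[a == 0].sum()
            e1, M1 = y[a == 1].sum(), m[a == 1].sum()
            expected = math.log(e1 * (M0 - e0) / (e0 * (M1 - e1)))
            assert fit.converged
            assert fit.beta1 == pytest.approx(expected, abs=1e-10)

    def test_singleton_clusters_make_working_correlations_equal(self):
        data = TrialDataset.from_arrays(
            [0] * 6 + [1] * 6,
            [0, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 1],
            [1] * 12,
        )
        fi = fit_gee(data, "independence")
        fe = fit_gee(data, "exchangeable")
        assert fi.beta1 == pytest.approx(fe.beta1, abs=1e-10)

    def test_separation_flagged(self):
        data = TrialDataset.from_arrays([0, 0, 1, 1], [0, 0, 3, 4], [10] * 4)
        assert not fit_gee(data, "independence").converged

    def test_unknown_working(self):
        with pytest.raises(ConfigurationError):
            fit_gee(make_trial(1), "ar1")

    def test_statsmodels_cross_check(self):
        """Independent oracle: statsmodels GEE on the expanded
        individual-level data agrees on beta and the uncorrected sandwich."""
        import statsmodels.api as sm

        data = make_trial(3, n_clusters=8, mean_size=12, cv_size=0.5)
        rows_y, rows_x, rows_g = [], [], []
        for i, rec in enumerate(data.records):
            rows_y += [1] * rec.events + [0] * (rec.size - rec.events)
            rows_x += [[1.0, float(rec.arm)]] * rec.size
            rows_g += [i] * rec.size
        model = sm.GEE(
            np.array(rows_y), np.array(rows_x), groups=np.array(rows_g),
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Independence(),
        )
        res = model.fit()
        fit = fit_gee(data, "independence")
        assert fit.beta1 == pytest.approx(res.params[1], abs=1e-6)
        ours = sandwich(fit, SandwichSpec("none"))
        sm_cov = np.asarray(res.cov_params())
        assert ours[1, 1] == pytest.approx(sm_cov[1, 1], rel=1e-4)


class TestSandwich:
    def test_three_cluster_printed_toy(self):
        """Uncorrected sandwich on a minimal toy (sizes 4; control events
        1,2; intervention 3) matches the direct matrix assembly.  Note the
        single intervention cluster has leverage one, so the KC correction
        is undefined here by construction."""
        data = TrialDataset.from_arrays([0, 0, 1], [1, 2, 3], [4, 4, 4])
        fit = fit_gee(data, "independence")
        ours = sandwich(fit, SandwichSpec("none"))
        assert np.allclose(ours, brute_force_sandwich(fit, "none"), atol=1e-10)
        from smallcrt.errors import NumericalError

        with pytest.raises(NumericalError):
            sandwich(fit, SandwichSpec("KC"))

    @pytest.mark.parametrize("correction", ["none", "KC", "FG"])
    @pytest.mark.parametrize("working", ["independence", "exchangeable"])
    def test_matches_brute_force_matrix_oracle(self, correction, working):
        """The collapsed O(1)-per-cluster computation equals the printed
        matrix formulas assembled term by term at individual level."""
        data = TrialDataset.from_arrays(
            [0, 0, 1, 1], [1, 2, 3, 2], [4, 4, 4, 5]
        )
        fit = fit_gee(data, working)
        ours = sandwich(fit, SandwichSpec(correction))
        brute = brute_force_sandwich(fit, correction)
        assert np.allclose(ours, brute, atol=1e-10)

    @pytest.mark.parametrize("correction", ["none", "KC", "FG"])
    def test_cluster_collapse_equivalence_larger(self, correction):
        """Collapse equivalence holds with cluster sizes up to 50, which is
        what licenses running very large clusters at desk scale."""
        data = make_trial(17, n_clusters=8, mean_size=30, cv_size=0.5)
        fit = fit_gee(data, "exchangeable")
        ours = sandwich(fit, SandwichSpec(correction))
        brute = brute_force_sandwich(fit, correction)
        assert np.allclose(ours, brute, atol=1e-10)

    def test_corrections_inflate_on_balanced_toy(self):
        data = TrialDataset.from_arrays(
            [0, 0, 1, 1], [1, 2, 2, 3], [6, 6, 6, 6]
        )
        fit = fit_gee(data, "independence")
        v_s = sandwich(fit, SandwichSpec("none"))[1, 1]
        v_kc = sandwich(fit, SandwichSpec("KC"))[1, 1]
        v_fg = sandwich(fit, SandwichSpec("FG"))[1, 1]
        assert v_kc >= v_s
        assert v_fg >= v_s

    def test_asymptotic_agreement(self):
        """As cluster leverages vanish (400 clusters) the corrected and
        uncorrected sandwich agree within 2% on the arm variance."""
        scen = Scenario(400, 30, 0.5, 0.3, 0.05, "null", "normal")
        data = generate_trial(scen, np.random.default_rng(42))
        fit = fit_gee(data, "independence")
        v_s = sandwich(fit, SandwichSpec("none"))[1, 1]
        assert sandwich(fit, SandwichSpec("KC"))[1, 1] / v_s == pytest.approx(1, abs=0.02)
        assert sandwich(fit, SandwichSpec("FG"))[1, 1] / v_s == pytest.approx(1, abs=0.02)


class TestInference:
    def test_equal_arms_give_p_one(self):
        data = TrialDataset.from_arrays([0, 0, 1, 1], [1, 3, 3, 1], [10] * 4)
        res = gee_analysis(data, "independence", "FG")
        assert res.estimate == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_p_monotone_in_variance(self):
        data = make_trial(23, n_clusters=8)
        fit = fit_gee(data, "independence")
        v_kc = sandwich(fit, SandwichSpec("KC"))
        v_fg = sandwich(fit, SandwichSpec("FG"))
        p_kc = gee_test(fit, v_kc, correction="KC").p
        p_fg = gee_test(fit, v_fg, correction="FG").p
        if v_fg[1, 1] >= v_kc[1, 1]:
            assert p_fg >= p_kc
        else:
            assert p_fg <= p_kc

    def test_method_vocabulary(self):
        data = make_trial(24)
        fit = fit_gee(data, "exchangeable")
        res = gee_test(fit, sandwich(fit, SandwichSpec("FG")), correction="FG")
        assert res.method == "FG.E.DF_CP"
        assert res.df == data.n - 2

    def test_marginal_estimand(self):
        """500 simulated trials with a conditional OR of 2: the mean GEE
        estimate matches the converted marginal log OR, not the
        conditional one."""
        scen = Scenario(30, 50, 0.0, 0.3, 0.1, 2.0, "normal")
        rng = np.random.default_rng(7)
        arm, sizes, events = generate_trial_arrays(scen, 500, rng)
        from smallcrt._batch import _gee_independence

        out = _gee_independence(arm, sizes, events, corrections=("none",))["none"]
        est = out["estimate"][out["converged"]]
        target = marginal_truth(math.log(2), scen.sigma_b2)
        mc_se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - target) < 3 * mc_se
        # and it is distinguishable from the conditional truth
        assert abs(est.mean() - math.log(2)) > 3 * mc_se

    def test_fg_null_rejection_not_inflated(self):
        """FG.I with t(n-2) does not exceed the nominal band's upper edge
        at a representative null scenario."""
        from smallcrt.evaluation import run_grid

        scen = Scenario(20, 50, 0.0, 0.3, 0.05, "null", "normal", seed=4)
        df = run_grid([scen], ["FG.I.DF_CP"], reps=5000, master_seed=31)
        assert float(df.rejection_pct.iloc[0]) <= 6.4
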