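"""MML estimation: oracle equivalence, invariances, recovery, bookkeeping."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from dsrt.estimate import (
    QuadratureSpec,
    fit_hm,
    fit_irtree,
    fit_mml,
    marginal_loglik,
)
from dsrt.models import (
    ScoreMatrix,
    intercepts_to_masters,
    prob_gpcm1d,
    prob_nominal,
)
from dsrt.simulate import (
    draw_latents,
    benchmark_item_params,
    simulate_hm,
    simulate_irtree,
    simulate_scores,
)

Q21 = QuadratureSpec(21)
Q11 = QuadratureSpec(11)
FAST_OPTS = {"tol": 1e-5, "maxiter": 200}


@pytest.fixture(scope="module")
def tiny_scores():
    rng = np.random.default_rng(42)
    return ScoreMatrix(rng.integers(0, 4, size=(8, 3)))


@pytest.fixture(scope="module")
def params_1d():
    return {
        "slope": np.array([0.5, 1.0, 0.8]),
        "intercepts": np.array([[1.5, 1.5, 0.0], [0.0, -1.5, -1.5], [0.2, -0.3, 0.5]]),
    }


class TestMarginalLoglik:
    def test_matches_dense_grid_1d(self, tiny_scores, params_1d):
        """41-node quadrature vs brute-force integration on a dense grid."""
        ll = marginal_loglik(params_1d, tiny_scores, QuadratureSpec(41), "srt1d")
        grid = np.linspace(-10, 10, 40001)
        dens = norm.pdf(grid) * (grid[1] - grid[0])
        like = np.ones((tiny_scores.n_persons, grid.size))
        for i in range(3):
            p = prob_gpcm1d(grid, params_1d["slope"][i], params_1d["intercepts"][i])
            like *= p[:, tiny_scores.scores[:, i]].T
        ll_dense = np.log(like @ dens).sum()
        assert ll == pytest.approx(ll_dense, rel=1e-8)

    def test_matches_dense_grid_2d(self, tiny_scores):
        """2-D quadrature with correlated latents vs a dense rectangular grid."""
        params = {
            "slope_ability": np.array([0.5, 0.9, 0.7]),
            "slope_speed": np.array([1.0, 0.6, 1.2]),
            "intercepts": np.array([[1.5, 1.5, 0.0], [0.0, -1.5, -1.5], [0.1, 0.2, -0.4]]),
        }
        rho = 0.4
        ll = marginal_loglik(params, tiny_scores, QuadratureSpec(31), "srt2d", rho=rho)
        g = np.linspace(-7, 7, 281)
        t1, t2 = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([t1.ravel(), t2.ravel()])
        w = multivariate_normal.pdf(pts, cov=[[1, rho], [rho, 1]]) * (g[1] - g[0]) ** 2
        like = np.ones((tiny_scores.n_persons, pts.shape[0]))
        scoring = np.vstack([np.arange(4.0), [1.0, 0.0, 0.0, 1.0]])
        for i in range(3):
            p = np.array(
                [
                    prob_nominal(
                        pt,
                        [params["slope_ability"][i], params["slope_speed"][i]],
                        params["intercepts"][i],
                        scoring,
                    )
                    for pt in pts
                ]
            )
            like *= p[:, tiny_scores.scores[:, i]].T
        ll_dense = np.log(like @ w).sum()
        assert ll == pytest.approx(ll_dense, rel=1e-6)

    def test_rho_zero_equals_product_rule(self, tiny_scores):
        params = {
            "slope_ability": np.array([0.5, 0.9, 0.7]),
            "slope_speed": np.array([1.0, 0.6, 1.2]),
            "intercepts": np.zeros((3, 3)),
        }
        from dsrt.quadrature import grid_2d, weights_2d

        nodes, base = grid_2d(Q21)
        np.testing.assert_allclose(weights_2d(nodes, base, 0.0), base, atol=1e-15)
        ll0 = marginal_loglik(params, tiny_scores, Q21, "srt2d", rho=0.0)
        ll0b = marginal_loglik(params, tiny_scores, QuadratureSpec(31), "srt2d", rho=0.0)
        assert ll0 == pytest.approx(ll0b, rel=1e-5)

    def test_missing_item_leaves_loglik_unchanged(self, params_1d, tiny_scores):
        ll = marginal_loglik(params_1d, tiny_scores, Q21, "srt1d")
        padded = np.column_stack([tiny_scores.scores, np.full(8, -1)])
        params4 = {
            "slope": np.append(params_1d["slope"], 1.0),
            "intercepts": np.vstack([params_1d["intercepts"], np.zeros(3)]),
        }
        with pytest.raises(ValueError, match="item"):
            marginal_loglik(params4, ScoreMatrix(padded), Q21, "srt1d")
        padded[0, 3] = 2  # one observation: item no longer empty
        ll4 = marginal_loglik(params4, ScoreMatrix(padded), Q21, "srt1d")
        # persons 1..7 contribute identically with or without the extra item
        ll0_with = marginal_loglik(params4, ScoreMatrix(padded[:1]), Q21, "srt1d")
        ll0_without = marginal_loglik(
            params_1d, ScoreMatrix(tiny_scores.scores[:1]), Q21, "srt1d"
        )
        assert ll4 - ll0_with == pytest.approx(ll - ll0_without, abs=1e-9)

    def test_all_missing_person_named(self, params_1d):
        scores = np.array([[0, 1, 2], [-1, -1, -1]])
        with pytest.raises(ValueError, match=r"person\(s\) \[1\]"):
            marginal_loglik(params_1d, ScoreMatrix(scores), Q21, "srt1d")

    def test_increases_with_node_count_toward_limit(self, tiny_scores, params_1d):
        lls = [
            marginal_loglik(params_1d, tiny_scores, QuadratureSpec(n), "srt1d")
            for n in (11, 21, 41, 81)
        ]
        diffs = np.abs(np.diff(lls))
        assert diffs[-1] < 1e-6  # stable limit
        assert diffs[0] > diffs[-1]


class TestParameterizationInvariance:
    def test_masters_reparameterization_same_loglik(self, tiny_scores):
        """The adjacent-category and step parameterizations describe the same
        model: identical marginal likelihood after conversion."""
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 1, (3, 3))
        ll_pcm = marginal_loglik({"intercepts": beta}, tiny_scores, Q21, "pcm")
        steps = intercepts_to_masters(beta)
        ll_steps = marginal_loglik(
            {"intercepts": np.array([-np.cumsum(s) for s in steps])},
            tiny_scores,
            Q21,
            "pcm",
        )
        assert ll_pcm == pytest.approx(ll_steps, rel=1e-12)


class TestFitting:
    def test_loglik_improves_and_converges(self, rng):
        theta = draw_latents(400, 0.0, rng)
        sm = simulate_scores(theta, benchmark_item_params(10, 0.5, 0.0), rng)
        start = {
            "slope": np.ones(10),
            "intercepts": np.zeros((10, 3)),
        }
        ll_start = marginal_loglik(start, sm, Q21, "srt1d")
        fit = fit_mml(sm, "srt1d", Q21, start=start)
        assert fit.converged
        assert fit.loglik >= ll_start
        assert np.all(fit.item_estimates["slope"] > 0)

    def test_deterministic_given_data_and_start(self, rng):
        theta = draw_latents(300, 0.0, 5)
        sm = simulate_scores(theta, benchmark_item_params(5), 5)
        f1 = fit_mml(sm, "srt1d", Q21)
        f2 = fit_mml(sm, "srt1d", Q21)
        np.testing.assert_array_equal(f1.item_estimates["slope"], f2.item_estimates["slope"])
        assert f1.loglik == f2.loglik

    def test_1d_parameter_recovery_improves_with_n(self):
        errs = []
        for n in (500, 5000):
            theta = draw_latents(n, 0.0, 13)
            sm = simulate_scores(theta, benchmark_item_params(20, 0.5, 0.0), 14)
            fit = fit_mml(sm, "srt1d", Q21, options=FAST_OPTS)
            errs.append(np.abs(fit.item_estimates["slope"] - 0.5).mean())
        assert errs[1] < errs[0]
        assert errs[1] < 0.1

    def test_2d_recovery_rho_and_slopes(self):
        """rho within .05 and slopes within .1 (mean absolute error) at N=5000."""
        theta = draw_latents(5000, 0.5, 11)
        sm = simulate_scores(theta, benchmark_item_params(20, 0.5, 1.0), 12)
        fit = fit_mml(sm, "srt2d", QuadratureSpec(15), options=FAST_OPTS)
        assert fit.rho_estimate == pytest.approx(0.5, abs=0.05)
        assert np.abs(fit.item_estimates["slope_ability"] - 0.5).mean() < 0.1
        assert np.abs(fit.item_estimates["slope_speed"] - 1.0).mean() < 0.1

    def test_hm_recovery(self):
        k = 10
        theta = draw_latents(5000, 0.5, 21)
        acc, fast = simulate_hm(
            theta,
            acc_slope=np.full(k, 1.2),
            acc_intercept=np.linspace(-1, 1, k),
            speed_slope=np.full(k, 1.0),
            speed_intercept=np.linspace(-0.5, 0.5, k),
            seed=22,
        )
        fit = fit_hm(acc, fast, QuadratureSpec(15), options=FAST_OPTS)
        assert fit.rho_estimate == pytest.approx(0.5, abs=0.05)
        assert fit.item_estimates["acc_slope"].mean() == pytest.approx(1.2, abs=0.1)
        np.testing.assert_allclose(
            fit.item_estimates["speed_intercept"], np.linspace(-0.5, 0.5, k), atol=0.15
        )

    def test_irtree_recovers_branch_specific_difficulties(self):
        k = 10
        theta = draw_latents(5000, 0.0, 31)
        fast_int = np.linspace(-1.5, 0.5, k)
        slow_int = np.linspace(0.5, -1.5, k)
        acc, fast = simulate_irtree(
            theta,
            speed_slope=np.ones(k),
            speed_intercept=np.zeros(k),
            fast_slope=np.ones(k),
            fast_intercept=fast_int,
            slow_slope=np.ones(k),
            slow_intercept=slow_int,
            seed=32,
        )
        fit = fit_irtree(acc, fast, QuadratureSpec(15), options=FAST_OPTS)
        np.testing.assert_allclose(fit.item_estimates["fast_intercept"], fast_int, atol=0.25)
        np.testing.assert_allclose(fit.item_estimates["slow_intercept"], slow_int, atol=0.25)

    def test_irtree_nests_hm(self, rng):
        theta = draw_latents(500, 0.3, rng)
        acc, fast = simulate_hm(
            theta,
            acc_slope=np.ones(5),
            acc_intercept=np.zeros(5),
            speed_slope=np.ones(5),
            speed_intercept=np.zeros(5),
            seed=rng,
        )
        f_hm = fit_hm(acc, fast, Q11, options=FAST_OPTS)
        f_tree = fit_irtree(acc, fast, Q11, options=FAST_OPTS)
        assert f_tree.loglik >= f_hm.loglik - 1e-6
        assert f_tree.n_params > f_hm.n_params

    @pytest.mark.parametrize(
        "model,k,expected",
        [
            ("coomans", 10, 10),
            ("pcm", 10, 30),
            ("srt1d", 10, 40),
            ("nrm", 10, 60),
            ("srt2d", 10, 51),
            ("hm", 10, 41),
            ("irtree", 10, 61),
        ],
    )
    def test_free_parameter_counts(self, model, k, expected, rng):
        theta = draw_latents(600, 0.2, rng)
        sm = simulate_scores(theta, benchmark_item_params(k, 0.5, 1.0), rng)
        if model in ("hm", "irtree"):
            acc, fast = sm.accuracy_and_fast()
            fit = (fit_hm if model == "hm" else fit_irtree)(acc, fast, Q11, options=FAST_OPTS)
        else:
            quad = Q11 if model == "srt2d" else Q21
            fit = fit_mml(sm, model, quad, options=FAST_OPTS)
        assert fit.n_params == expected
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * expected)
        assert fit.bic == pytest.approx(-2 * fit.loglik + np.log(600) * expected)

    def test_empty_category_named(self):
        scores = np.array([[0, 1], [1, 2], [2, 1], [0, 2], [3, 1]])
        with pytest.raises(ValueError, match="item 1"):
            fit_mml(ScoreMatrix(scores), "srt1d", Q21)

    def test_nonconvergence_flagged_not_raised(self, rng):
        theta = draw_latents(300, 0.0, rng)
        sm = simulate_scores(theta, benchmark_item_params(5), rng)
        fit = fit_mml(sm, "srt1d", Q21, options={"maxiter": 2})
        assert not fit.converged
        assert fit.n_iterations == 2

    def test_aic_bic_prefer_generating_model(self):
        """On 2-D generated data the 2-D SRT model beats the 1-D on AIC/BIC."""
        theta = draw_latents(1000, 0.0, 17)
        sm = simulate_scores(theta, benchmark_item_params(20, 0.5, 1.0), 18)
        f1 = fit_mml(sm, "srt1d", Q21, options=FAST_OPTS)
        f2 = fit_mml(sm, "srt2d", QuadratureSpec(15), options=FAST_OPTS)
        assert f2.aic < f1.aic
        assert f2.bic < f1.bic
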