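"""Scoring rules, category probabilities, and the continuous SRT density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad as sp_quad

from dsrt.models import (
    ContinuousSRTParams,
    ItemParams1D,
    ItemParams2D,
    assign_scores,
    discretize_rt,
    intercepts_to_masters,
    masters_to_intercepts,
    p_fast_given_accuracy,
    prob_2d,
    prob_coomans,
    prob_gpcm1d,
    prob_nominal,
    prob_pcm,
    srt_density,
    srt_marginal_p_correct,
    srt_score,
)

finite = st.floats(-5, 5, allow_nan=False)


class TestScoringRules:
    @pytest.mark.parametrize(
        "x,t,d,expected",
        [(1, 5, 20, 15), (0, 5, 20, -15), (1, 20, 20, 0), (0, 0, 20, -20)],
    )
    def test_signed_residual_time(self, x, t, d, expected):
        assert srt_score(x, t, d) == expected

    def test_rt_outside_deadline_rejected(self):
        with pytest.raises(ValueError):
            srt_score(1, 21, 20)
        with pytest.raises(ValueError):
            discretize_rt(-0.1, 20)

    @pytest.mark.parametrize(
        "t,d,n_bins,expected",
        [
            (9.99, 20, 2, 1),  # just below half deadline -> fast
            (10.0, 20, 2, 0),  # exactly half deadline -> slow
            (7.0, 20, 3, 1),  # between 20/3 and 40/3 -> middle bin
            (6.0, 20, 3, 2),  # below 20/3 -> fastest bin
            (20.0, 20, 3, 0),  # at deadline -> slowest bin
        ],
    )
    def test_discretize_boundaries(self, t, d, n_bins, expected):
        assert discretize_rt(t, d, n_bins) == expected

    @pytest.mark.parametrize(
        "x,t_star,expected", [(0, 1, 0), (0, 0, 1), (1, 0, 2), (1, 1, 3)]
    )
    def test_four_category_assignment(self, x, t_star, expected):
        assert assign_scores(x, t_star) == expected

    def test_six_category_assignment_ordered(self):
        # fast incorrect ... fast correct for the three-bin split
        got = [assign_scores(x, sp, n_bins=3) for x in (0, 1) for sp in (2, 1, 0)]
        assert got == [0, 1, 2, 5, 4, 3]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            assign_scores(2, 0)
        with pytest.raises(ValueError):
            assign_scores(1, 3, n_bins=2)
        with pytest.raises(ValueError):
            discretize_rt(5, 20, n_bins=1)


class TestCategoryProbabilities:
    def test_coomans_uniform_at_difficulty(self):
        np.testing.assert_allclose(prob_coomans(1.3, 1.3), np.full(4, 0.25), atol=1e-12)

    def test_coomans_softmax_value(self):
        # softmax([0,1,2,3]) computed independently
        expected = np.exp(np.arange(4.0)) / np.exp(np.arange(4.0)).sum()
        np.testing.assert_allclose(prob_coomans(1.0, 0.0), expected, atol=1e-12)
        assert np.all(np.diff(prob_coomans(1.0, 0.0)) > 0)

    @pytest.mark.parametrize(
        "beta,expected",
        [
            ([1.5, 1.5, 0.0], [0.1, 0.4, 0.4, 0.1]),
            ([-1.5, -1.5, 0.0], [0.4, 0.1, 0.1, 0.4]),
            ([0.0, 1.5, 1.5], [0.1, 0.1, 0.4, 0.4]),
            ([0.0, -1.5, -1.5], [0.4, 0.4, 0.1, 0.1]),
            ([0.0, 0.0, 0.0], [0.2, 0.2, 0.2, 0.2]),  # uniform, rounds to .2
        ],
    )
    def test_design_probabilities_at_population_mean(self, beta, expected):
        p = prob_gpcm1d(0.0, 0.5, beta)
        if np.allclose(expected, 0.2):
            np.testing.assert_allclose(p, 0.25, atol=1e-12)
        else:
            np.testing.assert_allclose(np.round(p, 1), expected)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            prob_gpcm1d(0.0, 0.0, [0.0, 0.0, 0.0])

    def test_two_dimensional_hand_computed(self):
        params = ItemParams2D([0.5], [1.0], [[0.0, 0.0, 0.0]])
        p = prob_2d(0.0, 1.0, params)
        e = np.e
        np.testing.assert_allclose(p, np.array([e, 1, 1, e]) / (2 * e + 2), atol=1e-12)
        assert p[0] + p[3] == pytest.approx(e / (e + 1), abs=1e-12)

    def test_scoring_vector_length_mismatch(self):
        with pytest.raises(ValueError):
            ItemParams2D([0.5], [1.0], [[0.0, 0.0, 0.0]], scoring_speed=[1, 0, 0])

    @given(
        theta=finite,
        delta=finite,
        alpha=st.floats(0.05, 3),
        beta=st.lists(finite, min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_probability_vectors_sum_to_one(self, theta, delta, alpha, beta):
        for p in (
            prob_coomans(theta, delta),
            prob_pcm(theta, np.array(beta)),
            prob_gpcm1d(theta, alpha, np.array(beta)),
        ):
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p > 0) and np.all(p < 1)

    @given(
        theta1=finite,
        theta2=finite,
        alpha=st.floats(0.05, 3),
        beta=st.lists(finite, min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_reduction_chain(self, theta1, theta2, alpha, beta):
        """Nominal form -> 2-D SRT -> 1-D SRT -> PCM -> Coomans, numerically."""
        beta = np.array(beta)
        p2 = ItemParams2D([alpha], [1.0], [beta])
        # general nominal form with the default scoring vectors equals the 2-D model
        nom = prob_nominal(
            [theta1, theta2],
            [alpha, 1.0],
            beta,
            np.vstack([np.arange(4.0), [1.0, 0.0, 0.0, 1.0]]),
        )
        np.testing.assert_allclose(nom, prob_2d(theta1, theta2, p2), atol=1e-12)
        # zero speed slope reduces the 2-D model to the 1-D model
        p2_null = ItemParams2D([alpha], [1e-300], [beta])
        np.testing.assert_allclose(
            prob_2d(theta1, theta2, p2_null), prob_gpcm1d(theta1, alpha, beta), atol=1e-10
        )
        # slope 1 reduces the 1-D model to the partial-credit form
        np.testing.assert_allclose(
            prob_gpcm1d(theta1, 1.0, beta), prob_pcm(theta1, beta), atol=1e-12
        )
        # beta_s = -s*delta reduces the partial-credit form to the one-parameter model
        delta = 0.7
        np.testing.assert_allclose(
            prob_pcm(theta1, -delta * np.arange(1.0, 4.0)),
            prob_coomans(theta1, delta),
            atol=1e-12,
        )


class TestMastersConversion:
    def test_examples(self):
        np.testing.assert_allclose(masters_to_intercepts([0, 0, 0]), [0, 0, 0])
        np.testing.assert_allclose(masters_to_intercepts([1, -1, 0]), [-1, 0, 0])

    @given(st.lists(finite, min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, beta):
        beta = np.array(beta)
        np.testing.assert_allclose(
            masters_to_intercepts(intercepts_to_masters(beta)), beta, atol=1e-10
        )


class TestConditionalFastProbability:
    def test_centered_item_gives_half(self):
        params = ItemParams1D([1.0], [[0.0, 0.0, 0.0]])
        assert p_fast_given_accuracy(0.0, None, params, x=1) == pytest.approx(0.5)
        assert p_fast_given_accuracy(0.0, None, params, x=0) == pytest.approx(0.5)

    def test_monotone_in_ability(self):
        params = ItemParams1D([1.0], [[0.0, 0.0, 0.0]])
        # P(fast | correct) increases in theta; P(fast | incorrect) decreases
        assert p_fast_given_accuracy(1.0, None, params, x=1) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-12
        )
        grid = np.linspace(-3, 3, 21)
        p_corr = [p_fast_given_accuracy(t, None, params, x=1) for t in grid]
        p_inc = [p_fast_given_accuracy(t, None, params, x=0) for t in grid]
        assert np.all(np.diff(p_corr) > 0)
        assert np.all(np.diff(p_inc) < 0)

    def test_fast_indicator_correlation_signs(self, rng):
        """Across the latent population, fast indicators of two items correlate
        positively given equal accuracy and negatively given unequal accuracy
        (enumeration over the 16 joint outcomes, theta integrated numerically)
        — so a 1-D model cannot produce a positive manifold."""
        grid = np.linspace(-6, 6, 401)
        prior = np.exp(-0.5 * grid**2)
        acc = np.array([0, 0, 1, 1])
        fast = np.array([1, 0, 0, 1])
        for _ in range(10):
            params = ItemParams1D(rng.uniform(0.3, 2.0, 2), rng.normal(0, 1.5, (2, 3)))
            p_i = prob_gpcm1d(grid, params.slope[0], params.intercepts[0])
            p_k = prob_gpcm1d(grid, params.slope[1], params.intercepts[1])
            for xi in (0, 1):
                for xk in (0, 1):
                    pi_acc = p_i[:, acc == xi]  # (grid, 2 categories)
                    pk_acc = p_k[:, acc == xk]
                    w = prior * pi_acc.sum(1) * pk_acc.sum(1)
                    w = w / w.sum()
                    fi = pi_acc @ fast[acc == xi] / pi_acc.sum(1)
                    fk = pk_acc @ fast[acc == xk] / pk_acc.sum(1)
                    # E[T*_i T*_k | X] - E[T*_i | X] E[T*_k | X]
                    cov = w @ (fi * fk) - (w @ fi) * (w @ fk)
                    assert (cov > 0) if xi == xk else (cov < 0)


class TestContinuousDensity:
    def test_uniform_at_difficulty(self):
        params = ContinuousSRTParams(difficulty=0.4, slope=1.2, deadline=20.0)
        dens = srt_density(1, np.array([0.0, 5.0, 20.0]), 0.4, params)
        np.testing.assert_allclose(dens, 1.0 / 40.0, atol=1e-12)

    @pytest.mark.parametrize(
        "theta,delta,alpha,d",
        [(1.0, 0.0, 1.0, 1.0), (0.3, -0.5, 0.7, 3.0), (-1.2, 0.4, 2.0, 0.5)],
    )
    def test_density_integrates_to_one(self, theta, delta, alpha, d):
        params = ContinuousSRTParams(difficulty=delta, slope=alpha, deadline=d)
        total = sum(
            sp_quad(lambda t, x=x: srt_density(x, t, theta, params), 0, d, limit=200)[0]
            for x in (0, 1)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_marginal_accuracy_is_two_parameter_logistic(self):
        params = ContinuousSRTParams(difficulty=0.0, slope=1.0, deadline=1.0)
        p_correct = sp_quad(lambda t: srt_density(1, t, 1.0, params), 0, 1)[0]
        assert p_correct == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-8)
        assert srt_marginal_p_correct(1.0, params) == pytest.approx(p_correct, abs=1e-8)

    def test_rt_outside_support_rejected(self):
        params = ContinuousSRTParams(difficulty=0.0, slope=1.0, deadline=2.0)
        with pytest.raises(ValueError):
            srt_density(1, 2.5, 0.0, params)
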