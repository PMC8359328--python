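"""Category probabilities, scoring rules, and densities of the SRT model family.

The signed-residual-time (SRT) scoring rule assigns to a timed item response
the residual time to the deadline, signed by accuracy::

    S = (2X - 1) * (d - T),        X in {0, 1},  0 <= T <= d.

Discretizing response time at half the deadline yields a four-category
polytomous item score (0 = fast incorrect, 1 = slow incorrect, 2 = slow
correct, 3 = fast correct), which the discretized SRT models treat with
adjacent-category (partial-credit / nominal-response) logistic forms.  The
two-dimensional variant adds a latent speed dimension loading on the fast
categories {0, 3} through a second scoring vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

MISSING = -1
"""Integer code for a missing entry in a score matrix."""

#: Ability scoring vector of the discretized SRT model (credit per category).
ABILITY_SCORES = np.array([0.0, 1.0, 2.0, 3.0])
#: Speed scoring vector: indicator of the fast categories {0, 3}.
SPEED_SCORES = np.array([1.0, 0.0, 0.0, 1.0])
#: Accuracy implied by each score category (0,1 incorrect; 2,3 correct).
ACCURACY_OF_SCORE = np.array([0, 0, 1, 1])
#: Fast indicator implied by each score category.
FAST_OF_SCORE = np.array([1, 0, 0, 1])


def _softmax(logits: NDArray, axis: int = -1) -> NDArray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ResponseData:
    """Raw accuracy and response-time matrices with a shared item deadline.

    Parameters
    ----------
    accuracy : (N, K) float array
        Binary response accuracy, NaN where missing.
    rt : (N, K) float array
        Response time in seconds, NaN exactly where accuracy is missing.
    deadline : float
        Item time limit ``d`` in seconds, shared by all items.
    """

    accuracy: NDArray
    rt: NDArray
    deadline: float

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        if self.accuracy.shape != self.rt.shape:
            raise ValueError("accuracy and rt must have the same shape")
        if not self.deadline > 0:
            raise ValueError("deadline must be positive")
        if not np.array_equal(np.isnan(self.accuracy), np.isnan(self.rt)):
            raise ValueError("missingness patterns of accuracy and rt must coincide")
        obs = ~np.isnan(self.rt)
        if np.any((self.rt[obs] < 0) | (self.rt[obs] > self.deadline)):
            raise ValueError("observed response times must lie in [0, deadline]")
        vals = self.accuracy[obs]
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("accuracy must be binary (0/1)")

    @property
    def n_persons(self) -> int:
        return self.accuracy.shape[0]

    @property
    def n_items(self) -> int:
        return self.accuracy.shape[1]

    def to_scores(self, n_bins: int = 2) -> "ScoreMatrix":
        """Discretize into a polytomous score matrix (4 categories for 2 bins)."""
        obs = ~np.isnan(self.accuracy)
        scores = np.full(self.accuracy.shape, MISSING, dtype=np.int64)
        t_star = discretize_rt(self.rt[obs], self.deadline, n_bins=n_bins)
        scores[obs] = assign_scores(self.accuracy[obs].astype(np.int64), t_star, n_bins=n_bins)
        return ScoreMatrix(scores, n_categories=2 * n_bins)


@dataclass
class ScoreMatrix:
    """Person x item polytomous item scores, ``MISSING`` (-1) where unobserved."""

    scores: NDArray
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D person x item matrix")
        valid = (self.scores == MISSING) | (
            (self.scores >= 0) & (self.scores < self.n_categories)
        )
        if not valid.all():
            raise ValueError(f"scores must be in 0..{self.n_categories - 1} or {MISSING}")

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def observed(self) -> NDArray:
        return self.scores != MISSING

    def accuracy_and_fast(self) -> tuple[NDArray, NDArray]:
        """Split 4-category scores into accuracy and fast-indicator matrices.

        Returns float matrices with NaN for missing entries.
        """
        if self.n_categories != 4:
            raise ValueError("accuracy/fast split is defined for 4-category scores")
        acc = np.where(self.observed, ACCURACY_OF_SCORE[np.clip(self.scores, 0, 3)], np.nan)
        fast = np.where(self.observed, FAST_OF_SCORE[np.clip(self.scores, 0, 3)], np.nan)
        return acc.astype(float), fast.astype(float)


@dataclass
class ItemParams1D:
    """Item parameters of the unidimensional discretized SRT model.

    ``slope`` is the discrimination alpha_i > 0 and ``intercepts`` the category
    intercepts (beta_i1, beta_i2, beta_i3), with beta_i0 fixed to 0.
    """

    slope: NDArray
    intercepts: NDArray

    def __post_init__(self) -> None:
        self.slope = np.atleast_1d(np.asarray(self.slope, dtype=float))
        self.intercepts = np.atleast_2d(np.asarray(self.intercepts, dtype=float))
        if np.any(self.slope <= 0):
            raise ValueError("slopes must be strictly positive")
        if self.intercepts.shape != (self.slope.shape[0], self.intercepts.shape[1]):
            raise ValueError("intercepts must be (K, C-1)")


@dataclass
class ItemParams2D:
    """Item parameters of the two-dimensional discretized SRT / nominal model."""

    slope_ability: NDArray
    slope_speed: NDArray
    intercepts: NDArray
    scoring_ability: NDArray = field(default_factory=lambda: ABILITY_SCORES.copy())
    scoring_speed: NDArray = field(default_factory=lambda: SPEED_SCORES.copy())

    def __post_init__(self) -> None:
        self.slope_ability = np.atleast_1d(np.asarray(self.slope_ability, dtype=float))
        self.slope_speed = np.atleast_1d(np.asarray(self.slope_speed, dtype=float))
        self.intercepts = np.atleast_2d(np.asarray(self.intercepts, dtype=float))
        self.scoring_ability = np.asarray(self.scoring_ability, dtype=float)
        self.scoring_speed = np.asarray(self.scoring_speed, dtype=float)
        if np.any(self.slope_ability <= 0):
            raise ValueError("ability slopes must be strictly positive")
        if np.any(self.slope_speed < 0):
            raise ValueError("speed slopes must be nonnegative")
        c = self.intercepts.shape[1] + 1
        if len(self.scoring_ability) != c or len(self.scoring_speed) != c:
            raise ValueError(
                f"scoring vectors must have length {c} (one entry per category)"
            )


@dataclass
class PopulationSpec:
    """Bivariate-normal latent population: means 0, variances 1, free correlation."""

    rho: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (-1, 1)")

    @property
    def cov(self) -> NDArray:
        return np.array([[1.0, self.rho], [self.rho, 1.0]])


@dataclass
class ContinuousSRTParams:
    """Parameters of the continuous SRT density: difficulty, slope, deadline."""

    difficulty: float
    slope: float = 1.0
    deadline: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.deadline <= 0:
            raise ValueError("deadline must be positive")


# ---------------------------------------------------------------------------
# Scoring rules
# ---------------------------------------------------------------------------


def srt_score(x: ArrayLike, t: ArrayLike, d: float) -> NDArray | float:
    """Continuous SRT score ``(2x - 1)(d - t)``: residual time signed by accuracy."""
    x = np.asarray(x)
    t = np.asarray(t)
    if np.any((t < 0) | (t > d)):
        raise ValueError("response time must lie in [0, d]")
    out = (2.0 * x - 1.0) * (d - t)
    return out if out.ndim else float(out)


def discretize_rt(t: ArrayLike, d: float, n_bins: int = 2) -> NDArray | int:
    """Discretize response time into equal-width speed categories.

    For ``n_bins=2`` returns the fast indicator T* = 1 iff t < d/2 (a response
    at exactly half the deadline counts as slow).  For more bins, returns a
    speed code in ``0..n_bins-1`` with the fastest interval getting the highest
    code; bin edges are half-open ``[lower, upper)`` except the last, which
    includes ``d``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > d)):
        raise ValueError("response time must lie in [0, d]")
    # interval index counted from the slow end, so that faster => higher code
    raw = np.floor(t / d * n_bins).astype(np.int64)
    raw = np.minimum(raw, n_bins - 1)
    out = (n_bins - 1) - raw
    return out if out.ndim else int(out)


def assign_scores(x: ArrayLike, t_star: ArrayLike, n_bins: int = 2) -> NDArray | int:
    """Combine accuracy and a speed code into the ordered polytomous item score.

    For the half-deadline split (``n_bins=2``, ``t_star`` the fast indicator)
    this is the four-category rule 0 = fast incorrect, 1 = slow incorrect,
    2 = slow correct, 3 = fast correct.  For ``n_bins`` speed categories the
    ``2 * n_bins`` scores are ordered fast-incorrect ... fast-correct, the
    ordering implied by the continuous scoring rule.
    """
    x = np.asarray(x, dtype=np.int64)
    t_star = np.asarray(t_star, dtype=np.int64)
    if np.any((x != 0) & (x != 1)):
        raise ValueError("accuracy must be binary (0/1)")
    if np.any((t_star < 0) | (t_star >= n_bins)):
        raise ValueError(f"speed code must be in 0..{n_bins - 1}")
    out = np.where(x == 0, (n_bins - 1) - t_star, n_bins + t_star)
    return out if out.ndim else int(out)


# ---------------------------------------------------------------------------
# Category probability functions
# ---------------------------------------------------------------------------


def prob_coomans(theta: ArrayLike, delta: ArrayLike, n_categories: int = 4) -> NDArray:
    """One-parameter discretized SRT model: softmax over s of ``s (theta - delta)``.

    The sum score is sufficient for the person and the item total score for the
    item, mirroring the Rasch-type structure of the continuous SRT model.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    s = np.arange(n_categories, dtype=float)
    logits = np.multiply.outer(theta - delta, s)
    return _softmax(logits)


def prob_pcm(theta: ArrayLike, beta: ArrayLike) -> NDArray:
    """Partial-credit form: softmax over s of ``s*theta + beta_s`` (beta_0 = 0)."""
    return prob_gpcm1d(theta, 1.0, beta)


def prob_gpcm1d(theta: ArrayLike, alpha: ArrayLike, beta: ArrayLike) -> NDArray:
    """Unidimensional discretized SRT model with item discrimination.

    ``P(S = s | theta) = softmax_s(s * alpha * theta + beta_s)`` with
    ``beta_0 = 0`` and ``beta`` supplying ``(beta_1, ..., beta_{C-1})``.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    beta_full = np.concatenate([np.zeros(beta.shape[:-1] + (1,)), beta], axis=-1)
    s = np.arange(beta_full.shape[-1], dtype=float)
    logits = np.multiply.outer(alpha * theta, s) + beta_full
    return _softmax(logits)


def masters_to_intercepts(beta_star: ArrayLike) -> NDArray:
    """Convert step parameters beta*_ir to category intercepts beta_is.

    ``beta_is = -sum_{r<=s} beta*_ir`` for s >= 1 (beta_i0 = 0 implicit).
    """
    beta_star = np.asarray(beta_star, dtype=float)
    return -np.cumsum(beta_star, axis=-1)


def intercepts_to_masters(beta: ArrayLike) -> NDArray:
    """Inverse of :func:`masters_to_intercepts` (first differences, negated)."""
    beta = np.asarray(beta, dtype=float)
    padded = np.concatenate([np.zeros(beta.shape[:-1] + (1,)), beta], axis=-1)
    return -np.diff(padded, axis=-1)


def prob_nominal(
    theta: ArrayLike,
    slopes: ArrayLike,
    beta: ArrayLike,
    scoring: ArrayLike,
) -> NDArray:
    """Multidimensional nominal response model with per-dimension scoring vectors.

    ``P(S = s | theta) = softmax_s( sum_m c_m[s] * alpha_m * theta_m + beta_s )``
    with ``beta_0 = 0``.

    Parameters
    ----------
    theta : (..., M) latent values.
    slopes : (M,) positive slopes.
    beta : (C-1,) category intercepts (beta_1 .. beta_{C-1}).
    scoring : (M, C) scoring vectors c_m.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    beta = np.asarray(beta, dtype=float)
    scoring = np.atleast_2d(np.asarray(scoring, dtype=float))
    n_cat = scoring.shape[1]
    if beta.shape[-1] != n_cat - 1:
        raise ValueError("beta must have one entry per non-reference category")
    if scoring.shape[0] != slopes.shape[0]:
        raise ValueError("one scoring vector per dimension is required")
    beta_full = np.concatenate([np.zeros(1), beta])
    logits = np.tensordot(theta * slopes, scoring, axes=([-1], [0])) + beta_full
    return _softmax(logits)


def prob_2d(theta1: ArrayLike, theta2: ArrayLike, params: ItemParams2D, item: int = 0) -> NDArray:
    """Two-dimensional discretized SRT model category probabilities.

    ``P(S = s | theta) = softmax_s( s*alpha_1*theta1 + I(s in {0,3})*alpha_2*theta2
    + beta_s )`` with the default scoring vectors; arbitrary scoring vectors give
    the general multidimensional nominal form.
    """
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    a1 = params.slope_ability[item]
    a2 = params.slope_speed[item]
    beta = params.intercepts[item]
    beta_full = np.concatenate([np.zeros(1), beta])
    logits = (
        np.multiply.outer(a1 * theta1, params.scoring_ability)
        + np.multiply.outer(a2 * theta2, params.scoring_speed)
        + beta_full
    )
    return _softmax(logits)


def p_fast_given_accuracy(
    theta1: ArrayLike,
    theta2: ArrayLike | None,
    params: ItemParams1D | ItemParams2D,
    x: int,
    item: int = 0,
) -> NDArray | float:
    """Conditional probability of a fast response given accuracy.

    ``P(T* = 1 | theta, X = 1) = P(S = 3) / (P(S = 3) + P(S = 2))`` and
    ``P(T* = 1 | theta, X = 0) = P(S = 0) / (P(S = 0) + P(S = 1))``.  Under the
    unidimensional model the former increases and the latter decreases in
    theta, so fast indicators of two items correlate negatively when their
    accuracies differ — the model cannot produce a positive manifold.
    """
    if x not in (0, 1):
        raise ValueError("x must be 0 or 1")
    if isinstance(params, ItemParams2D):
        if theta2 is None:
            raise ValueError("theta2 required for a two-dimensional model")
        p = prob_2d(theta1, theta2, params, item=item)
    else:
        p = prob_gpcm1d(theta1, params.slope[item], params.intercepts[item])
    if x == 1:
        out = p[..., 3] / (p[..., 3] + p[..., 2])
    else:
        out = p[..., 0] / (p[..., 0] + p[..., 1])
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Continuous SRT density
# ---------------------------------------------------------------------------


def srt_density(
    x: ArrayLike, t: ArrayLike, theta: ArrayLike, params: ContinuousSRTParams
) -> NDArray | float:
    """Joint density of (accuracy, response time) under the continuous SRT model.

    With ``a = alpha * (theta - delta)`` the signed score S = (2X-1)(d-T) has
    density proportional to ``exp(s * a)`` on [-d, d]; the joint density is

        f(x, t | theta) = a * exp((2x - 1)(d - t) * a) / (exp(d a) - exp(-d a)),

    which integrates to 1 over x in {0, 1}, t in [0, d] and implies the
    two-parameter-logistic accuracy margin P(X=1 | theta) = logistic(d * a).
    At theta = delta the density degenerates to the uniform 1 / (2 d).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > params.deadline)):
        raise ValueError("response time must lie in [0, deadline]")
    d = params.deadline
    a = params.slope * (np.asarray(theta, dtype=float) - params.difficulty)
    s = (2.0 * x - 1.0) * (d - t)
    with np.errstate(over="ignore", invalid="ignore"):
        # stable form: a * exp((s - d) a) / (1 - exp(-2 d a)); symmetric in sign(a)
        aa = np.abs(a)
        ss = np.where(a >= 0, s, -s)
        dens = np.where(
            aa < 1e-10,
            np.full(np.broadcast_shapes(np.shape(ss), np.shape(aa)), 1.0 / (2.0 * d)),
            aa * np.exp((ss - d) * aa) / (1.0 - np.exp(-2.0 * d * aa)),
        )
    return dens if np.ndim(dens) else float(dens)


def srt_marginal_p_correct(theta: ArrayLike, params: ContinuousSRTParams) -> NDArray | float:
    """Accuracy margin of the continuous SRT model: logistic(d * alpha * (theta - delta))."""
    a = params.slope * (np.asarray(theta, dtype=float) - params.difficulty)
    from scipy.special import expit

    out = expit(params.deadline * a)
    return out if np.ndim(out) else float(out)
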