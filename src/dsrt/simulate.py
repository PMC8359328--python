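"""Data generation for every model variant, including the benchmark study design.

The benchmark design tiles five category-intercept sets across items (so a
test of K items uses each set K/5 times), uses an ability slope of 0.5 for all
items, and either no speed dimension (``alpha2 = 0``, the null condition) or a
unit speed slope (``alpha2 = 1``).  Latent (ability, speed) pairs are drawn
from a standard bivariate normal with correlation rho.

Seeding: every generator takes a :class:`numpy.random.Generator` or an integer
seed.  Replication studies derive child seeds deterministically as
``SeedSequence((master_seed, condition_index, replication_index))`` so any
single replication can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.typing import NDArray

from dsrt.models import (
    ABILITY_SCORES,
    ACCURACY_OF_SCORE,
    FAST_OF_SCORE,
    SPEED_SCORES,
    ContinuousSRTParams,
    ItemParams1D,
    ItemParams2D,
    ResponseData,
    ScoreMatrix,
)

#: The five category-intercept sets of the benchmark design; at theta = 0 they
#: imply score-probability vectors [.25,.25,.25,.25], [.1,.4,.4,.1],
#: [.4,.1,.1,.4], [.1,.1,.4,.4] and [.4,.4,.1,.1].
BETA_SETS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.5, 1.5, 0.0],
        [-1.5, -1.5, 0.0],
        [0.0, 1.5, 1.5],
        [0.0, -1.5, -1.5],
    ]
)


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence | None):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seed(master_seed: int, condition: int, replication: int) -> np.random.SeedSequence:
    """Deterministic per-replication seed: SeedSequence((master, condition, rep))."""
    return np.random.SeedSequence((master_seed, condition, replication))


@dataclass
class SimDesign:
    """A simulation condition of the benchmark design.

    ``alpha2 = 0`` gives the null condition (no person speed differences);
    ``K`` must be divisible by 5 to tile the intercept sets evenly.
    """

    n_persons: int = 1000
    n_items: int = 20
    alpha1: float = 0.5
    alpha2: float = 0.0
    rho: float = 0.0
    n_reps: int = 100
    seed: int = 0
    person_mode: Literal["fixed", "redrawn"] = "fixed"

    def __post_init__(self) -> None:
        if self.n_items % 5 != 0:
            raise ValueError("n_items must be divisible by 5 to tile the intercept sets")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (-1, 1)")

    def item_params(self) -> ItemParams2D:
        return benchmark_item_params(self.n_items, self.alpha1, self.alpha2)


def benchmark_item_params(n_items: int, alpha1: float = 0.5, alpha2: float = 0.0) -> ItemParams2D:
    """Benchmark item parameters: the five intercept sets tiled K/5 times."""
    if n_items % 5 != 0:
        raise ValueError("n_items must be divisible by 5")
    reps = n_items // 5
    intercepts = np.tile(BETA_SETS, (reps, 1))
    return ItemParams2D(
        slope_ability=np.full(n_items, alpha1),
        slope_speed=np.full(n_items, alpha2),
        intercepts=intercepts,
    )


def draw_latents(
    n: int,
    rho: float,
    seed: int | np.random.Generator | None = None,
    standardize: bool = False,
) -> NDArray:
    """Draw (n, 2) latent (ability, speed) pairs from N2(0, [[1, rho], [rho, 1]]).

    With ``standardize=True`` the realized sample is transformed to have
    exactly mean 0, SD 1 per dimension, and sample correlation ``rho``
    (Gram-Schmidt on the raw normal draws).  Recovery studies that hold one
    person sample fixed across replications use this so that the sample
    matches the unit-variance identification of the fitted models; otherwise
    the draw's sampling error in scale masquerades as estimation bias.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    rng = _as_rng(seed)
    z = rng.standard_normal((n, 2))
    if standardize:
        if n < 3:
            raise ValueError("standardized draws need at least 3 persons")
        z -= z.mean(axis=0)
        z[:, 0] /= z[:, 0].std()
        # residualize the second column on the first, then rescale
        z[:, 1] -= (z[:, 1] @ z[:, 0]) / n * z[:, 0]
        z[:, 1] /= z[:, 1].std()
    theta2 = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    return np.column_stack([z[:, 0], theta2])


def _sample_categorical(probs: NDArray, rng: np.random.Generator) -> NDArray:
    """Sample category indices from (N, K, C) probabilities by inverse CDF."""
    cum = probs.cumsum(axis=-1)
    u = rng.random(probs.shape[:-1])
    return (u[..., None] >= cum).sum(axis=-1)


def _nominal_probs(theta: NDArray, params: ItemParams2D) -> NDArray:
    """(N, K, C) category probabilities of the (possibly 2-D) nominal model."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    c = params.intercepts.shape[1] + 1
    beta_full = np.concatenate([np.zeros((params.intercepts.shape[0], 1)), params.intercepts], 1)
    logits = (
        np.einsum("n,k,c->nkc", theta[:, 0], params.slope_ability, params.scoring_ability)
        + np.einsum("n,k,c->nkc", theta[:, 1], params.slope_speed, params.scoring_speed)
        + beta_full[None, :, :]
    )
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


def _params_to_2d(params: ItemParams1D | ItemParams2D) -> ItemParams2D:
    if isinstance(params, ItemParams2D):
        return params
    k = params.slope.shape[0]
    c = params.intercepts.shape[1] + 1
    return ItemParams2D(
        slope_ability=params.slope,
        slope_speed=np.zeros(k),
        intercepts=params.intercepts,
        scoring_ability=np.arange(c, dtype=float),
        scoring_speed=np.zeros(c),
    )


def simulate_scores(
    theta: NDArray,
    params: ItemParams1D | ItemParams2D,
    seed: int | np.random.Generator | None = None,
) -> ScoreMatrix:
    """Simulate a polytomous score matrix under the (1-D or 2-D) discretized SRT model.

    ``theta`` is (N,) for a unidimensional item set or (N, 2) for the
    two-dimensional model (ItemParams2D with zero speed slopes reduces to the
    unidimensional model, so a (N, 2) latent matrix is always accepted).
    """
    rng = _as_rng(seed)
    p2 = _params_to_2d(params)
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = np.column_stack([theta, np.zeros_like(theta)])
    probs = _nominal_probs(theta, p2)
    scores = _sample_categorical(probs, rng)
    return ScoreMatrix(scores, n_categories=probs.shape[-1])


def simulate_design(design: SimDesign, replication: int = 0) -> tuple[ScoreMatrix, NDArray]:
    """One replication of a benchmark condition: (scores, true latents).

    With ``person_mode="fixed"`` the latents depend only on the design seed,
    are identical across replications, and are standardized to the exact
    population moments (matching the unit-variance identification of the
    fitted models); scores are redrawn per replication.
    """
    theta_rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0)))
    theta = draw_latents(design.n_persons, design.rho, theta_rng, standardize=True)
    if design.person_mode == "redrawn":
        theta = draw_latents(
            design.n_persons,
            design.rho,
            np.random.default_rng(np.random.SeedSequence((design.seed, 1, replication))),
        )
    score_rng = np.random.default_rng(np.random.SeedSequence((design.seed, 2, replication)))
    scores = simulate_scores(theta, design.item_params(), score_rng)
    return scores, theta


def _sigmoid(x: NDArray) -> NDArray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_hm(
    theta: NDArray,
    acc_slope: NDArray,
    acc_intercept: NDArray,
    speed_slope: NDArray,
    speed_intercept: NDArray,
    seed: int | np.random.Generator | None = None,
) -> tuple[NDArray, NDArray]:
    """Simulate (accuracy, fast indicator) under the hierarchical model."""
    rng = _as_rng(seed)
    theta = np.asarray(theta, dtype=float)
    p_acc = _sigmoid(np.outer(theta[:, 0], acc_slope) + acc_intercept)
    p_fast = _sigmoid(np.outer(theta[:, 1], speed_slope) + speed_intercept)
    acc = (rng.random(p_acc.shape) < p_acc).astype(float)
    fast = (rng.random(p_fast.shape) < p_fast).astype(float)
    return acc, fast


def simulate_irtree(
    theta: NDArray,
    speed_slope: NDArray,
    speed_intercept: NDArray,
    fast_slope: NDArray,
    fast_intercept: NDArray,
    slow_slope: NDArray,
    slow_intercept: NDArray,
    seed: int | np.random.Generator | None = None,
) -> tuple[NDArray, NDArray]:
    """Simulate (accuracy, fast indicator) under the IRTree model: the speed
    branch decides fast/slow, then accuracy follows the branch-specific 2PL."""
    rng = _as_rng(seed)
    theta = np.asarray(theta, dtype=float)
    p_fast = _sigmoid(np.outer(theta[:, 1], speed_slope) + speed_intercept)
    fast = (rng.random(p_fast.shape) < p_fast).astype(float)
    p_acc_fast = _sigmoid(np.outer(theta[:, 0], fast_slope) + fast_intercept)
    p_acc_slow = _sigmoid(np.outer(theta[:, 0], slow_slope) + slow_intercept)
    p_acc = np.where(fast == 1.0, p_acc_fast, p_acc_slow)
    acc = (rng.random(p_acc.shape) < p_acc).astype(float)
    return acc, fast


def simulate_continuous_srt(
    theta: NDArray,
    params: ContinuousSRTParams,
    seed: int | np.random.Generator | None = None,
) -> ResponseData:
    """Simulate (accuracy, response time) from the continuous SRT density.

    The signed score S = (2X - 1)(d - T) has density proportional to
    exp(s * a) on [-d, d] with a = alpha (theta - delta); S is drawn by inverse
    CDF, then X = 1 iff S >= 0 and T = d - |S|.
    """
    rng = _as_rng(seed)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    d = params.deadline
    a = params.slope * (theta - params.difficulty)
    u = rng.random(theta.shape)
    s = np.empty_like(theta)
    small = np.abs(a) < 1e-10
    s[small] = (2.0 * u[small] - 1.0) * d
    ab = np.abs(a[~small])
    # For a > 0, inverting F(s) = (e^{sa} - e^{-da}) / (e^{da} - e^{-da}) in a
    # form that stays finite for large d*a gives S = d + log(u + (1-u)e^{-2da})/a;
    # a < 0 follows by the sign symmetry S(-a) ~ -S(a).
    s[~small] = np.sign(a[~small]) * (
        d + np.log(u[~small] + (1.0 - u[~small]) * np.exp(-2.0 * d * ab)) / ab
    )
    x = (s >= 0).astype(float)
    t = d - np.abs(s)
    return ResponseData(accuracy=x[:, None], rt=t[:, None], deadline=d)


def inject_missing(
    smat: ScoreMatrix, p_missing: float, seed: int | np.random.Generator | None = None
) -> ScoreMatrix:
    """Mask entries missing-completely-at-random with probability ``p_missing``."""
    if not 0.0 <= p_missing < 1.0:
        raise ValueError("p_missing must be in [0, 1)")
    rng = _as_rng(seed)
    scores = smat.scores.copy()
    mask = rng.random(scores.shape) < p_missing
    scores[mask] = -1
    return ScoreMatrix(scores, n_categories=smat.n_categories)
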