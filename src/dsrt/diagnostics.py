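"""Positive-manifold model check: first eigenvalue of the RT correlation matrix.

Response times on different items typically show pervasive positive
correlations (a positive manifold), reflecting stable person differences in
speed.  The unidimensional SRT models cannot generate such a manifold: fast
indicators of two items correlate positively given equal accuracy but
negatively given unequal accuracy.  The check computes the first eigenvalue of
the inter-item correlation matrix of the (discretized or raw) response times
and compares it against its predictive distribution under a fitted model,
approximated by a parametric bootstrap at the MML point estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from dsrt.estimate import _TWO_DIM_MODELS, FitResult, fitted_cell_probs
from dsrt.models import FAST_OF_SCORE, MISSING, ScoreMatrix
from dsrt.simulate import _as_rng, _sample_categorical, draw_latents


@dataclass
class EigenCheckResult:
    """Observed first eigenvalue vs its parametric-bootstrap distribution."""

    observed_stat: float
    replicate_stats: NDArray
    interval: tuple[float, float]
    flag: bool  # True when the observed statistic falls outside the interval

    @property
    def above(self) -> bool:
        return self.observed_stat > self.interval[1]


def rt_eigen_stat(mat: NDArray, min_overlap: int = 30) -> float:
    """Largest eigenvalue of the pairwise-complete inter-item correlation matrix.

    ``mat`` is a person x item matrix (raw RTs or fast/slow indicators) with
    NaN marking missing entries.  Pairs of items with fewer than
    ``min_overlap`` joint observations raise an error naming the pair.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a person x item matrix with at least 2 items")
    obs = ~np.isnan(mat)
    overlap = obs.astype(float).T @ obs.astype(float)
    k = mat.shape[1]
    off = ~np.eye(k, dtype=bool)
    if (overlap[off] < min_overlap).any():
        i, j = np.argwhere((overlap < min_overlap) & off)[0]
        raise ValueError(
            f"items {i} and {j} share only {int(overlap[i, j])} observations "
            f"(min_overlap={min_overlap})"
        )
    sd = np.array([np.nanstd(mat[:, i]) for i in range(k)])
    degenerate = np.where(sd == 0)[0]
    if degenerate.size:
        raise ValueError(f"item(s) {degenerate.tolist()} have zero variance")
    corr = pd.DataFrame(mat).corr(min_periods=min_overlap).to_numpy()
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-8:
        warnings.warn(
            "pairwise-complete correlation matrix is not positive semi-definite",
            stacklevel=2,
        )
    return float(eig.max())


def fast_indicator_matrix(scores: ScoreMatrix) -> NDArray:
    """Fast/slow indicator matrix (NaN for missing) from 4-category scores."""
    _, fast = scores.accuracy_and_fast()
    return fast


def ppc_eigen(
    fit: FitResult,
    scores: ScoreMatrix,
    n_rep: int = 500,
    seed: int | np.random.Generator | None = None,
    min_overlap: int = 30,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> EigenCheckResult:
    """Parametric-bootstrap predictive check of the first-eigenvalue statistic.

    Simulates ``n_rep`` data sets from the fitted model at its point estimates
    (same persons, items, and missingness pattern as ``scores``), computes the
    first eigenvalue of the fast-indicator correlation matrix on each, and
    compares the observed statistic to the (2.5th, 97.5th) percentile interval.
    An observed value above the interval signals associations among the RTs
    that the fitted model cannot reproduce.
    """
    rng = _as_rng(seed)
    observed = rt_eigen_stat(fast_indicator_matrix(scores), min_overlap=min_overlap)
    n, k = scores.n_persons, scores.n_items
    obs_mask = scores.observed
    rho = fit.rho_estimate or 0.0
    two_dim = fit.model in _TWO_DIM_MODELS
    stats = np.empty(n_rep)
    for r in range(n_rep):
        theta = draw_latents(n, rho if two_dim else 0.0, rng)
        probs = fitted_cell_probs(fit, theta if two_dim else theta[:, 0])
        sim = _sample_categorical(np.moveaxis(probs, 0, 1), rng)
        sim[~obs_mask] = MISSING
        sim_scores = ScoreMatrix(sim, n_categories=fit.n_categories)
        stats[r] = rt_eigen_stat(
            fast_indicator_matrix(sim_scores), min_overlap=min_overlap
        )
    lo, hi = np.percentile(stats, percentiles)
    flag = not (lo <= observed <= hi)
    return EigenCheckResult(
        observed_stat=observed,
        replicate_stats=stats,
        interval=(float(lo), float(hi)),
        flag=bool(flag),
    )
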