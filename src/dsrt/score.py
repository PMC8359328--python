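"""EAP person scoring, model-based EAP reliability, and recovery summaries.

Person parameters are scored by their posterior mean (expected a posteriori,
EAP) given the maximum-likelihood item parameter estimates, integrating over
the fitted latent population (including the estimated correlation in the
two-dimensional models).  Model-based EAP reliability is the standard ratio

    rel = var(EAP) / (var(EAP) + mean(PSD^2)),

i.e. estimated true-score variance over total variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numpy.typing import NDArray

from dsrt.estimate import _TWO_DIM_MODELS, FitResult, _person_logliks, _posterior, _prepare
from dsrt.estimate import _make_family
from dsrt.models import ScoreMatrix
from dsrt.quadrature import QuadratureSpec, grid_1d, grid_2d, weights_2d


@dataclass
class PersonEstimates:
    """Per-person EAP estimates, posterior SDs, and log-likelihood contributions.

    ``eap`` and ``psd`` are (N, n_dims); dimension 0 is ability.  Persons with
    no observed responses are flagged (their posterior equals the prior:
    EAP 0, PSD 1) rather than silently scored.
    """

    eap: NDArray
    psd: NDArray
    loglik: NDArray
    flagged: NDArray

    @property
    def ability(self) -> NDArray:
        return self.eap[:, 0]

    @property
    def n_dims(self) -> int:
        return self.eap.shape[1]


def eap_scores(
    scores: ScoreMatrix, fit: FitResult, quad: QuadratureSpec | None = None
) -> PersonEstimates:
    """EAP posterior means and SDs of the latent(s) under a fitted model."""
    quad = quad or fit.quad
    if scores.n_items != fit.n_items:
        raise ValueError("score matrix and fit disagree on the number of items")
    two_dim = fit.model in _TWO_DIM_MODELS
    if two_dim:
        nodes, base_w = grid_2d(quad)
        w = weights_2d(nodes, base_w, fit.rho_estimate or 0.0)
    else:
        nodes, w = grid_1d(quad)
    sa = fit.scoring.get("ability") if fit.scoring else None
    ss = fit.scoring.get("speed") if fit.scoring else None
    family = _make_family(fit.model, nodes, fit.n_categories, quad.nodes_per_dim, sa, ss)
    s_ext, _ = _prepare_allow_empty(scores)
    log_joint = _person_logliks(family.logprobs(fit.raw_params), s_ext, np.log(w))
    post, lse = _posterior(log_joint)
    eap = post.T @ nodes  # (N, n_dims)
    second = post.T @ (nodes**2)
    psd = np.sqrt(np.maximum(second - eap**2, 0.0))
    flagged = ~scores.observed.any(axis=1)
    return PersonEstimates(eap=eap, psd=psd, loglik=lse, flagged=flagged)


def _prepare_allow_empty(smat: ScoreMatrix):
    # like estimate._prepare but tolerating all-missing persons (they are flagged)
    scores = smat.scores
    obs = smat.observed
    s_ext = np.where(obs, scores, smat.n_categories)
    return s_ext, None


def eap_reliability(estimates: PersonEstimates, dim: int = 0) -> float:
    """Model-based EAP reliability: var(EAP) / (var(EAP) + mean posterior variance)."""
    if estimates.eap.shape[0] < 2:
        raise ValueError("reliability needs at least 2 persons")
    keep = ~estimates.flagged
    eap = estimates.eap[keep, dim]
    pv = estimates.psd[keep, dim] ** 2
    v = float(np.var(eap))
    denom = v + float(np.mean(pv))
    return 0.0 if denom == 0.0 else v / denom


class BiasVarMse(NamedTuple):
    """Recovery summary of a replication study (aggregated over persons)."""

    bias: float  # mean over persons of |mean over reps of (estimate - truth)|
    var: float  # mean over persons of the variance over reps
    mse: float  # mean over persons and reps of the squared error
    per_person_bias: NDArray
    per_person_var: NDArray
    per_person_mse: NDArray


def bias_var_mse(estimates: NDArray, truth: NDArray) -> BiasVarMse:
    """Average absolute bias, variance, and MSE of person estimates.

    ``estimates`` is (n_reps, n_persons) with the same persons (fixed latents)
    in every replication; ``truth`` is (n_persons,).  Per person,
    ``mse_p = bias_p**2 + var_p`` holds exactly (variance uses ddof=0).
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.ndim != 2 or estimates.shape[1] != truth.shape[0]:
        raise ValueError("estimates must be (n_reps, n_persons) matching truth")
    err = estimates - truth
    bias_p = err.mean(axis=0)
    var_p = estimates.var(axis=0, ddof=0)
    mse_p = (err**2).mean(axis=0)
    return BiasVarMse(
        bias=float(np.abs(bias_p).mean()),
        var=float(var_p.mean()),
        mse=float(mse_p.mean()),
        per_person_bias=bias_p,
        per_person_var=var_p,
        per_person_mse=mse_p,
    )
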