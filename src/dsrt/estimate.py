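"""Marginal maximum-likelihood (MML) estimation of the discretized SRT family.

All models are estimated by an EM algorithm on the quadrature-approximated
marginal likelihood

    L = prod_j  int  prod_i  P(S_ji = s | theta; item i)  N(theta) dtheta,

with the latent distribution standard normal per dimension (means 0, variances
1 for identification) and, in the two-dimensional models, a free correlation
``rho``.  The E-step computes person posteriors over a fixed Gauss-Hermite
grid; the M-step solves small per-item Newton problems (batched across items)
and a one-dimensional search for ``rho`` through the quadrature weights.
Slopes constrained positive are log-reparameterized internally.

Supported model tags
--------------------
``coomans``  one-parameter discretized SRT (single difficulty per item)
``pcm``      partial-credit form (category intercepts, common slope 1)
``srt1d``    unidimensional discretized SRT (slope + category intercepts)
``nrm``      unidimensional nominal response model (free category slopes)
``srt2d``    two-dimensional discretized SRT (ability + speed, free rho)
``hm``       hierarchical model: 2PL accuracy on theta1, 2PL fast indicator
             on theta2, correlated latents
``irtree``   speed branch (2PL on theta2) followed by branch-specific 2PL
             accuracy models on theta1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import minimize_scalar

from dsrt.models import (
    ABILITY_SCORES,
    ACCURACY_OF_SCORE,
    FAST_OF_SCORE,
    MISSING,
    SPEED_SCORES,
    ScoreMatrix,
    assign_scores,
)
from dsrt.quadrature import QuadratureSpec, grid_1d, grid_2d, weights_2d

_TWO_DIM_MODELS = {"srt2d", "hm", "irtree"}
_CELL_MODELS = {"hm", "irtree"}

_DEFAULT_OPTIONS: dict[str, Any] = {
    "tol": 1e-6,  # relative log-likelihood change
    "maxiter": 500,
    "n_newton": 3,  # Newton steps per M-step
}


@dataclass
class FitResult:
    """Estimated item parameters and fit summary of an MML fit."""

    model: str
    item_estimates: dict[str, NDArray]
    rho_estimate: float | None
    loglik: float
    aic: float
    bic: float
    n_params: int
    converged: bool
    n_iterations: int
    n_persons: int
    n_items: int
    n_categories: int
    quad: QuadratureSpec
    scoring: dict[str, NDArray] | None = None
    raw_params: NDArray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------


def _logsumexp_last(z: NDArray) -> NDArray:
    m = z.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True))


def _log_sigmoid(x: NDArray) -> NDArray:
    return -np.logaddexp(0.0, -x)


class _LinearFamily:
    """Softmax model whose category logits are linear in (transformed) item params.

    ``z[k, q, c] = sum_p t(u[k, p]) * G[p, q, c] + offset[q, c]`` where ``t``
    is ``exp`` for positivity-constrained slope entries and identity otherwise.
    Covers every family in the package except the IRTree, whose branch-specific
    normalizers break linearity.
    """

    def __init__(
        self,
        name: str,
        n_dims: int,
        n_cat: int,
        G: NDArray,
        offset: NDArray | None,
        is_log: NDArray,
        param_names: list[str],
    ) -> None:
        self.name = name
        self.n_dims = n_dims
        self.n_cat = n_cat
        self.G = G  # (P, Q, C)
        self.offset = offset  # (Q, C) or None
        self.is_log = is_log
        self.param_names = param_names

    @property
    def n_item_params(self) -> int:
        return self.G.shape[0]

    def _transform(self, u: NDArray) -> NDArray:
        tp = u.copy()
        tp[:, self.is_log] = np.exp(u[:, self.is_log])
        return tp

    def logits(self, u: NDArray) -> NDArray:
        z = np.einsum("kp,pqc->kqc", self._transform(u), self.G)
        if self.offset is not None:
            z += self.offset
        return z

    def logprobs(self, u: NDArray) -> NDArray:
        z = self.logits(u)
        return z - _logsumexp_last(z)

    def mstep(self, counts: NDArray, u: NDArray, n_newton: int = 3) -> NDArray:
        """Maximize the expected complete-data log-likelihood per item (Newton)."""
        nq = counts.sum(axis=-1)  # (K, Q)
        u = u.copy()
        ridge = 1e-9 * np.eye(self.n_item_params)
        for _ in range(n_newton):
            tp = self._transform(u)
            z = self.logits(u)
            logz = _logsumexp_last(z)
            logp = z - logz
            p = np.exp(logp)
            q0 = np.einsum("kqc,kqc->k", counts, logp)
            r = counts - nq[..., None] * p
            g_tp = np.einsum("kqc,pqc->kp", r, self.G)
            a = np.einsum("pqc,kqc->kpq", self.G, p)
            b = np.einsum("pqc,rqc,kqc->kprq", self.G, self.G, p)
            h_tp = -np.einsum("kq,kprq->kpr", nq, b) + np.einsum(
                "kq,kpq,krq->kpr", nq, a, a
            )
            d = np.ones_like(tp)
            d[:, self.is_log] = tp[:, self.is_log]
            g_u = g_tp * d
            h_u = h_tp * d[:, :, None] * d[:, None, :]
            idx = np.where(self.is_log)[0]
            h_u[:, idx, idx] += g_tp[:, idx] * tp[:, idx]
            try:
                step = np.linalg.solve(-h_u + ridge, g_u[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = g_u  # fall back to a (scaled) gradient step
            step = np.clip(step, -2.0, 2.0)
            # step-halving safeguard (generalized EM: never decrease the Q-function)
            for _ in range(6):
                u_try = self._clip(u + step)
                z1 = self.logits(u_try)
                q1 = np.einsum("kqc,kqc->k", counts, z1 - _logsumexp_last(z1))
                worse = q1 < q0 - 1e-10
                if not worse.any():
                    break
                step[worse] *= 0.5
            u = self._clip(u + step)
        return u

    def _clip(self, u: NDArray) -> NDArray:
        u = u.copy()
        u[:, self.is_log] = np.clip(u[:, self.is_log], -8.0, 4.0)
        u[:, ~self.is_log] = np.clip(u[:, ~self.is_log], -30.0, 30.0)
        return u


class _IRTreeFamily:
    """Fast/slow branch model: 2PL speed on theta2, branch-specific 2PL accuracy.

    Cell probabilities on the four accuracy x speed outcomes (coded as the SRT
    score categories): ``P(x, f | theta) = P2PL(f | theta2) * P2PL(x | theta1;
    branch f)``.  Parameter layout per item: (log a_speed, d_speed, log a_fast,
    d_fast, log a_slow, d_slow).
    """

    name = "irtree"
    n_dims = 2
    n_cat = 4
    n_item_params = 6
    param_names = ["log_a_speed", "d_speed", "log_a_fast", "d_fast", "log_a_slow", "d_slow"]

    def __init__(self, nodes: NDArray, nodes_per_dim: int) -> None:
        self.nodes = nodes
        self.n1 = nodes_per_dim
        # unique per-dimension node values of the product grid
        self.ax1 = nodes[:: self.n1, 0]
        self.ax2 = nodes[: self.n1, 1]

    def logprobs(self, u: NDArray) -> NDArray:
        t1, t2 = self.nodes[:, 0], self.nodes[:, 1]
        a_sp, d_sp = np.exp(u[:, 0:1]), u[:, 1:2]
        a_f, d_f = np.exp(u[:, 2:3]), u[:, 3:4]
        a_s, d_s = np.exp(u[:, 4:5]), u[:, 5:6]
        eta_sp = a_sp * t2 + d_sp  # (K, Q)
        eta_f = a_f * t1 + d_f
        eta_s = a_s * t1 + d_s
        lf1, lf0 = _log_sigmoid(eta_sp), _log_sigmoid(-eta_sp)
        lxf1, lxf0 = _log_sigmoid(eta_f), _log_sigmoid(-eta_f)
        lxs1, lxs0 = _log_sigmoid(eta_s), _log_sigmoid(-eta_s)
        # cells: 0 = fast incorrect, 1 = slow incorrect, 2 = slow correct, 3 = fast correct
        return np.stack([lf1 + lxf0, lf0 + lxs0, lf0 + lxs1, lf1 + lxf1], axis=-1)

    def mstep(self, counts: NDArray, u: NDArray, n_newton: int = 3) -> NDArray:
        k, q, _ = counts.shape
        c = counts.reshape(k, self.n1, self.n1, 4)  # (K, theta1 axis, theta2 axis, cell)
        u = u.copy()
        # speed branch: fast indicator vs theta2 (marginalize over theta1)
        fast = (c[..., 0] + c[..., 3]).sum(axis=1)  # (K, n)
        total = c.sum(axis=(1, 3))
        u[:, 0:2] = _newton_2pl(u[:, 0:2], self.ax2, total, fast, n_newton)
        # fast-branch accuracy vs theta1 (marginalize over theta2)
        trials_f = (c[..., 0] + c[..., 3]).sum(axis=2)
        succ_f = c[..., 3].sum(axis=2)
        u[:, 2:4] = _newton_2pl(u[:, 2:4], self.ax1, trials_f, succ_f, n_newton)
        # slow-branch accuracy vs theta1
        trials_s = (c[..., 1] + c[..., 2]).sum(axis=2)
        succ_s = c[..., 2].sum(axis=2)
        u[:, 4:6] = _newton_2pl(u[:, 4:6], self.ax1, trials_s, succ_s, n_newton)
        return u


def _newton_2pl(
    u: NDArray, nodes: NDArray, trials: NDArray, succ: NDArray, n_newton: int
) -> NDArray:
    """Batched Newton ascent of a weighted 2PL Bernoulli likelihood.

    ``u`` is (K, 2) = (log slope, intercept); ``trials``/``succ`` are expected
    counts per node.
    """
    u = u.copy()
    for _ in range(n_newton):
        a = np.exp(u[:, 0:1])
        eta = a * nodes + u[:, 1:2]  # (K, Q)
        p = 1.0 / (1.0 + np.exp(-eta))
        r = succ - trials * p
        w = trials * p * (1.0 - p)
        g_a = (r * nodes).sum(axis=1)
        g_d = r.sum(axis=1)
        h_aa = -(w * nodes * nodes).sum(axis=1)
        h_ad = -(w * nodes).sum(axis=1)
        h_dd = -w.sum(axis=1)
        av = a[:, 0]
        # chain rule to log-slope space
        g_la = g_a * av
        h_lala = h_aa * av * av + g_a * av
        h_lad = h_ad * av
        det = h_lala * h_dd - h_lad * h_lad
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        step_la = -(h_dd * g_la - h_lad * g_d) / det
        step_d = -(h_lala * g_d - h_lad * g_la) / det
        step = np.clip(np.column_stack([step_la, step_d]), -1.5, 1.5)
        u = u + step
        u[:, 0] = np.clip(u[:, 0], -8.0, 4.0)
        u[:, 1] = np.clip(u[:, 1], -30.0, 30.0)
    return u


def _default_speed_scoring(n_cat: int) -> NDArray:
    """Default speed scoring vector: the fast-category indicator for the
    half-deadline split; for finer even splits, a symmetric loading that grows
    toward the extreme (fastest) categories, e.g. [2,1,0,0,1,2] for 6."""
    if n_cat % 2 != 0:
        raise ValueError(
            "no default speed scoring for an odd category count; pass scoring_speed"
        )
    half = n_cat // 2
    down = np.arange(half - 1, -1, -1, dtype=float)
    return np.concatenate([down, down[::-1]])


def _make_family(
    model: str,
    nodes: NDArray,
    n_cat: int,
    nodes_per_dim: int,
    scoring_ability: NDArray | None = None,
    scoring_speed: NDArray | None = None,
):
    q = nodes.shape[0]
    s = np.arange(n_cat, dtype=float) if scoring_ability is None else np.asarray(
        scoring_ability, dtype=float
    )
    c2 = None
    if model == "srt2d":
        if scoring_speed is None:
            c2 = _default_speed_scoring(n_cat)
        else:
            c2 = np.asarray(scoring_speed, dtype=float)
        if len(c2) != n_cat:
            raise ValueError("scoring_speed length must equal the number of categories")
    if len(s) != n_cat:
        raise ValueError("scoring_ability length must equal the number of categories")
    t1 = nodes[:, 0]
    beta_g = np.zeros((n_cat - 1, q, n_cat))
    for j in range(n_cat - 1):
        beta_g[j, :, j + 1] = 1.0
    if model == "coomans":
        G = -np.broadcast_to(s, (1, q, n_cat)).copy()
        offset = np.outer(t1, s)
        return _LinearFamily(model, 1, n_cat, G, offset, np.array([False]), ["difficulty"])
    if model == "pcm":
        offset = np.outer(t1, s)
        is_log = np.zeros(n_cat - 1, dtype=bool)
        names = [f"beta{j + 1}" for j in range(n_cat - 1)]
        return _LinearFamily(model, 1, n_cat, beta_g, offset, is_log, names)
    if model == "srt1d":
        slope_g = (np.outer(t1, s))[None, :, :]
        G = np.concatenate([slope_g, beta_g], axis=0)
        is_log = np.array([True] + [False] * (n_cat - 1))
        names = ["log_slope"] + [f"beta{j + 1}" for j in range(n_cat - 1)]
        return _LinearFamily(model, 1, n_cat, G, None, is_log, names)
    if model == "nrm":
        slope_g = np.zeros((n_cat - 1, q, n_cat))
        for j in range(n_cat - 1):
            slope_g[j, :, j + 1] = t1
        G = np.concatenate([slope_g, beta_g], axis=0)
        is_log = np.zeros(2 * (n_cat - 1), dtype=bool)
        names = [f"a{j + 1}" for j in range(n_cat - 1)] + [
            f"beta{j + 1}" for j in range(n_cat - 1)
        ]
        return _LinearFamily(model, 1, n_cat, G, None, is_log, names)
    if model == "srt2d":
        t2 = nodes[:, 1]
        g1 = (np.outer(t1, s))[None, :, :]
        g2 = (np.outer(t2, c2))[None, :, :]
        G = np.concatenate([g1, g2, beta_g], axis=0)
        is_log = np.array([True, True] + [False] * (n_cat - 1))
        names = ["log_slope_ability", "log_slope_speed"] + [
            f"beta{j + 1}" for j in range(n_cat - 1)
        ]
        return _LinearFamily(model, 2, n_cat, G, None, is_log, names)
    if model == "hm":
        if n_cat != 4:
            raise ValueError("the hierarchical model requires 4-category cells")
        t2 = nodes[:, 1]
        x = ACCURACY_OF_SCORE.astype(float)
        f = FAST_OF_SCORE.astype(float)
        g = np.stack(
            [
                np.outer(t1, x),  # log accuracy slope
                np.broadcast_to(x, (q, 4)),  # accuracy intercept
                np.outer(t2, f),  # log speed slope
                np.broadcast_to(f, (q, 4)),  # speed intercept
            ]
        )
        is_log = np.array([True, False, True, False])
        names = ["log_a_acc", "d_acc", "log_a_speed", "d_speed"]
        return _LinearFamily(model, 2, n_cat, g.copy(), None, is_log, names)
    if model == "irtree":
        if n_cat != 4:
            raise ValueError("the IRTree model requires 4-category cells")
        return _IRTreeFamily(nodes, nodes_per_dim)
    raise ValueError(f"unknown model tag: {model!r}")


# ---------------------------------------------------------------------------
# Starting values and parameter bookkeeping
# ---------------------------------------------------------------------------


def _category_freqs(smat: ScoreMatrix) -> NDArray:
    k, c = smat.n_items, smat.n_categories
    freq = np.zeros((k, c))
    for cat in range(c):
        freq[:, cat] = (smat.scores == cat).sum(axis=0)
    return freq


def _check_data(smat: ScoreMatrix, model: str) -> None:
    obs = smat.observed
    empty_persons = np.where(~obs.any(axis=1))[0]
    if empty_persons.size:
        raise ValueError(f"person(s) {empty_persons.tolist()} have no observed responses")
    empty_items = np.where(~obs.any(axis=0))[0]
    if empty_items.size:
        raise ValueError(f"item(s) {empty_items.tolist()} have no observed responses")
    freq = _category_freqs(smat)
    if model in ("pcm", "srt1d", "srt2d", "nrm", "hm"):
        bad = np.argwhere(freq == 0)
        if bad.size:
            i, c = bad[0]
            raise ValueError(
                f"item {i} has no observed responses in category {c}; "
                "merge categories or drop the item before fitting"
            )
    if model == "irtree":
        fast = freq[:, 0] + freq[:, 3]
        slow = freq[:, 1] + freq[:, 2]
        bad = np.where((fast == 0) | (slow == 0))[0]
        if bad.size:
            raise ValueError(
                f"item(s) {bad.tolist()} have an empty fast or slow branch; "
                "the IRTree model cannot be fitted"
            )


def _start_params(smat: ScoreMatrix, family) -> NDArray:
    freq = _category_freqs(smat) + 0.5  # light smoothing for the start only
    k, c = smat.n_items, smat.n_categories
    logodds = np.log(freq[:, 1:]) - np.log(freq[:, :1])
    model = family.name
    if model == "coomans":
        return np.zeros((k, 1))
    if model == "pcm":
        return logodds.copy()
    if model == "srt1d":
        return np.column_stack([np.zeros(k), logodds])
    if model == "nrm":
        start_a = np.tile(np.arange(1, c, dtype=float), (k, 1))
        return np.column_stack([start_a, logodds])
    if model == "srt2d":
        return np.column_stack([np.zeros(k), np.zeros(k), logodds])
    p_corr = (freq[:, 2] + freq[:, 3]) / freq.sum(axis=1)
    p_fast = (freq[:, 0] + freq[:, 3]) / freq.sum(axis=1)
    d_acc = np.log(p_corr / (1 - p_corr))
    d_fast = np.log(p_fast / (1 - p_fast))
    if model == "hm":
        return np.column_stack([np.zeros(k), d_acc, np.zeros(k), d_fast])
    if model == "irtree":
        return np.column_stack(
            [np.zeros(k), d_fast, np.zeros(k), d_acc, np.zeros(k), d_acc]
        )
    raise ValueError(model)


def _n_free_params(model: str, k: int, n_cat: int) -> int:
    per_item = {
        "coomans": 1,
        "pcm": n_cat - 1,
        "srt1d": n_cat,
        "nrm": 2 * (n_cat - 1),
        "srt2d": n_cat + 1,
        "hm": 4,
        "irtree": 6,
    }[model]
    return per_item * k + (1 if model in _TWO_DIM_MODELS else 0)


def _estimates_dict(model: str, u: NDArray) -> dict[str, NDArray]:
    if model == "coomans":
        return {"difficulty": u[:, 0].copy()}
    if model == "pcm":
        return {"intercepts": u.copy()}
    if model == "srt1d":
        return {"slope": np.exp(u[:, 0]), "intercepts": u[:, 1:].copy()}
    if model == "nrm":
        h = u.shape[1] // 2
        return {"slopes": u[:, :h].copy(), "intercepts": u[:, h:].copy()}
    if model == "srt2d":
        return {
            "slope_ability": np.exp(u[:, 0]),
            "slope_speed": np.exp(u[:, 1]),
            "intercepts": u[:, 2:].copy(),
        }
    if model == "hm":
        return {
            "acc_slope": np.exp(u[:, 0]),
            "acc_intercept": u[:, 1].copy(),
            "speed_slope": np.exp(u[:, 2]),
            "speed_intercept": u[:, 3].copy(),
        }
    if model == "irtree":
        return {
            "speed_slope": np.exp(u[:, 0]),
            "speed_intercept": u[:, 1].copy(),
            "fast_slope": np.exp(u[:, 2]),
            "fast_intercept": u[:, 3].copy(),
            "slow_slope": np.exp(u[:, 4]),
            "slow_intercept": u[:, 5].copy(),
        }
    raise ValueError(model)


def _raw_from_dict(model: str, est: dict[str, NDArray]) -> NDArray:
    if model == "coomans":
        return np.asarray(est["difficulty"], dtype=float)[:, None]
    if model == "pcm":
        return np.asarray(est["intercepts"], dtype=float)
    if model == "srt1d":
        return np.column_stack([np.log(est["slope"]), est["intercepts"]])
    if model == "nrm":
        return np.column_stack([est["slopes"], est["intercepts"]])
    if model == "srt2d":
        return np.column_stack(
            [np.log(est["slope_ability"]), np.log(est["slope_speed"]), est["intercepts"]]
        )
    if model == "hm":
        return np.column_stack(
            [
                np.log(est["acc_slope"]),
                est["acc_intercept"],
                np.log(est["speed_slope"]),
                est["speed_intercept"],
            ]
        )
    if model == "irtree":
        return np.column_stack(
            [
                np.log(est["speed_slope"]),
                est["speed_intercept"],
                np.log(est["fast_slope"]),
                est["fast_intercept"],
                np.log(est["slow_slope"]),
                est["slow_intercept"],
            ]
        )
    raise ValueError(model)


# ---------------------------------------------------------------------------
# E-step machinery
# ---------------------------------------------------------------------------


def _prepare(smat: ScoreMatrix):
    scores = smat.scores
    n, k = scores.shape
    c = smat.n_categories
    obs = smat.observed
    s_ext = np.where(obs, scores, c)  # missing mapped to a dummy zero-logprob column
    onehot = np.zeros((k, n, c))
    rows = np.arange(n)
    for i in range(k):
        m = obs[:, i]
        onehot[i, rows[m], scores[m, i]] = 1.0
    return s_ext, onehot


def _person_logliks(logp: NDArray, s_ext: NDArray, logw: NDArray):
    """Log joint over the grid: returns (Q, N) unnormalized log posterior."""
    k, q, c = logp.shape
    n = s_ext.shape[0]
    ext = np.zeros((q, c + 1))
    loglik = np.tile(logw[:, None], (1, n))
    for i in range(k):
        ext[:, :c] = logp[i]
        loglik += ext[:, s_ext[:, i]]
    return loglik


def _posterior(log_joint: NDArray):
    m = log_joint.max(axis=0)
    lse = m + np.log(np.exp(log_joint - m).sum(axis=0))
    post = np.exp(log_joint - lse)
    return post, lse


def _update_rho(nodes: NDArray, base_w: NDArray, nq: NDArray) -> float:
    def negobj(r: float) -> float:
        return -float(nq @ np.log(weights_2d(nodes, base_w, r)))

    res = minimize_scalar(negobj, bounds=(-0.98, 0.98), method="bounded", options={"xatol": 1e-6})
    return float(res.x)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def marginal_loglik(
    params: FitResult | dict[str, NDArray],
    scores: ScoreMatrix,
    quad: QuadratureSpec | None = None,
    model: str | None = None,
    rho: float | None = None,
    scoring_ability: NDArray | None = None,
    scoring_speed: NDArray | None = None,
) -> float:
    """Quadrature-approximated marginal log-likelihood at fixed parameters.

    Missing entries contribute nothing to the within-person product; persons or
    items with no observations at all raise an error naming the offender.
    """
    if isinstance(params, FitResult):
        model = params.model
        raw = params.raw_params
        rho = params.rho_estimate if rho is None else rho
        quad = quad or params.quad
        if params.scoring is not None:
            scoring_ability = params.scoring.get("ability")
            scoring_speed = params.scoring.get("speed")
    else:
        if model is None:
            raise ValueError("model tag is required when passing a parameter dict")
        raw = _raw_from_dict(model, params)
        if rho is None:
            rho = params.get("rho", 0.0) if isinstance(params, dict) else 0.0
            rho = float(np.asarray(rho))
    quad = quad or QuadratureSpec()
    obs = scores.observed
    empty_p = np.where(~obs.any(axis=1))[0]
    if empty_p.size:
        raise ValueError(f"person(s) {empty_p.tolist()} have no observed responses")
    empty_i = np.where(~obs.any(axis=0))[0]
    if empty_i.size:
        raise ValueError(f"item(s) {empty_i.tolist()} have no observed responses")
    if model in _TWO_DIM_MODELS:
        nodes, base_w = grid_2d(quad)
        w = weights_2d(nodes, base_w, float(rho or 0.0))
    else:
        nodes, w = grid_1d(quad)
    family = _make_family(
        model, nodes, scores.n_categories, quad.nodes_per_dim, scoring_ability, scoring_speed
    )
    s_ext, _ = _prepare(scores)
    log_joint = _person_logliks(family.logprobs(raw), s_ext, np.log(w))
    _, lse = _posterior(log_joint)
    return float(lse.sum())


def fit_mml(
    scores: ScoreMatrix,
    model: str = "srt1d",
    quad: QuadratureSpec | None = None,
    options: dict[str, Any] | None = None,
    scoring_ability: NDArray | None = None,
    scoring_speed: NDArray | None = None,
    start: dict[str, NDArray] | None = None,
) -> FitResult:
    """Fit a discretized SRT family model by marginal maximum likelihood (EM).

    Parameters
    ----------
    scores : ScoreMatrix
        Person x item polytomous scores (cells for ``hm``/``irtree``).
    model : str
        One of ``coomans, pcm, srt1d, nrm, srt2d, hm, irtree``.
    quad : QuadratureSpec, optional
        Gauss-Hermite settings (default 21 nodes per dimension).
    options : dict, optional
        ``tol`` (relative log-likelihood change, default 1e-6), ``maxiter``
        (default 500), ``n_newton`` (Newton steps per M-step, default 3).
    start : dict, optional
        Item-parameter starting values in the same layout as
        ``FitResult.item_estimates`` (defaults: slopes 1, intercepts from
        observed category log-odds, rho 0).

    Non-convergence is flagged on the result, never raised.
    """
    opts = dict(_DEFAULT_OPTIONS)
    opts.update(options or {})
    quad = quad or QuadratureSpec()
    _check_data(scores, model)
    two_dim = model in _TWO_DIM_MODELS
    if two_dim:
        nodes, base_w = grid_2d(quad)
    else:
        nodes, base_w = grid_1d(quad)
    family = _make_family(
        model, nodes, scores.n_categories, quad.nodes_per_dim, scoring_ability, scoring_speed
    )
    u = _raw_from_dict(model, start) if start is not None else _start_params(scores, family)
    rho = float(opts.get("start_rho", 0.0))
    s_ext, onehot = _prepare(scores)
    logw = np.log(weights_2d(nodes, base_w, rho) if two_dim else base_w)

    ll_prev = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    k = scores.n_items
    counts = np.empty((k, nodes.shape[0], scores.n_categories))
    for it in range(1, opts["maxiter"] + 1):
        logp = family.logprobs(u)
        log_joint = _person_logliks(logp, s_ext, logw)
        post, lse = _posterior(log_joint)
        ll = float(lse.sum())
        if abs(ll - ll_prev) / (abs(ll) + 1.0) < opts["tol"]:
            converged = True
            break
        ll_prev = ll
        for i in range(k):
            counts[i] = post @ onehot[i]
        u = family.mstep(counts, u, n_newton=opts["n_newton"])
        if two_dim:
            rho = _update_rho(nodes, base_w, post.sum(axis=1))
            logw = np.log(weights_2d(nodes, base_w, rho))

    n_par = _n_free_params(model, k, scores.n_categories)
    n = scores.n_persons
    scoring = None
    if model == "srt2d":
        s_vec = (
            np.arange(scores.n_categories, dtype=float)
            if scoring_ability is None
            else np.asarray(scoring_ability, dtype=float)
        )
        c2 = (
            _default_speed_scoring(scores.n_categories)
            if scoring_speed is None
            else np.asarray(scoring_speed, dtype=float)
        )
        scoring = {"ability": s_vec, "speed": c2}
    return FitResult(
        model=model,
        item_estimates=_estimates_dict(model, u),
        rho_estimate=rho if two_dim else None,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * n_par,
        bic=-2.0 * ll + np.log(n) * n_par,
        n_params=n_par,
        converged=converged,
        n_iterations=it,
        n_persons=n,
        n_items=k,
        n_categories=scores.n_categories,
        quad=quad,
        scoring=scoring,
        raw_params=u,
    )


def _cells_from_split(accuracy: NDArray, fast: NDArray) -> ScoreMatrix:
    accuracy = np.asarray(accuracy, dtype=float)
    fast = np.asarray(fast, dtype=float)
    if accuracy.shape != fast.shape:
        raise ValueError("accuracy and fast indicator must have the same shape")
    obs = ~np.isnan(accuracy)
    if not np.array_equal(obs, ~np.isnan(fast)):
        raise ValueError("missingness of accuracy and fast indicator must coincide")
    cells = np.full(accuracy.shape, MISSING, dtype=np.int64)
    cells[obs] = assign_scores(accuracy[obs].astype(np.int64), fast[obs].astype(np.int64))
    return ScoreMatrix(cells, n_categories=4)


def fit_hm(
    accuracy: NDArray,
    fast_indicator: NDArray,
    quad: QuadratureSpec | None = None,
    options: dict[str, Any] | None = None,
) -> FitResult:
    """Fit the hierarchical model: 2PL accuracy on ability, 2PL fast indicator
    on speed, bivariate-normal latents with free correlation."""
    return fit_mml(_cells_from_split(accuracy, fast_indicator), "hm", quad, options)


def fit_irtree(
    accuracy: NDArray,
    fast_indicator: NDArray,
    quad: QuadratureSpec | None = None,
    options: dict[str, Any] | None = None,
) -> FitResult:
    """Fit the IRTree model: a 2PL speed branch followed by branch-specific
    2PL accuracy models (separate item parameters for fast and slow responses)."""
    return fit_mml(_cells_from_split(accuracy, fast_indicator), "irtree", quad, options)


def fitted_cell_probs(fit: FitResult, theta: NDArray) -> NDArray:
    """Category probabilities of a fitted model at arbitrary latent values.

    ``theta`` is (N,) for unidimensional models or (N, 2) for two-dimensional
    ones; returns a (K, N, C) probability array.
    """
    theta = np.asarray(theta, dtype=float)
    if fit.model in _TWO_DIM_MODELS:
        nodes = theta if theta.ndim == 2 else np.column_stack([theta, theta])
        if nodes.shape[1] != 2:
            raise ValueError("two-dimensional models need (N, 2) latent values")
    else:
        nodes = (theta if theta.ndim == 2 else theta[:, None])[:, :1]
    sa = fit.scoring.get("ability") if fit.scoring else None
    ss = fit.scoring.get("speed") if fit.scoring else None
    family = _make_family(fit.model, nodes, fit.n_categories, nodes.shape[0], sa, ss)
    if fit.model == "irtree":
        # the irtree family assumes a product grid only in its M-step; rebuild
        family = _IRTreeFamily(nodes, nodes.shape[0])
    return np.exp(family.logprobs(fit.raw_params))
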