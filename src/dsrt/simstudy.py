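"""Replication-study harness: simulate, fit, score, and aggregate recovery tables.

The benchmark design crosses a null condition (no person speed differences,
``alpha2 = 0``) with a speed-difference condition (``alpha2 = 1``), test
lengths K in {20, 40}, and latent correlations rho in {0, .2, .5}; N = 1000
persons, latents drawn once per condition and held fixed across replications.
Each replicated data set is fitted with the requested models (1-D and 2-D
discretized SRT, hierarchical, IRTree), persons are EAP-scored, and ability
recovery is summarized as average absolute bias, variance, and MSE, plus
model-based EAP reliability — with Monte-Carlo standard errors for every cell.

Monte-Carlo error accounting: jackknife-over-replications standard errors for
the bias/variance/MSE aggregates and the standard error of the mean for
reliability.  Because per-person bias is estimated from finitely many
replications, the average *absolute* bias statistic is inflated upward by
Monte-Carlo noise; ``abs_bias_inflation`` reports a plug-in estimate of that
inflation (closed-form E|N(b, s)| minus |b|), so that scaled-down runs can be
compared against large-replication reference values on equal terms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.stats import norm

from dsrt.estimate import QuadratureSpec, fit_hm, fit_irtree, fit_mml
from dsrt.score import bias_var_mse, eap_reliability, eap_scores
from dsrt.simulate import SimDesign, simulate_design

_ALL_MODELS = ("srt1d", "srt2d", "hm", "irtree")


@dataclass
class Condition:
    """One cell of the study design."""

    alpha2: float
    n_items: int
    rho: float = 0.0

    @property
    def label(self) -> str:
        rho = "-" if self.alpha2 == 0 else f"{self.rho:g}"
        return f"a2={self.alpha2:g} K={self.n_items} rho={rho}"


#: The eight conditions of the benchmark study (rho as tabulated: 0, .2, .5).
BENCHMARK_CONDITIONS = [
    Condition(0.0, 20),
    Condition(0.0, 40),
    Condition(1.0, 20, 0.0),
    Condition(1.0, 20, 0.2),
    Condition(1.0, 20, 0.5),
    Condition(1.0, 40, 0.0),
    Condition(1.0, 40, 0.2),
    Condition(1.0, 40, 0.5),
]


@dataclass
class StudyConfig:
    """Study settings: conditions, replication count, models, seeds, workers.

    ``n_reps`` below the reference 1000 is permitted (scaled-down runs) and is
    recorded in the output together with Monte-Carlo standard errors.
    """

    conditions: list[Condition] = field(default_factory=lambda: list(BENCHMARK_CONDITIONS))
    n_reps: int = 100
    n_persons: int = 1000
    models: tuple[str, ...] = _ALL_MODELS
    seed: int = 1
    nodes_1d: int = 21
    nodes_2d: int = 15
    nodes_score: int = 21
    n_workers: int = 1
    fit_options: dict[str, Any] = field(default_factory=dict)


@dataclass
class ModelSummary:
    """Aggregated ability-recovery results for one model in one condition."""

    model: str
    bias: float
    var: float
    mse: float
    reliability: float
    bias_se: float
    var_se: float
    mse_se: float
    reliability_se: float
    # person-sampling SEs: the aggregates also vary with the (fixed) latent
    # draw of N persons, an error source any finite-N reference study shares
    bias_se_persons: float
    var_se_persons: float
    mse_se_persons: float
    reliability_se_persons: float
    abs_bias_inflation: float
    n_reps_used: int
    n_failed: int
    mean_estimates: NDArray  # per-person average EAP across replications

    def comparison_se(self, stat: str) -> float:
        """Monte-Carlo SE for comparing a cell against an independent study's
        value: replication SE plus person-sampling SE counted on both sides."""
        se_rep = getattr(self, f"{stat}_se")
        se_pers = getattr(self, f"{stat}_se_persons")
        return float(np.sqrt(se_rep**2 + 2.0 * se_pers**2))


@dataclass
class ConditionResult:
    condition: Condition
    n_reps: int
    truth: NDArray  # per-person true theta1 (fixed across replications)
    models: dict[str, ModelSummary]


def _jackknife_se(loo_stats: NDArray) -> float:
    r = loo_stats.shape[0]
    return float(np.sqrt((r - 1) / r * ((loo_stats - loo_stats.mean()) ** 2).sum()))


def _abs_bias_inflation(bias_p: NDArray, noise_sd_p: NDArray) -> float:
    """Plug-in estimate of E|b + noise| - |b| averaged over persons."""
    s = np.where(noise_sd_p > 0, noise_sd_p, 1e-12)
    z = bias_p / s
    expected_abs = bias_p * (1.0 - 2.0 * norm.cdf(-z)) + 2.0 * s * norm.pdf(z)
    return float((expected_abs - np.abs(bias_p)).mean())


def _aggregate(model: str, est: NDArray, rels: NDArray, truth: NDArray, n_failed: int) -> ModelSummary:
    r = est.shape[0]
    summary = bias_var_mse(est, truth)
    err = est - truth
    s1, s2 = err.sum(axis=0), (err**2).sum(axis=0)
    a1, a2 = est.sum(axis=0), (est**2).sum(axis=0)
    # leave-one-replication-out aggregates, vectorized over reps x persons
    loo_bias = (s1 - err) / (r - 1)
    loo_mse = (s2 - err**2) / (r - 1)
    loo_mean = (a1 - est) / (r - 1)
    loo_var = (a2 - est**2) / (r - 1) - loo_mean**2
    bias_se = _jackknife_se(np.abs(loo_bias).mean(axis=1))
    mse_se = _jackknife_se(loo_mse.mean(axis=1))
    var_se = _jackknife_se(loo_var.mean(axis=1))
    rel_se = float(np.std(rels, ddof=1) / np.sqrt(r)) if r > 1 else float("nan")
    noise_sd = np.sqrt(summary.per_person_var / r)
    n = truth.shape[0]
    rel_mean = float(rels.mean())
    # person-sampling SEs: SD over persons of the per-person summaries; for the
    # reliability, a delta-method SE through var(EAP) under normal latents,
    # rel * (1 - rel) * sqrt(2 / (N - 1)).
    bias_sep = float(np.std(np.abs(summary.per_person_bias), ddof=1) / np.sqrt(n))
    var_sep = float(np.std(summary.per_person_var, ddof=1) / np.sqrt(n))
    mse_sep = float(np.std(summary.per_person_mse, ddof=1) / np.sqrt(n))
    rel_sep = rel_mean * (1.0 - rel_mean) * float(np.sqrt(2.0 / (n - 1)))
    return ModelSummary(
        model=model,
        bias=summary.bias,
        var=summary.var,
        mse=summary.mse,
        reliability=rel_mean,
        bias_se=bias_se,
        var_se=var_se,
        mse_se=mse_se,
        reliability_se=rel_se,
        bias_se_persons=bias_sep,
        var_se_persons=var_sep,
        mse_se_persons=mse_sep,
        reliability_se_persons=rel_sep,
        abs_bias_inflation=_abs_bias_inflation(summary.per_person_bias, noise_sd),
        n_reps_used=r,
        n_failed=n_failed,
        mean_estimates=est.mean(axis=0),
    )


def _fit_and_score(scores, model: str, q1, q2, qs, opts):
    if model in ("srt1d", "srt2d", "nrm", "pcm", "coomans"):
        quad = q2 if model == "srt2d" else q1
        fit = fit_mml(scores, model, quad, options=opts)
    else:
        acc, fast = scores.accuracy_and_fast()
        fit = (fit_hm if model == "hm" else fit_irtree)(acc, fast, q2, options=opts)
    pe = eap_scores(scores, fit, qs)
    return pe.ability, eap_reliability(pe)


def _one_replication(design: SimDesign, rep: int, models, q1, q2, qs, opts):
    scores, _ = simulate_design(design, rep)
    out = {}
    for model in models:
        try:
            out[model] = _fit_and_score(scores, model, q1, q2, qs, opts)
        except Exception as exc:  # noqa: BLE001 - replication failures are data
            out[model] = ("failed", repr(exc))
    return out


def run_condition(
    config: StudyConfig, condition: Condition, condition_index: int = 0
) -> ConditionResult:
    """Run all replications of one condition and aggregate recovery summaries."""
    design_seed = int(
        np.random.SeedSequence((config.seed, condition_index)).generate_state(1)[0] % (2**31)
    )
    design = SimDesign(
        n_persons=config.n_persons,
        n_items=condition.n_items,
        alpha1=0.5,
        alpha2=condition.alpha2,
        rho=condition.rho,
        n_reps=config.n_reps,
        seed=design_seed,
    )
    _, truth2 = simulate_design(design, 0)
    truth = truth2[:, 0]
    q1 = QuadratureSpec(config.nodes_1d)
    q2 = QuadratureSpec(config.nodes_2d)
    qs = QuadratureSpec(config.nodes_score)
    opts = dict(config.fit_options)

    if config.n_workers > 1:
        from joblib import Parallel, delayed

        rep_results = Parallel(n_jobs=config.n_workers)(
            delayed(_one_replication)(design, r, config.models, q1, q2, qs, opts)
            for r in range(config.n_reps)
        )
    else:
        rep_results = [
            _one_replication(design, r, config.models, q1, q2, qs, opts)
            for r in range(config.n_reps)
        ]

    models: dict[str, ModelSummary] = {}
    for model in config.models:
        est_rows, rels, n_failed = [], [], 0
        for rr in rep_results:
            res = rr[model]
            if isinstance(res[0], str):
                n_failed += 1
                continue
            est_rows.append(res[0])
            rels.append(res[1])
        if not est_rows:
            raise RuntimeError(
                f"all replications failed for model {model} in condition {condition.label}"
            )
        models[model] = _aggregate(
            model, np.asarray(est_rows), np.asarray(rels), truth, n_failed
        )
    return ConditionResult(
        condition=condition, n_reps=config.n_reps, truth=truth, models=models
    )


def run_study(config: StudyConfig) -> list[ConditionResult]:
    """Run every condition of the study configuration."""
    return [
        run_condition(config, cond, idx) for idx, cond in enumerate(config.conditions)
    ]


def mse_reduction_pct(result: ConditionResult) -> float:
    """Percent MSE reduction of the 2-D over the 1-D discretized SRT model."""
    m1, m2 = result.models["srt1d"].mse, result.models["srt2d"].mse
    return 100.0 * (m1 - m2) / m1


def emit_tables(results: list[ConditionResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recovery and reliability tables (one row per condition x model cell).

    The first table holds average absolute bias, variance, and MSE of the
    ability estimates with Monte-Carlo standard errors; the second the EAP
    reliabilities.  Empty input yields empty tables.
    """
    rows1, rows2 = [], []
    for res in results:
        cond = res.condition
        base = {
            "alpha2": cond.alpha2,
            "K": cond.n_items,
            "rho": np.nan if cond.alpha2 == 0 else cond.rho,
            "n_reps": res.n_reps,
        }
        for name, m in res.models.items():
            rows1.append(
                base
                | {
                    "model": name,
                    "bias": m.bias,
                    "var": m.var,
                    "mse": m.mse,
                    "bias_se": m.bias_se,
                    "var_se": m.var_se,
                    "mse_se": m.mse_se,
                    "abs_bias_inflation": m.abs_bias_inflation,
                    "n_failed": m.n_failed,
                }
            )
            rows2.append(
                base
                | {
                    "model": name,
                    "eap_reliability": m.reliability,
                    "reliability_se": m.reliability_se,
                    "n_failed": m.n_failed,
                }
            )
    cols1 = [
        "alpha2", "K", "rho", "n_reps", "model", "bias", "var", "mse",
        "bias_se", "var_se", "mse_se", "abs_bias_inflation", "n_failed",
    ]
    cols2 = [
        "alpha2", "K", "rho", "n_reps", "model",
        "eap_reliability", "reliability_se", "n_failed",
    ]
    return pd.DataFrame(rows1, columns=cols1), pd.DataFrame(rows2, columns=cols2)


def person_plot_data(results: list[ConditionResult]) -> pd.DataFrame:
    """Per-person true ability vs average estimate per model (plot source data)."""
    rows = []
    for res in results:
        for name, m in res.models.items():
            rows.append(
                pd.DataFrame(
                    {
                        "condition": res.condition.label,
                        "model": name,
                        "true_theta1": res.truth,
                        "mean_estimate": m.mean_estimates,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["condition", "model", "true_theta1", "mean_estimate"]
        )
    return pd.concat(rows, ignore_index=True)


def condition_to_dict(res: ConditionResult) -> dict:
    """JSON-serializable summary (drops per-person arrays)."""
    out = {
        "condition": dataclasses.asdict(res.condition),
        "n_reps": res.n_reps,
        "models": {},
    }
    for name, m in res.models.items():
        d = dataclasses.asdict(m)
        d.pop("mean_estimates")
        out["models"][name] = d
    return out
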