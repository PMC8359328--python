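"""Delimited-text readers/writers and fit-result (de)serialization.

Matrices are person-major wide CSV/TSV with person identifiers in the first
column and item identifiers in the header; missing entries are empty fields or
``NA`` on read and ``NA`` on write.  A YAML sidecar carries the metadata a
score file cannot express itself (deadline, discretization rule, category
count), and every derived dataset keeps a provenance block.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray

from dsrt.estimate import FitResult, QuadratureSpec
from dsrt.models import MISSING, ResponseData, ScoreMatrix


@dataclass
class Dataset:
    """A score matrix or raw (accuracy, rt) pair with identifiers and provenance."""

    scores: ScoreMatrix | None = None
    responses: ResponseData | None = None
    person_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.scores is None) == (self.responses is None):
            raise ValueError("exactly one of scores/responses must be provided")
        n, k = (
            (self.scores.n_persons, self.scores.n_items)
            if self.scores is not None
            else (self.responses.n_persons, self.responses.n_items)
        )
        if len(self.person_ids) != n or len(self.item_ids) != k:
            raise ValueError("identifier counts must match the matrix shape")
        if len(set(self.person_ids)) != n or len(set(self.item_ids)) != k:
            raise ValueError("person and item identifiers must be unique")
        if not self.provenance:
            raise ValueError("provenance must be populated")


def _read_matrix(path: str | Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""], keep_default_na=False)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: person/item identifiers must be unique")
    return df


def _drop_empty(df: pd.DataFrame, what: str) -> pd.DataFrame:
    empty_rows = df.index[df.isna().all(axis=1)]
    empty_cols = df.columns[df.isna().all(axis=0)]
    if len(empty_rows):
        warnings.warn(f"dropping {len(empty_rows)} all-missing person row(s) from {what}")
        df = df.drop(index=empty_rows)
    if len(empty_cols):
        warnings.warn(f"dropping {len(empty_cols)} all-missing item column(s) from {what}")
        df = df.drop(columns=empty_cols)
    return df


def read_scores(
    path: str | Path, n_categories: int = 4, sep: str = ","
) -> Dataset:
    """Read a wide polytomous score matrix (NA/empty marks missing entries)."""
    df = _drop_empty(_read_matrix(path, sep), str(path))
    vals = df.to_numpy(dtype=float)
    bad = np.argwhere(
        ~np.isnan(vals) & ((vals % 1 != 0) | (vals < 0) | (vals >= n_categories))
    )
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: invalid score {vals[r, c]!r} for person {df.index[r]!r}, "
            f"item {df.columns[c]!r} (expected 0..{n_categories - 1} or NA)"
        )
    scores = np.where(np.isnan(vals), MISSING, vals).astype(np.int64)
    return Dataset(
        scores=ScoreMatrix(scores, n_categories=n_categories),
        person_ids=[str(i) for i in df.index],
        item_ids=[str(c) for c in df.columns],
        provenance={"source": str(path), "kind": "scores", "n_categories": n_categories},
    )


def read_responses(
    accuracy_path: str | Path,
    rt_path: str | Path,
    deadline: float,
    sep: str = ",",
) -> Dataset:
    """Read accuracy and response-time matrices sharing one item deadline."""
    acc = _read_matrix(accuracy_path, sep)
    rt = _read_matrix(rt_path, sep)
    if not acc.index.equals(rt.index) or not acc.columns.equals(rt.columns):
        raise ValueError("accuracy and rt files must share identifiers")
    both_obs = acc.notna() & rt.notna()
    acc = acc.where(both_obs)
    rt = rt.where(both_obs)
    acc = _drop_empty(acc, str(accuracy_path))
    rt = rt.loc[acc.index, acc.columns]
    rtv = rt.to_numpy(dtype=float)
    over = np.argwhere(~np.isnan(rtv) & (rtv > deadline))
    if over.size:
        r, c = over[0]
        raise ValueError(
            f"{rt_path}: response time {rtv[r, c]} exceeds the deadline {deadline} "
            f"for person {rt.index[r]!r}, item {rt.columns[c]!r}"
        )
    data = ResponseData(
        accuracy=acc.to_numpy(dtype=float), rt=rtv, deadline=float(deadline)
    )
    return Dataset(
        responses=data,
        person_ids=[str(i) for i in acc.index],
        item_ids=[str(c) for c in acc.columns],
        provenance={
            "source": [str(accuracy_path), str(rt_path)],
            "kind": "responses",
            "deadline": float(deadline),
        },
    )


def read_dataset(path: str | Path, sidecar: str | Path | None = None) -> Dataset:
    """Read a dataset using an optional YAML sidecar for metadata.

    The sidecar may specify ``kind`` (scores/responses), ``n_categories``,
    ``deadline``, ``rt_path``, and ``sep``.
    """
    meta: dict = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    sep = meta.get("sep", ",")
    if meta.get("kind", "scores") == "responses":
        if "deadline" not in meta or "rt_path" not in meta:
            raise ValueError("responses sidecar must provide 'deadline' and 'rt_path'")
        rt_path = Path(path).parent / meta["rt_path"]
        ds = read_responses(path, rt_path, float(meta["deadline"]), sep=sep)
    else:
        ds = read_scores(path, int(meta.get("n_categories", 4)), sep=sep)
    ds.provenance.update({k: v for k, v in meta.items() if k != "kind"})
    return ds


def write_scores(
    dataset: Dataset, path: str | Path, sidecar: str | Path | None = None, sep: str = ","
) -> None:
    """Write a score matrix (missing as NA) plus an optional YAML sidecar."""
    if dataset.scores is None:
        raise ValueError("dataset holds raw responses, not scores")
    vals = dataset.scores.scores.astype(object)
    df = pd.DataFrame(vals, index=dataset.person_ids, columns=dataset.item_ids)
    df = df.where(df != MISSING, other=pd.NA)
    df.to_csv(path, sep=sep, na_rep="NA", index_label="person")
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            yaml.safe_dump(
                {"kind": "scores", "n_categories": dataset.scores.n_categories}
                | {"provenance": dataset.provenance},
                fh,
                sort_keys=True,
            )


def fit_to_dict(fit: FitResult) -> dict:
    """JSON-serializable representation of a fit (round-trips via fit_from_dict)."""
    return {
        "model": fit.model,
        "item_estimates": {k: np.asarray(v).tolist() for k, v in fit.item_estimates.items()},
        "rho_estimate": fit.rho_estimate,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "bic": fit.bic,
        "n_params": fit.n_params,
        "converged": bool(fit.converged),
        "n_iterations": fit.n_iterations,
        "n_persons": fit.n_persons,
        "n_items": fit.n_items,
        "n_categories": fit.n_categories,
        "nodes_per_dim": fit.quad.nodes_per_dim,
        "scoring": {k: np.asarray(v).tolist() for k, v in fit.scoring.items()}
        if fit.scoring
        else None,
    }


def fit_from_dict(d: dict) -> FitResult:
    from dsrt.estimate import _raw_from_dict

    est = {k: np.asarray(v, dtype=float) for k, v in d["item_estimates"].items()}
    scoring = (
        {k: np.asarray(v, dtype=float) for k, v in d["scoring"].items()}
        if d.get("scoring")
        else None
    )
    return FitResult(
        model=d["model"],
        item_estimates=est,
        rho_estimate=d.get("rho_estimate"),
        loglik=d["loglik"],
        aic=d["aic"],
        bic=d["bic"],
        n_params=d["n_params"],
        converged=d["converged"],
        n_iterations=d["n_iterations"],
        n_persons=d["n_persons"],
        n_items=d["n_items"],
        n_categories=d["n_categories"],
        quad=QuadratureSpec(d.get("nodes_per_dim", 21)),
        scoring=scoring,
        raw_params=_raw_from_dict(d["model"], est),
    )


def save_fit(fit: FitResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=1)


def load_fit(path: str | Path) -> FitResult:
    with open(path) as fh:
        return fit_from_dict(json.load(fh))
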