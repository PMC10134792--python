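"""Multinomial-regression differential ranking of features against response.

Each dataset is fit independently with a per-feature intercept and a single
binary response covariate under a softmax link and an L2 penalty.  The
response coefficients, mean-centered across features, are the
"differentials": the centered log-fold change of each feature associated
with response.  Only ranks and signs are interpretable; the centering makes
the coefficients sum to zero by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import softmax

from metabiomark.data_model import FeatureTable, SampleRecord, as_model_counts

__all__ = ["AssociationCall", "DifferentialResult", "call_top_k", "fit_differentials"]


@dataclass
class DifferentialResult:
    """Centered response coefficients for one dataset, sorted for ranking."""

    study: str
    feature_ids: list[str]
    differentials: dict[str, float]
    rank_order: list[str]
    fit_info: dict = field(default_factory=dict)

    def differential_array(self) -> np.ndarray:
        return np.array([self.differentials[f] for f in self.feature_ids])


@dataclass(frozen=True)
class AssociationCall:
    """Direction call for one feature in one study: RMI, UMI or none."""

    feature_id: str
    study: str
    call: str

    def __post_init__(self) -> None:
        if self.call not in {"RMI", "UMI", "none"}:
            raise ValueError(f"call must be RMI, UMI or none, got {self.call!r}")


def _negative_penalized_loglik(
    params: np.ndarray, counts: np.ndarray, x: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    n, j = counts.shape
    b0 = params[:j]
    b1 = params[j:]
    eta = b0[None, :] + x[:, None] * b1[None, :]
    eta_shift = eta - eta.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(eta_shift).sum(axis=1)) + eta.max(axis=1)
    depths = counts.sum(axis=1)
    loglik = float((counts * eta).sum() - (depths * log_z).sum())
    probs = softmax(eta, axis=1)
    grad_eta = depths[:, None] * probs - counts
    g0 = grad_eta.sum(axis=0) + 2.0 * lam * b0
    g1 = (grad_eta * x[:, None]).sum(axis=0) + 2.0 * lam * b1
    value = -loglik + lam * float(b0 @ b0 + b1 @ b1)
    return value, np.concatenate([g0, g1])


def fit_differentials(
    table: FeatureTable,
    metadata: Sequence[SampleRecord],
    formula_covariate: str = "response",
    regularization: float = 0.1,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
    study: str | None = None,
) -> DifferentialResult:
    """Fit the multinomial response model and return centered differentials.

    Only samples labelled R or NR are used; both groups need at least two
    samples.  The fit is deterministic (zero initialisation); ``seed`` is
    recorded for provenance.  Relative-abundance tables are rescaled to a
    pseudo-depth before fitting (see :func:`as_model_counts`).
    """
    if formula_covariate != "response":
        raise ValueError("only the response covariate is supported")
    if regularization <= 0:
        raise ValueError("regularization must be positive")

    by_sample = {r.sample_id: r for r in metadata}
    kept = [
        s
        for s in table.sample_ids
        if s in by_sample and by_sample[s].response in {"R", "NR"}
    ]
    n_r = sum(1 for s in kept if by_sample[s].response == "R")
    n_nr = len(kept) - n_r
    if n_r < 2 or n_nr < 2:
        raise ValueError(f"need >=2 samples per group, got R={n_r}, NR={n_nr}")

    sub = as_model_counts(table.subset_samples(kept))
    counts = sub.values.T  # samples x features
    depths = counts.sum(axis=1)
    if np.any(depths <= 0):
        empty = [s for s, d in zip(kept, depths) if d <= 0]
        warnings.warn(f"dropping {len(empty)} zero-depth sample(s)", stacklevel=2)
        keep_rows = depths > 0
        counts = counts[keep_rows]
        kept = [s for s, ok in zip(kept, keep_rows) if ok]
    x = np.array([1.0 if by_sample[s].response == "R" else 0.0 for s in kept])
    if x.sum() < 2 or (len(x) - x.sum()) < 2:
        raise ValueError("need >=2 non-empty samples per group")

    j = sub.n_features
    res = minimize(
        _negative_penalized_loglik,
        np.zeros(2 * j),
        args=(counts, x, regularization),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-6},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"differential fit did not converge after {res.nit} iterations: {res.message}",
            stacklevel=2,
        )
    beta1 = res.x[j:]
    centered = beta1 - beta1.mean()
    differentials = {f: float(d) for f, d in zip(sub.feature_ids, centered)}
    rank_order = sorted(sub.feature_ids, key=lambda f: (-differentials[f], f))
    study_name = study if study is not None else (metadata[0].study if metadata else "")
    return DifferentialResult(
        study=study_name,
        feature_ids=list(sub.feature_ids),
        differentials=differentials,
        rank_order=rank_order,
        fit_info={
            "iterations": int(res.nit),
            "final_objective": float(res.fun),
            "converged": converged,
            "seed": int(seed),
            "n_samples": len(kept),
            "n_R": int(x.sum()),
            "n_NR": int(len(x) - x.sum()),
            "regularization": float(regularization),
        },
    )


def call_top_k(result: DifferentialResult, k: int) -> list[AssociationCall]:
    """Top-k association calls from a ranked differential result.

    Up to ``k`` RMI calls go to the highest strictly positive differentials
    and up to ``k`` UMI calls to the lowest strictly negative ones; zero
    differentials are never called.  Ties at the k-th slot keep the
    lexicographically smaller feature id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(result.feature_ids)
    if k > n:
        warnings.warn(f"k={k} exceeds feature count {n}; truncating", stacklevel=2)
        k = n
    positive = [f for f in result.rank_order if result.differentials[f] > 0]
    negative = [f for f in result.rank_order[::-1] if result.differentials[f] < 0]
    # rank_order breaks ties by ascending id; reversing flips that for the
    # negative tail, so re-sort to keep the documented tie-break.
    negative = sorted(negative, key=lambda f: (result.differentials[f], f))
    rmi = set(positive[:k])
    umi = set(negative[:k])
    calls = []
    for f in result.feature_ids:
        call = "RMI" if f in rmi else "UMI" if f in umi else "none"
        calls.append(AssociationCall(f, result.study, call))
    return calls
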