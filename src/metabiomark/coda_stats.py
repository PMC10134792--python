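"""Compositional and nonparametric statistics.

Log-ratio assessment, Wilcoxon rank-sum, Benjamini-Hochberg adjustment,
Aitchison and Bray-Curtis distances, and PERMANOVA on an arbitrary distance
matrix.  Natural logarithms are used throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from metabiomark.data_model import FeatureTable, SampleRecord

__all__ = [
    "LogRatioResult",
    "PermanovaResult",
    "aitchison_distance",
    "aitchison_distance_matrix",
    "assess_log_ratio",
    "benjamini_hochberg",
    "bray_curtis",
    "bray_curtis_matrix",
    "log_ratio",
    "permanova",
    "wilcoxon_rank_sum",
]


@dataclass
class LogRatioResult:
    """Per-sample log of summed numerator over summed denominator abundances.

    Samples where either side sums to zero are dropped (and counted) rather
    than pseudocounted, matching the drop-and-count convention of log-ratio
    visualisation tools.
    """

    numerator_set: frozenset[str]
    denominator_set: frozenset[str]
    per_sample_log_ratio: dict[str, float]
    n_dropped: int
    dropped_samples: list[str] = field(default_factory=list)
    group_p_value: float | None = None
    test: str | None = None


@dataclass
class PermanovaResult:
    """Permutational multivariate analysis of variance summary."""

    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


def log_ratio(
    table: FeatureTable,
    numerator: Iterable[str],
    denominator: Iterable[str],
) -> LogRatioResult:
    """Natural log of (sum of numerator features / sum of denominator features).

    ``numerator`` and ``denominator`` must be disjoint; features missing from
    the table are ignored, but each side must intersect the table.
    """
    num = frozenset(numerator)
    den = frozenset(denominator)
    if not num or not den:
        raise ValueError("numerator and denominator must be non-empty")
    if num & den:
        raise ValueError(f"numerator and denominator overlap: {sorted(num & den)[:5]}")
    present = set(table.feature_ids)
    num_present = sorted(num & present)
    den_present = sorted(den & present)
    if not num_present:
        raise ValueError("no numerator feature present in the table")
    if not den_present:
        raise ValueError("no denominator feature present in the table")

    num_rows = [table.feature_index(f) for f in num_present]
    den_rows = [table.feature_index(f) for f in den_present]
    num_sum = table.values[num_rows, :].sum(axis=0)
    den_sum = table.values[den_rows, :].sum(axis=0)

    values: dict[str, float] = {}
    dropped: list[str] = []
    for j, sample in enumerate(table.sample_ids):
        if num_sum[j] <= 0 or den_sum[j] <= 0:
            dropped.append(sample)
        else:
            values[sample] = float(np.log(num_sum[j] / den_sum[j]))
    return LogRatioResult(num, den, values, len(dropped), dropped)


def assess_log_ratio(
    table: FeatureTable,
    numerator: Iterable[str],
    denominator: Iterable[str],
    records: Sequence[SampleRecord],
    groups: tuple[str, str] = ("R", "NR"),
) -> LogRatioResult:
    """Log-ratio per sample plus a two-sided rank-sum test between groups."""
    result = log_ratio(table, numerator, denominator)
    by_sample = {r.sample_id: r.response for r in records}
    a = [v for s, v in result.per_sample_log_ratio.items() if by_sample.get(s) == groups[0]]
    b = [v for s, v in result.per_sample_log_ratio.items() if by_sample.get(s) == groups[1]]
    if a and b:
        result.group_p_value = wilcoxon_rank_sum(a, b)
        result.test = f"wilcoxon_rank_sum[{groups[0]} vs {groups[1]}]"
    return result


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``auto`` uses exact enumeration when both groups have at most 12
    observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = "exact" if (a.size <= 12 and b.size <= 12 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode is only defined for tie-free data")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; returns q-values in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _clr(v: np.ndarray) -> np.ndarray:
    logs = np.log(v)
    return logs - logs.mean()


def aitchison_distance(
    x: Sequence[float], y: Sequence[float], pseudocount: float = 0.0
) -> float:
    """Euclidean distance between centered-log-ratio transforms.

    A positive ``pseudocount`` is required whenever either vector contains
    zeros; the transform is scale-invariant, so the two compositions need
    not share a total.
    """
    x = np.asarray(x, dtype=float) + pseudocount
    y = np.asarray(y, dtype=float) + pseudocount
    if x.shape != y.shape:
        raise ValueError("compositions must share a feature set")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("zero entries require a positive pseudocount")
    return float(np.linalg.norm(_clr(x) - _clr(y)))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min)/(sum(x)+sum(y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share a feature set")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("vectors must be non-negative")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def aitchison_distance_matrix(table: FeatureTable, pseudocount: float = 1.0) -> np.ndarray:
    """Pairwise Aitchison distances between samples (square matrix)."""
    v = table.values.T + pseudocount
    if np.any(v <= 0):
        raise ValueError("zero entries require a positive pseudocount")
    logs = np.log(v)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return squareform(pdist(clr, metric="euclidean"))


def bray_curtis_matrix(table: FeatureTable) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities between samples (square matrix)."""
    if np.any(table.values.sum(axis=0) == 0):
        raise ValueError("all-zero sample column; Bray-Curtis undefined")
    return squareform(pdist(table.values.T, metric="braycurtis"))


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for level in levels:
        mask = labels == level
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss_total, ss_within


def _pseudo_f(ss_total: float, ss_within: float, n: int, g: int) -> float:
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g)) if ss_within > 0 else np.inf


def permanova(
    dist: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a square distance matrix.

    The pseudo-F statistic is computed from the standard sums-of-squares
    decomposition of squared distances; the p-value comes from free label
    permutations with the +1 small-sample correction, or from exhaustive
    enumeration of all label arrangements when ``exhaustive`` is set
    (feasible for n <= 10).
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray([str(x) for x in labels])
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if labels.size != n:
        raise ValueError("one label per sample required")
    levels, counts = np.unique(labels, return_counts=True)
    if levels.size < 2:
        raise ValueError("at least two groups required")
    if np.any(counts < 2):
        singles = levels[counts < 2].tolist()
        raise ValueError(f"singleton group(s): {singles}")

    g = levels.size
    d2 = dist**2
    ss_total, ss_within = _permanova_ss(d2, labels, levels)
    f_obs = _pseudo_f(ss_total, ss_within, n, g)
    r2 = float((ss_total - ss_within) / ss_total) if ss_total > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    eps = 1e-12

    if exhaustive:
        if n > 10:
            raise ValueError("exhaustive enumeration limited to n <= 10")
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm_labels = labels[list(perm)]
            _, ss_w = _permanova_ss(d2, perm_labels, levels)
            if _pseudo_f(ss_total, ss_w, n, g) >= f_obs - eps:
                hits += 1
            total += 1
        p = hits / total
        return PermanovaResult(r2, float(f_obs), float(p), total, None)

    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm_labels = rng.permutation(labels)
        _, ss_w = _permanova_ss(d2, perm_labels, levels)
        if _pseudo_f(ss_total, ss_w, n, g) >= f_obs - eps:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(r2, float(f_obs), float(p), n_permutations, seed)
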