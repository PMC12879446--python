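"""Consistency and contrast statistics for correlation matrices.

Implements the randomization machinery used to ask whether connectivity
structure is shared: the observed statistic is the mean absolute difference
of corresponding correlations between two matrices, and the null is built
by randomly permuting the unique off-diagonal entries of each matrix
(symmetry and the diagonal preserved, so the null keeps the value multiset
and destroys only the structure). The observed value is located in the
pooled null with the empirical CDF; quantiles below 0.05 indicate more
similarity than chance. Also provides a split-half within-recording
variant, a Kolmogorov-Smirnov normality screen, and a two-sided Wilcoxon
rank-sum test (exact by enumeration for small samples, tie-corrected
normal approximation otherwise).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .connectivity import CorrMatrix, RegionTable, correlation_matrix, unit_traces
from .exceptions import StatsError
from .preprocess import HemoStack

__all__ = [
    "RandomizationResult",
    "RankSumResult",
    "matrix_delta",
    "shuffle_matrix",
    "align_matrices",
    "between_individual_test",
    "split_half_test",
    "split_half_from_traces",
    "normality_check",
    "rank_sum_test",
]


@dataclass
class RandomizationResult:
    """Outcome of a matrix-shuffling randomization test.

    ``quantile`` is the empirical-CDF position of the observed delta in the
    pooled null: the fraction of null deltas <= observed. It is 0 only when
    the observed value lies below every null draw.
    """

    observed_delta: float
    null_deltas: np.ndarray
    quantile: float
    n_shuffles: int
    pair_ids: list[tuple[int, int]]
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_delta": self.observed_delta,
            "quantile": self.quantile,
            "n_shuffles": self.n_shuffles,
            "n_null": int(len(self.null_deltas)),
            "pair_ids": [list(p) for p in self.pair_ids],
            "seed": self.seed,
        }


@dataclass
class RankSumResult:
    """Two-sided Wilcoxon rank-sum outcome (statistic = rank sum of sample 1)."""

    statistic: float
    z_value: float
    p_two_sided: float
    n1: int
    n2: int
    method: str = "normal"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "z_value": self.z_value,
            "p_two_sided": self.p_two_sided,
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
        }


def align_matrices(matrices: Sequence[CorrMatrix]) -> list[CorrMatrix]:
    """Subset and reorder matrices onto their shared units.

    Units are matched by (name, hemisphere) when those labels exist, else by
    unit id; each output matrix covers exactly the shared units, in one
    canonical order with canonical unit ids, so they are directly comparable
    by :func:`matrix_delta`. Raises when fewer than three units are shared.
    """
    import pandas as pd

    def keys(m: CorrMatrix) -> list:
        lab = m.labels
        if "name" in lab.columns and "hemisphere" in lab.columns:
            return list(zip(lab["name"], lab["hemisphere"]))
        return lab["unit_id"].tolist()

    all_keys = [keys(m) for m in matrices]
    common = [k for k in all_keys[0] if all(k in ks for ks in all_keys[1:])]
    if len(common) < 3:
        raise StatsError(
            f"only {len(common)} units shared across matrices; need >= 3"
        )
    out = []
    for m, ks in zip(matrices, all_keys):
        pos = np.array([ks.index(k) for k in common])
        lab = m.labels.iloc[pos].copy().reset_index(drop=True)
        lab["unit_id"] = np.arange(1, len(common) + 1)
        out.append(
            CorrMatrix(m.values[np.ix_(pos, pos)], lab, level=m.level,
                       ordering="aligned")
        )
    return out


def _check_compatible(a: CorrMatrix, b: CorrMatrix) -> None:
    ia = a.labels["unit_id"].to_numpy()
    ib = b.labels["unit_id"].to_numpy()
    if a.n != b.n or not np.array_equal(ia, ib):
        raise StatsError(
            f"matrices have incompatible labels: {ia.tolist()} vs {ib.tolist()}"
        )


def matrix_delta(a: CorrMatrix, b: CorrMatrix) -> float:
    """Mean absolute difference of corresponding unique off-diagonal pairs."""
    _check_compatible(a, b)
    return float(np.mean(np.abs(a.off_diagonal() - b.off_diagonal())))


def shuffle_matrix(
    corr: CorrMatrix,
    seed: int | np.random.Generator = 0,
    unit: str = "entries",
) -> CorrMatrix:
    """Randomly permute a correlation matrix under the chosen null.

    ``unit="entries"`` (default) permutes the unique off-diagonal entries
    and writes them back symmetrically, preserving the value multiset and
    the unit diagonal; ``unit="labels"`` applies one random simultaneous
    row/column permutation instead.
    """
    if corr.n < 3:
        raise StatsError("shuffling needs at least a 3x3 matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = corr.values.copy()
    if unit == "entries":
        iu = np.triu_indices(corr.n, k=1)
        vals = v[iu]
        vals = vals[rng.permutation(len(vals))]
        v[iu] = vals
        v.T[iu] = vals
    elif unit == "labels":
        p = rng.permutation(corr.n)
        v = v[np.ix_(p, p)]
    else:
        raise StatsError(f"unknown shuffle unit {unit!r}")
    return CorrMatrix(v, corr.labels, level=corr.level, ordering=corr.ordering)


def _ecdf_quantile(null: np.ndarray, observed: float) -> float:
    return float(np.mean(null <= observed))


def _randomization(
    matrices: Sequence[CorrMatrix],
    n_shuffles: int,
    seed: int,
    shuffle_unit: str = "entries",
) -> RandomizationResult:
    if len(matrices) < 2:
        raise StatsError("need at least two matrices")
    for m in matrices[1:]:
        _check_compatible(matrices[0], m)
    pairs = list(combinations(range(len(matrices)), 2))
    observed = float(np.mean([matrix_delta(matrices[i], matrices[j]) for i, j in pairs]))
    rng = np.random.default_rng(seed)
    null = np.empty(len(pairs) * n_shuffles)
    k = 0
    for i, j in pairs:
        for _ in range(n_shuffles):
            a = shuffle_matrix(matrices[i], rng, unit=shuffle_unit)
            b = shuffle_matrix(matrices[j], rng, unit=shuffle_unit)
            null[k] = matrix_delta(a, b)
            k += 1
    return RandomizationResult(
        observed_delta=observed,
        null_deltas=null,
        quantile=_ecdf_quantile(null, observed),
        n_shuffles=n_shuffles,
        pair_ids=pairs,
        seed=seed,
    )


def between_individual_test(
    matrices: Sequence[CorrMatrix],
    n_shuffles: int = 1000,
    seed: int = 0,
    shuffle_unit: str = "entries",
) -> RandomizationResult:
    """Are individuals' correlation structures more alike than chance?

    The observed delta is the mean of :func:`matrix_delta` over all
    unordered pairs of individuals. For each pair, both matrices are
    independently shuffled ``n_shuffles`` times and each shuffled pair's
    delta enters a single pooled null; the quantile of the group-mean
    observed delta in that pooled null is the reported probability-like
    value (small = more similar than chance).
    """
    return _randomization(matrices, n_shuffles, seed, shuffle_unit)


def split_half_from_traces(
    traces: np.ndarray,
    ids: Sequence[int],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Split-half stability from (n_units, n_frames) traces directly."""
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[1]
    if n < 4:
        raise StatsError("need at least 4 frames to split")
    half = n // 2
    mats = []
    for sl in (slice(0, half), slice(half, n)):
        sub = traces[:, sl]
        sd = sub.std(axis=1)
        tol = 1e-12 * max(float(np.abs(sub).max()), 1.0)
        if np.any(sd <= tol):
            bad = [ids[i] for i in np.flatnonzero(sd <= tol)]
            raise StatsError(f"zero-variance regions in one half: {bad}")
        mats.append(correlation_matrix(sub, ids))
    return _randomization(mats, n_shuffles, seed)


def split_half_test(
    hemo: HemoStack,
    membership: Mapping[int, np.ndarray],
    table: RegionTable | None = None,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Within-recording stability: first half vs second half of the frames.

    Region matrices are computed per half (censored frames are already
    absent from the series, so the split respects them) and compared with
    exactly the machinery of :func:`between_individual_test` applied to the
    single pair of halves.
    """
    traces = unit_traces(hemo, membership)  # (units, T)
    return split_half_from_traces(traces, sorted(membership), n_shuffles, seed)


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a standard normal.

    Values are standardized first; used only to gate how results are
    reported (the pipeline always proceeds to the rank-sum test).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise StatsError(f"need at least 5 values, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise StatsError("zero-variance sample")
    z = (v - v.mean()) / sd
    res = sps.kstest(z, "norm")
    return float(res.statistic), float(res.pvalue)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses midranks for ties. For n1+n2 <= 10 the p-value is exact, by full
    enumeration of all rank assignments; otherwise a tie-corrected normal
    approximation with continuity correction is used. Swapping the samples
    negates z and preserves p. If every value is identical the test is
    degenerate and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(w, 0.0, 1.0, n1, n2, method="degenerate")
    dev = w - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if dev != 0 else 0.0
    if n <= 10:
        total = comb(n, n1)
        extreme = 0
        for idx in combinations(range(n), n1):
            ws = ranks[list(idx)].sum()
            if abs(ws - mu) >= abs(dev) - 1e-12:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal"
    return RankSumResult(w, float(z), float(p), n1, n2, method=method)
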