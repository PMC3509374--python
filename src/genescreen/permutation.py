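"""Permutation null for the exceedance-count curves.

The null distribution of the per-gene scores is obtained by scoring the
matrix against B random rearrangements of the classification vector that
preserve the class sizes n1/n2 (Monte-Carlo sampling of the randomization
distribution; full enumeration is infeasible beyond toy sample sizes —
a 27/11 split of 38 samples already admits 38!/(27!*11!) = 1,203,322,288
distinct arrangements).  For each permutation vector and each threshold r
in a grid we count the genes scoring >= r (N1) and <= -r (N2); the right
5% quantiles of those counts over the ensemble, L1^r and L2^r, form the
null envelope curves that the observed counts are compared with.

The B x n_genes null score matrix is processed one permutation at a time
and never stored (unless explicitly requested for grid refinement), so
ensembles of 500 permutations over thousands of genes run in modest
memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import ClassVector, ExpressionMatrix
from .snr import ScoreVector, _as_values, class_summaries, _scores_from_summaries

__all__ = [
    "PermutationEnsemble",
    "NullCountTable",
    "combination_count",
    "generate_null_labels",
    "enumerate_labelings",
    "exhaustive_ensemble",
    "exceedance_counts",
    "right_quantile",
    "null_count_table",
    "null_score_matrix",
    "table_from_score_matrix",
]

_ENUMERATION_CAP = 12  # full enumeration is a toy-scale testing oracle only


def combination_count(n1: int, n2: int) -> int:
    """Exact number of distinct n1/n2 class assignments of n1+n2 samples.

    This is the size of the randomization space, C(n1+n2, n1); it is the
    quantity that motivates Monte-Carlo sampling over full enumeration
    (e.g. C(38, 27) = 1,203,322,288 for a 27/11 split).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("class sizes must be nonnegative")
    return math.comb(n1 + n2, n1)


@dataclass(frozen=True)
class PermutationEnsemble:
    """B class-size-preserving permutation vectors of one labeling.

    ``perms`` has shape (B, m) with entries in {0, 1}; every row has
    exactly ``n1`` ones.  ``seed`` is None for an exhaustively enumerated
    ensemble.
    """

    perms: np.ndarray
    seed: int | None

    def __post_init__(self) -> None:
        perms = np.asarray(self.perms, dtype=np.int8)
        if perms.ndim != 2:
            raise ValueError("perms must be 2-D (B x m)")
        object.__setattr__(self, "perms", perms)
        ones = perms.sum(axis=1)
        if perms.shape[0] and not np.all(ones == ones[0]):
            raise ValueError("all permutation vectors must share the same n1")

    @property
    def B(self) -> int:
        return int(self.perms.shape[0])

    @property
    def m(self) -> int:
        return int(self.perms.shape[1])


def generate_null_labels(
    labels: ClassVector, B: int, seed: int
) -> PermutationEnsemble:
    """Draw B uniform random rearrangements of the classification vector.

    Draws are independent and with replacement from the n1/n2-preserving
    arrangement space (duplicates, including the observed labeling, are
    allowed — at realistic sample sizes the space is so large that their
    probability is negligible).  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be a positive integer")
    rng = np.random.default_rng(seed)
    base = labels.labels
    perms = np.empty((B, base.size), dtype=np.int8)
    for j in range(B):
        perms[j] = rng.permutation(base)
    return PermutationEnsemble(perms=perms, seed=seed)


def enumerate_labelings(labels: ClassVector) -> np.ndarray:
    """All C(m, n1) distinct arrangements of the labeling (toy m only)."""
    m, n1 = labels.m, labels.n1
    if m > _ENUMERATION_CAP:
        raise ValueError(
            f"full enumeration supported only for m <= {_ENUMERATION_CAP} "
            f"(got m={m}; the space has {combination_count(n1, m - n1)} members)"
        )
    out = np.zeros((math.comb(m, n1), m), dtype=np.int8)
    for row, ones in enumerate(combinations(range(m), n1)):
        out[row, list(ones)] = 1
    return out


def exhaustive_ensemble(labels: ClassVector) -> PermutationEnsemble:
    """The full randomization ensemble as a PermutationEnsemble (toy m)."""
    return PermutationEnsemble(perms=enumerate_labelings(labels), seed=None)


def exceedance_counts(scores: ScoreVector | np.ndarray, r: float) -> tuple[int, int]:
    """Tail counts at threshold r: N1 = #{score >= r}, N2 = #{score <= -r}.

    Comparisons are inclusive; infinite sentinel scores count on their
    sign's side.  ``r`` must be positive, otherwise the two tails would
    overlap at zero.
    """
    if not r > 0:
        raise ValueError("threshold r must be positive")
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    return int(np.sum(s >= r)), int(np.sum(s <= -r))


def right_quantile(values: np.ndarray, alpha: float) -> float:
    """Right-tail quantile as the k-th largest value, k = ceil(alpha * B).

    This order-statistic convention guarantees at most an ``alpha``
    fraction of the sample lies strictly above the returned value, and it
    is exact on integer counts (no interpolation): for B = 500 and
    alpha = 0.05 it returns the 25th largest count.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("right_quantile of an empty sample")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    k = math.ceil(alpha * values.size)
    return float(np.sort(values)[::-1][k - 1])


def _validate_grid(r_grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(r_grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("r_grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("r_grid thresholds must all be positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    return grid


@dataclass(frozen=True)
class NullCountTable:
    """Exceedance counts over an ensemble plus their quantile envelopes.

    ``counts_pos[j, k]`` is N1 for ensemble member j at threshold
    ``r_grid[k]`` (``counts_neg`` likewise for N2); ``l1``/``l2`` are the
    per-threshold right-``alpha`` quantiles of those columns.  Every row
    and both envelopes are nonincreasing along the grid because the
    counting is an inclusive tail count.
    """

    r_grid: np.ndarray
    counts_pos: np.ndarray
    counts_neg: np.ndarray
    l1: np.ndarray
    l2: np.ndarray
    alpha: float = 0.05


def _member_scores(values: np.ndarray, perm_row: np.ndarray) -> np.ndarray:
    return _scores_from_summaries(class_summaries(values, perm_row))


def null_count_table(
    matrix: ExpressionMatrix | np.ndarray,
    ensemble: PermutationEnsemble,
    r_grid: np.ndarray,
    alpha: float = 0.05,
) -> NullCountTable:
    """Score every ensemble member and tabulate tail counts per threshold.

    The observed labeling is not part of the ensemble statistics.  Member
    score vectors are discarded as soon as their counts are taken.
    """
    values = _as_values(matrix)
    grid = _validate_grid(r_grid)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    B = ensemble.B
    counts_pos = np.empty((B, grid.size), dtype=np.int64)
    counts_neg = np.empty((B, grid.size), dtype=np.int64)
    for j in range(B):
        s = _member_scores(values, ensemble.perms[j])
        counts_pos[j] = np.sum(s[:, None] >= grid[None, :], axis=0)
        counts_neg[j] = np.sum(s[:, None] <= -grid[None, :], axis=0)
    l1 = np.array([right_quantile(counts_pos[:, k], alpha) for k in range(grid.size)])
    l2 = np.array([right_quantile(counts_neg[:, k], alpha) for k in range(grid.size)])
    return NullCountTable(grid, counts_pos, counts_neg, l1, l2, alpha)


def null_score_matrix(
    matrix: ExpressionMatrix | np.ndarray, ensemble: PermutationEnsemble
) -> np.ndarray:
    """The full (n_genes, B) null score matrix, materialized.

    Only needed when counts must be recomputed on refined grids without
    redrawing permutations; plain envelope estimation streams instead.
    """
    values = _as_values(matrix)
    out = np.empty((values.shape[0], ensemble.B))
    for j in range(ensemble.B):
        out[:, j] = _member_scores(values, ensemble.perms[j])
    return out


def table_from_score_matrix(
    score_matrix: np.ndarray, r_grid: np.ndarray, alpha: float = 0.05
) -> NullCountTable:
    """Tabulate counts and envelopes from a retained null score matrix."""
    grid = _validate_grid(r_grid)
    counts_pos = np.sum(score_matrix[:, :, None] >= grid[None, None, :], axis=0).astype(np.int64)
    counts_neg = np.sum(score_matrix[:, :, None] <= -grid[None, None, :], axis=0).astype(np.int64)
    l1 = np.array([right_quantile(counts_pos[:, k], alpha) for k in range(grid.size)])
    l2 = np.array([right_quantile(counts_neg[:, k], alpha) for k in range(grid.size)])
    return NullCountTable(grid, counts_pos, counts_neg, l1, l2, alpha)
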