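"""Threshold selection by intersecting observed and null count curves.

Plotting the observed tail count N1(c, r) and the null envelope L1^r
against r gives two decreasing curves: with real class signal the
observed curve starts below the envelope (the null inflates small-|score|
counts) and ends above it (genuinely discriminative genes survive large
r).  The abscissa where the observed curve rises through the envelope,
found by piecewise-linear interpolation of the count difference between
adjacent grid points, is r0; the same construction on the negative tail
(in |r| coordinates, reported with a negative sign) gives t0.  The
selection threshold is r* = max{r0, |t0|}, optionally tightened by a
user-chosen adjustment a >= 0 when too many genes pass; genes with
|P| >= r* form the selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GeneSelection
from .permutation import NullCountTable, _validate_grid, exceedance_counts
from .snr import ScoreVector

__all__ = [
    "CountCurvePair",
    "ThresholdResult",
    "NoCrossingError",
    "observed_count_curve",
    "curve_intersection",
    "combine_threshold",
    "select_genes",
    "determine_threshold",
]

logger = logging.getLogger(__name__)

DEFAULT_R_GRID = np.round(np.arange(0.1, 0.65, 0.1), 10)


class NoCrossingError(RuntimeError):
    """The observed and null curves do not cross on the grid."""


@dataclass(frozen=True)
class CountCurvePair:
    """Observed counts and null quantile envelope over one r grid.

    ``tail`` is "positive" (N1 vs L1) or "negative" (N2 vs L2, indexed by
    r > 0, i.e. counts of scores <= -r).
    """

    r_grid: np.ndarray
    observed: np.ndarray
    null_quantile: np.ndarray
    tail: str = "positive"

    def __post_init__(self) -> None:
        grid = _validate_grid(self.r_grid)
        observed = np.asarray(self.observed, dtype=float).ravel()
        null_q = np.asarray(self.null_quantile, dtype=float).ravel()
        if not (grid.size == observed.size == null_q.size):
            raise ValueError("r_grid, observed and null_quantile must align")
        if self.tail not in ("positive", "negative"):
            raise ValueError("tail must be 'positive' or 'negative'")
        if np.any(np.diff(observed) > 0) or np.any(np.diff(null_q) > 0):
            raise ValueError("count curves must be nonincreasing along r_grid")
        object.__setattr__(self, "r_grid", grid)
        object.__setattr__(self, "observed", observed)
        object.__setattr__(self, "null_quantile", null_q)


@dataclass(frozen=True)
class ThresholdResult:
    """Intersection abscissas and the combined selection threshold.

    ``t0`` follows the plotting convention of the negative-tail curve and
    is stored as a negative number; ``r_star = max(r0, |t0|) + adjustment_a``.
    """

    r0: float
    t0: float
    adjustment_a: float
    r_star: float

    def rounded(self, ndigits: int = 2) -> "ThresholdResult":
        """Display rounding (the full-precision values stay canonical)."""
        return ThresholdResult(
            r0=round(self.r0, ndigits),
            t0=round(self.t0, ndigits),
            adjustment_a=self.adjustment_a,
            r_star=round(self.r_star, ndigits),
        )


def observed_count_curve(
    scores: ScoreVector | np.ndarray,
    r_grid: Sequence[float] | np.ndarray,
    tail: str = "positive",
    null_quantile: np.ndarray | None = None,
) -> CountCurvePair:
    """Tail counts of the observed scores at each grid threshold.

    ``null_quantile`` may be attached immediately (the envelope from a
    NullCountTable) or left as NaN placeholders to be paired later.
    """
    grid = _validate_grid(np.asarray(r_grid, float))
    counts = np.empty(grid.size)
    for k, r in enumerate(grid):
        n1, n2 = exceedance_counts(scores, float(r))
        counts[k] = n1 if tail == "positive" else n2
    if null_quantile is None:
        null_quantile = np.full(grid.size, np.nan)  # envelope attached later
    return CountCurvePair(grid, counts, np.asarray(null_quantile, float), tail)


def curve_intersection(pair: CountCurvePair) -> float:
    """Abscissa where the observed curve rises through the null envelope.

    The difference d(r) = observed - null_quantile is interpolated
    linearly between grid points; the first change from negative to
    positive (as r increases) is returned, or the grid point itself where
    d is exactly zero.  With real signal d is negative at small r and
    positive at large r, so exactly one crossing is expected; additional
    crossings are logged and the first is returned.
    """
    d = pair.observed - pair.null_quantile
    if np.any(np.isnan(d)):
        raise ValueError("curve pair has no null envelope attached")
    crossings: list[float] = []
    for k in range(d.size):
        if d[k] == 0:
            crossings.append(float(pair.r_grid[k]))
        elif k + 1 < d.size and d[k] < 0 < d[k + 1]:
            r_lo, r_hi = pair.r_grid[k], pair.r_grid[k + 1]
            frac = -d[k] / (d[k + 1] - d[k])
            crossings.append(float(r_lo + frac * (r_hi - r_lo)))
    if not crossings:
        raise NoCrossingError(
            f"observed and null curves do not cross on the {pair.tail} grid "
            f"[{pair.r_grid[0]:g}, {pair.r_grid[-1]:g}]; widen or refine r_grid"
        )
    if len(crossings) > 1:
        warnings.warn(
            f"multiple curve crossings on the {pair.tail} tail at {crossings}; "
            "returning the first",
            stacklevel=2,
        )
        logger.warning("multiple %s-tail crossings: %s", pair.tail, crossings)
    return crossings[0]


def combine_threshold(
    r0: float, t0: float, adjustment_a: float = 0.0
) -> ThresholdResult:
    """Combine the two tail abscissas into r* = max{r0, |t0|} + a."""
    if not r0 > 0:
        raise ValueError("r0 must be positive")
    if adjustment_a < 0:
        raise ValueError("adjustment_a must be nonnegative")
    t0_signed = -abs(float(t0))
    r_star = max(float(r0), abs(t0_signed)) + float(adjustment_a)
    return ThresholdResult(
        r0=float(r0), t0=t0_signed, adjustment_a=float(adjustment_a), r_star=r_star
    )


def select_genes(
    scores: ScoreVector | np.ndarray,
    gene_ids: Sequence[str],
    r_star: float,
) -> GeneSelection:
    """Genes with |score| >= r* (inclusive), signed by score direction.

    The selection size equals N1(c, r*) + N2(c, r*) by construction (the
    two tails are disjoint for r* > 0).
    """
    if not r_star > 0:
        raise ValueError("r_star must be positive")
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    if len(gene_ids) != s.size:
        raise ValueError("gene_ids and scores must align")
    keep = np.abs(s) >= r_star
    kept_scores = s[keep]
    return GeneSelection(
        gene_ids=tuple(g for g, k in zip(gene_ids, keep) if k),
        scores=kept_scores,
        threshold=float(r_star),
        directions=np.where(kept_scores >= 0, 1, -1),
    )


def determine_threshold(
    scores: ScoreVector | np.ndarray,
    table: NullCountTable,
    adjustment_a: float = 0.0,
) -> tuple[ThresholdResult, CountCurvePair, CountCurvePair]:
    """Build both tail curve pairs from a null table and combine r0, t0."""
    pos = observed_count_curve(scores, table.r_grid, "positive", table.l1)
    neg = observed_count_curve(scores, table.r_grid, "negative", table.l2)
    r0 = curve_intersection(pos)
    t0 = -curve_intersection(neg)
    return combine_threshold(r0, t0, adjustment_a), pos, neg
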