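"""Scikit-learn estimator wrapping the whole selection procedure.

``PermutationSNRSelector`` is a supervised feature selector: ``fit``
computes the observed per-gene signal-to-noise scores, builds the
permutation null envelope, intersects the count curves on both tails and
keeps the genes with ``|score| >= r_star``; ``transform`` then reduces a
samples-by-genes matrix to the selected panel, so the selector composes
with sklearn Pipelines and model selection.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ClassVector
from .permutation import (
    generate_null_labels,
    null_count_table,
    null_score_matrix,
    table_from_score_matrix,
)
from .snr import snr_scores
from .threshold import (
    DEFAULT_R_GRID,
    CountCurvePair,
    combine_threshold,
    curve_intersection,
    observed_count_curve,
)

__all__ = ["PermutationSNRSelector"]


def _resolve_seed(random_state) -> int:
    if random_state is None:
        return int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    if isinstance(random_state, numbers.Integral):
        return int(random_state)
    if isinstance(random_state, np.random.Generator):
        return int(random_state.integers(2**31))
    raise ValueError("random_state must be None, an int, or a numpy Generator")


def _refined_abscissa(
    observed_scores: np.ndarray,
    score_matrix: np.ndarray,
    coarse: CountCurvePair,
    alpha: float,
    tail: str,
) -> float:
    """Re-intersect on a 10x finer grid inside the coarse bracketing interval."""
    d = coarse.observed - coarse.null_quantile
    for k in range(d.size):
        if d[k] == 0:
            return float(coarse.r_grid[k])
        if k + 1 < d.size and d[k] < 0 < d[k + 1]:
            fine_grid = np.linspace(coarse.r_grid[k], coarse.r_grid[k + 1], 11)
            fine_table = table_from_score_matrix(score_matrix, fine_grid, alpha)
            envelope = fine_table.l1 if tail == "positive" else fine_table.l2
            fine = observed_count_curve(observed_scores, fine_grid, tail, envelope)
            return curve_intersection(fine)
    return curve_intersection(coarse)  # raises NoCrossingError


class PermutationSNRSelector(SelectorMixin, BaseEstimator):
    """Select genes whose signal-to-noise score exceeds a permutation-
    calibrated threshold.

    Parameters
    ----------
    n_permutations : int, default=500
        Ensemble size B of random class-size-preserving relabelings.
    alpha : float, default=0.05
        Right-tail fraction of the null envelope (right 5% quantile).
    r_grid : array-like of float or None, default=None
        Strictly increasing positive thresholds; None means 0.1-0.6 in
        steps of 0.1.
    adjustment : float, default=0.0
        Nonnegative additive tightening ``a`` of the final threshold,
        for when too many genes pass.
    refine : bool, default=False
        Re-intersect on a 10x finer grid inside the bracketing interval
        (retains the null score matrix in memory).
    random_state : int, numpy Generator or None, default=None
        Seed for the permutation ensemble; the seed actually used is
        stored as ``seed_``.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Observed per-gene signal-to-noise scores.
    null_table_ : NullCountTable
        Permutation exceedance counts and quantile envelopes.
    r0_, t0_ : float
        Curve-intersection abscissas (``t0_`` is negative).
    r_star_ : float
        Final selection threshold ``max(r0, |t0|) + adjustment``.
    support_ : ndarray of bool, shape (n_features,)
        Mask of selected genes.

    Examples
    --------
    >>> from genescreen import PermutationSNRSelector, simulate, SimulationSpec
    >>> matrix, labels, truth = simulate(SimulationSpec(n_genes=300, seed=7))
    >>> sel = PermutationSNRSelector(n_permutations=100, random_state=0)
    >>> X_sel = sel.fit_transform(matrix.values.T, labels.labels)
    >>> X_sel.shape[0] == matrix.n_samples
    True
    """

    def __init__(
        self,
        n_permutations: int = 500,
        alpha: float = 0.05,
        r_grid=None,
        adjustment: float = 0.0,
        refine: bool = False,
        random_state=None,
    ):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.r_grid = r_grid
        self.adjustment = adjustment
        self.refine = refine
        self.random_state = random_state

    def fit(self, X, y):
        """Learn the threshold and support from (n_samples, n_features) data.

        ``y`` must take exactly two values with at least two samples
        each; the larger value (in sort order) plays the role of class A
        (label 1).
        """
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"expected exactly 2 classes, got {classes.size}")
        binary = (y == classes[1]).astype(np.int8)
        labels = ClassVector(binary)
        values = X.T

        grid = np.asarray(
            DEFAULT_R_GRID if self.r_grid is None else self.r_grid, dtype=float
        )
        self.seed_ = _resolve_seed(self.random_state)
        ensemble = generate_null_labels(labels, int(self.n_permutations), self.seed_)

        self.scores_ = snr_scores(values, labels).scores
        if self.refine:
            scores_null = null_score_matrix(values, ensemble)
            self.null_table_ = table_from_score_matrix(scores_null, grid, self.alpha)
        else:
            scores_null = None
            self.null_table_ = null_count_table(values, ensemble, grid, self.alpha)

        pos = observed_count_curve(self.scores_, grid, "positive", self.null_table_.l1)
        neg = observed_count_curve(self.scores_, grid, "negative", self.null_table_.l2)
        if self.refine:
            r0 = _refined_abscissa(self.scores_, scores_null, pos, self.alpha, "positive")
            t0_mag = _refined_abscissa(self.scores_, scores_null, neg, self.alpha, "negative")
        else:
            r0 = curve_intersection(pos)
            t0_mag = curve_intersection(neg)
        result = combine_threshold(r0, -t0_mag, self.adjustment)

        self.classes_ = classes
        self.curve_pos_ = pos
        self.curve_neg_ = neg
        self.threshold_result_ = result
        self.r0_ = result.r0
        self.t0_ = result.t0
        self.r_star_ = result.r_star
        self.support_ = np.abs(self.scores_) >= self.r_star_
        self.n_selected_ = int(self.support_.sum())
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
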