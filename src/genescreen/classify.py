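"""Two-class discrimination over a selected gene panel.

The selection stage only says which genes discriminate; turning them
into a class call needs a discrimination function, and no single
canonical choice exists for this family of methods.  The default here is
the classical companion of the signal-to-noise statistic: a weighted
vote toward the nearer class centroid.  For each selected gene the model
stores the two training class means (centroids) and a weight |P(g, c)|;
a new sample casts, per gene, a vote of that weight for whichever
centroid its value is closer to, and the class with the larger total
vote wins.  Exact per-gene equidistance casts no vote; a total-vote tie
is broken deterministically toward class A and logged.  The reported
margin is |vote_A - vote_B| / (vote_A + vote_B), in [0, 1].

Error rates are plain misclassification fractions — retrospective when
evaluated on the training samples, prospective on an independent cohort.
The stage is pluggable: any classifier consuming the selected-gene
submatrix can replace it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ClassVector, ExpressionMatrix, GeneSelection
from .snr import class_summaries, snr_scores

__all__ = [
    "CentroidModel",
    "fit_classifier",
    "classify",
    "error_rate",
    "WeightedVotingClassifier",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CentroidModel:
    """Per-gene class centroids and |score| voting weights."""

    gene_ids: tuple[str, ...]
    centroid_a: np.ndarray
    centroid_b: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if not (self.centroid_a.size == self.centroid_b.size == self.weights.size == n):
            raise ValueError("model vectors must align with gene_ids")
        if np.any(self.weights <= 0):
            raise ValueError("voting weights must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "centroid_a": self.centroid_a,
                "centroid_b": self.centroid_b,
                "weight": self.weights,
            }
        )


def _vote(values: np.ndarray, model: CentroidModel) -> tuple[np.ndarray, np.ndarray]:
    """Total votes (vote_a, vote_b) for samples in columns of ``values``."""
    da = np.abs(values - model.centroid_a[:, None])
    db = np.abs(values - model.centroid_b[:, None])
    w = model.weights[:, None]
    vote_a = np.sum(np.where(da < db, w, 0.0), axis=0)
    vote_b = np.sum(np.where(db < da, w, 0.0), axis=0)
    return vote_a, vote_b


def fit_classifier(
    matrix: ExpressionMatrix,
    labels: ClassVector,
    selection: GeneSelection,
) -> CentroidModel:
    """Fit centroids and |score| weights on training data, selected genes only."""
    if len(selection) == 0:
        raise ValueError("cannot fit a discrimination model on an empty selection")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in selection.gene_ids if g not in index]
    if missing:
        raise ValueError(f"selected gene(s) absent from matrix: {missing}")
    rows = [index[g] for g in selection.gene_ids]
    sub = matrix.values[rows, :]
    summ = class_summaries(sub, labels)
    # weights come from the training data restricted to the panel; infinite
    # sentinel scores get a large finite weight so votes stay comparable
    raw = snr_scores(sub, labels).scores
    finite = np.abs(raw[np.isfinite(raw)])
    cap = 10.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
    weights = np.where(np.isfinite(raw), np.abs(raw), cap)
    weights = np.where(weights > 0, weights, np.finfo(float).tiny)
    return CentroidModel(
        gene_ids=tuple(selection.gene_ids),
        centroid_a=summ.mu_a,
        centroid_b=summ.mu_b,
        weights=weights,
    )


def classify(
    model: CentroidModel,
    sample: Mapping[str, float] | pd.Series,
) -> tuple[int, float]:
    """Classify one sample; returns (predicted label, margin).

    The predicted label is 1 for class A, 0 for class B; the margin is
    the normalized vote imbalance.  Every model gene must be present in
    the sample.
    """
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    missing = [g for g in model.gene_ids if g not in sample]
    if missing:
        raise ValueError(f"sample is missing model gene(s): {missing}")
    vec = np.array([[float(sample[g])] for g in model.gene_ids])
    vote_a, vote_b = _vote(vec, model)
    va, vb = float(vote_a[0]), float(vote_b[0])
    total = va + vb
    margin = abs(va - vb) / total if total > 0 else 0.0
    if va == vb:
        logger.info("vote tie (%.6g vs %.6g); breaking toward class A", va, vb)
        return 1, margin
    return (1 if va > vb else 0), margin


def error_rate(
    model: CentroidModel,
    matrix: ExpressionMatrix,
    labels: ClassVector,
) -> float:
    """Misclassification fraction of the model on a labeled matrix."""
    if labels.m != matrix.n_samples:
        raise ValueError("labels are not aligned with the matrix samples")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in model.gene_ids if g not in index]
    if missing:
        raise ValueError(f"matrix is missing model gene(s): {missing}")
    sub = matrix.values[[index[g] for g in model.gene_ids], :]
    vote_a, vote_b = _vote(sub, model)
    predicted = np.where(vote_a >= vote_b, 1, 0)  # ties toward class A
    return float(np.mean(predicted != labels.labels))


class WeightedVotingClassifier(ClassifierMixin, BaseEstimator):
    """Signal-to-noise-weighted nearest-centroid voting, sklearn style.

    Expects ``X`` of shape (n_samples, n_features) already restricted to
    a discriminative panel (e.g. by ``PermutationSNRSelector`` in a
    Pipeline).  The larger of the two class labels plays the role of
    class A in the tie-break.
    """

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"expected exactly 2 classes, got {self.classes_.size}"
            )
        binary = (y == self.classes_[1]).astype(np.int8)
        if binary.sum() < 2 or (1 - binary).sum() < 2:
            raise ValueError("each class needs at least 2 training samples")
        values = X.T  # genes in rows internally
        summ = class_summaries(values, binary)
        raw = snr_scores(values, binary).scores
        finite = np.abs(raw[np.isfinite(raw)])
        cap = 10.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
        weights = np.where(np.isfinite(raw), np.abs(raw), cap)
        self.model_ = CentroidModel(
            gene_ids=tuple(f"f{i}" for i in range(values.shape[0])),
            centroid_a=summ.mu_a,
            centroid_b=summ.mu_b,
            weights=np.where(weights > 0, weights, np.finfo(float).tiny),
        )
        return self

    def decision_function(self, X):
        """Signed vote imbalance (positive favors class A = classes_[1])."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        vote_a, vote_b = _vote(X.T, self.model_)
        return vote_a - vote_b

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])

    def vote_margin(self, X):
        """Normalized vote imbalance |vA - vB| / (vA + vB) per sample."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        vote_a, vote_b = _vote(X.T, self.model_)
        total = vote_a + vote_b
        with np.errstate(invalid="ignore"):
            margin = np.where(total > 0, np.abs(vote_a - vote_b) / total, 0.0)
        return margin
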