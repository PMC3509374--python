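"""Per-gene signal-to-noise scores against a binary classification vector.

For gene ``g`` with class means ``mu_A, mu_B`` and sample standard
deviations ``sigma_A, sigma_B`` (``n - 1`` denominator), the score is

    P(g, c) = (mu_A - mu_B) / (sigma_A + sigma_B)

the classical signal-to-noise (Golub-style) statistic.  It is unbounded
— despite the name "correlation" sometimes used for it — and is applied
literally, without clipping.  The score is invariant to positive affine
rescaling of a gene's row and is negated by swapping the class roles.

Zero-denominator rule: a gene constant within both classes but with
different class means is maximally discriminative, so it receives a
``+inf``/``-inf`` sentinel carrying the sign of the mean difference; a
gene whose class means also agree is uninformative and scores 0.  The
sentinels compare correctly (beyond any finite threshold) in all
downstream counting, and are serialized as ``inf``/``-inf`` tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ClassVector, ExpressionMatrix

__all__ = ["ClassSummaries", "ScoreVector", "class_summaries", "snr_scores"]


@dataclass(frozen=True)
class ClassSummaries:
    """Per-gene class means and standard deviations (expression units)."""

    mu_a: np.ndarray
    sigma_a: np.ndarray
    mu_b: np.ndarray
    sigma_b: np.ndarray

    def __post_init__(self) -> None:
        n = self.mu_a.size
        if not (self.sigma_a.size == self.mu_b.size == self.sigma_b.size == n):
            raise ValueError("summary vectors must share one length")
        if np.any(self.sigma_a < 0) or np.any(self.sigma_b < 0):
            raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class ScoreVector:
    """Per-gene scores for one labeling, tagged by ``labeling_id``."""

    scores: np.ndarray
    labeling_id: str = "observed"

    def __len__(self) -> int:
        return int(self.scores.size)


def _as_values(matrix: ExpressionMatrix | np.ndarray) -> np.ndarray:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    if values.ndim != 2:
        raise ValueError("expression values must be 2-D (genes x samples)")
    return values


def _as_labels(labels: ClassVector | np.ndarray, m: int) -> np.ndarray:
    lab = labels.labels if isinstance(labels, ClassVector) else np.asarray(labels, np.int8)
    if lab.size != m:
        raise ValueError(f"labels have length {lab.size} but matrix has {m} samples")
    return lab


def class_summaries(
    matrix: ExpressionMatrix | np.ndarray, labels: ClassVector | np.ndarray
) -> ClassSummaries:
    """Per-gene mean and sample (``n - 1``) standard deviation per class."""
    values = _as_values(matrix)
    lab = _as_labels(labels, values.shape[1])
    in_a = lab == 1
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    a = values[:, in_a]
    b = values[:, ~in_a]
    return ClassSummaries(
        mu_a=a.mean(axis=1),
        sigma_a=a.std(axis=1, ddof=1),
        mu_b=b.mean(axis=1),
        sigma_b=b.std(axis=1, ddof=1),
    )


def _scores_from_summaries(s: ClassSummaries) -> np.ndarray:
    num = s.mu_a - s.mu_b
    den = s.sigma_a + s.sigma_b
    out = np.empty_like(num)
    zero = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(num, den, out=out, where=~zero)
    out[zero] = np.sign(num[zero]) * np.inf
    out[zero & (num == 0)] = 0.0
    return out


def snr_scores(
    matrix: ExpressionMatrix | np.ndarray,
    labels: ClassVector | np.ndarray,
    labeling_id: str = "observed",
) -> ScoreVector:
    """Signal-to-noise score of every gene against one labeling."""
    return ScoreVector(
        scores=_scores_from_summaries(class_summaries(matrix, labels)),
        labeling_id=labeling_id,
    )
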