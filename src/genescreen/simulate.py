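"""Synthetic two-class expression matrices with planted informative genes.

The generator emulates the shape of a two-class microarray study at desk
scale: two unbalanced classes (default 27 vs 11 samples, the ALL/AML
split of the classic leukemia benchmark), a few thousand genes, and a
minority of genes whose class means differ.  Within-class noise is
normal with a common standard deviation ``sigma``; informative genes
receive a mean shift of ``effect * sigma`` between classes, split
symmetrically around the baseline, with the shift sign alternating from
gene to gene so that both score tails — and hence both intersection
abscissas r0 and t0 — are exercised.  Under this model the population
signal-to-noise score of an informative gene is effect / 2, which makes
power reasoning transparent (effect = 2 puts planted genes around
score 1, well past typical thresholds near 0.5).

The generator makes no attempt to mimic microarray-specific artefacts
(probe effects, intensity-dependent variance), so passing tests show the
method's statistical behaviour under clean normal noise, not robustness
to platform noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import ClassVector, ExpressionMatrix

__all__ = [
    "SimulationSpec",
    "simulate",
    "simulate_cohorts",
    "simulate_null",
    "write_truth",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    effect is the between-class mean shift in units of the within-class
    standard deviation; baseline is the grand mean in (arbitrary)
    expression units.
    """

    n1: int = 27
    n2: int = 11
    n_genes: int = 2000
    n_informative: int = 100
    effect: float = 2.0
    sigma: float = 1.0
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each class needs at least 2 samples")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("0 <= n_informative <= n_genes required")
        if self.effect < 0:
            raise ValueError("effect must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def simulate(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, ClassVector, pd.DataFrame]:
    """Generate a matrix, its class vector and the planted-gene truth table.

    Returns ``(matrix, labels, truth)`` where ``truth`` has one row per
    gene with columns ``gene_id``, ``informative`` (bool) and
    ``direction`` (+1 if the class-A mean is shifted up, -1 if down, 0
    for uninformative genes).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n1 + spec.n2
    width = max(4, len(str(spec.n_genes)))
    gene_ids = tuple(f"g{i + 1:0{width}d}" for i in range(spec.n_genes))
    sample_ids = tuple(f"s{j + 1:03d}" for j in range(m))
    labels = ClassVector(
        np.array([1] * spec.n1 + [0] * spec.n2, dtype=np.int8), sample_ids
    )

    informative_idx = rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    informative_idx.sort()
    direction = np.zeros(spec.n_genes, dtype=np.int8)
    direction[informative_idx] = np.where(np.arange(spec.n_informative) % 2 == 0, 1, -1)

    half_shift = spec.effect * spec.sigma / 2.0
    means = np.full((spec.n_genes, m), spec.baseline)
    in_a = labels.labels == 1
    means[:, in_a] += direction[:, None] * half_shift
    means[:, ~in_a] -= direction[:, None] * half_shift

    values = rng.normal(loc=means, scale=spec.sigma)
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "informative": direction != 0,
            "direction": direction,
        }
    )
    return matrix, labels, truth


def _sample_cohort(
    spec: SimulationSpec,
    direction: np.ndarray,
    gene_ids: tuple[str, ...],
    seed: int,
    sample_prefix: str,
) -> tuple[ExpressionMatrix, ClassVector]:
    rng = np.random.default_rng(seed)
    m = spec.n1 + spec.n2
    sample_ids = tuple(f"{sample_prefix}{j + 1:03d}" for j in range(m))
    labels = ClassVector(
        np.array([1] * spec.n1 + [0] * spec.n2, dtype=np.int8), sample_ids
    )
    half_shift = spec.effect * spec.sigma / 2.0
    means = np.full((spec.n_genes, m), spec.baseline)
    in_a = labels.labels == 1
    means[:, in_a] += direction[:, None] * half_shift
    means[:, ~in_a] -= direction[:, None] * half_shift
    values = rng.normal(loc=means, scale=spec.sigma)
    return ExpressionMatrix(gene_ids, sample_ids, values), labels


def simulate_cohorts(
    spec: SimulationSpec,
    test_seed: int,
    test_n1: int | None = None,
    test_n2: int | None = None,
) -> tuple[
    tuple[ExpressionMatrix, ClassVector, pd.DataFrame],
    tuple[ExpressionMatrix, ClassVector],
]:
    """A training cohort plus an independent test cohort of the same genes.

    The test cohort shares the planted informative genes and shift
    directions (the gene-level population) but draws fresh samples and
    noise from ``test_seed``, emulating a prospective evaluation set.
    """
    train_matrix, train_labels, truth = simulate(spec)
    test_spec = replace(
        spec,
        n1=spec.n1 if test_n1 is None else test_n1,
        n2=spec.n2 if test_n2 is None else test_n2,
    )
    test_matrix, test_labels = _sample_cohort(
        test_spec,
        truth["direction"].to_numpy(),
        train_matrix.gene_ids,
        test_seed,
        sample_prefix="t",
    )
    return (train_matrix, train_labels, truth), (test_matrix, test_labels)


def simulate_null(
    n1: int = 27,
    n2: int = 11,
    n_genes: int = 500,
    sigma: float = 1.0,
    baseline: float = 8.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ClassVector]:
    """Global-null dataset: no informative genes, labels pure noise."""
    matrix, labels, _ = simulate(
        SimulationSpec(
            n1=n1,
            n2=n2,
            n_genes=n_genes,
            n_informative=0,
            effect=0.0,
            sigma=sigma,
            baseline=baseline,
            seed=seed,
        )
    )
    return matrix, labels


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
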