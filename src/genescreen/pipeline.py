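"""End-to-end screening on ExpressionMatrix / ClassVector containers.

Thin wrapper over :class:`~genescreen.selector.PermutationSNRSelector`
for callers that hold the genes-by-samples containers rather than
sklearn-oriented arrays, plus the delimited run-report writers used by
the command-line interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import ClassVector, ExpressionMatrix, GeneSelection, write_selection
from .permutation import NullCountTable
from .selector import PermutationSNRSelector
from .snr import ScoreVector
from .threshold import CountCurvePair, ThresholdResult, select_genes

__all__ = ["ScreenResult", "screen_genes", "write_run_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenResult:
    """Everything one screening run produces."""

    scores: ScoreVector
    null_table: NullCountTable
    curve_pos: CountCurvePair
    curve_neg: CountCurvePair
    thresholds: ThresholdResult
    selection: GeneSelection
    seed: int
    n_permutations: int
    alpha: float


def screen_genes(
    matrix: ExpressionMatrix,
    labels: ClassVector,
    n_permutations: int = 500,
    alpha: float = 0.05,
    r_grid=None,
    adjustment_a: float = 0.0,
    seed: int | None = None,
    refine: bool = False,
) -> ScreenResult:
    """Run the full selection procedure on a labeled expression matrix."""
    if labels.m != matrix.n_samples:
        raise ValueError("labels are not aligned with the matrix samples")
    selector = PermutationSNRSelector(
        n_permutations=n_permutations,
        alpha=alpha,
        r_grid=r_grid,
        adjustment=adjustment_a,
        refine=refine,
        random_state=seed,
    )
    selector.fit(matrix.values.T, labels.labels)
    selection = select_genes(selector.scores_, matrix.gene_ids, selector.r_star_)
    logger.info(
        "screened %d genes over %d samples (n1=%d, n2=%d): r0=%.4f, t0=%.4f, "
        "r*=%.4f, %d genes selected",
        matrix.n_genes,
        matrix.n_samples,
        labels.n1,
        labels.n2,
        selector.r0_,
        selector.t0_,
        selector.r_star_,
        len(selection),
    )
    return ScreenResult(
        scores=ScoreVector(selector.scores_),
        null_table=selector.null_table_,
        curve_pos=selector.curve_pos_,
        curve_neg=selector.curve_neg_,
        thresholds=selector.threshold_result_,
        selection=selection,
        seed=selector.seed_,
        n_permutations=n_permutations,
        alpha=alpha,
    )


def _curve_frame(pair: CountCurvePair, tail_sign: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "r": tail_sign * pair.r_grid,
            "observed": pair.observed.astype(int),
            "null_quantile": pair.null_quantile,
        }
    )


def write_run_report(
    result: ScreenResult,
    matrix: ExpressionMatrix,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write scores, count curves, threshold summary and selection files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": out / "scores.tsv",
        "counts_pos": out / "counts_positive_tail.tsv",
        "counts_neg": out / "counts_negative_tail.tsv",
        "threshold": out / "threshold.json",
        "selection": out / "selection.tsv",
    }
    pd.DataFrame(
        {"gene_id": list(matrix.gene_ids), "score": result.scores.scores}
    ).to_csv(paths["scores"], sep="\t", index=False, float_format="%.6f")
    _curve_frame(result.curve_pos, 1).to_csv(
        paths["counts_pos"], sep="\t", index=False
    )
    _curve_frame(result.curve_neg, -1).to_csv(
        paths["counts_neg"], sep="\t", index=False
    )
    summary = {
        "r0": result.thresholds.r0,
        "t0": result.thresholds.t0,
        "adjustment_a": result.thresholds.adjustment_a,
        "r_star": result.thresholds.r_star,
        "n_selected": len(result.selection),
        "seed": result.seed,
        "n_permutations": result.n_permutations,
        "alpha": result.alpha,
        "r_grid": [float(r) for r in result.null_table.r_grid],
    }
    with open(paths["threshold"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_selection(result.selection, paths["selection"])
    return paths
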