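"""Published count curves of the ALL/AML leukemia worked example.

The classic benchmark applies the method to a 38-sample, 7129-gene
leukemia matrix (27 acute lymphoblastic, 11 acute myeloid cases) with
B = 500 permutation vectors, a threshold grid of 0.1-0.6 in steps of
0.1 and right 5% quantile envelopes.  The raw expression matrix is an
external download, but the published per-threshold observed counts and
null envelopes are reproduced here verbatim so the threshold stage can
be exercised and regression-tested on real numbers: feeding these
curves through the intersection rule recovers the published reading
r0 = 0.44 and selection threshold r* ~ 0.5, and the 893-gene selection
size equals the sum of the two printed tail counts at r = 0.5.
"""

from __future__ import annotations

import numpy as np

from .permutation import combination_count
from .threshold import (
    CountCurvePair,
    ThresholdResult,
    combine_threshold,
    curve_intersection,
)

__all__ = [
    "N1_SPLIT",
    "N2_SPLIT",
    "R_GRID",
    "POSITIVE_TAIL",
    "NEGATIVE_TAIL",
    "positive_tail_curve",
    "negative_tail_curve",
    "leukemia_threshold",
]

N1_SPLIT = 27  # ALL cases
N2_SPLIT = 11  # AML cases
N_GENES = 7129
N_PERMUTATIONS = 500

R_GRID = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])

# columns: observed N1(c, r), envelope L1^r
POSITIVE_TAIL = {
    "observed": np.array([2907, 2058, 1385, 868, 514, 278]),
    "null_quantile": np.array([4128, 2946, 1985, 996, 325, 80]),
}

# columns: observed N2(c, r), envelope L2^r (indexed by |r|)
NEGATIVE_TAIL = {
    "observed": np.array([2389, 1628, 1062, 638, 379, 204]),
    "null_quantile": np.array([4245, 2725, 1785, 902, 372, 53]),
}


def positive_tail_curve() -> CountCurvePair:
    return CountCurvePair(
        R_GRID, POSITIVE_TAIL["observed"], POSITIVE_TAIL["null_quantile"], "positive"
    )


def negative_tail_curve() -> CountCurvePair:
    return CountCurvePair(
        R_GRID, NEGATIVE_TAIL["observed"], NEGATIVE_TAIL["null_quantile"], "negative"
    )


def leukemia_threshold(adjustment_a: float = 0.0) -> dict:
    """Re-derive the worked example's threshold from the printed curves.

    Returns the full-precision and display-rounded threshold results,
    the implied selection size at r = 0.5, and the size of the exact
    randomization space that motivates Monte-Carlo sampling.
    """
    r0 = curve_intersection(positive_tail_curve())
    t0 = -curve_intersection(negative_tail_curve())
    result: ThresholdResult = combine_threshold(r0, t0, adjustment_a)
    at_half = int(np.where(np.isclose(R_GRID, 0.5))[0][0])
    n_selected = int(
        POSITIVE_TAIL["observed"][at_half] + NEGATIVE_TAIL["observed"][at_half]
    )
    return {
        "result": result,
        "rounded": result.rounded(2),
        "n_selected_at_half": n_selected,
        "arrangements": combination_count(N1_SPLIT, N2_SPLIT),
    }
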