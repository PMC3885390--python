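"""Normalize, select differentially expressed genes, smooth.

Quantile-normalizes each replicate across time points, runs the per-time-
point baseline t-tests (p < 0.05 at three or more time points), averages
replicates and Fourier-smooths each retained profile.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from dynregnet.datatypes import ExpressionMatrix, ReplicatedExpression
from dynregnet.io import read_replicated_expression, write_matrix
from dynregnet.preprocess import (
    average_replicates,
    quantile_normalize,
    select_degs,
    smooth_matrix,
)


def main() -> None:
    out = RESULTS / "preprocess"
    expr = read_replicated_expression(RESULTS / "simulated" / "expression.tsv")

    normalized = np.empty_like(expr.values)
    for r in range(expr.n_replicates):
        mat = ExpressionMatrix(expr.values[:, :, r], expr.gene_ids, expr.timepoints)
        normalized[:, :, r] = quantile_normalize(mat).values
    norm_expr = ReplicatedExpression(
        normalized, list(expr.gene_ids), expr.timepoints, list(expr.replicate_labels)
    )

    degs = select_degs(norm_expr, alpha=0.05, min_sig_timepoints=3)
    averaged = average_replicates(norm_expr)
    smoothed = smooth_matrix(averaged, n_harmonics=3, period_factor=2.0)

    out.mkdir(parents=True, exist_ok=True)
    (out / "degs.txt").write_text("".join(f"{g}\n" for g in sorted(degs)))
    write_matrix(smoothed, out / "expression_smoothed.tsv")
    print(
        f"{len(degs)} of {len(expr.gene_ids)} genes differentially expressed "
        f"(p<0.05 at >=3 time points vs t=0); smoothed profiles -> {out}"
    )


if __name__ == "__main__":
    main()
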