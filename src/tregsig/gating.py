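"""Flow-style threshold gating of expression matrices.

Cells are gated on single markers at a fixed cutoff on the log2(TPM+1)
scale (default 4), mirroring how bivariate marker plots are quadrant-gated
in flow cytometry.  Inequalities are strict on both sides: a cell sitting
exactly at the threshold is neither positive nor negative, and quadrant
statistics report those boundary cells explicitly so that counts always
add up to the total.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix, GateDefinition, QuadrantStats

__all__ = ["apply_gate", "quadrant_fractions", "fraction_positive"]

DEFAULT_THRESHOLD = 4.0


def _require_genes(matrix: ExpressionMatrix, genes: Sequence[str]) -> None:
    missing = [g for g in genes if not matrix.has_gene(g)]
    if missing:
        raise KeyError(f"gene(s) not present in matrix: {missing}")


def apply_gate(matrix: ExpressionMatrix, gates: Sequence[GateDefinition]) -> list[str]:
    """Sample ids of the columns satisfying *all* gates (conjunction).

    An empty result is a legitimate outcome, not an error.
    """
    _require_genes(matrix, [g.gene for g in gates])
    mask = np.ones(matrix.n_samples, dtype=bool)
    for gate in gates:
        row = matrix.gene_row(gate.gene)
        if gate.direction == "positive":
            mask &= row > gate.threshold
        else:
            mask &= row < gate.threshold
    return [s for s, keep in zip(matrix.sample_ids, mask) if keep]


def quadrant_fractions(
    matrix: ExpressionMatrix,
    gene_x: str,
    gene_y: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> QuadrantStats:
    """Quadrant counts/percentages for two markers at a shared cutoff.

    Percentages are over all cells in the matrix; pass a pre-subset matrix
    (e.g. tumor-tissue cells only) to change the denominator.
    """
    _require_genes(matrix, [gene_x, gene_y])
    if matrix.n_samples < 1:
        raise ValueError("quadrant statistics require at least one cell")
    x = matrix.gene_row(gene_x)
    y = matrix.gene_row(gene_y)
    xp, xn = x > threshold, x < threshold
    yp, yn = y > threshold, y < threshold
    n_pp = int(np.sum(xp & yp))
    n_pn = int(np.sum(xp & yn))
    n_np = int(np.sum(xn & yp))
    n_nn = int(np.sum(xn & yn))
    total = matrix.n_samples
    return QuadrantStats(
        gene_x=gene_x,
        gene_y=gene_y,
        threshold=threshold,
        n_total=total,
        n_double_pos=n_pp,
        n_x_only=n_pn,
        n_y_only=n_np,
        n_double_neg=n_nn,
        n_boundary=total - (n_pp + n_pn + n_np + n_nn),
    )


def fraction_positive(
    matrix: ExpressionMatrix,
    subset: Sequence[str],
    gene: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Percentage of cells in ``subset`` with ``gene`` above the cutoff."""
    _require_genes(matrix, [gene])
    subset = list(subset)
    if not subset:
        raise ValueError("fraction_positive is undefined on an empty subset")
    sub = matrix.subset_samples(subset)
    row = sub.gene_row(gene)
    return 100.0 * float(np.sum(row > threshold)) / len(subset)
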