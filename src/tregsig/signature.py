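"""Signature derivation: per-gene two-group testing with FDR and fold-change filters.

The signature of interest contrasts CD4+LAIR2+ against CD4+LAIR2- tumor
T cells: each gene is tested with Welch's unequal-variance t-test, p-values
are converted to Benjamini-Hochberg q-values, and genes pass if they are
up-regulated in the positive group with q below ``q_max`` and fold change
at least ``fc_min``.  Fold change is computed on the matrix's log2 scale
as ``2**(mean_pos - mean_neg)``; a linear-mean alternative is available
for matrices where raw-scale means are meaningful.

A Pearson correlation screen against an anchor gene is also provided; it
is the computation that feeds gene-ontology analysis of genes co-expressed
with the anchor.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SignatureGeneSet

__all__ = [
    "welch_t",
    "benjamini_hochberg",
    "fold_change",
    "derive_signature",
    "correlation_screen",
]

#: Variance floor guarding against exactly-constant (dropout-heavy) genes.
VAR_FLOOR = 1e-8


def _welch_arrays(
    a: np.ndarray, b: np.ndarray, var_floor: float = VAR_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t over rows of two genes x cells blocks."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = np.maximum(a.var(axis=1, ddof=1), var_floor)
    vb = np.maximum(b.var(axis=1, ddof=1), var_floor)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sided t-test (unequal variances, Welch-Satterthwaite df).

    Groups must each have at least 2 values.  Two identical constant
    groups return (0, 1) by convention; a variance floor of ``1e-8`` keeps
    nearly-constant groups finite.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = _welch_arrays(a[None, :], b[None, :])
    return float(t[0]), float(p[0])


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR q-values: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.

    Input order is preserved in the output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def fold_change(mean_pos: float, mean_neg: float) -> float:
    """Linear fold change from two means on the log2 scale: 2**(pos - neg)."""
    return float(2.0 ** (np.asarray(mean_pos) - np.asarray(mean_neg)))


def derive_signature(
    matrix: ExpressionMatrix,
    pos_cells: Sequence[str],
    neg_cells: Sequence[str],
    q_max: float = 0.001,
    fc_min: float = 1.55,
    fc_scale: str = "log2_delta",
) -> SignatureGeneSet:
    """Genes up-regulated in ``pos_cells`` vs ``neg_cells`` passing both filters.

    Every gene in the matrix is Welch-tested between the two disjoint cell
    sets; membership requires ``q < q_max``, ``fold_change >= fc_min`` and
    ``mean_pos > mean_neg`` (up-regulated only).  Output order is
    deterministic: ascending q, then descending fold change, then gene id.

    ``fc_scale`` chooses the fold-change definition: ``"log2_delta"``
    (``2**(mean_pos - mean_neg)``, the default for log2 matrices) or
    ``"linear_ratio"`` (ratio of means of ``2**x - 1``).
    """
    pos = list(pos_cells)
    neg = list(neg_cells)
    if not pos or not neg:
        raise ValueError("both cell sets must be non-empty")
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"cell sets overlap: {sorted(overlap)[:5]}")
    if q_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be positive")
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each cell set needs at least 2 cells for a t-test")

    a = matrix.subset_samples(pos).values
    b = matrix.subset_samples(neg).values
    t, p = _welch_arrays(a, b)
    q = benjamini_hochberg(p)
    mean_pos = a.mean(axis=1)
    mean_neg = b.mean(axis=1)
    if fc_scale == "log2_delta":
        fc = 2.0 ** (mean_pos - mean_neg)
    elif fc_scale == "linear_ratio":
        lin_pos = np.maximum((2.0**a - 1.0).mean(axis=1), 1e-12)
        lin_neg = np.maximum((2.0**b - 1.0).mean(axis=1), 1e-12)
        fc = lin_pos / lin_neg
    else:
        raise ValueError(f"unknown fc_scale {fc_scale!r}")

    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "fold_change": fc,
        }
    )
    keep = (q < q_max) & (fc >= fc_min) & (mean_pos > mean_neg)
    hits = table.loc[keep].sort_values(
        ["q_value", "fold_change", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    hits = hits.reset_index(drop=True)
    return SignatureGeneSet(
        genes=hits["gene"].tolist(), table=hits, q_max=q_max, fc_min=fc_min
    )


def correlation_screen(
    matrix: ExpressionMatrix,
    anchor_gene: str,
    top_k: int = 500,
    r_min: float = 0.37,
) -> pd.DataFrame:
    """Genes most positively correlated (Pearson) with an anchor gene.

    Returns at most ``top_k`` genes with ``r > r_min``, ranked by
    descending r, with two-sided p-values from the t transform of r.  The
    anchor is excluded from its own list; constant genes are skipped.
    """
    if not matrix.has_gene(anchor_gene):
        raise KeyError(f"anchor gene {anchor_gene!r} not present in matrix")
    n = matrix.n_samples
    if n < 3:
        raise ValueError("correlation screen needs at least 3 samples")
    anchor = matrix.gene_row(anchor_gene)
    if np.ptp(anchor) == 0:
        raise ValueError("anchor gene has zero variance")

    X = matrix.values
    xc = anchor - anchor.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (xc**2).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = (Xc @ xc) / denom
    valid = np.isfinite(r)
    r_clip = np.clip(r, -0.9999999999999, 0.9999999999999)
    t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)

    out = pd.DataFrame({"gene": matrix.gene_ids, "r": r, "p_value": p})
    out = out[valid & (out["gene"] != anchor_gene)]
    out = out[out["r"] > r_min]
    out = out.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort")
    return out.head(top_k).reset_index(drop=True)
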