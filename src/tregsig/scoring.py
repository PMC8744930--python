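"""Per-sample signature scoring and median-split risk stratification.

A cohort's signature score is the unweighted mean, over the signature
genes present in the matrix, of each gene's across-sample median-centered
expression (optionally additionally scaled to unit SD).  Samples are then
dichotomized at the cohort median score: strictly above the median is
high risk, at or below is low risk (ties deterministically go low, which
is conservative for the high-vs-low hazard ratio).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, RiskStratification, ScoreResult, SignatureGeneSet

__all__ = ["signature_score", "median_split", "cd4_adjusted_score"]

logger = logging.getLogger(__name__)


def signature_score(
    matrix: ExpressionMatrix,
    signature: SignatureGeneSet,
    normalize: str = "median_center",
) -> ScoreResult:
    """Mean median-centered expression of the signature genes, per sample.

    ``normalize="median_center"`` subtracts each gene's across-sample
    median; ``"zscore"`` additionally divides by the gene's across-sample
    SD (zero-SD genes are dropped with a warning).  Signature genes absent
    from the matrix are dropped, not imputed, and reported in the result.
    """
    if normalize not in ("median_center", "zscore"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    if matrix.n_samples < 2:
        raise ValueError("scoring needs at least 2 samples")
    present = [g for g in signature.genes if matrix.has_gene(g)]
    absent = [g for g in signature.genes if not matrix.has_gene(g)]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if absent:
        logger.info(
            "signature_score: %d/%d signature genes absent from matrix",
            len(absent), len(signature.genes),
        )
    X = matrix.subset_genes(present).values
    centered = X - np.median(X, axis=1, keepdims=True)
    if normalize == "zscore":
        sd = X.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [g for g, k in zip(present, keep) if not k]
            warnings.warn(
                f"zscore scoring dropped {len(dropped)} zero-SD gene(s): {dropped[:5]}",
                stacklevel=2,
            )
            centered = centered[keep]
            sd = sd[keep]
            if centered.shape[0] == 0:
                raise ValueError("all present signature genes have zero SD")
        centered = centered / sd[:, None]
    scores = pd.Series(centered.mean(axis=0), index=matrix.sample_ids, name="score")
    return ScoreResult(scores=scores, absent_genes=absent, normalize=normalize)


def median_split(scores: pd.Series | ScoreResult) -> RiskStratification:
    """Dichotomize at the cohort median: > median -> high, <= median -> low."""
    if isinstance(scores, ScoreResult):
        scores = scores.scores
    scores = pd.Series(scores).astype(float)
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 samples")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no stratification possible")
    cutoff = float(scores.median())
    group = pd.Series(
        np.where(scores.values > cutoff, "high", "low"), index=scores.index, name="group"
    )
    return RiskStratification(scores=scores, cutoff=cutoff, group=group)


def cd4_adjusted_score(
    scores: pd.Series | ScoreResult,
    matrix: ExpressionMatrix,
    cd4_gene: str = "CD4",
) -> pd.Series:
    """Signature score residualized on CD4 expression.

    Removes the component of the score explained (least squares) by
    median-centered CD4 expression, so the adjusted score reflects the
    signature beyond the overall abundance of CD4+ T cells.  This is one
    plausible operationalization of "taking CD4+ T-cell presence into
    account" and is labeled non-canonical in outputs.
    """
    if isinstance(scores, ScoreResult):
        scores = scores.scores
    scores = pd.Series(scores).astype(float)
    if not matrix.has_gene(cd4_gene):
        raise KeyError(f"gene {cd4_gene!r} not present in matrix")
    cd4 = pd.Series(matrix.gene_row(cd4_gene), index=matrix.sample_ids)
    cd4 = cd4.reindex(scores.index)
    if cd4.isna().any():
        raise KeyError("score index contains samples absent from the matrix")
    if cd4.nunique() == 1:
        warnings.warn("CD4 expression is constant; returning unadjusted scores", stacklevel=2)
        return scores.copy()
    x = cd4.to_numpy() - np.median(cd4.to_numpy())
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, scores.to_numpy(), rcond=None)
    resid = scores.to_numpy() - X @ beta
    return pd.Series(resid, index=scores.index, name="cd4_adjusted_score")
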