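"""End-to-end orchestration: simulate -> gate -> derive -> score -> survive -> pool.

This mirrors the full analysis: gate single-cell TILs into CD4+LAIR2+
versus CD4+LAIR2- groups, derive the differential-expression signature,
score several bulk cohorts, stratify at the median, fit Cox models, and
pool the per-cohort hazard ratios.  It exists so the whole chain can be
exercised (and reported) with one call; each stage remains usable on its
own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GateDefinition, MetaResult, SignatureGeneSet, SurvivalFit
from .gating import apply_gate, fraction_positive, quadrant_fractions
from .meta import pool_hr
from .scoring import median_split, signature_score
from .signature import derive_signature
from .simulate import SimConfig, simulate_bulk_cohort, simulate_tils
from .survival import cox_fit, logrank_test

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the end-to-end run measured."""

    signature: SignatureGeneSet
    signature_sensitivity: float
    signature_fdp: float
    double_pos_pct: float
    foxp3_pct_in_gate: float
    cohort_fits: list[SurvivalFit]  # continuous-score Cox, one per cohort
    split_fits: list[SurvivalFit]  # median-split high-vs-low Cox
    logrank_ps: list[float]
    pooled: MetaResult  # continuous-score log HRs pooled (fixed effect)
    pooled_split: MetaResult
    planted_hr: float


def run_pipeline(
    config: SimConfig | None = None,
    n_cohorts: int = 3,
    threshold: float = 4.0,
    meta_method: str = "fixed",
) -> PipelineResult:
    """Run the full synthetic analysis once and collect every stage's output.

    The signature is derived from gated CD4+LAIR2+ vs CD4+LAIR2- cells,
    then each simulated bulk cohort is scored, median-split (Kaplan-Meier
    style log-rank + high-vs-low Cox) and fitted with a continuous-score
    Cox model; the continuous-score log HRs are pooled across cohorts.
    The planted hazard ratio refers to one unit of the latent score, so
    the continuous-score pooling is the recovery check; the median-split
    pooling estimates a different (coarsened) contrast and is reported
    alongside.
    """
    config = config or SimConfig()
    matrix, annotations, truth = simulate_tils(config)

    pos = apply_gate(
        matrix,
        [GateDefinition("CD4", threshold), GateDefinition("LAIR2", threshold)],
    )
    neg = apply_gate(
        matrix,
        [
            GateDefinition("CD4", threshold),
            GateDefinition("LAIR2", threshold, direction="negative"),
        ],
    )
    quad = quadrant_fractions(matrix, "CD4", "LAIR2", threshold)
    foxp3_pct = fraction_positive(matrix, pos, "FOXP3", threshold) if pos else float("nan")

    signature = derive_signature(matrix, pos, neg)
    planted = set(truth.program_genes)
    hits = set(signature.genes)
    sensitivity = len(hits & planted) / len(planted) if planted else float("nan")
    fdp = len(hits - planted) / len(hits) if hits else 0.0

    cohort_fits: list[SurvivalFit] = []
    split_fits: list[SurvivalFit] = []
    logrank_ps: list[float] = []
    for k in range(n_cohorts):
        bulk, clinical, bulk_truth = simulate_bulk_cohort(config, signature, cohort_index=k)
        scores = signature_score(bulk, signature)
        strat = median_split(scores)
        fit = cox_fit(clinical, extra=scores.scores.rename("score"))
        cohort_fits.append(fit)
        high = pd.Series(
            (strat.group == "high").astype(float).values,
            index=strat.group.index,
            name="high_risk",
        )
        split_fit = cox_fit(clinical, extra=high)
        split_fits.append(split_fit)
        group = np.asarray([1 if g == "high" else 0 for g in strat.group])
        _, lr_p = logrank_test(clinical.os_time, clinical.event, group)
        logrank_ps.append(lr_p)

    pooled = pool_hr(
        [
            (f"cohort_{k + 1}", f.coefficient("score").coef, f.coefficient("score").se)
            for k, f in enumerate(cohort_fits)
        ],
        method=meta_method,
    )
    pooled_split = pool_hr(
        [
            (f"cohort_{k + 1}", f.coefficient("high_risk").coef, f.coefficient("high_risk").se)
            for k, f in enumerate(split_fits)
        ],
        method=meta_method,
    )
    return PipelineResult(
        signature=signature,
        signature_sensitivity=sensitivity,
        signature_fdp=fdp,
        double_pos_pct=quad.pct_double_pos,
        foxp3_pct_in_gate=foxp3_pct,
        cohort_fits=cohort_fits,
        split_fits=split_fits,
        logrank_ps=logrank_ps,
        pooled=pooled,
        pooled_split=pooled_split,
        planted_hr=float(np.exp(config.planted_beta)),
    )
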