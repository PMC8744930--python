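# tregsig

Tumor-infiltrating regulatory T (Treg) cells that express the secreted
collagen receptor **LAIR2** mark an adversely prognostic immune state in
lung adenocarcinoma. `tregsig` implements, as a reusable and tested
pipeline, the analysis that derives and validates a CD4⁺LAIR2⁺ Treg gene
signature:

1. **Threshold gating** of a single-cell expression matrix
   (log₂(TPM+1) > 4, flow-cytometry style) into CD4⁺LAIR2⁺ and CD4⁺LAIR2⁻
   T cells, with quadrant co-expression statistics.
2. **Signature derivation**: per-gene Welch *t*-tests between the gated
   groups, Benjamini–Hochberg FDR, and the filters *q* < 0.001,
   fold change ≥ 1.55 (FC = 2^Δmean on the log₂ scale), up-regulated only.
3. **Signature scoring** of bulk cohorts: per-gene across-sample
   median-centering, unweighted mean over signature genes, median-split
   into high/low risk groups.
4. **Survival analysis**: Kaplan–Meier curves, log-rank tests, and Cox
   proportional hazards (Newton–Raphson on the Efron or Breslow partial
   likelihood), plus a per-gene 5-year-horizon prognostic screen.
5. **Meta-analysis**: inverse-variance pooling of per-cohort log hazard
   ratios (fixed effect or DerSimonian–Laird random effects).

Because the original patient cohorts require controlled-access downloads
and undocumented preprocessing, the package ships a **synthetic-data
generator** that plants known ground truth — a Treg population carrying a
LAIR2/FOXP3 co-expression program with dropout, and bulk cohorts whose
hazard is log-linear in a latent signature score — so every stage's
recovery can be verified quantitatively.

The core quantities, in standard notation: for sample *j* and signature
set *S*, the score is
*score(j) = |S|⁻¹ Σ_{g∈S} (x_gj − median_j(x_gj))*; Cox models fit
*h(t|z) = h₀(t)·exp(βᵀz)* with hazard ratio HR = exp(β) and 95% Wald CI
exp(β ± 1.96·SE); cohorts are pooled by inverse-variance weights
*w_k = 1/SE_k²* (random effects: *1/(SE_k² + τ̂²_DL)*).

## Worked example

```python
from tregsig import SimConfig, run_pipeline

res = run_pipeline(SimConfig(seed=1))
print(f"CD4+LAIR2+ double-positive TILs: {res.double_pos_pct:.1f}%")
print(f"FOXP3+ within the CD4+LAIR2+ gate: {res.foxp3_pct_in_gate:.1f}%")
print(f"signature genes recovered: {res.signature.n_genes}")
print(f"pooled HR per unit score: {res.pooled.pooled_hr:.2f} "
      f"(95% CI {res.pooled.ci_low:.2f}-{res.pooled.ci_high:.2f}); "
      f"planted HR {res.planted_hr:.2f}")
```

prints

```
CD4+LAIR2+ double-positive TILs: 9.7%
FOXP3+ within the CD4+LAIR2+ gate: 95.9%
signature genes recovered: 50
pooled HR per unit score: 2.08 (95% CI 1.87-2.31); planted HR 2.00
```

Reading: about 10% of simulated TILs co-express CD4 and LAIR2 above the
log₂(TPM+1) > 4 cutoff (that is the planted Treg fraction); nearly all
gated cells are FOXP3⁺, as expected for a Treg program; the
differential-expression step recovers the full 50-gene planted program;
and scoring three independent 300-patient cohorts, fitting Cox models
and pooling yields a hazard ratio of 2.08 per unit score whose interval
covers the planted HR of 2.

Each stage is also available as a CLI subcommand over config files:
`tregsig simulate|gate|derive-signature|score|survival|screen|meta`
(see `tregsig --help`).

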