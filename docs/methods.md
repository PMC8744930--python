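# Methods

This note records the statistical models, defaults, and design choices
behind `tregsig`, in the order the pipeline runs.

## Single-cell generator

The generator emulates sorted tumor-infiltrating T cells on the
log₂(TPM+1) scale. Four populations are drawn (defaults in parentheses):
CD4⁺ Treg carrying the LAIR2 program (150), conventional CD4⁺ (600),
CD8⁺ (600), other (150) — 1,500 cells over 1,000 genes. Sizes are scaled
down from the ~9,000-cell datasets this emulates to keep simulations
cheap while leaving every per-gene test well powered; the Treg fraction
(10%) matches the ~11% CD4/LAIR2 double-positive fraction reported for
such data.

Per cell and gene, expression is Normal(μ, σ) truncated at 0, with
σ = `base_sd` = 0.8 and μ = `base_mean` = 2.0 plus shifts:

* compartment markers: CD4 (+`marker_shift` = 4.0) in both CD4
  populations, CD8A (+4.0) in the CD8 population;
* the Treg program — FOXP3, LAIR2, IL2RA, CTLA4, TNFRSF18, ICOS, TIGIT,
  CCR8 plus 42 synthetic ids, 50 genes total — gets `program_shift`
  (default 4.0) in the Treg population only.

Truncation is implemented as clipping; thresholds of interest sit at 4
log₂ units, far from 0, so the point mass at 0 does not affect
gate-crossing fractions, and the noise-free limit stays exact.

Dropout then zeroes each value with probability
logistic(`dropout_rate0` − `dropout_slope`·μ) (defaults 1.5, 0.9):
~43% dropout for background genes (μ = 2), ~2% for marker-level genes
(μ = 6), the qualitative zero-inflation pattern of plate-based scRNA-seq.

The default `program_shift` = 4.0 makes the default dataset reproduce
the study conditions downstream stages assume: LAIR2 is gateable at
log₂(TPM+1) > 4 in Tregs, and >90% of gated CD4⁺LAIR2⁺ cells are FOXP3⁺.
Because the program shift is the *only* difference between the Treg and
conventional CD4 populations, setting it to 0 makes the two populations
exactly exchangeable — the basis of the type-I-error checks. Recovery
benchmarks use shift 1.5, a deliberately harder setting.

What the generator does **not** model: library-size variation, patient
batch effects, doublets, a count layer (the emulated data are already
log-TPM), or correlation between non-program genes. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated noise model, not robustness to every artifact of real scRNA-seq.

## Bulk cohort generator

Each cohort draws a latent signature activity *s* ~ N(0,1) per sample
(default n = 300). Expression is a per-gene uniform baseline plus
Gaussian noise (SD 1.0, microarray-like log₂-intensity scale; this
scale admits negative values, which the log₂(TPM+1) invariant would
not); signature genes additionally gain `bulk_loading`·s (default 1.0).
With 50 signature genes the computed median-centered score tracks *s*
with correlation ≈ 0.99, so score-based fits estimate nearly the planted
coefficient (attenuation ≈ 2%).

Survival is exponential: hazard = `baseline_hazard`·exp(β·s + covariate
terms), with β = `planted_beta` (default log 2) and baseline 0.012
events/month (median survival ≈ 58 months, typical of resected lung
adenocarcinoma). Censoring is independent exponential at `censor_rate`
(default 0.012 → ~50% events); censoring and death times are generated
as standard exponentials divided by their rates, so with a fixed seed
the event fraction is exactly monotone in `censor_rate`. Covariates
(age, sex, smoking, stage, histology) are generated with realistic
marginals; their hazard effects default to 0 so that the default cohort
isolates the planted score effect — nonzero effects are config options
used to exercise multivariate models. The emulated studies report only
fitted hazard ratios, not generative effect sizes, so no quantitative
covariate effect is planted by default.

One integer seed expands to per-stage substreams via `SeedSequence`
spawn keys (single-cell: key (0,·); cohort *k*: key (1, k)), so stages
and cohorts are independently reproducible.

## Gating

Gates are strict inequalities on one gene at a shared cutoff (default 4
log₂(TPM+1)); a cell exactly at the threshold satisfies neither
direction, and quadrant statistics report boundary cells explicitly so
counts always sum to the total. Percentages are kept exact internally
and rounded only for display. The quadrant denominator is whatever
matrix is passed in; pre-subset the matrix (e.g. to tumor-tissue cells)
to change it.

## Signature derivation

Welch's unequal-variance *t*-test is used per gene (the gated LAIR2⁺
minority vs LAIR2⁻ majority makes pooled variance unsafe); a variance
floor of 1e-8 keeps dropout-flattened genes finite, and two identical
constant groups return t = 0, p = 1 by convention. q-values are the
Benjamini–Hochberg step-up, implemented directly and verified against
both a definitional brute force and statsmodels. Membership requires
q < 0.001, fold change ≥ 1.55 and mean_pos > mean_neg (up-regulated
only). Fold change defaults to 2^(Δ mean log₂) since the matrix exists
only on the log scale; a linear-mean ratio is available
(`fc_scale="linear_ratio"`) because the emulated analysis does not state
which was used. Cells, not patients, are treated as replicates — again
matching the emulated analysis rather than current pseudobulk practice.
Output order is deterministic: ascending q, descending FC, gene id.

## Scoring and stratification

The score is the unweighted mean over present signature genes of
per-gene across-sample **median-centered** expression. The ambiguous
"normalized" in the source description is exposed as a switch:
`median_center` (default, the unambiguous part) or `zscore` (additional
per-gene SD scaling, ddof = 1; zero-SD genes dropped with a warning).
Signature genes absent from a cohort are dropped, never imputed, and
reported. The median split assigns scores strictly above the cohort
median to high risk; ties and the median itself go low — deterministic
and conservative for the high-vs-low hazard ratio. The CD4-adjusted
variant residualizes the score on median-centered CD4 expression by
least squares; this is one plausible reading of "taking CD4⁺ T-cell
presence into account" and is labeled non-canonical.

## Survival models

Kaplan–Meier uses the product-limit estimator with
deaths-before-censorings tie handling. The log-rank test is the
standard two-group statistic against χ²(1); at very small n the χ²
reference is approximate, and the test suite checks it against a
10,000-permutation exact null with a tolerance (0.05) that covers both
Monte-Carlo error and that approximation.

Cox models maximize the Efron (default; matching the R survival
ecosystem) or Breslow partial likelihood by Newton–Raphson with step
halving, from β = 0, converged when the gradient max-norm < 1e-8;
covariates are mean-centered internally for conditioning (β is
invariant). Standard errors come from the inverse observed information;
CIs are 95% Wald on the log-HR scale. Monotone likelihood (perfect
separation) is flagged when a per-SD coefficient exceeds 10 — a hazard
ratio above e¹⁰ per SD does not occur at an interior maximum — and
raises an error naming the covariate. Missing covariate codings (e.g.
stage III under the II-vs-I contrast) are handled per model by
complete-case analysis with the dropped count recorded. The 5-year
screen applies administrative censoring at 60 months before fitting,
the standard truncation rule; single-gene screens dichotomize at the
cohort median by default (the emulated high/low cut is unstated) with a
continuous option.

Covariate codings follow the emulated clinical table: stage II vs I,
sex female vs male, smoking no vs yes, histology micropapillary/solid
vs acinar/papillary/lepidic, age continuous per year.

## Meta-analysis

Fixed-effect pooling uses inverse-variance weights; random effects use
the DerSimonian–Laird moment estimator τ̂² = max(0, (Q − df)/C), chosen
for its closed form and testability (the emulated workflow's estimator
choice is unrecorded; the method used is stamped into every output).
Heterogeneity is reported as Q, τ², and I². A single study passes
through unchanged.

## End-to-end check

The pipeline chain gates the simulated TILs, derives the signature from
the gated groups, scores three cohorts, median-splits (KM/log-rank and
high-vs-low Cox), fits continuous-score Cox models, and pools. The
planted hazard ratio is defined per unit of the latent score, so the
recovery check pools the continuous-score fits; the median-split HR
estimates a different, coarsened contrast (roughly exp(β·E[s|high] −
β·E[s|low]) attenuated by within-group heterogeneity) and is reported
alongside rather than compared to the planted value.

## Problem sizes and numerical tolerances

Simulation-based checks use: signature recovery, 20 seeds at shift 1.5;
null controls, 50 seeds and 10,000 Welch tests; hazard recovery, 100
replicates at n = 500 plus 200 null replicates at n = 300 — sizes chosen
so the whole suite runs in well under a minute of simulation time while
keeping Monte-Carlo error small relative to the asserted margins.
Grid-search Cox oracles use a 1e-4 grid over β ∈ [−4, 4]; BH and
cross-library comparisons assert at 1e-12 (identical definitions),
lifelines comparisons at 1e-4 (different convergence tolerance).
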