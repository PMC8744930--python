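"""Synthetic single-cell and bulk-cohort generators with planted ground truth.

The single-cell generator emulates sorted tumor-infiltrating T cells
(TILs) on the log2(TPM+1) scale: a mixture of four populations
(CD4+ Treg carrying an elevated LAIR2/FOXP3 program, conventional CD4,
CD8, other), Gaussian per-gene noise truncated at zero, and logistic
zero-inflation dropout whose probability decreases with a gene's mean.
Compartment markers (CD4, CD8A) are elevated in their populations; the
Treg program genes — which must include FOXP3, LAIR2 and the Treg lineage
markers IL2RA, CTLA4, TNFRSF18, ICOS, TIGIT, CCR8 — are elevated only in
the Treg population, by ``program_shift`` log2 units.

The bulk generator emulates validation cohorts whose hazard is
log-linear in a planted per-sample signature activity: signature genes'
expression is shifted proportionally to a latent N(0,1) score, survival
times are exponential with hazard ``baseline_hazard * exp(planted_beta *
score + covariate terms)``, and censoring is independent exponential.

One global integer seed expands to per-stage substreams
(``numpy.random.SeedSequence`` spawn keys), so stages can be rerun
independently and reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import ClinicalTable, ExpressionMatrix, SignatureGeneSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_tils",
    "simulate_bulk_cohort",
    "REQUIRED_PROGRAM_GENES",
    "DEFAULT_PROGRAM_GENES",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: Treg lineage / tumor-associated markers every program must contain.
REQUIRED_PROGRAM_GENES = (
    "FOXP3",
    "LAIR2",
    "IL2RA",
    "CTLA4",
    "TNFRSF18",
    "ICOS",
    "TIGIT",
    "CCR8",
)

#: Default 50-gene planted program: the named markers plus synthetic ids.
DEFAULT_PROGRAM_GENES = REQUIRED_PROGRAM_GENES + tuple(
    f"TREGP{i:03d}" for i in range(9, 51)
)

_COMPARTMENT = {
    "CD4_treg_lair2pos": "CD4",
    "CD4_conv": "CD4",
    "CD8": "CD8",
    "other": "other",
}


def _default_n_cells() -> dict[str, int]:
    return {"CD4_treg_lair2pos": 150, "CD4_conv": 600, "CD8": 600, "other": 150}


def _default_covariate_effects() -> dict[str, float]:
    # Zero by default: the default cohort isolates the planted score effect;
    # nonzero values exercise the multivariate survival models.
    return {"age": 0.0, "sex": 0.0, "stage": 0.0}


@dataclass
class SimConfig:
    """All knobs of the synthetic single-cell and bulk generators.

    Expression units are log2(TPM+1) (single cell) or log2 intensity
    (bulk); survival times are months; ``baseline_hazard`` and
    ``censor_rate`` are events per month.
    """

    seed: int = 0
    n_cells: dict[str, int] = field(default_factory=_default_n_cells)
    n_genes: int = 1000
    program_genes: tuple[str, ...] = DEFAULT_PROGRAM_GENES
    program_shift: float = 4.0
    marker_shift: float = 4.0
    base_mean: float = 2.0
    base_sd: float = 0.8
    dropout_rate0: float = 1.5
    dropout_slope: float = 0.9
    n_samples: int = 300
    bulk_loading: float = 1.0
    bulk_noise_sd: float = 1.0
    planted_beta: float = math.log(2.0)
    baseline_hazard: float = 0.012
    censor_rate: float = 0.012
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)

    def validate(self) -> None:
        if set(self.n_cells) != set(_COMPARTMENT):
            raise ConfigError(f"n_cells must have keys {sorted(_COMPARTMENT)}")
        if any(int(c) <= 0 for c in self.n_cells.values()):
            raise ConfigError("all population counts must be > 0")
        if self.program_shift < 0:
            raise ConfigError("program_shift must be >= 0")
        if self.base_sd < 0 or self.marker_shift < 0:
            raise ConfigError("base_sd and marker_shift must be >= 0")
        missing = [g for g in REQUIRED_PROGRAM_GENES if g not in self.program_genes]
        if missing:
            raise ConfigError(f"program_genes must include {missing}")
        universe = set(self.gene_universe())
        absent = [g for g in self.program_genes if g not in universe]
        if absent:
            raise ConfigError(f"program gene(s) outside the gene universe: {absent}")
        if not math.isfinite(self.planted_beta):
            raise ConfigError("planted_beta must be finite")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")

    def gene_universe(self) -> list[str]:
        """Deterministic gene id list: markers, program genes, then filler."""
        named = ["CD4", "CD8A"] + [g for g in self.program_genes if g not in ("CD4", "CD8A")]
        if self.n_genes < len(named):
            raise ConfigError(
                f"n_genes={self.n_genes} too small for the {len(named)} named genes"
            )
        filler = [f"GENE{i:04d}" for i in range(1, self.n_genes - len(named) + 1)]
        return named + filler


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    labels: pd.Series  # cell/sample id -> population (single cell) or NA
    program_genes: list[str]
    planted_beta: float | None = None
    true_scores: pd.Series | None = None

    def cells_of(self, population: str) -> list[str]:
        return list(self.labels.index[self.labels == population])


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def simulate_tils(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate sorted TILs: (matrix, per-cell annotations, ground truth).

    Expression is Normal(base_mean + population shift, base_sd) truncated
    at 0 on the log2(TPM+1) scale, then zeroed with probability
    ``logistic(dropout_rate0 - dropout_slope * mean)`` where ``mean`` is
    the cell's pre-noise gene mean.
    """
    config.validate()
    genes = config.gene_universe()
    gene_idx = {g: i for i, g in enumerate(genes)}

    pops: list[str] = []
    for pop in _COMPARTMENT:  # fixed population order
        pops.extend([pop] * int(config.n_cells[pop]))
    n_cells = len(pops)
    cell_ids = [f"C{i:05d}" for i in range(1, n_cells + 1)]
    pop_arr = np.asarray(pops)

    means = np.full((len(genes), n_cells), config.base_mean, dtype=float)
    is_cd4_pop = np.isin(pop_arr, ["CD4_treg_lair2pos", "CD4_conv"])
    means[gene_idx["CD4"], is_cd4_pop] += config.marker_shift
    means[gene_idx["CD8A"], pop_arr == "CD8"] += config.marker_shift
    is_treg = pop_arr == "CD4_treg_lair2pos"
    prog_rows = [gene_idx[g] for g in config.program_genes]
    means[np.ix_(prog_rows, is_treg)] += config.program_shift

    rng_expr = _rng(config.seed, 0, 0)
    rng_drop = _rng(config.seed, 0, 1)
    values = means if config.base_sd == 0 else rng_expr.normal(means, config.base_sd)
    values = np.clip(values, 0.0, None)
    p_drop = expit(config.dropout_rate0 - config.dropout_slope * means)
    values[rng_drop.random(values.shape) < p_drop] = 0.0

    matrix = ExpressionMatrix(genes, cell_ids, values, scale="log2_tpm_plus1")
    annotations = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "population": pops,
            "compartment": [_COMPARTMENT[p] for p in pops],
            "patient": [f"P{1 + i % 5}" for i in range(n_cells)],
            "tissue": "tumor",
        }
    )
    truth = GroundTruth(
        labels=pd.Series(pops, index=cell_ids, name="population"),
        program_genes=list(config.program_genes),
    )
    return matrix, annotations, truth


def simulate_bulk_cohort(
    config: SimConfig,
    signature: SignatureGeneSet | Sequence[str],
    cohort_index: int = 0,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Simulate one bulk cohort whose hazard is log-linear in a planted score.

    Each sample's latent signature activity ``s ~ N(0,1)`` shifts the
    signature genes' expression by ``bulk_loading * s``; overall survival
    is exponential with hazard ``baseline_hazard * exp(planted_beta * s +
    covariate terms)`` under independent exponential censoring at
    ``censor_rate``.  ``cohort_index`` selects an independent random
    substream, so several cohorts can be drawn from one seed.
    """
    config.validate()
    sig_genes = list(signature.genes) if isinstance(signature, SignatureGeneSet) else list(signature)
    if not sig_genes:
        raise ConfigError("signature must contain at least one gene")
    genes = config.gene_universe()
    gene_idx = {g: i for i, g in enumerate(genes)}
    outside = [g for g in sig_genes if g not in gene_idx]
    if outside:
        raise ConfigError(f"signature gene(s) outside the gene universe: {outside[:5]}")

    n = int(config.n_samples)
    sample_ids = [f"S{cohort_index}_{i:04d}" for i in range(1, n + 1)]
    rng = _rng(config.seed, 1, cohort_index)

    s = rng.normal(0.0, 1.0, n)
    baselines = rng.uniform(2.0, 8.0, len(genes))
    values = baselines[:, None] + rng.normal(0.0, config.bulk_noise_sd, (len(genes), n))
    sig_rows = [gene_idx[g] for g in sig_genes]
    values[sig_rows, :] += config.bulk_loading * s[None, :]

    age = np.clip(rng.normal(65.0, 8.0, n), 30.0, 90.0).round(1)
    sex = rng.choice(["female", "male"], size=n)
    smoking = rng.choice(["no", "yes"], size=n, p=[0.3, 0.7])
    stage = rng.choice(["I", "II", "III"], size=n, p=[0.45, 0.40, 0.15])
    histology = rng.choice(
        ["micropapillary/solid", "acinar/papillary/lepidic", "other"],
        size=n,
        p=[0.35, 0.55, 0.10],
    )

    eff = config.covariate_effects
    lp = (
        config.planted_beta * s
        + eff.get("age", 0.0) * (age - 65.0)
        + eff.get("sex", 0.0) * (sex == "female")
        + eff.get("stage", 0.0) * (stage == "II")
    )
    hazard = config.baseline_hazard * np.exp(lp)
    # standard exponentials scaled by the rates, so that with a fixed seed
    # the censoring times shrink monotonically as censor_rate grows
    death = rng.exponential(1.0, n) / hazard
    if config.censor_rate > 0:
        censor = rng.exponential(1.0, n) / config.censor_rate
    else:
        censor = np.full(n, np.inf)
    os_time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    matrix = ExpressionMatrix(genes, sample_ids, values, scale="log2_intensity")
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "os_time": os_time,
                "event": event,
                "age": age,
                "sex": sex,
                "smoking": smoking,
                "stage": stage,
                "histology": histology,
            }
        )
    )
    truth = GroundTruth(
        labels=pd.Series(pd.NA, index=sample_ids, name="population"),
        program_genes=sig_genes,
        planted_beta=config.planted_beta,
        true_scores=pd.Series(s, index=sample_ids, name="true_score"),
    )
    return matrix, clinical, truth
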