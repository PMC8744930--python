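"""Core data containers shared by every pipeline stage.

The central substrate is :class:`ExpressionMatrix`, a genes x samples
matrix on a declared log2 scale.  Orientation is fixed everywhere in the
package: rows are genes, columns are samples (cells for single-cell data).
Transposed input is never detected heuristically — silently transposing an
expression matrix is the classic bug this rigidity prevents.

Clinical data travel in :class:`ClinicalTable`, which validates overall
survival (OS) fields at construction and exposes the covariate codings
used by the survival models: stage II vs I, sex female vs male, smoking
no vs yes, histology micropapillary/solid vs acinar/papillary/lepidic,
age continuous per year.  Categories outside a contrast (e.g. stage III)
are kept but coded missing, and each fitted model handles them by
complete-case analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GateDefinition",
    "QuadrantStats",
    "SignatureGeneSet",
    "ScoreResult",
    "RiskStratification",
    "CoxCoefficient",
    "SurvivalFit",
    "KMCurve",
    "StudyEffect",
    "MetaResult",
    "FormatError",
    "ValidationError",
]

#: Allowed values for ``ExpressionMatrix.scale``.
SCALES = ("log2_tpm_plus1", "log2_intensity")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, dimension mismatch, ...)."""


class ValidationError(ValueError):
    """Input violates a domain invariant (negative OS time, bad event code)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise FormatError(f"duplicate {what} id(s): {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix on a declared log2 scale.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample (or cell) identifiers, one per column.
    values
        Dense float matrix, shape ``(len(gene_ids), len(sample_ids))``.
    scale
        ``"log2_tpm_plus1"`` (non-negative by construction) or
        ``"log2_intensity"`` (microarray-like, may be negative).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "log2_tpm_plus1"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if np.isnan(self.values).any():
            raise ValidationError("missing expression values are not allowed")
        if self.scale == "log2_tpm_plus1" and (self.values < 0).any():
            raise ValidationError("negative values are invalid on the log2(TPM+1) scale")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        """Expression of one gene across all samples (view, do not mutate)."""
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column subset, in the order given."""
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [idx[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not present in matrix") from None
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[str(s) for s in sample_ids],
            values=self.values[:, cols].copy(),
            scale=self.scale,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        rows = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=[str(g) for g in gene_ids],
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :].copy(),
            scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


# Covariate codings (1 vs 0) used throughout the survival models.
STAGE_CONTRAST = {"II": 1.0, "I": 0.0}
SEX_CONTRAST = {"female": 1.0, "male": 0.0}
SMOKING_CONTRAST = {"no": 1.0, "yes": 0.0}
HISTOLOGY_CONTRAST = {
    "micropapillary/solid": 1.0,
    "acinar/papillary/lepidic": 0.0,
}

#: Design-column builders: name -> (source column, mapping or None for numeric)
_COVARIATE_CODINGS = {
    "age": ("age", None),
    "sex": ("sex", SEX_CONTRAST),
    "smoking": ("smoking", SMOKING_CONTRAST),
    "stage": ("stage", STAGE_CONTRAST),
    "histology": ("histology", HISTOLOGY_CONTRAST),
}


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations with overall-survival endpoints.

    ``data`` must contain ``sample_id``, ``os_time`` (months) and ``event``
    (1 = death, 0 = censored); ``age``, ``sex``, ``smoking``, ``stage`` and
    ``histology`` are optional covariates.  Categories outside a model
    contrast are retained and coded as missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"sample_id", "os_time", "event"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"clinical table missing column(s): {sorted(missing)}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"].tolist(), "sample")
        df["os_time"] = pd.to_numeric(df["os_time"])
        df["event"] = pd.to_numeric(df["event"])
        if not np.isfinite(df["os_time"]).all() or (df["os_time"] < 0).any():
            bad = df.loc[~np.isfinite(df["os_time"]) | (df["os_time"] < 0), "sample_id"]
            raise ValidationError(f"os_time must be finite and >= 0; offending sample(s): {list(bad)}")
        if not df["event"].isin([0, 1]).all():
            bad = df.loc[~df["event"].isin([0, 1]), "sample_id"]
            raise ValidationError(f"event must be 0 or 1; offending sample(s): {list(bad)}")
        df["event"] = df["event"].astype(int)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def os_time(self) -> np.ndarray:
        return self.data["os_time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)

    def design_matrix(self, covariates: Sequence[str]) -> pd.DataFrame:
        """Numeric design columns for the requested covariates.

        Categorical covariates are coded per their 1-vs-0 contrast; values
        outside the contrast (e.g. stage III under the II-vs-I contrast)
        become NaN and are excluded downstream by complete-case analysis.
        """
        cols = {}
        for name in covariates:
            if name not in _COVARIATE_CODINGS:
                raise KeyError(
                    f"unknown covariate {name!r}; expected one of {sorted(_COVARIATE_CODINGS)}"
                )
            source, mapping = _COVARIATE_CODINGS[name]
            if source not in self.data.columns:
                raise KeyError(f"clinical table has no column {source!r}")
            col = self.data[source]
            if mapping is None:
                cols[name] = pd.to_numeric(col, errors="coerce")
            else:
                cols[name] = col.astype(str).str.strip().str.lower().map(
                    {k.lower(): v for k, v in mapping.items()}
                )
        design = pd.DataFrame(cols)
        design.index = pd.Index(self.data["sample_id"], name="sample_id")
        return design


@dataclass(frozen=True)
class GateDefinition:
    """Single-marker threshold gate: value > threshold (positive) or < (negative)."""

    gene: str
    threshold: float = 4.0
    direction: str = "positive"

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gate gene must be non-empty")
        if not np.isfinite(self.threshold):
            raise ValidationError("gate threshold must be finite")
        if self.direction not in ("positive", "negative"):
            raise ValidationError("gate direction must be 'positive' or 'negative'")


@dataclass
class QuadrantStats:
    """Quadrant co-expression counts for two markers at one shared cutoff.

    Strict inequalities on both sides mean cells lying exactly on a
    threshold belong to no quadrant; they are tallied in ``n_boundary`` so
    the four counts plus the boundary count always sum to ``n_total``.
    """

    gene_x: str
    gene_y: str
    threshold: float
    n_total: int
    n_double_pos: int
    n_x_only: int
    n_y_only: int
    n_double_neg: int
    n_boundary: int

    def __post_init__(self) -> None:
        parts = self.n_double_pos + self.n_x_only + self.n_y_only + self.n_double_neg
        if parts + self.n_boundary != self.n_total:
            raise ValidationError("quadrant counts + boundary must sum to total cells")

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_total if self.n_total else float("nan")

    @property
    def pct_double_pos(self) -> float:
        return self._pct(self.n_double_pos)

    @property
    def pct_x_only(self) -> float:
        return self._pct(self.n_x_only)

    @property
    def pct_y_only(self) -> float:
        return self._pct(self.n_y_only)

    @property
    def pct_double_neg(self) -> float:
        return self._pct(self.n_double_neg)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("double_positive", self.n_double_pos, self.pct_double_pos),
            (f"{self.gene_x}_only", self.n_x_only, self.pct_x_only),
            (f"{self.gene_y}_only", self.n_y_only, self.pct_y_only),
            ("double_negative", self.n_double_neg, self.pct_double_neg),
            ("boundary", self.n_boundary, self._pct(self.n_boundary)),
        ]
        return pd.DataFrame(rows, columns=["quadrant", "count", "percent"])


@dataclass
class SignatureGeneSet:
    """Gene signature with full differential-expression provenance.

    ``table`` holds one row per signature gene with columns
    ``gene, mean_pos, mean_neg, t_stat, p_value, q_value, fold_change``,
    ordered by ascending q, then descending fold change, then gene id.
    """

    genes: list[str]
    table: pd.DataFrame
    q_max: float
    fc_min: float

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "table": self.table.to_dict(orient="list"),
            "q_max": self.q_max,
            "fc_min": self.fc_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureGeneSet":
        return cls(
            genes=list(d["genes"]),
            table=pd.DataFrame(d["table"]),
            q_max=float(d["q_max"]),
            fc_min=float(d["fc_min"]),
        )


@dataclass
class ScoreResult:
    """Per-sample signature scores plus the signature genes not found."""

    scores: pd.Series  # index = sample ids, values = scores
    absent_genes: list[str]
    normalize: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class RiskStratification:
    """Median-split risk groups: score > median -> high, otherwise low."""

    scores: pd.Series
    cutoff: float
    group: pd.Series  # 'high' / 'low', same index as scores

    @property
    def high_ids(self) -> list[str]:
        return list(self.group.index[self.group == "high"])

    @property
    def low_ids(self) -> list[str]:
        return list(self.group.index[self.group == "low"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.scores.index, "score": self.scores.values, "group": self.group.values}
        )


@dataclass
class CoxCoefficient:
    name: str
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class SurvivalFit:
    """Fitted Cox proportional-hazards model.

    Hazard ratios are exp(coef) with 95% Wald intervals on the log scale.
    ``logrank_p`` is filled only when the model has a single binary
    covariate, where the log-rank test is the natural companion.
    """

    coefficients: list[CoxCoefficient]
    n: int
    n_events: int
    log_likelihood: float
    ties: str
    n_dropped_missing: int = 0
    logrank_p: float | None = None

    def coefficient(self, name: str) -> CoxCoefficient:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(f"no covariate named {name!r} in fit")

    def to_dict(self) -> dict:
        return {
            "coefficients": [dataclasses.asdict(c) for c in self.coefficients],
            "n": self.n,
            "n_events": self.n_events,
            "log_likelihood": self.log_likelihood,
            "ties": self.ties,
            "n_dropped_missing": self.n_dropped_missing,
            "logrank_p": self.logrank_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalFit":
        return cls(
            coefficients=[CoxCoefficient(**c) for c in d["coefficients"]],
            n=int(d["n"]),
            n_events=int(d["n_events"]),
            log_likelihood=float(d["log_likelihood"]),
            ties=d["ties"],
            n_dropped_missing=int(d.get("n_dropped_missing", 0)),
            logrank_p=d.get("logrank_p"),
        )


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are the ordered distinct event times; ``survival[i]`` is the
    estimated survival probability just after ``times[i]``.  ``at_risk``
    and ``n_events`` refer to the risk set at each event time; censoring
    times are kept for plotting marks.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "survival": self.survival.tolist(),
            "at_risk": self.at_risk.tolist(),
            "n_events": self.n_events.tolist(),
            "censor_times": self.censor_times.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KMCurve":
        return cls(
            times=np.asarray(d["times"], dtype=float),
            survival=np.asarray(d["survival"], dtype=float),
            at_risk=np.asarray(d["at_risk"], dtype=int),
            n_events=np.asarray(d["n_events"], dtype=int),
            censor_times=np.asarray(d["censor_times"], dtype=float),
        )


@dataclass
class StudyEffect:
    label: str
    log_hr: float
    se: float
    weight: float = float("nan")


@dataclass
class MetaResult:
    """Inverse-variance pooled hazard ratio across cohorts.

    ``method`` is ``"fixed"`` or ``"dersimonian_laird"``; heterogeneity is
    summarised by Cochran's Q (df = k-1), the between-study variance tau2
    and I2 (%).
    """

    studies: list[StudyEffect]
    method: str
    pooled_log_hr: float
    pooled_se: float
    q_statistic: float
    df: int
    tau2: float
    i2: float

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.pooled_log_hr - 1.959963984540054 * self.pooled_se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.pooled_log_hr + 1.959963984540054 * self.pooled_se))

    def to_dict(self) -> dict:
        return {
            "studies": [dataclasses.asdict(s) for s in self.studies],
            "method": self.method,
            "pooled_log_hr": self.pooled_log_hr,
            "pooled_se": self.pooled_se,
            "pooled_hr": self.pooled_hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "q_statistic": self.q_statistic,
            "df": self.df,
            "tau2": self.tau2,
            "i2": self.i2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetaResult":
        return cls(
            studies=[StudyEffect(**s) for s in d["studies"]],
            method=d["method"],
            pooled_log_hr=float(d["pooled_log_hr"]),
            pooled_se=float(d["pooled_se"]),
            q_statistic=float(d["q_statistic"]),
            df=int(d["df"]),
            tau2=float(d["tau2"]),
            i2=float(d["i2"]),
        )
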