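"""Readers and writers for the tabular and sparse formats the pipeline uses.

Expression matrices travel as TSV/CSV (first column = gene ids, header =
sample ids) or as a Matrix Market triple (``matrix.mtx`` + ``genes.tsv`` +
``barcodes.tsv``).  Clinical tables are delimited text with at least
``sample_id``, ``os_time`` and ``event`` columns.  Result objects go to
JSON (lossless round trip) or TSV (for humans and spreadsheets).

Readers never reorder genes or samples, never guess orientation, and
refuse duplicate identifiers; the scale of an expression matrix is always
supplied by the caller, never inferred.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    FormatError,
    KMCurve,
    MetaResult,
    QuadrantStats,
    RiskStratification,
    SignatureGeneSet,
    SurvivalFit,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "write_results",
    "read_survival_fit",
    "read_meta_result",
    "read_signature",
]

_DELIMS = {"tsv": "\t", "csv": ","}


def read_expression_matrix(
    path: str | Path, format: str = "tsv", scale: str = "log2_tpm_plus1"
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV or a Matrix Market triple.

    For ``mtx_triple``, ``path`` is the ``.mtx`` file; ``genes.tsv`` and
    ``barcodes.tsv`` sidecars are looked up next to it (first column used).
    The scale is taken from the caller, never guessed from the values.
    """
    path = Path(path)
    if format in _DELIMS:
        df = pd.read_csv(path, sep=_DELIMS[format], index_col=0)
        genes = [str(g) for g in df.index]
        samples = [str(s) for s in df.columns]
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as e:
            raise FormatError(f"non-numeric expression value in {path}: {e}") from None
        return ExpressionMatrix(genes, samples, values, scale=scale)
    if format == "mtx_triple":
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        for side in (genes_path, barcodes_path):
            if not side.exists():
                raise FormatError(f"missing sidecar file {side}")
        mat = spio.mmread(path)
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
        if mat.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"MTX header shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(barcodes)} barcodes)"
            )
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        return ExpressionMatrix(genes, barcodes, dense, scale=scale)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> Path:
    """Write to TSV/CSV or a Matrix Market triple (``path`` = the .mtx file)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format in _DELIMS:
        matrix.to_frame().to_csv(path, sep=_DELIMS[format], index_label="gene_id")
        return path
    if format == "mtx_triple":
        spio.mmwrite(path, sparse.coo_matrix(matrix.values))
        pd.Series(matrix.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(matrix.sample_ids).to_csv(path.parent / "barcodes.tsv", sep="\t", index=False, header=False)
        return path
    raise ValueError(f"unknown expression format {format!r}")


def read_clinical_table(path: str | Path, sep: str = "\t") -> ClinicalTable:
    """Read a clinical table; validation happens in :class:`ClinicalTable`."""
    df = pd.read_csv(path, sep=sep)
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep=sep, index=False)
    return path


def read_signature(path: str | Path) -> SignatureGeneSet:
    with open(path) as fh:
        return SignatureGeneSet.from_dict(json.load(fh))


def read_survival_fit(path: str | Path) -> SurvivalFit:
    with open(path) as fh:
        return SurvivalFit.from_dict(json.load(fh))


def read_meta_result(path: str | Path) -> MetaResult:
    with open(path) as fh:
        return MetaResult.from_dict(json.load(fh))


def _meta_to_frame(res: MetaResult) -> pd.DataFrame:
    rows = [
        {"study": s.label, "log_hr": s.log_hr, "se": s.se, "weight": s.weight}
        for s in res.studies
    ]
    rows.append(
        {
            "study": f"pooled ({res.method})",
            "log_hr": res.pooled_log_hr,
            "se": res.pooled_se,
            "weight": float("nan"),
        }
    )
    return pd.DataFrame(rows)


def write_results(obj, path: str | Path, format: str = "json") -> Path:
    """Serialize a pipeline result object to JSON or TSV.

    JSON keeps full float precision (lossless round trip); TSV output is
    one row per record.  Unknown object types raise ``TypeError``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        if isinstance(obj, (SurvivalFit, MetaResult, SignatureGeneSet, KMCurve)):
            payload = obj.to_dict()
        elif isinstance(obj, QuadrantStats):
            payload = {
                "gene_x": obj.gene_x,
                "gene_y": obj.gene_y,
                "threshold": obj.threshold,
                "counts": obj.to_frame().to_dict(orient="list"),
                "n_total": obj.n_total,
            }
        elif isinstance(obj, RiskStratification):
            payload = {
                "cutoff": obj.cutoff,
                "samples": obj.to_frame().to_dict(orient="list"),
            }
        else:
            raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return path
    if format == "tsv":
        if isinstance(obj, MetaResult):
            frame = _meta_to_frame(obj)
        elif isinstance(obj, SignatureGeneSet):
            frame = obj.table
        elif isinstance(obj, QuadrantStats):
            frame = obj.to_frame()
        elif isinstance(obj, RiskStratification):
            frame = obj.to_frame()
        elif isinstance(obj, KMCurve):
            frame = pd.DataFrame(
                {
                    "time": obj.times,
                    "survival": obj.survival,
                    "at_risk": obj.at_risk,
                    "n_events": obj.n_events,
                }
            )
        elif isinstance(obj, SurvivalFit):
            frame = pd.DataFrame(
                [
                    {
                        "covariate": c.name,
                        "coef": c.coef,
                        "se": c.se,
                        "hr": c.hr,
                        "ci_low": c.ci_low,
                        "ci_high": c.ci_high,
                        "p": c.p,
                    }
                    for c in obj.coefficients
                ]
            )
        else:
            raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
        frame.to_csv(path, sep="\t", index=False)
        return path
    raise ValueError(f"unknown result format {format!r}")
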