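"""Readers and writers for the external representations the pipeline touches.

Formats supported:

* expression matrices — TSV (genes in rows, header row of sample ids) or
  MatrixMarket MTX with sidecar gene / barcode lists for UMI counts;
* sample phenotype tables and survival tables — TSV with named columns;
* gene sets — GMT;
* biclusters — versioned JSON.

All readers validate on load and fail loudly: duplicate identifiers,
missing values, negative survival times and unknown enum levels are
errors, never silently repaired.  Orientation of expression TSVs is fixed
as genes-in-rows (the RSEM/Xena convention); an explicit ``transpose``
flag exists but orientation is never inferred.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "SurvivalRecord",
    "GeneSet",
    "VALID_SCALES",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_survival",
    "write_survival",
    "read_geneset_gmt",
    "write_geneset_gmt",
    "read_biclusters",
    "write_biclusters",
]

VALID_SCALES = frozenset({"log_rsem", "log_tpm", "umi_count", "residual"})

#: scales on which percentile-set analysis is meaningful (anything continuous)
CONTINUOUS_SCALES = frozenset({"log_rsem", "log_tpm", "residual"})

COHORTS = frozenset({"normal", "tumor"})
SUBTYPES = frozenset({"LGG", "GBM"})
GRADES = frozenset({"II", "III", "IV"})
IDH_LEVELS = frozenset({"mutant_and_or_codel", "wildtype", "unknown"})

BICLUSTER_SCHEMA_VERSION = 1


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: set[str] = set()
    for i in ids:
        if i in seen:
            dups.add(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(dups)[:5]}")


@dataclass
class ExpressionMatrix:
    """A dense genes x samples expression matrix with a scale tag.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers.
    values
        Dense ``(n_genes, n_samples)`` float array with no missing values.
    scale
        One of ``log_rsem``, ``log_tpm``, ``umi_count``, ``residual``.
        ``umi_count`` additionally requires non-negative integer values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {sorted(VALID_SCALES)}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")
        if self.scale == "umi_count":
            if np.any(self.values < 0):
                raise ValueError("umi_count matrix contains negative values")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("umi_count matrix contains non-integer values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[rows, :], self.scale)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), samples, self.values[:, cols], self.scale)


@dataclass
class SampleAnnotation:
    """Phenotype record for one sample.

    ``region`` is only meaningful for normal (GTEx-like) samples;
    ``subtype``/``grade``/``idh_codel`` only for tumor samples.  Missing
    fields stay ``None`` (or ``"unknown"`` for idh_codel), never imputed.
    """

    sample_id: str
    cohort: str
    region: str | None = None
    subtype: str | None = None
    grade: str | None = None
    idh_codel: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r} for sample {self.sample_id}")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r} for sample {self.sample_id}")
        if self.grade is not None and self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r} for sample {self.sample_id}")
        if self.idh_codel is not None and self.idh_codel not in IDH_LEVELS:
            raise ValueError(f"unknown idh_codel {self.idh_codel!r} for sample {self.sample_id}")
        if self.cohort == "tumor" and self.region is not None:
            warnings.warn(
                f"sample {self.sample_id}: region given for a tumor sample; ignored",
                stacklevel=2,
            )
            self.region = None
        if self.cohort == "normal":
            for fld in ("subtype", "grade", "idh_codel"):
                if getattr(self, fld) is not None:
                    warnings.warn(
                        f"sample {self.sample_id}: {fld} given for a normal sample; ignored",
                        stacklevel=2,
                    )
                    setattr(self, fld, None)
        if self.age is not None and self.age < 0:
            raise ValueError(f"negative age for sample {self.sample_id}")


@dataclass(frozen=True)
class SurvivalRecord:
    """Overall-survival observation: follow-up time in days and death indicator."""

    sample_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for sample {self.sample_id}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    scale: str,
    *,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or MatrixMarket MTX.

    TSV layout is genes-in-rows: header row of sample ids, first column
    gene ids.  For ``.mtx`` input the sidecar ``genes_path`` and
    ``barcodes_path`` (one id per line; rows = genes, columns = barcodes)
    are required.  Duplicate ids are an error, never collapsed.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or barcodes_path is None:
            raise ValueError("MTX input requires genes_path and barcodes_path sidecars")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [ln.strip().split("\t")[0] for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        barcodes = [ln.strip().split("\t")[0] for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
        values = np.asarray(mat, dtype=float)
        if transpose:
            values = values.T
        return ExpressionMatrix(genes, barcodes, values, scale)

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in expression matrix") from exc
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    if transpose:
        genes, samples = samples, genes
        values = values.T
    return ExpressionMatrix(genes, samples, values, scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as genes-in-rows TSV (index label ``gene_id``)."""
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_expression_mtx(
    expr: ExpressionMatrix,
    path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write a UMI matrix as MTX plus gene / barcode sidecar lists."""
    sparse = scipy.sparse.coo_matrix(expr.values)
    scipy.io.mmwrite(str(path), sparse)
    Path(genes_path).write_text("\n".join(expr.gene_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(expr.sample_ids) + "\n")


# ---------------------------------------------------------------------------
# annotations / survival / gene sets
# ---------------------------------------------------------------------------

def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s if s and s.lower() not in {"na", "nan", ""} else None


def read_annotations(
    path: str | Path,
    *,
    expression_samples: Iterable[str] | None = None,
) -> list[SampleAnnotation]:
    """Read a phenotype TSV; required columns ``sample_id`` and ``cohort``.

    Optional columns: region, subtype, grade, idh_codel, age.  When
    ``expression_samples`` is given, annotated samples absent from the
    expression matrix trigger a single summary warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "cohort"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    _check_unique(list(df["sample_id"]), "sample ids in annotation table")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        age = _opt(d.get("age"))
        records.append(
            SampleAnnotation(
                sample_id=str(d["sample_id"]),
                cohort=str(d["cohort"]).strip(),
                region=_opt(d.get("region")),
                subtype=_opt(d.get("subtype")),
                grade=_opt(d.get("grade")),
                idh_codel=_opt(d.get("idh_codel")),
                age=float(age) if age is not None else None,
            )
        )
    if expression_samples is not None:
        known = set(expression_samples)
        n_missing = sum(1 for r in records if r.sample_id not in known)
        if n_missing:
            warnings.warn(
                f"{n_missing} annotated sample(s) absent from expression matrix",
                stacklevel=2,
            )
    return records


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "cohort": a.cohort,
            "region": a.region,
            "subtype": a.subtype,
            "grade": a.grade,
            "idh_codel": a.idh_codel,
            "age": a.age,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_survival(
    path: str | Path,
    *,
    expression_samples: Iterable[str] | None = None,
) -> list[SurvivalRecord]:
    """Read a survival TSV with columns ``sample_id``, ``time``, ``event``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    _check_unique([str(s) for s in df["sample_id"]], "sample ids in survival table")
    records = []
    for row in df.itertuples(index=False):
        ev = int(row.event)
        if ev not in (0, 1):
            raise ValueError(f"{path}: event must be 0/1, got {row.event!r}")
        records.append(SurvivalRecord(str(row.sample_id), float(row.time), bool(ev)))
    if expression_samples is not None:
        known = set(expression_samples)
        n_missing = sum(1 for r in records if r.sample_id not in known)
        if n_missing:
            warnings.warn(
                f"{n_missing} survival sample(s) absent from expression matrix",
                stacklevel=2,
            )
    return records


def write_survival(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    rows = [{"sample_id": r.sample_id, "time": r.time, "event": int(r.event)} for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_geneset_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: one set per line — name, description, then tab-separated genes."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        sets.append(GeneSet(name, frozenset(genes)))
    return sets


def write_geneset_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = [f"{s.name}\t\t" + "\t".join(sorted(s.genes)) for s in sets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# biclusters (versioned JSON)
# ---------------------------------------------------------------------------

def write_biclusters(biclusters, path: str | Path) -> None:
    """Serialize biclusters (with provenance parameters) to versioned JSON."""
    payload = {
        "schema_version": BICLUSTER_SCHEMA_VERSION,
        "biclusters": [
            {
                "genes": sorted(b.genes),
                "samples": sorted(b.samples),
                "direction": b.direction,
                "params": {
                    "p": b.params.p,
                    "j_min": b.params.j_min,
                    "min_genes": b.params.min_genes,
                    "min_samples": b.params.min_samples,
                    "sample_frequency_threshold": b.params.sample_frequency_threshold,
                },
            }
            for b in biclusters
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_biclusters(path: str | Path):
    """Read biclusters written by :func:`write_biclusters`; round-trip exact."""
    from .biclustering_core import Bicluster, BiclusterParams

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed bicluster file") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ValueError(f"{path}: missing schema_version")
    if payload["schema_version"] != BICLUSTER_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported schema_version {payload['schema_version']!r} "
            f"(expected {BICLUSTER_SCHEMA_VERSION})"
        )
    out = []
    for b in payload["biclusters"]:
        params = BiclusterParams(
            p=b["params"]["p"],
            j_min=b["params"]["j_min"],
            min_genes=b["params"]["min_genes"],
            min_samples=b["params"]["min_samples"],
            sample_frequency_threshold=b["params"]["sample_frequency_threshold"],
        )
        out.append(
            Bicluster(
                genes=frozenset(b["genes"]),
                samples=frozenset(b["samples"]),
                direction=b["direction"],
                params=params,
            )
        )
    return out
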