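"""Readers and writers for expression models, dosage matrices, and
predicted-expression matrices.

Three plain-text tab-separated formats are shared by every other module:

* **Model TSV** — header ``gene  variant_id  ref_allele  effect_allele
  weight``; one row per (gene, variant) weight.  An optional SQLite dialect
  mirrors the PredictDB convention of a ``weights`` table plus a gene-level
  ``extra`` table.
* **Dosage TSV** — header ``FID IID`` followed by variant ids; one row per
  subject, dosages in [0, 2].
* **Prediction TSV** — header ``FID IID`` followed by gene ids; one row per
  subject (the PrediXcan output dialect).

Variant identifiers are opaque string tokens (``chr_pos_ref_alt_build``
convention) and matching anywhere in the package is exact string equality;
no allele harmonization or liftover is attempted.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "ModelVariant",
    "ExpressionModel",
    "DosageMatrix",
    "PredictionMatrix",
    "ModelParseError",
    "read_model",
    "write_model",
    "read_dosage",
    "write_dosage",
    "read_prediction",
    "write_prediction",
]

_MODEL_HEADER = ["gene", "variant_id", "ref_allele", "effect_allele", "weight"]


class ModelParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ModelVariant:
    """A weighted cis-variant of one gene's prediction model."""

    variant_id: str
    ref_allele: str
    effect_allele: str
    weight: float

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if not np.isfinite(self.weight):
            raise ValueError(f"weight for {self.variant_id!r} is not finite")


@dataclass
class ExpressionModel:
    """Per-tissue map gene -> ordered list of weighted cis-variants."""

    tissue: str
    genes: dict[str, list[ModelVariant]]

    def __post_init__(self) -> None:
        for gene, variants in self.genes.items():
            if not variants:
                raise ValueError(f"gene {gene!r} has no variants")
            ids = [v.variant_id for v in variants]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate variant ids within gene {gene!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def variant_ids(self) -> list[str]:
        """All variant ids in first-appearance order, deduplicated."""
        seen: dict[str, None] = {}
        for variants in self.genes.values():
            for v in variants:
                seen.setdefault(v.variant_id, None)
        return list(seen)


@dataclass
class DosageMatrix:
    """Subjects x variants effect-allele count matrix.

    ``subject_ids`` are (family_id, individual_id) pairs; every dosage lies
    in [0, 2].
    """

    subject_ids: list[tuple[str, str]]
    variant_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subject_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.variant_ids)} variants"
            )
        if self.dosages.size and (
            np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2
        ):
            raise ValueError("dosages must lie in [0, 2]")
        if np.isnan(self.dosages).any():
            raise ValueError("dosages contain NaN")


@dataclass
class PredictionMatrix:
    """Subjects x genes predicted-expression matrix."""

    subject_ids: list[tuple[str, str]]
    gene_ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.gene_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.gene_ids)} genes"
            )
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("prediction values must be finite")


# ---------------------------------------------------------------------------
# model TSV / SQLite


def _parse_model_rows(
    rows: Iterable[tuple[str, str, str, str, str]],
    tissue: str,
    source: str,
) -> ExpressionModel:
    genes: dict[str, list[ModelVariant]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, (gene, vid, ref, eff, weight_text) in rows:
        if weight_text == "" or weight_text.lower() == "nan":
            raise ModelParseError(
                f"{source}: missing or NaN weight on line {lineno}"
            )
        try:
            weight = float(weight_text)
        except ValueError as exc:
            raise ModelParseError(
                f"{source}: unparsable weight {weight_text!r} on line {lineno}"
            ) from exc
        if not np.isfinite(weight):
            raise ModelParseError(
                f"{source}: missing or NaN weight on line {lineno}"
            )
        key = (gene, vid)
        if key in seen:
            raise ModelParseError(
                f"{source}: duplicate (gene, variant) record {key} on line {lineno}"
            )
        seen.add(key)
        genes.setdefault(gene, []).append(ModelVariant(vid, ref, eff, weight))
    if not genes:
        raise ModelParseError(f"{source}: model contains no weight rows")
    return ExpressionModel(tissue=tissue, genes=genes)


def read_model(path: str | Path, dialect: str = "tsv", tissue: str | None = None) -> ExpressionModel:
    """Read an expression model.

    Gene order is first-appearance order; variant order within a gene is file
    order.  Missing/NaN weights and duplicate (gene, variant) pairs are
    errors, never silently dropped or merged.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_model_tsv(path, tissue)
    if dialect == "sqlite":
        return _read_model_sqlite(path, tissue)
    raise ValueError(f"unknown model dialect {dialect!r}")


def _read_model_tsv(path: Path, tissue: str | None) -> ExpressionModel:
    with open(path, encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ModelParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header != _MODEL_HEADER:
        raise ModelParseError(
            f"{path}: expected header {_MODEL_HEADER}, got {header}"
        )

    def rows():
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ModelParseError(
                    f"{path}: expected 5 fields on line {lineno}, got {len(fields)}"
                )
            yield lineno, tuple(fields)

    return _parse_model_rows(rows(), tissue or path.stem, str(path))


def _read_model_sqlite(path: Path, tissue: str | None) -> ExpressionModel:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        cur = con.execute(
            "SELECT rowid, gene, varID, ref_allele, eff_allele, weight "
            "FROM weights ORDER BY rowid"
        )
        def rows():
            for rowid, gene, vid, ref, eff, weight in cur:
                yield rowid, (gene, vid, ref, eff, "" if weight is None else str(weight))
        return _parse_model_rows(rows(), tissue or Path(path).stem, str(path))
    finally:
        con.close()


def write_model(model: ExpressionModel, path: str | Path, dialect: str = "tsv") -> None:
    """Write a model re-readable by :func:`read_model`, deterministic row order."""
    if dialect == "tsv":
        _write_model_tsv(model, Path(path))
    elif dialect == "sqlite":
        _write_model_sqlite(model, Path(path))
    else:
        raise ValueError(f"unknown model dialect {dialect!r}")


def _write_model_tsv(model: ExpressionModel, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_MODEL_HEADER) + "\n")
        for gene, variants in model.genes.items():
            for v in variants:
                fh.write(
                    f"{gene}\t{v.variant_id}\t{v.ref_allele}\t{v.effect_allele}"
                    f"\t{v.weight!r}\n"
                )


def _write_model_sqlite(model: ExpressionModel, path: Path) -> None:
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.execute(
            "CREATE TABLE weights (gene TEXT, rsid TEXT, varID TEXT, "
            "ref_allele TEXT, eff_allele TEXT, weight REAL)"
        )
        con.execute(
            "CREATE TABLE extra (gene TEXT PRIMARY KEY, n_snps_in_model INTEGER)"
        )
        for gene, variants in model.genes.items():
            con.executemany(
                "INSERT INTO weights VALUES (?, ?, ?, ?, ?, ?)",
                [
                    (gene, v.variant_id, v.variant_id, v.ref_allele,
                     v.effect_allele, v.weight)
                    for v in variants
                ],
            )
            con.execute(
                "INSERT INTO extra VALUES (?, ?)", (gene, len(variants))
            )
        con.commit()
    finally:
        con.close()


# ---------------------------------------------------------------------------
# subject x column matrices (dosage, prediction)


def _read_subject_matrix(path: Path) -> tuple[list[tuple[str, str]], list[str], np.ndarray]:
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise ModelParseError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) < 2 or header[0] != "FID" or header[1] != "IID":
        raise ModelParseError(f"{path}: header must start with 'FID IID'")
    columns = header[2:]
    n_cols = len(columns)
    subjects: list[tuple[str, str]] = []
    data = np.empty((len(lines) - 1, n_cols), dtype=float)
    for i, line in enumerate(lines[1:]):
        fields = line.split()
        if len(fields) != n_cols + 2:
            raise ModelParseError(
                f"{path}: ragged row {i + 1} (expected {n_cols + 2} fields, "
                f"got {len(fields)})"
            )
        subjects.append((fields[0], fields[1]))
        try:
            data[i] = [float(x) for x in fields[2:]]
        except ValueError as exc:
            raise ModelParseError(f"{path}: unparsable value in row {i + 1}") from exc
    return subjects, columns, data


def read_dosage(path: str | Path) -> DosageMatrix:
    """Read a whitespace-delimited dosage file (``FID IID v1 v2 ...``)."""
    subjects, variant_ids, data = _read_subject_matrix(Path(path))
    if data.size and (data.min() < 0 or data.max() > 2):
        bad = np.argwhere((data < 0) | (data > 2))[0]
        raise ModelParseError(
            f"{path}: dosage {data[tuple(bad)]} outside [0, 2] at row "
            f"{bad[0] + 1}, variant {variant_ids[bad[1]]}"
        )
    return DosageMatrix(subjects, variant_ids, data)


def read_prediction(path: str | Path) -> PredictionMatrix:
    """Read a PrediXcan-style predicted-expression file."""
    subjects, gene_ids, data = _read_subject_matrix(Path(path))
    return PredictionMatrix(subjects, gene_ids, data)


def _write_subject_matrix(
    subject_ids: list[tuple[str, str]],
    columns: list[str],
    data: np.ndarray,
    path: Path,
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["FID", "IID", *columns]) + "\n")
        for (fid, iid), row in zip(subject_ids, data):
            fh.write("\t".join([fid, iid, *(repr(float(x)) for x in row)]) + "\n")


def write_dosage(dm: DosageMatrix, path: str | Path) -> None:
    _write_subject_matrix(dm.subject_ids, dm.variant_ids, dm.dosages, Path(path))


def write_prediction(pm: PredictionMatrix, path: str | Path) -> None:
    _write_subject_matrix(pm.subject_ids, pm.gene_ids, pm.values, Path(path))
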