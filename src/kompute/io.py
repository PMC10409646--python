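"""Delimited-text I/O for Z-score matrices, correlation matrices and tables.

Matrix dialect: header row of gene IDs, first column of phenotype IDs,
missing cells empty or "NA". Delimiter (comma/tab) is auto-detected unless
given. Phenotypes-in-rows is the default orientation; pass
``orientation="genes_in_rows"`` for transposed files.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import PhenotypeTable
from .types import CorrelationMatrix, ImputationResult, ZScoreMatrix, \
    nearest_psd_correlation

__all__ = [
    "read_zscore_matrix",
    "write_zscore_matrix",
    "read_correlation_matrix",
    "write_correlation_matrix",
    "read_phenotype_table",
    "write_imputation_result",
]

_NA = ("", "NA", "NaN", "nan")
#: float format used by all writers: 17 significant digits round-trips doubles
_FLOAT_FMT = "%.17g"


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def _read_labeled_matrix(
    path: str | Path, delimiter: str | None
) -> tuple[np.ndarray, list[str], list[str]]:
    delimiter = delimiter or _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        col_labels = [c.strip() for c in header[1:]]
        width = len(header)
        row_labels: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(rec)} fields, "
                    f"expected {width})"
                )
            row_labels.append(rec[0].strip())
            vals = []
            for ci, cell in enumerate(rec[1:], start=2):
                cell = cell.strip()
                if cell in _NA:
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} "
                            f"in field {ci}"
                        ) from None
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.array(rows, dtype=float), row_labels, col_labels


def read_zscore_matrix(
    path: str | Path,
    orientation: str = "phenotypes_in_rows",
    delimiter: str | None = None,
) -> ZScoreMatrix:
    """Read a Z-score matrix; labels preserved verbatim, NA/empty = missing."""
    values, row_labels, col_labels = _read_labeled_matrix(path, delimiter)
    if orientation == "genes_in_rows":
        values = values.T
        row_labels, col_labels = col_labels, row_labels
    elif orientation != "phenotypes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ZScoreMatrix(values, row_labels, col_labels)


def _write_labeled_matrix(
    path: str | Path,
    values: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
    delimiter: str,
    corner: str,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow([corner] + list(col_labels))
        for label, row in zip(row_labels, values):
            writer.writerow(
                [label]
                + ["NA" if np.isnan(v) else _FLOAT_FMT % v for v in row]
            )


def write_zscore_matrix(
    z: ZScoreMatrix, path: str | Path, delimiter: str = ","
) -> None:
    values = np.where(z.mask, np.nan, z.values)
    _write_labeled_matrix(
        path, values, z.phenotype_ids, z.gene_ids, delimiter, "phenotype_id"
    )


def read_correlation_matrix(
    path: str | Path,
    repair_psd: bool = False,
    delimiter: str | None = None,
) -> CorrelationMatrix:
    """Read and validate a square labeled correlation matrix.

    With ``repair_psd=True``, asymmetry, off-unit diagonals and indefiniteness
    are repaired (symmetrize, eigenvalue clipping, diagonal rescale) instead
    of raising.
    """
    values, row_labels, col_labels = _read_labeled_matrix(path, delimiter)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: correlation matrix must be square, got {values.shape}"
        )
    if row_labels != col_labels:
        raise ValueError(f"{path}: row and column labels differ")
    if repair_psd:
        values = nearest_psd_correlation(values)
    return CorrelationMatrix(values, row_labels)


def write_correlation_matrix(
    sigma: CorrelationMatrix, path: str | Path, delimiter: str = ","
) -> None:
    _write_labeled_matrix(
        path,
        sigma.values,
        sigma.phenotype_ids,
        sigma.phenotype_ids,
        delimiter,
        "phenotype_id",
    )


def read_phenotype_table(
    path: str | Path, delimiter: str | None = None
) -> PhenotypeTable:
    """Read a long-format phenotype table (subject_id, phenotype_id, value,
    plus one column per covariate)."""
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str, "phenotype_id": str})
    if "value" in df.columns:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    return PhenotypeTable(df)


def write_imputation_result(
    result: ImputationResult,
    z_path: str | Path,
    info_path: str | Path | None = None,
    report_path: str | Path | None = None,
    delimiter: str = ",",
) -> None:
    """Write the imputed matrix, its info companion, and the flag report.

    The report is tab-delimited with one line per non-imputable gene column
    and one per below-threshold imputed cell.
    """
    _write_labeled_matrix(
        z_path,
        result.z_full,
        result.phenotype_ids,
        result.gene_ids,
        delimiter,
        "phenotype_id",
    )
    if info_path is not None:
        _write_labeled_matrix(
            info_path,
            result.info,
            result.phenotype_ids,
            result.gene_ids,
            delimiter,
            "phenotype_id",
        )
    if report_path is not None:
        with open(report_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["flag", "phenotype_id", "gene_id", "info"])
            for gene in result.non_imputable:
                writer.writerow(["non_imputable", "", gene, ""])
            for pheno, gene, info in result.below_threshold:
                writer.writerow(
                    ["below_threshold", pheno, gene, "%.6g" % info]
                )
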