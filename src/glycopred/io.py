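"""Readers and writers for the on-disk exchange formats.

Expression matrices travel as a 10X-style Matrix Market triplet
(``matrix.mtx`` in genes x cells orientation, plus line-aligned
``features.tsv`` and ``barcodes.tsv``); the lectin signal as a two-column
CSV (cell_id, raw_count); subtype labels as a TSV; the planted ground truth
as JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simdata import ExpressionMatrix, GroundTruthManifest, LectinProfile

__all__ = [
    "FormatError",
    "write_matrix",
    "read_matrix",
    "write_lectin",
    "read_lectin",
    "write_manifest",
    "read_manifest",
    "write_labels",
]

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
SUBTYPES_FILE = "subtypes.tsv"
LECTIN_FILE = "lectin.csv"
MANIFEST_FILE = "manifest.json"


class FormatError(ValueError):
    """A triplet member is missing, malformed, or inconsistent with the rest."""


def write_matrix(expr: ExpressionMatrix, directory) -> None:
    """Write the MTX triplet plus the subtype TSV.

    Raw counts are written when the matrix carries them (round-trips
    bit-exactly for integers); otherwise the log-normalized values are
    written. Orientation on disk is genes x cells, the 10X convention.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    values = expr.counts if expr.counts is not None else expr.values
    mat = sparse.csc_matrix(np.asarray(values).T)
    spio.mmwrite(directory / MATRIX_FILE, mat)
    (directory / FEATURES_FILE).write_text("".join(f"{g}\n" for g in expr.gene_ids))
    (directory / BARCODES_FILE).write_text("".join(f"{c}\n" for c in expr.cell_ids))
    with open(directory / SUBTYPES_FILE, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cell_id", "subtype"])
        for c, s in zip(expr.cell_ids, expr.subtype_labels):
            writer.writerow([c, s])


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    return [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]


def read_matrix(
    matrix_path, features_path=None, barcodes_path=None, subtypes_path=None
) -> ExpressionMatrix:
    """Read an MTX triplet (genes x cells on disk) into a cells x genes matrix.

    ``matrix_path`` may be the directory holding the conventional file names.
    Counts (integer data) are normalized to log1p counts-per-10k; the raw
    counts are retained on the result. A subtype TSV is optional; absent
    labels default to a single pseudo-subtype.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.is_dir():
        directory = matrix_path
        matrix_path = directory / MATRIX_FILE
        features_path = features_path or directory / FEATURES_FILE
        barcodes_path = barcodes_path or directory / BARCODES_FILE
        if subtypes_path is None and (directory / SUBTYPES_FILE).exists():
            subtypes_path = directory / SUBTYPES_FILE
    if features_path is None or barcodes_path is None:
        raise FormatError("features and barcodes paths required when not reading a directory")
    if not Path(matrix_path).exists():
        raise FormatError(f"missing file: {matrix_path}")

    mat = spio.mmread(matrix_path)
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    n_genes, n_cells = dense.shape

    gene_ids = _read_lines(Path(features_path))
    cell_ids = _read_lines(Path(barcodes_path))
    if len(gene_ids) != n_genes:
        raise FormatError(
            f"{features_path}: {len(gene_ids)} features but matrix has {n_genes} rows"
        )
    if len(cell_ids) != n_cells:
        raise FormatError(
            f"{barcodes_path}: {len(cell_ids)} barcodes but matrix has {n_cells} columns"
        )

    if subtypes_path is not None:
        table = pd.read_csv(subtypes_path, sep="\t")
        if set(table["cell_id"]) != set(cell_ids):
            raise FormatError(f"{subtypes_path}: cell ids do not match the barcodes file")
        subtypes = table.set_index("cell_id")["subtype"].reindex(cell_ids).astype(str).tolist()
    else:
        subtypes = ["subtype1"] * n_cells

    counts = dense.T.astype(float)
    is_integer = np.allclose(counts, np.round(counts))
    if is_integer:
        lib = counts.sum(axis=1)
        scale = np.divide(1e4, lib, out=np.zeros_like(lib), where=lib > 0)
        values = np.log1p(counts * scale[:, None])
    else:
        values = counts  # already normalized upstream
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        subtype_labels=subtypes,
        counts=counts if is_integer else None,
    )


def write_lectin(lectin: LectinProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["cell_id", "raw_count"])
        for c, x in zip(lectin.cell_ids, lectin.raw_counts):
            writer.writerow([c, int(x)])


def read_lectin(path) -> LectinProfile:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    table = pd.read_csv(path)
    return LectinProfile(
        raw_counts=table["raw_count"].to_numpy(), cell_ids=table["cell_id"].astype(str).tolist()
    )


def write_manifest(truth: GroundTruthManifest, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> GroundTruthManifest:
    return GroundTruthManifest.from_dict(json.loads(Path(path).read_text()))


def write_labels(dataset, clr_all: np.ndarray, all_cell_ids: list[str], labels_all, path) -> None:
    """Labels TSV over all cells: cell_id, clr_value, label|excluded, split."""
    split_by_cell = {}
    if dataset.split is not None:
        split_by_cell = dict(zip(dataset.retained_cell_ids, dataset.split))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cell_id", "clr_value", "label", "split"])
        for cell, clr, label in zip(all_cell_ids, clr_all, labels_all):
            writer.writerow(
                [
                    cell,
                    f"{clr:.6f}",
                    "excluded" if label < 0 else str(int(label)),
                    split_by_cell.get(cell, ""),
                ]
            )
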