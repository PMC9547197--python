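"""Lectin normalization, quartile phenotype labels, and dataset splitting.

The phenotype labels are built from the lectin signal alone: cells in the top
quartile of the CLR-transformed counts become class 1 (lectin-high), cells in
the bottom quartile class 0 (lectin-low), and the middle half is excluded.
Labeled cells are then randomly partitioned 72/18/10 into train, validation
and test sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simdata import ExpressionMatrix, LectinProfile

__all__ = [
    "DegenerateInputError",
    "LabeledDataset",
    "clr_transform",
    "quartile_binarize",
    "random_split",
    "build_labeled_dataset",
    "with_split",
]

SPLIT_NAMES = ("train", "validation", "test")
DEFAULT_SPLIT = (0.72, 0.18, 0.10)
EXCLUDED = -1


class DegenerateInputError(ValueError):
    """Input too small or otherwise degenerate for the operation."""


def clr_transform(raw_counts) -> np.ndarray:
    """Centered log-ratio across cells with a +1 pseudocount.

    Returns ``ln((x_c + 1) / g)`` where ``g`` is the geometric mean of
    ``x + 1`` over all cells, computed as ``ln(x+1) - mean(ln(x+1))`` so the
    output mean is exactly zero. This is the ADT-tag convention for a single
    lectin feature normalized across cells (across-feature CLR is degenerate
    with one feature).
    """
    x = np.asarray(raw_counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("raw_counts must be a one-dimensional per-cell vector")
    if x.shape[0] < 2:
        raise DegenerateInputError("CLR needs at least 2 cells")
    if np.any(x < 0):
        raise ValueError("lectin counts must be nonnegative")
    logs = np.log1p(x)
    return logs - logs.mean()


def quartile_binarize(values, cell_ids, fraction: float = 0.25) -> np.ndarray:
    """Label the top ``fraction`` of cells 1, the bottom ``fraction`` 0.

    Exactly ``floor(fraction * N)`` cells receive each label; the rest are
    marked excluded (-1). Ties are broken by ascending cell identifier, so
    the labeling is deterministic: among tied values the lexicographically
    last identifiers win the high label.
    """
    values = np.asarray(values, dtype=float)
    cell_ids = list(cell_ids)
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    n = values.shape[0]
    if n != len(cell_ids):
        raise ValueError("values and cell_ids must have equal length")
    if n < 4:
        raise DegenerateInputError("need at least 4 cells to binarize")

    k = int(np.floor(fraction * n))
    order = sorted(range(n), key=lambda i: (values[i], cell_ids[i]))
    labels = np.full(n, EXCLUDED, dtype=int)
    labels[order[:k]] = 0
    labels[order[n - k :]] = 1
    return labels


def random_split(
    cell_ids,
    proportions: tuple[float, float, float] = DEFAULT_SPLIT,
    seed: int = 0,
) -> np.ndarray:
    """Simple random (non-stratified) train/validation/test partition.

    Split sizes are ``floor(p_i * N)`` for validation and test; the
    remainder goes to train. Deterministic given the seed.
    """
    cell_ids = list(cell_ids)
    n = len(cell_ids)
    if n < 3:
        raise DegenerateInputError("need at least 3 cells to split three ways")
    p = np.asarray(proportions, dtype=float)
    if p.shape != (3,) or np.any(p <= 0) or abs(float(p.sum()) - 1.0) > 1e-9:
        raise ValueError("proportions must be three positive numbers summing to 1")

    n_val = int(np.floor(p[1] * n))
    n_test = int(np.floor(p[2] * n))
    n_train = n - n_val - n_test  # floor(p_train * n) + remainder

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=object)
    assignment[perm[:n_train]] = "train"
    assignment[perm[n_train : n_train + n_val]] = "validation"
    assignment[perm[n_train + n_val :]] = "test"
    return assignment.astype(str)


@dataclass
class LabeledDataset:
    """Quartile-labeled feature matrix with an optional split assignment."""

    features: np.ndarray  # retained cells x genes
    labels: np.ndarray  # 1 = lectin-high, 0 = lectin-low
    retained_cell_ids: list[str]
    gene_ids: list[str]
    clr_values: np.ndarray  # per retained cell
    subtype_labels: list[str]
    split: np.ndarray | None = None  # per retained cell, in SPLIT_NAMES

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (
            self.labels.shape[0] == n
            and len(self.retained_cell_ids) == n
            and self.clr_values.shape[0] == n
            and len(self.subtype_labels) == n
        ):
            raise ValueError("per-cell field lengths disagree")
        if self.split is not None and self.split.shape[0] != n:
            raise ValueError("split must assign every retained cell")

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]

    def mask(self, name: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("dataset has no split assignment yet")
        if name not in SPLIT_NAMES:
            raise ValueError(f"unknown split {name!r}")
        return self.split == name

    def subset(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.mask(name)
        return self.features[m], self.labels[m]


def build_labeled_dataset(
    expr: ExpressionMatrix,
    lectin: LectinProfile,
    fraction: float = 0.25,
) -> LabeledDataset:
    """CLR-normalize the lectin counts, then binarize into quartile labels.

    The pipeline order is fixed: CLR first, labels from CLR values (never
    from the raw counts), split assignment afterwards via :func:`with_split`.
    """
    if list(lectin.cell_ids) != list(expr.cell_ids):
        raise ValueError("lectin and expression matrices must share cell order")
    clr = clr_transform(lectin.raw_counts)
    lectin.clr_values = clr
    labels = quartile_binarize(clr, expr.cell_ids, fraction=fraction)
    keep = labels != EXCLUDED
    return LabeledDataset(
        features=expr.values[keep],
        labels=labels[keep],
        retained_cell_ids=[c for c, k in zip(expr.cell_ids, keep) if k],
        gene_ids=list(expr.gene_ids),
        clr_values=clr[keep],
        subtype_labels=[s for s, k in zip(expr.subtype_labels, keep) if k],
    )


def with_split(
    dataset: LabeledDataset,
    proportions: tuple[float, float, float] = DEFAULT_SPLIT,
    seed: int = 0,
) -> LabeledDataset:
    """Return a copy of the dataset with a fresh random split assignment."""
    assignment = random_split(dataset.retained_cell_ids, proportions, seed)
    return replace(dataset, split=assignment)
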