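"""Permutation feature importance, rank-sum differential expression, overlaps.

Permutation importance shuffles one gene column at a time (labels intact),
re-scores the classifier and reports the mean loss increase over the
permutations. Differential expression compares lectin-high vs lectin-low
cells per gene with a two-sided Wilcoxon rank-sum test after a log2
fold-change pre-filter, with Benjamini-Hochberg (or optionally Bonferroni)
control of the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classifier import MLPClassifier, bce_loss

__all__ = [
    "OverlapReport",
    "permutation_importance",
    "wilcoxon_de",
    "bh_adjust",
    "overlap_stats",
]


@dataclass
class OverlapReport:
    size_a: int
    size_b: int
    shared: int
    fraction_shared: float  # shared / size_b * 100, in percent
    jaccard: float

    def to_dict(self) -> dict:
        return {
            "size_a": self.size_a,
            "size_b": self.size_b,
            "shared": self.shared,
            "fraction_shared": self.fraction_shared,
            "jaccard": self.jaccard,
        }


def permutation_importance(
    model: MLPClassifier,
    features: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str],
    n_permutations: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean loss increase when one gene column is shuffled, per gene.

    importance(g) = mean over permutations of BCE(permuted) - BCE(original).
    Only the first network layer sees the inputs, so each permutation is
    scored by shifting the cached first-layer pre-activation by
    ``(x_perm - x) w_g`` instead of re-running the full forward pass.
    Permutations are deterministic given the seed; the returned frame is
    sorted by importance descending (ties by gene id) with a 1-based rank.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    n, d = X.shape
    if len(gene_ids) != d:
        raise ValueError("gene_ids length must match the feature dimension")

    z1 = model.first_layer_preactivation(X)
    base_loss = bce_loss(model.predict_proba_from_z1(z1), y)

    rng = np.random.default_rng(seed)
    # one set of shared permutations keeps the loop over genes cheap and the
    # result invariant to gene order
    perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])

    mean_loss = np.empty(d)
    for g in range(d):
        col = X[:, g]
        w = model.W[0][g]
        losses = np.empty(n_permutations)
        for t in range(n_permutations):
            delta = col[perms[t]] - col
            p = model.predict_proba_from_z1(z1 + delta[:, None] * w[None, :])
            losses[t] = bce_loss(p, y)
        mean_loss[g] = losses.mean()

    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_permuted_loss": mean_loss,
            "importance": mean_loss - base_loss,
            "n_permutations": n_permutations,
        }
    )
    df = df.sort_values(
        ["importance", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, d + 1)
    return df


def _log2_fold_change(high: np.ndarray, low: np.ndarray) -> np.ndarray:
    """log2((mean(expm1(high)) + 1) / (mean(expm1(low)) + 1)), per gene.

    Means are taken on the de-logged (counts-per-10k) scale with a +1
    pseudocount, the convention of the single-cell toolkits this mirrors.
    """
    mean_high = np.expm1(high).mean(axis=0)
    mean_low = np.expm1(low).mean(axis=0)
    return np.log2((mean_high + 1.0) / (mean_low + 1.0))


def wilcoxon_de(
    expression: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str],
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum differential expression with FDR control.

    Genes failing the absolute log2 fold-change pre-filter are not tested
    (their p-values are recorded as missing and excluded from the
    adjustment). Tie-free groups of at most 10 cells each are tested by
    exact enumeration; larger or tied groups use the tie-corrected normal
    approximation. ``adjust`` selects Benjamini-Hochberg ("bh") or
    "bonferroni".
    """
    X = np.asarray(expression, dtype=float)
    y = np.asarray(labels, dtype=int)
    high = X[y == 1]
    low = X[y == 0]
    if high.shape[0] == 0 or low.shape[0] == 0:
        raise ValueError("both label groups must be nonempty")
    if len(gene_ids) != X.shape[1]:
        raise ValueError("gene_ids length must match the feature dimension")

    lfc = _log2_fold_change(high, low)
    tested = np.abs(lfc) >= logfc_threshold

    p = np.full(X.shape[1], np.nan)
    small = high.shape[0] <= 10 and low.shape[0] <= 10
    for g in np.flatnonzero(tested):
        a, b = high[:, g], low[:, g]
        combined = np.concatenate([a, b])
        method = "exact" if small and np.unique(combined).size == combined.size else "asymptotic"
        p[g] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue

    adjusted = np.full_like(p, np.nan)
    if tested.any():
        if adjust == "bh":
            adjusted[tested] = bh_adjust(p[tested])
        elif adjust == "bonferroni":
            adjusted[tested] = np.minimum(p[tested] * tested.sum(), 1.0)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")

    significant = tested & (np.nan_to_num(adjusted, nan=1.0) < alpha)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": adjusted,
            "significant": significant,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def overlap_stats(set_a, set_b) -> OverlapReport:
    """Set overlap: shared count, percent of set B shared, Jaccard index."""
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    union = len(a | b)
    return OverlapReport(
        size_a=len(a),
        size_b=len(b),
        shared=shared,
        fraction_shared=100.0 * shared / len(b) if b else 0.0,
        jaccard=shared / union if union else 0.0,
    )
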