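"""Shapley-style attribution of classifier output to genes.

``deep_attribution`` re-implements the multiple-reference DeepLIFT scheme
popularized for feed-forward networks: multipliers propagate from the output
probability back to the inputs using the linear rule through affine layers
(with batch normalization folded into an elementwise affine transform from
its running statistics) and the rescale rule through the leaky-rectifier and
sigmoid nonlinearities. Contributions are averaged over all background
references. For each reference the contributions sum exactly to
``f(x) - f(reference)``, so after averaging they sum to ``f(x) - base_value``
(local accuracy).

Two independent oracles are provided for testing: an unbiased Monte-Carlo
permutation-sampling Shapley estimator and exact Shapley values by full
coalition enumeration (feasible for small feature counts).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .classifier import MLPClassifier, _BN_EPS, _sigmoid

__all__ = [
    "AttributionMatrix",
    "SubtypeSpecificity",
    "model_ops",
    "deep_attribution",
    "sampling_shapley",
    "exact_shapley",
    "ensemble_average",
    "rank_genes",
    "top_fraction",
    "subtype_rankings",
    "percentile_table",
    "specific_genes",
]

logger = logging.getLogger(__name__)

_DELTA_EPS = 1e-9  # below this input difference, fall back to the derivative


@dataclass
class AttributionMatrix:
    """Per-cell, per-gene attributions on the probability scale."""

    phi: np.ndarray  # explain cells x genes
    base_value: float  # mean model output over the background set
    explain_cell_ids: list[str]
    background_cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.phi.shape != (len(self.explain_cell_ids), len(self.gene_ids)):
            raise ValueError("phi shape does not match identifier lists")


@dataclass
class SubtypeSpecificity:
    gene_id: str
    percentile_by_subtype: dict[str, float]
    specific_in: tuple[str, ...]


# ---------------------------------------------------------------------------
# network as an op chain


def model_ops(model: MLPClassifier) -> list[tuple]:
    """Inference-mode network as a chain of primitive operations.

    Batch norm is folded into an elementwise affine transform from its
    running statistics; dropout is identity at inference and is omitted.
    """
    slope = model.spec.negative_slope
    ops: list[tuple] = []
    for i in range(3):
        ops.append(("affine", model.W[i], model.b[i]))
        ops.append(("lrelu", slope))
        inv_std = 1.0 / np.sqrt(model.running_var[i] + _BN_EPS)
        scale = model.gamma[i] * inv_std
        shift = model.beta[i] - model.running_mean[i] * scale
        ops.append(("scale", scale, shift))
    ops.append(("affine", model.W[3], model.b[3]))
    ops.append(("affine", model.W[4], model.b[4]))
    ops.append(("sigmoid",))
    return ops


def _forward_ops(ops: list[tuple], X: np.ndarray) -> list[np.ndarray]:
    """Return the input of every op plus the final output (len(ops)+1 arrays)."""
    acts = [X]
    h = X
    for op in ops:
        kind = op[0]
        if kind == "affine":
            h = h @ op[1] + op[2]
        elif kind == "scale":
            h = h * op[1] + op[2]
        elif kind == "lrelu":
            h = np.where(h >= 0, h, op[1] * h)
        elif kind == "sigmoid":
            h = _sigmoid(h)
        else:  # pragma: no cover
            raise ValueError(f"unknown op {kind!r}")
        acts.append(h)
    return acts


def _rescale_ratio(din: np.ndarray, dout: np.ndarray, deriv: np.ndarray) -> np.ndarray:
    """Rescale-rule multiplier dout/din, derivative where the difference vanishes."""
    small = np.abs(din) < _DELTA_EPS
    safe = np.where(small, 1.0, din)
    return np.where(small, deriv, dout / safe)


def _multipliers(ops: list[tuple], X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """DeepLIFT multipliers from the scalar output to the inputs, one reference."""
    acts_x = _forward_ops(ops, X)
    acts_r = _forward_ops(ops, ref[None, :])
    m = np.ones((X.shape[0], 1))
    for k in range(len(ops) - 1, -1, -1):
        op = ops[k]
        kind = op[0]
        zx, zr = acts_x[k], acts_r[k]
        if kind == "affine":
            m = m @ op[1].T
        elif kind == "scale":
            m = m * op[1]
        elif kind == "lrelu":
            slope = op[1]
            fx = acts_x[k + 1]
            fr = acts_r[k + 1]
            mid = 0.5 * (zx + zr)
            deriv = np.where(mid >= 0, 1.0, slope)
            m = m * _rescale_ratio(zx - zr, fx - fr, deriv)
        elif kind == "sigmoid":
            fx, fr = acts_x[k + 1], acts_r[k + 1]
            mid = _sigmoid(0.5 * (zx + zr))
            deriv = mid * (1.0 - mid)
            m = m * _rescale_ratio(zx - zr, fx - fr, deriv)
    return m


def deep_attribution(
    model: MLPClassifier,
    X_explain: np.ndarray,
    X_background: np.ndarray,
    explain_cell_ids: list[str] | None = None,
    background_cell_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> AttributionMatrix:
    """Multiple-reference DeepLIFT attribution of the output probability.

    phi[c, g] is the contribution of gene g to ``f(x_c) - base_value``,
    averaged over all background references.
    """
    X = np.asarray(X_explain, dtype=float)
    B = np.asarray(X_background, dtype=float)
    if B.ndim != 2 or B.shape[0] == 0:
        raise ValueError("background must be a nonempty 2-d array")
    if X.shape[1] != B.shape[1]:
        raise ValueError(
            f"explain ({X.shape[1]}) and background ({B.shape[1]}) feature dimensions differ"
        )
    ops = model_ops(model)
    phi = np.zeros_like(X)
    for r in B:
        m = _multipliers(ops, X, r)
        phi += m * (X - r[None, :])
    phi /= B.shape[0]
    base_value = float(model.predict_proba(B).mean())
    n, d = X.shape
    return AttributionMatrix(
        phi=phi,
        base_value=base_value,
        explain_cell_ids=list(explain_cell_ids) if explain_cell_ids is not None
        else [f"cell{i}" for i in range(n)],
        background_cell_ids=list(background_cell_ids) if background_cell_ids is not None
        else [f"bg{i}" for i in range(B.shape[0])],
        gene_ids=list(gene_ids) if gene_ids is not None else [f"gene{i}" for i in range(d)],
    )


# ---------------------------------------------------------------------------
# oracles


def sampling_shapley(
    predict_fn,
    x: np.ndarray,
    X_background: np.ndarray,
    n_draws: int,
    seed: int = 0,
    return_se: bool = False,
):
    """Monte-Carlo Shapley estimate via random feature orderings.

    Each draw pairs one random background row with one random permutation and
    accumulates the marginal change in model output as features switch from
    the background to the explained cell in permutation order. Unbiased for
    the Shapley values of v(S) = E_background f(x_S, b_~S).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    B = np.asarray(X_background, dtype=float)
    if B.ndim != 2 or B.shape[0] == 0:
        raise ValueError("background must be a nonempty 2-d array")
    x = np.asarray(x, dtype=float)
    d = x.shape[0]
    rng = np.random.default_rng(seed)

    contributions = np.zeros((n_draws, d))
    for t in range(n_draws):
        b = B[rng.integers(B.shape[0])]
        perm = rng.permutation(d)
        rows = np.tile(b, (d + 1, 1))
        current = b.copy()
        for j, feat in enumerate(perm):
            current[feat] = x[feat]
            rows[j + 1] = current
        out = np.asarray(predict_fn(rows), dtype=float)
        contributions[t, perm] = np.diff(out)
    phi = contributions.mean(axis=0)
    if return_se:
        se = contributions.std(axis=0, ddof=1) / np.sqrt(n_draws) if n_draws > 1 else np.full(d, np.inf)
        return phi, se
    return phi


def exact_shapley(predict_fn, x: np.ndarray, X_background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration (small d only)."""
    x = np.asarray(x, dtype=float)
    B = np.asarray(X_background, dtype=float)
    d = x.shape[0]
    if d > 16:
        raise ValueError("exact enumeration is limited to 16 features")
    n_sets = 1 << d
    masks = (np.arange(n_sets)[:, None] >> np.arange(d)) & 1  # n_sets x d

    # v(S) = mean over background rows of f(x_S, b_~S)
    v = np.zeros(n_sets)
    for b in B:
        rows = np.where(masks.astype(bool), x[None, :], b[None, :])
        v += np.asarray(predict_fn(rows), dtype=float)
    v /= B.shape[0]

    sizes = masks.sum(axis=1)
    fact = np.array([factorial(k) for k in range(d + 1)], dtype=float)
    phi = np.zeros(d)
    for i in range(d):
        without = np.flatnonzero(masks[:, i] == 0)
        s = sizes[without]
        w = fact[s] * fact[d - s - 1] / fact[d]
        phi[i] = np.sum(w * (v[without | (1 << i)] - v[without]))
    return phi


# ---------------------------------------------------------------------------
# aggregation


def ensemble_average(attributions: list[AttributionMatrix]) -> AttributionMatrix:
    """Element-wise mean of phi and base value across replicate models."""
    if not attributions:
        raise ValueError("no attribution matrices given")
    first = attributions[0]
    for a in attributions[1:]:
        if a.explain_cell_ids != first.explain_cell_ids or a.gene_ids != first.gene_ids:
            raise ValueError("attribution matrices must share explain cells and genes")
    phi = np.mean([a.phi for a in attributions], axis=0)
    base = float(np.mean([a.base_value for a in attributions]))
    background = sorted(set().union(*(a.background_cell_ids for a in attributions)))
    return AttributionMatrix(
        phi=phi,
        base_value=base,
        explain_cell_ids=list(first.explain_cell_ids),
        background_cell_ids=background,
        gene_ids=list(first.gene_ids),
    )


def rank_genes(attr: AttributionMatrix) -> pd.DataFrame:
    """Rank genes by the median absolute attribution across explained cells.

    Descending by ``median_abs_shap``; ties broken by ascending gene
    identifier for determinism. Percentile = rank / n_genes * 100.
    """
    if attr.phi.shape[0] < 1:
        raise ValueError("at least one explained cell required")
    med = np.median(np.abs(attr.phi), axis=0)
    df = pd.DataFrame({"gene_id": attr.gene_ids, "median_abs_shap": med})
    df = df.sort_values(
        ["median_abs_shap", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["percentile"] = df["rank"] / len(df) * 100.0
    return df


def top_fraction(ranking: pd.DataFrame, fraction: float = 0.10) -> list[str]:
    """The top ``round(fraction * n_genes)`` genes (half rounds away from zero)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(ranking)
    k = int(np.floor(fraction * n + 0.5))
    return ranking["gene_id"].head(k).tolist()


def subtype_rankings(
    models: list[MLPClassifier],
    backgrounds: list[np.ndarray],
    X: np.ndarray,
    cell_ids: list[str],
    subtype_labels: list[str],
    gene_ids: list[str],
    cap: int = 1000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-subtype gene rankings from ensemble-averaged attributions.

    For each subtype, up to ``cap`` cells are sampled (all cells if the
    subtype is smaller); the same cells are explained by every replicate
    model so the ensemble average is well-defined.
    """
    if len(models) != len(backgrounds):
        raise ValueError("one background set per model required")
    labels = np.asarray(subtype_labels)
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for subtype in sorted(set(subtype_labels)):
        idx = np.flatnonzero(labels == subtype)
        if idx.size == 0:
            logger.warning("subtype %s has no cells; skipped", subtype)
            warnings.warn(f"subtype {subtype} has no cells; skipped", RuntimeWarning)
            continue
        if idx.size > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        ids = [cell_ids[i] for i in idx]
        attrs = [
            deep_attribution(m, X[idx], bg, explain_cell_ids=ids, gene_ids=gene_ids)
            for m, bg in zip(models, backgrounds)
        ]
        out[subtype] = rank_genes(ensemble_average(attrs))
    return out


def percentile_table(rankings: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x subtypes table of ranking percentiles."""
    cols = {
        subtype: df.set_index("gene_id")["percentile"] for subtype, df in rankings.items()
    }
    return pd.DataFrame(cols).sort_index()


def specific_genes(
    percentiles: pd.DataFrame, top_pct: float = 2.0, sd_mult: float = 1.25
) -> list[SubtypeSpecificity]:
    """Cell-type-specific importance rule.

    Gene g is specific to subtype k iff its percentile in k is at most
    ``top_pct`` and the mean percentile over the other subtypes exceeds it by
    at least ``sd_mult`` sample standard deviations (computed over the other
    subtypes, which must have strictly positive spread).
    """
    if percentiles.shape[1] < 2:
        raise ValueError("specificity rule needs at least 2 subtypes")
    out: list[SubtypeSpecificity] = []
    values = percentiles.to_numpy(dtype=float)
    subtypes = list(percentiles.columns)
    for gi, gene in enumerate(percentiles.index):
        row = values[gi]
        hits = []
        for k in range(len(subtypes)):
            if row[k] > top_pct:
                continue
            others = np.delete(row, k)
            sd = others.std(ddof=1)
            if sd > 0 and others.mean() - row[k] >= sd_mult * sd:
                hits.append(subtypes[k])
        if hits:
            out.append(
                SubtypeSpecificity(
                    gene_id=str(gene),
                    percentile_by_subtype={s: float(v) for s, v in zip(subtypes, row)},
                    specific_in=tuple(hits),
                )
            )
    return out
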