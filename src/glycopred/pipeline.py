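"""End-to-end orchestration: simulate/load -> label -> train x replicates ->
attribute -> rank -> permutation importance -> differential expression ->
compare, with all outputs written to one directory and summarized in a
single deterministic JSON report.

Replicates differ only in the dataset-split seed; each model's
initialization seed is derived deterministically from its split seed. All
randomness is funneled through seeds recorded in the report, so an identical
configuration reproduces the report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy import stats

from . import io as gio
from .attribution import (
    AttributionMatrix,
    deep_attribution,
    ensemble_average,
    percentile_table,
    rank_genes,
    specific_genes,
    subtype_rankings,
    top_fraction,
)
from .classifier import (
    Metrics,
    MLPClassifier,
    MLPSpec,
    TrainConfig,
    build_mlp,
    evaluate,
    train_baselines,
    train_mlp,
)
from .importance import overlap_stats, permutation_importance, wilcoxon_de
from .preprocess import (
    DEFAULT_SPLIT,
    LabeledDataset,
    build_labeled_dataset,
    clr_transform,
    quartile_binarize,
    with_split,
)
from .simdata import ExpressionMatrix, GroundTruthManifest, LectinProfile, SyntheticConfig

__all__ = ["PipelineConfig", "PipelineStageError", "PipelineResult", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("data", "preprocess", "train", "explain", "pfi", "dea", "report")

#: which earlier products each stage consumes; recorded in the report so a
#: reviewer can check that no stage reads test-split labels before evaluation
STAGE_DEPENDENCIES = {
    "data": [],
    "preprocess": ["data:lectin_counts", "data:expression"],
    "train": ["preprocess:train_features", "preprocess:train_labels",
              "preprocess:validation_features", "preprocess:validation_labels"],
    "evaluate": ["train:model", "preprocess:test_labels"],
    "explain": ["train:model", "preprocess:features"],
    "pfi": ["train:model", "preprocess:test_features", "preprocess:test_labels"],
    "dea": ["preprocess:features", "preprocess:labels"],
    "report": ["evaluate", "explain", "pfi", "dea"],
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved configuration of one analysis run."""

    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    matrix_dir: str | None = None  # alternative to synthetic: MTX triplet dir
    lectin_csv: str | None = None
    subtypes_tsv: str | None = None
    manifest_json: str | None = None

    label_fraction: float = 0.25
    split_proportions: tuple[float, float, float] = DEFAULT_SPLIT
    replicate_seeds: tuple[int, ...] = (101, 202, 303)

    max_epochs: int = 300
    batch_size: int = 128
    learning_rate: float = 1e-4

    n_explain: int = 1000
    n_background: int = 100
    subtype_cap: int = 1000
    shap_fraction: float = 0.10

    pfi_permutations: int = 25
    dea_logfc_threshold: float = 0.25
    dea_alpha: float = 0.05
    dea_adjust: str = "bh"

    seed: int = 0  # master seed for sampling decisions outside training
    output_dir: str | None = None

    def validate(self) -> None:
        if len(self.replicate_seeds) < 1:
            raise ValueError("at least one replicate seed required")
        if not 0 < self.label_fraction <= 0.5:
            raise ValueError("label_fraction must lie in (0, 0.5]")
        if self.synthetic is None and (self.matrix_dir is None or self.lectin_csv is None):
            raise ValueError("either a synthetic config or matrix_dir + lectin_csv required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            if syn.get("subtype_proportions") is not None:
                syn["subtype_proportions"] = tuple(syn["subtype_proportions"])
            d["synthetic"] = SyntheticConfig(**syn)
        elif "synthetic" in d:
            d["synthetic"] = None
        if "replicate_seeds" in d:
            d["replicate_seeds"] = tuple(d["replicate_seeds"])
        if "split_proportions" in d:
            d["split_proportions"] = tuple(d["split_proportions"])
        return cls(**d)


class ReportV1(BaseModel):
    """Versioned schema of the analysis report; validates on construction."""

    schema_version: str
    package_version: str
    config: dict
    seeds: dict
    n_cells: int
    n_genes: int
    n_labeled: int
    replicates: list[dict]
    baselines: dict
    gene_ranking_top: list[dict]
    shap_genes: dict
    subtype_specific: dict
    pfi_top: list[dict]
    dea_summary: dict
    overlaps: dict
    recovery: dict | None
    stage_order: list[str]
    stage_dependencies: dict


@dataclass
class PipelineResult:
    """Rich in-memory result; ``report`` is the serializable summary."""

    config: PipelineConfig
    expression: ExpressionMatrix
    lectin: LectinProfile
    truth: GroundTruthManifest | None
    labeled: LabeledDataset
    splits: list[LabeledDataset]
    models: list[MLPClassifier]
    histories: list
    metrics: list[dict[str, Metrics]]
    baselines: dict[str, Metrics]
    attribution: AttributionMatrix
    attributions_per_model: list[AttributionMatrix]
    ranking: pd.DataFrame
    shap_genes: list[str]
    subtype_ranks: dict[str, pd.DataFrame]
    specificity: list
    pfi: pd.DataFrame | None
    dea: pd.DataFrame | None
    overlaps: dict
    recovery: dict | None
    report: dict


def _model_seed(split_seed: int) -> int:
    """Deterministic initialization seed derived from the split seed."""
    return int(np.random.SeedSequence(split_seed, spawn_key=(1,)).generate_state(1)[0] % (2**31))


def _sub_seed(master: int, stream: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


def _metrics_block(metrics: dict[str, Metrics]) -> dict:
    return {split: m.to_dict() for split, m in metrics.items()}


def _load_data(config: PipelineConfig):
    if config.synthetic is not None:
        from .simdata import generate_dataset

        expr, lectin, truth = generate_dataset(config.synthetic)
        return expr, lectin, truth
    expr = gio.read_matrix(config.matrix_dir, subtypes_path=config.subtypes_tsv)
    lectin = gio.read_lectin(config.lectin_csv)
    if list(lectin.cell_ids) != list(expr.cell_ids):
        raise gio.FormatError("lectin CSV cell order does not match the barcodes file")
    truth = gio.read_manifest(config.manifest_json) if config.manifest_json else None
    return expr, lectin, truth


def _recovery_scores(
    truth: GroundTruthManifest,
    shap_genes: list[str],
    attr: AttributionMatrix,
    labeled: LabeledDataset,
    explain_idx: np.ndarray,
    dea_significant: set[str] | None = None,
) -> dict:
    """Score planted-driver recovery against the attribution output."""
    strong = set(truth.strong_driver_ids)
    top = set(shap_genes)
    recall_strong = len(strong & top) / len(strong) if strong else float("nan")
    recall_all = (
        len(set(truth.driver_ids) & top) / len(truth.driver_ids)
        if truth.driver_ids
        else float("nan")
    )

    gene_pos = {g: i for i, g in enumerate(attr.gene_ids)}
    correlations = {}
    n_positive_corr = 0
    pos_ids = truth.positive_driver_ids
    for g in pos_ids:
        j = gene_pos[g]
        x = labeled.features[explain_idx, j]
        rho = stats.spearmanr(x, attr.phi[:, j]).statistic if np.std(x) > 0 else np.nan
        correlations[g] = None if np.isnan(rho) else float(rho)
        if rho is not None and not np.isnan(rho) and rho > 0:
            n_positive_corr += 1
    out = {
        "n_drivers": len(truth.driver_ids),
        "n_strong_drivers": len(strong),
        "strong_driver_recall_top_fraction": recall_strong,
        "all_driver_recall_top_fraction": recall_all,
        "positive_driver_expression_phi_spearman": correlations,
        "fraction_positive_drivers_with_positive_correlation": (
            n_positive_corr / len(pos_ids) if pos_ids else float("nan")
        ),
    }
    if dea_significant is not None:
        # drivers the attribution ranking surfaces that differential
        # expression misses (the low-abundance-driver comparison)
        attribution_only = sorted((set(truth.driver_ids) & top) - dea_significant)
        out["drivers_in_top_set_not_dea_significant"] = attribution_only
        out["n_drivers_attribution_only"] = len(attribution_only)
    return out


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> PipelineResult:
    """Execute the analysis up to and including the requested stages.

    Stages form a chain; requesting a late stage implies all earlier ones.
    Outputs are written under ``config.output_dir`` when set. Deterministic
    given the configuration.
    """
    config.validate()
    last = max(STAGES.index(s) for s in stages)
    wanted = STAGES[: last + 1]
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _run(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise PipelineStageError(stage, exc) from exc
        logger.info("stage %-10s finished in %.1fs", stage, time.perf_counter() - t0)
        return result

    # ---- data ----------------------------------------------------------------
    expr, lectin, truth = _run("data", lambda: _load_data(config))
    if out_dir and config.synthetic is not None:
        gio.write_matrix(expr, out_dir / "dataset")
        gio.write_lectin(lectin, out_dir / "dataset" / gio.LECTIN_FILE)
        if truth is not None:
            gio.write_manifest(truth, out_dir / "dataset" / gio.MANIFEST_FILE)
    if wanted[-1] == "data":
        return _partial_result(config, expr, lectin, truth)

    # ---- preprocess ----------------------------------------------------------
    labeled = _run("preprocess", lambda: build_labeled_dataset(expr, lectin, config.label_fraction))
    if out_dir:
        clr_all = clr_transform(lectin.raw_counts)
        labels_all = quartile_binarize(clr_all, expr.cell_ids, config.label_fraction)
        first_split = with_split(labeled, config.split_proportions, config.replicate_seeds[0])
        gio.write_labels(first_split, clr_all, expr.cell_ids, labels_all, out_dir / "labels.tsv")
    if wanted[-1] == "preprocess":
        return _partial_result(config, expr, lectin, truth, labeled=labeled)

    # ---- train (one model per replicate split seed) --------------------------
    def _train_all():
        splits, models, histories, metrics = [], [], [], []
        spec = MLPSpec(input_dim=len(labeled.gene_ids))
        for split_seed in config.replicate_seeds:
            ds = with_split(labeled, config.split_proportions, split_seed)
            model = build_mlp(spec, seed=_model_seed(split_seed))
            tc = TrainConfig(
                batch_size=config.batch_size,
                initial_learning_rate=config.learning_rate,
                max_epochs=config.max_epochs,
                seed=_model_seed(split_seed) + 1,
            )
            model, history = train_mlp(model, *ds.subset("train"), *ds.subset("validation"), tc)
            m = {
                split: evaluate(model.predict_proba(ds.subset(split)[0]), ds.subset(split)[1])
                for split in ("train", "validation", "test")
            }
            splits.append(ds)
            models.append(model)
            histories.append(history)
            metrics.append(m)
        return splits, models, histories, metrics

    splits, models, histories, metrics = _run("train", _train_all)

    def _baselines():
        ds = splits[0]
        return train_baselines(
            *ds.subset("train"), *ds.subset("test"), seed=_sub_seed(config.seed, 5)
        )

    baselines = _run("train", _baselines)
    if out_dir:
        for i, (model, history) in enumerate(zip(models, histories)):
            model.save(out_dir / f"model_replicate{i}.npz")
            (out_dir / f"history_replicate{i}.json").write_text(
                json.dumps(history.to_dict(), indent=2) + "\n"
            )
    if wanted[-1] == "train":
        return _partial_result(
            config, expr, lectin, truth, labeled, splits, models, histories, metrics, baselines
        )

    # ---- explain --------------------------------------------------------------
    def _explain():
        n_labeled = labeled.n_cells
        rng = np.random.default_rng(_sub_seed(config.seed, 1))
        explain_idx = np.sort(
            rng.choice(n_labeled, size=min(config.n_explain, n_labeled), replace=False)
        )
        explain_ids = [labeled.retained_cell_ids[i] for i in explain_idx]
        attrs = []
        backgrounds = []
        for k, (model, ds) in enumerate(zip(models, splits)):
            train_idx = np.flatnonzero(ds.mask("train"))
            bg_rng = np.random.default_rng(_sub_seed(config.seed, 100 + k))
            bg_idx = np.sort(
                bg_rng.choice(
                    train_idx, size=min(config.n_background, train_idx.size), replace=False
                )
            )
            backgrounds.append(labeled.features[bg_idx])
            attrs.append(
                deep_attribution(
                    model,
                    labeled.features[explain_idx],
                    backgrounds[-1],
                    explain_cell_ids=explain_ids,
                    background_cell_ids=[labeled.retained_cell_ids[i] for i in bg_idx],
                    gene_ids=labeled.gene_ids,
                )
            )
        averaged = ensemble_average(attrs)
        ranking = rank_genes(averaged)
        shap_genes = top_fraction(ranking, config.shap_fraction)
        sub_ranks = subtype_rankings(
            models,
            backgrounds,
            labeled.features,
            labeled.retained_cell_ids,
            labeled.subtype_labels,
            labeled.gene_ids,
            cap=config.subtype_cap,
            seed=_sub_seed(config.seed, 2),
        )
        table = percentile_table(sub_ranks)
        spec_list = specific_genes(table) if table.shape[1] >= 2 else []
        return explain_idx, attrs, averaged, ranking, shap_genes, sub_ranks, spec_list

    explain_idx, attrs, averaged, ranking, shap_genes, sub_ranks, spec_list = _run(
        "explain", _explain
    )
    if out_dir:
        ranking.to_csv(out_dir / "gene_ranking.tsv", sep="\t", index=False)
        for subtype, df in sub_ranks.items():
            df.to_csv(out_dir / f"gene_ranking_{subtype}.tsv", sep="\t", index=False)
        spec_rows = [
            {"gene_id": s.gene_id, "specific_in": ";".join(s.specific_in),
             **{f"pct_{k}": v for k, v in s.percentile_by_subtype.items()}}
            for s in spec_list
        ]
        pd.DataFrame(spec_rows).to_csv(out_dir / "subtype_specific_genes.tsv", sep="\t", index=False)
        np.savez_compressed(
            out_dir / "attributions.npz",
            phi=averaged.phi,
            base_value=averaged.base_value,
            explain_cell_ids=np.asarray(averaged.explain_cell_ids),
            gene_ids=np.asarray(averaged.gene_ids),
        )

    # ---- permutation feature importance (first replicate, test split) ---------
    pfi = None
    if "pfi" in wanted:
        def _pfi():
            ds = splits[0]
            X_test, y_test = ds.subset("test")
            return permutation_importance(
                models[0],
                X_test,
                y_test,
                labeled.gene_ids,
                n_permutations=config.pfi_permutations,
                seed=_sub_seed(config.seed, 3),
            )

        pfi = _run("pfi", _pfi)
        if out_dir:
            pfi.to_csv(out_dir / "pfi_ranking.tsv", sep="\t", index=False)

    # ---- differential expression ----------------------------------------------
    dea = None
    if "dea" in wanted:
        dea = _run(
            "dea",
            lambda: wilcoxon_de(
                labeled.features,
                labeled.labels,
                labeled.gene_ids,
                logfc_threshold=config.dea_logfc_threshold,
                alpha=config.dea_alpha,
                adjust=config.dea_adjust,
            ),
        )
        if out_dir:
            dea.to_csv(out_dir / "dea.tsv", sep="\t", index=False)

    # ---- comparisons + report ---------------------------------------------------
    overlaps: dict[str, Any] = {}
    if pfi is not None:
        k = len(shap_genes)
        pfi_top = pfi["gene_id"].head(k).tolist()
        overlaps["shap_vs_pfi"] = overlap_stats(shap_genes, pfi_top).to_dict()
    if dea is not None:
        dea_sig = dea.loc[dea["significant"], "gene_id"].tolist()
        overlaps["shap_vs_dea"] = overlap_stats(shap_genes, dea_sig).to_dict()
    if out_dir and overlaps:
        (out_dir / "overlaps.json").write_text(
            json.dumps(overlaps, indent=2, sort_keys=True) + "\n"
        )

    recovery = (
        _recovery_scores(
            truth, shap_genes, averaged, labeled, explain_idx,
            dea_significant=(
                set(dea.loc[dea["significant"], "gene_id"]) if dea is not None else None
            ),
        )
        if truth is not None
        else None
    )

    report_model = ReportV1(
        schema_version="1.0",
        package_version=_package_version(),
        config=config.to_dict(),
        seeds={
            "master": config.seed,
            "replicate_split_seeds": list(config.replicate_seeds),
            "model_seeds": [_model_seed(s) for s in config.replicate_seeds],
            "explain_seed": _sub_seed(config.seed, 1),
            "subtype_seed": _sub_seed(config.seed, 2),
            "pfi_seed": _sub_seed(config.seed, 3),
            "baseline_seed": _sub_seed(config.seed, 5),
        },
        n_cells=expr.n_cells,
        n_genes=expr.n_genes,
        n_labeled=labeled.n_cells,
        replicates=[
            {
                "split_seed": seed,
                "model_seed": _model_seed(seed),
                "best_epoch": history.best_epoch,
                "metrics": _metrics_block(m),
            }
            for seed, history, m in zip(config.replicate_seeds, histories, metrics)
        ],
        baselines=_metrics_block(baselines),
        gene_ranking_top=ranking.head(20).to_dict(orient="records"),
        shap_genes={"fraction": config.shap_fraction, "count": len(shap_genes),
                    "genes": shap_genes},
        subtype_specific={
            "n_genes": len(spec_list),
            "by_subtype": _specific_counts(spec_list),
        },
        pfi_top=pfi.head(20).to_dict(orient="records") if pfi is not None else [],
        dea_summary=_dea_summary(dea) if dea is not None else {},
        overlaps=overlaps,
        recovery=recovery,
        stage_order=list(wanted),
        stage_dependencies=STAGE_DEPENDENCIES,
    )
    report = report_model.model_dump()
    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        config=config,
        expression=expr,
        lectin=lectin,
        truth=truth,
        labeled=labeled,
        splits=splits,
        models=models,
        histories=histories,
        metrics=metrics,
        baselines=baselines,
        attribution=averaged,
        attributions_per_model=attrs,
        ranking=ranking,
        shap_genes=shap_genes,
        subtype_ranks=sub_ranks,
        specificity=spec_list,
        pfi=pfi,
        dea=dea,
        overlaps=overlaps,
        recovery=recovery,
        report=report,
    )


def _specific_counts(spec_list) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in spec_list:
        for subtype in s.specific_in:
            counts[subtype] = counts.get(subtype, 0) + 1
    return dict(sorted(counts.items()))


def _dea_summary(dea: pd.DataFrame) -> dict:
    sig = dea[dea["significant"]]
    return {
        "n_tested": int(dea["p_value"].notna().sum()),
        "n_significant": int(len(sig)),
        "top_significant": sig.nsmallest(20, "adjusted_p")["gene_id"].tolist(),
    }


def _package_version() -> str:
    from . import __version__

    return __version__


def _partial_result(config, expr, lectin, truth, labeled=None, splits=None, models=None,
                    histories=None, metrics=None, baselines=None) -> PipelineResult:
    """Result object for a run stopped at an early stage."""
    empty_attr = AttributionMatrix(
        phi=np.zeros((0, expr.n_genes)),
        base_value=float("nan"),
        explain_cell_ids=[],
        background_cell_ids=[],
        gene_ids=list(expr.gene_ids),
    )
    return PipelineResult(
        config=config, expression=expr, lectin=lectin, truth=truth,
        labeled=labeled, splits=splits or [], models=models or [],
        histories=histories or [], metrics=metrics or [], baselines=baselines or {},
        attribution=empty_attr, attributions_per_model=[],
        ranking=pd.DataFrame(), shap_genes=[], subtype_ranks={}, specificity=[],
        pfi=None, dea=None, overlaps={}, recovery=None, report={},
    )
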