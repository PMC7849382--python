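"""End-to-end orchestration: COV files -> features -> ensemble -> activity.

These functions are the substance behind the CLI subcommands and are also
directly usable from Python.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import RunConfig, derive_seed
from .features import FeatureTensor, assemble_features, build_promoter_model, mpd_matrix
from .io_formats import (
    ExpressionMatrix,
    GeneTSS,
    MethylationCalls,
    normalize_expression,
    read_bismark_cov,
    read_cell_manifest,
)
from .metacell import (
    MetaCellMap,
    build_metacells,
    compute_pca_embedding,
    compute_promoter_methylation_matrix,
    select_variable_promoters,
)
from .predictors import (
    EnsembleModel,
    predict,
    save_bundle,
    subsample_training_pairs,
    train_ensemble,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_cells",
    "build_feature_tensor",
    "train_pipeline",
    "predict_pipeline",
    "mpd_pipeline",
]


def load_cells(manifest_path: str | Path) -> list[MethylationCalls]:
    manifest = read_cell_manifest(manifest_path)
    return [read_bismark_cov(path, cell_id=cid) for cid, path in manifest.items()]


def build_feature_tensor(
    calls: Sequence[MethylationCalls],
    tss: Sequence[GeneTSS],
    genome,
    config: RunConfig,
) -> tuple[FeatureTensor, MetaCellMap]:
    """Promoter matrix -> variable promoters -> PCA -> meta-cells -> features."""
    promoter = compute_promoter_methylation_matrix(calls, tss, flank=config.flank)
    top = select_variable_promoters(promoter, n_top=config.n_variable_promoters)
    d = min(config.pca_d, len(promoter.cells), len(top))
    if d < config.pca_d:
        logger.warning("reducing PCA dimensions from %d to %d (small dataset)", config.pca_d, d)
    embedding = compute_pca_embedding(promoter, gene_subset=top, d=d)
    metacells = build_metacells(
        embedding,
        k=config.knn_k,
        include_self=config.include_self,
        cell_ids=promoter.cells,
    )
    models = [
        build_promoter_model(g, flank=config.flank, bin_size=config.bin_size) for g in tss
    ]
    tensor = assemble_features(models, metacells, calls, genome)
    return tensor, metacells


def train_pipeline(
    calls: Sequence[MethylationCalls],
    tss: Sequence[GeneTSS],
    genome,
    counts: ExpressionMatrix,
    config: RunConfig,
    allow_unmatched: bool = False,
) -> tuple[EnsembleModel, FeatureTensor, ExpressionMatrix]:
    """Train the ensemble on matched methylome + transcriptome cells.

    Returns (model, feature tensor, normalized expression). Cells present in
    the methylome but absent from the expression matrix are an error unless
    ``allow_unmatched`` (then the intersection is used).
    """
    expr_cells = set(counts.cells)
    unmatched = [c.cell_id for c in calls if c.cell_id not in expr_cells]
    if unmatched and not allow_unmatched:
        raise ValueError(f"cells without expression data: {unmatched[:10]}")
    matched = [c for c in calls if c.cell_id in expr_cells]
    if not matched:
        raise ValueError("no cells shared between methylome and expression data")
    norm = normalize_expression(counts)
    tensor, _ = build_feature_tensor(matched, tss, genome, config)
    X, y = subsample_training_pairs(
        tensor, norm, n=config.subsample_n, seed=derive_seed(config.seed, "subsample")
    )
    model = train_ensemble(
        X,
        y,
        rule=config.ensemble_rule,
        seed=derive_seed(config.seed, "ensemble"),
        component_params=config.component_params(),
    )
    for comp in model.components:
        comp.training_max_log_expr = norm.norm_constant
    return model, tensor, norm


def predict_pipeline(
    model: EnsembleModel,
    calls: Sequence[MethylationCalls],
    tss: Sequence[GeneTSS],
    genome,
    config: RunConfig,
) -> ExpressionMatrix:
    """Predict a genes x cells activity matrix for a (possibly new) dataset."""
    if not calls:
        raise ValueError("empty cell set")
    tensor, _ = build_feature_tensor(calls, tss, genome, config)
    if tensor.feature_names != model.feature_order:
        raise ValueError(
            "feature layout mismatch between bundle and assembled features; "
            "check flank/bin_size settings"
        )
    pred = predict(model, tensor.X)
    values = np.full((len(tensor.gene_ids), len(tensor.cell_ids)), np.nan)
    values[tensor.pair_gene_idx, tensor.pair_cell_idx] = pred
    return ExpressionMatrix(
        genes=list(tensor.gene_ids), cells=list(tensor.cell_ids), values=values
    )


def mpd_pipeline(
    calls: Sequence[MethylationCalls], tss: Sequence[GeneTSS], config: RunConfig
) -> ExpressionMatrix:
    """Genes x cells mean-promoter-demethylation baseline matrix."""
    values = mpd_matrix(tss, calls, flank=config.flank)
    return ExpressionMatrix(
        genes=[g.gene_id for g in tss], cells=[c.cell_id for c in calls], values=values
    )
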