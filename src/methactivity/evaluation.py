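"""Evaluation metrics and cross-validation harness.

Metrics: global Spearman over all pooled (gene, cell) pairs, per-cell
Spearman across genes, and median squared error, optionally stratified by
promoter CpG context (island / shore / shelf / open sea).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.model_selection import KFold

from .features import FeatureTensor
from .io_formats import ExpressionMatrix, GeneTSS
from .predictors import EnsembleModel, predict, subsample_training_pairs, train_ensemble

__all__ = [
    "EvaluationReport",
    "global_spearman",
    "per_cell_spearman",
    "median_squared_error",
    "evaluate_predictions",
    "cross_validate",
    "classify_cpg_context",
    "read_islands_bed",
]

CPG_CONTEXTS = ("island", "shore", "shelf", "open_sea")


@dataclass
class EvaluationReport:
    global_spearman: float
    per_cell_spearman: list[float]  # NaN for constant cells
    median_squared_error: float
    stratified: dict[str, dict[str, float]] = field(default_factory=dict)
    n_pairs: int = 0
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_pairs": self.n_pairs,
            "global_spearman": self.global_spearman,
            "per_cell_spearman": self.per_cell_spearman,
            "median_squared_error": self.median_squared_error,
            "stratified": self.stratified,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def global_spearman(pred: np.ndarray, obs: np.ndarray) -> float:
    """Spearman rank correlation over pooled pairs (average ranks for ties).

    Returns NaN (with a warning) when either input is constant.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape or len(pred) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.all(pred == pred[0]) or np.all(obs == obs[0]):
        warnings.warn("constant input: Spearman undefined, returning NaN")
        return float("nan")
    return float(spearmanr(pred, obs).statistic)


def per_cell_spearman(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Per-cell Spearman across genes for matched genes x cells matrices."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("shape mismatch")
    out = np.full(pred.shape[1], np.nan)
    if pred.shape[0] < 2:
        return out
    for c in range(pred.shape[1]):
        p, o = pred[:, c], obs[:, c]
        if np.all(p == p[0]) or np.all(o == o[0]):
            continue
        out[c] = spearmanr(p, o).statistic
    return out


def median_squared_error(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("length mismatch")
    return float(np.median((pred - obs) ** 2))


def evaluate_predictions(
    pred: ExpressionMatrix,
    obs: ExpressionMatrix,
    contexts: dict[str, str] | None = None,
    label: str = "",
) -> EvaluationReport:
    """Full report over the genes and cells shared by both matrices.

    ``contexts`` optionally maps gene_id -> CpG context class for stratified
    metrics. Genes or cells absent from either matrix are excluded.
    """
    genes = [g for g in pred.genes if g in set(obs.genes)]
    cells = [c for c in pred.cells if c in set(obs.cells)]
    if not genes or not cells:
        raise ValueError("no overlapping gene/cell labels between pred and obs")
    pg = [pred.gene_idx(g) for g in genes]
    pc = [pred.cell_idx(c) for c in cells]
    og = [obs.gene_idx(g) for g in genes]
    oc = [obs.cell_idx(c) for c in cells]
    P = pred.values[np.ix_(pg, pc)]
    O = obs.values[np.ix_(og, oc)]
    keep = np.isfinite(P.ravel()) & np.isfinite(O.ravel())
    report = EvaluationReport(
        global_spearman=global_spearman(P.ravel()[keep], O.ravel()[keep]),
        per_cell_spearman=[float(v) for v in per_cell_spearman(P, O)],
        median_squared_error=median_squared_error(P.ravel()[keep], O.ravel()[keep]),
        n_pairs=int(keep.sum()),
        label=label,
    )
    if contexts is not None:
        for ctx in CPG_CONTEXTS:
            rows = [i for i, g in enumerate(genes) if contexts.get(g) == ctx]
            if len(rows) < 2:
                continue
            p_sub, o_sub = P[rows].ravel(), O[rows].ravel()
            k = np.isfinite(p_sub) & np.isfinite(o_sub)
            if k.sum() < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = global_spearman(p_sub[k], o_sub[k])
            report.stratified[ctx] = {
                "global_spearman": rho,
                "median_squared_error": median_squared_error(p_sub[k], o_sub[k]),
                "n_genes": len(rows),
            }
    return report


def _pairwise_targets(
    tensor: FeatureTensor, targets: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(pair row indices with available targets, target values)."""
    gmap = {g: i for i, g in enumerate(targets.genes)}
    cmap = {c: i for i, c in enumerate(targets.cells)}
    rows, vals = [], []
    for r in range(len(tensor)):
        g = tensor.gene_ids[tensor.pair_gene_idx[r]]
        c = tensor.cell_ids[tensor.pair_cell_idx[r]]
        if g in gmap and c in cmap and np.isfinite(targets.values[gmap[g], cmap[c]]):
            rows.append(r)
            vals.append(targets.values[gmap[g], cmap[c]])
    return np.asarray(rows, dtype=int), np.asarray(vals, dtype=float)


def _report_from_pairs(
    tensor: FeatureTensor,
    rows: np.ndarray,
    pred: np.ndarray,
    obs: np.ndarray,
    contexts: dict[str, str] | None,
    label: str,
) -> EvaluationReport:
    """Assemble matrices from pair-level predictions and evaluate."""
    n_g, n_c = len(tensor.gene_ids), len(tensor.cell_ids)
    P = np.full((n_g, n_c), np.nan)
    O = np.full((n_g, n_c), np.nan)
    gi = tensor.pair_gene_idx[rows]
    ci = tensor.pair_cell_idx[rows]
    P[gi, ci] = pred
    O[gi, ci] = obs
    pred_m = ExpressionMatrix(genes=list(tensor.gene_ids), cells=list(tensor.cell_ids), values=P)
    obs_m = ExpressionMatrix(genes=list(tensor.gene_ids), cells=list(tensor.cell_ids), values=O)
    return evaluate_predictions(pred_m, obs_m, contexts=contexts, label=label)


def cross_validate(
    datasets: Sequence[tuple[FeatureTensor, ExpressionMatrix]],
    mode: str = "external",
    rule: str = "unweighted",
    seed: int = 0,
    n_folds: int = 5,
    subsample_n: int = 100_000,
    component_params: dict | None = None,
    contexts: dict[str, str] | None = None,
) -> dict:
    """Internal (K-fold over pairs) or external (cross-dataset) CV.

    External mode returns ``{(i, j): EvaluationReport}`` for every ordered
    train/test dataset pair with i != j — n x (n - 1) reports. Internal mode
    returns ``{fold: EvaluationReport}`` over a seeded partition of the first
    dataset's (gene, cell) pairs. Expression matrices must already be
    normalized; each test set keeps its own normalization.
    """
    if mode == "external":
        if len(datasets) < 2:
            raise ValueError("external CV needs at least 2 datasets")
        reports: dict = {}
        for i, (tensor_i, expr_i) in enumerate(datasets):
            X_train, y_train = subsample_training_pairs(
                tensor_i, expr_i, n=subsample_n, seed=seed + i
            )
            model = train_ensemble(
                X_train, y_train, rule=rule, seed=seed + i, component_params=component_params
            )
            for j, (tensor_j, expr_j) in enumerate(datasets):
                if j == i:
                    continue
                rows, obs = _pairwise_targets(tensor_j, expr_j)
                pred = predict(model, tensor_j.X[rows])
                reports[(i, j)] = _report_from_pairs(
                    tensor_j, rows, pred, obs, contexts, label=f"train={i},test={j}"
                )
        return reports

    if mode == "internal_5fold":
        if len(datasets) < 1:
            raise ValueError("internal CV needs a dataset")
        tensor, expr = datasets[0]
        rows, vals = _pairwise_targets(tensor, expr)
        if len(rows) > subsample_n:
            rng = np.random.default_rng(seed)
            keep = np.sort(rng.choice(len(rows), size=subsample_n, replace=False))
            rows, vals = rows[keep], vals[keep]
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        reports = {}
        X_all = tensor.X[rows]
        for fold_i, (tr, te) in enumerate(kf.split(rows)):
            model = train_ensemble(
                X_all[tr],
                vals[tr],
                rule=rule,
                seed=seed + 100 * (fold_i + 1),
                component_params=component_params,
            )
            pred = predict(model, X_all[te])
            reports[fold_i] = _report_from_pairs(
                tensor, rows[te], pred, vals[te], contexts, label=f"fold={fold_i}"
            )
        return reports

    raise ValueError(f"unknown mode {mode!r}")


def read_islands_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """CpG islands as 0-based half-open intervals per chromosome, sorted."""
    islands: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            islands.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    for chrom in islands:
        islands[chrom].sort()
    return islands


def classify_cpg_context(
    gene: GeneTSS,
    islands: dict[str, list[tuple[int, int]]],
    flank: int = 5000,
    shore_width: int = 2000,
    shelf_width: int = 2000,
) -> str:
    """Context of a gene's promoter relative to CpG islands.

    Promoter = [tss - flank, tss + flank] (1-based inclusive). Overlapping an
    island -> ``island``; within ``shore_width`` of one -> ``shore``; within a
    further ``shelf_width`` -> ``shelf``; else ``open_sea``. Precedence
    island > shore > shelf.
    """
    p_start0 = gene.tss - 1 - flank
    p_end0 = gene.tss + flank  # half-open
    gap = np.inf
    for start, end in islands.get(gene.chrom, []):
        if start < p_end0 and end > p_start0:
            return "island"
        gap = min(gap, start - p_end0 if start >= p_end0 else p_start0 - end)
    if gap <= shore_width:
        return "shore"
    if gap <= shore_width + shelf_width:
        return "shelf"
    return "open_sea"
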