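"""Meta-cell construction: promoter methylation matrix -> PCA -> exact k-NN.

A meta-cell is a cell together with its k nearest neighbors in a
low-dimensional PCA embedding of promoter-level methylation. Pooling calls
across a meta-cell de-sparsifies per-bin methylation estimates while keeping
one meta-cell per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import GeneTSS, MethylationCalls

__all__ = [
    "PromoterMethylationMatrix",
    "MetaCellMap",
    "compute_promoter_methylation_matrix",
    "select_variable_promoters",
    "compute_pca_embedding",
    "build_metacells",
    "adjacency_difference",
]


@dataclass
class PromoterMethylationMatrix:
    """Genes x cells promoter mean methylation, imputed, with missingness mask."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # (n_genes, n_cells) in [0, 1], no NaNs post-imputation
    missing_mask: np.ndarray  # bool, True where the promoter had zero calls

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("imputed matrix must not contain NaNs")


@dataclass
class MetaCellMap:
    """For each cell, the index set of its meta-cell members."""

    cell_ids: list[str]
    members: list[np.ndarray]  # sorted int arrays; members[i] includes i unless exclude_self
    k: int
    include_self: bool = True

    def __post_init__(self) -> None:
        if len(self.members) != len(self.cell_ids):
            raise ValueError("one member set per cell required")
        expected = self.k + 1 if self.include_self else self.k
        for i, m in enumerate(self.members):
            if len(m) != expected:
                raise ValueError(f"cell {i}: expected {expected} members, got {len(m)}")
            if self.include_self and i not in m:
                raise ValueError(f"cell {i} missing from its own meta-cell")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def edges(self) -> set[tuple[int, int]]:
        """Directed neighbor edges (i, j), j != i."""
        return {(i, int(j)) for i, m in enumerate(self.members) for j in m if j != i}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("cell_id\tmembers\n")
            for cid, m in zip(self.cell_ids, self.members):
                fh.write(f"{cid}\t{','.join(self.cell_ids[int(j)] for j in m)}\n")


def compute_promoter_methylation_matrix(
    calls: Sequence[MethylationCalls],
    tss: Sequence[GeneTSS],
    flank: int = 5000,
) -> PromoterMethylationMatrix:
    """Pool calls in [tss - flank, tss + flank] per gene per cell.

    Entry = sum(n_meth) / sum(n_meth + n_unmeth). Promoters with zero calls in
    a cell are imputed with that cell's mean over covered promoters; a cell
    covering no promoter at all is an error.
    """
    if len(calls) < 2:
        raise ValueError("need at least 2 cells")
    if len(tss) < 1:
        raise ValueError("need at least 1 gene")
    n_genes, n_cells = len(tss), len(calls)
    meth = np.zeros((n_genes, n_cells))
    total = np.zeros((n_genes, n_cells))

    by_chrom: dict[str, list[tuple[int, GeneTSS]]] = {}
    for gi, g in enumerate(tss):
        by_chrom.setdefault(g.chrom, []).append((gi, g))

    for ci, cell in enumerate(calls):
        if len(cell) == 0:
            continue
        order = np.lexsort((cell.pos, cell.chrom.astype(str)))
        chrom_sorted = cell.chrom[order].astype(str)
        pos_sorted = cell.pos[order]
        m_sorted = cell.n_meth[order]
        u_sorted = cell.n_unmeth[order]
        # contiguous chromosome blocks after the sort
        uniq, starts = np.unique(chrom_sorted, return_index=True)
        bounds = dict(zip(uniq, starts))
        ends = dict(zip(uniq, list(starts[1:]) + [len(pos_sorted)]))
        for chrom, gene_list in by_chrom.items():
            if chrom not in bounds:
                continue
            lo, hi = bounds[chrom], ends[chrom]
            cpos = pos_sorted[lo:hi]
            cm = m_sorted[lo:hi]
            cu = u_sorted[lo:hi]
            for gi, g in gene_list:
                a = np.searchsorted(cpos, g.tss - flank, side="left")
                b = np.searchsorted(cpos, g.tss + flank, side="right")
                if b > a:
                    meth[gi, ci] = cm[a:b].sum()
                    total[gi, ci] = (cm[a:b] + cu[a:b]).sum()

    missing = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(missing, np.nan, meth / np.where(total == 0, 1, total))
    covered_per_cell = (~missing).sum(axis=0)
    dead = [calls[ci].cell_id for ci in np.nonzero(covered_per_cell == 0)[0]]
    if dead:
        raise ValueError(f"cells with zero calls in every promoter: {dead}")
    cell_means = np.nanmean(np.where(missing, np.nan, values), axis=0)
    values = np.where(missing, cell_means[None, :], values)
    return PromoterMethylationMatrix(
        genes=[g.gene_id for g in tss],
        cells=[c.cell_id for c in calls],
        values=values,
        missing_mask=missing,
    )


def select_variable_promoters(
    matrix: PromoterMethylationMatrix, n_top: int = 5000
) -> np.ndarray:
    """Indices of the genes with highest across-cell (population) variance.

    Deterministic: ties broken by ascending gene index; clamps to n_genes.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    var = matrix.values.var(axis=1)  # population variance (ddof=0)
    order = np.lexsort((np.arange(len(var)), -var))
    return order[: min(n_top, len(var))]


def compute_pca_embedding(
    matrix: PromoterMethylationMatrix,
    gene_subset: np.ndarray | Sequence[int] | None = None,
    d: int = 10,
    scale: bool = False,
) -> np.ndarray:
    """Cells x d PCA embedding of the (restricted) promoter matrix.

    Columns (genes) are mean-centered; no variance scaling by default since
    methylation levels already share a [0, 1] scale. Component signs are fixed
    so each component's largest-magnitude gene loading is positive.
    """
    if gene_subset is None:
        gene_subset = np.arange(len(matrix.genes))
    gene_subset = np.asarray(gene_subset, dtype=int)
    X = matrix.values[gene_subset].T.astype(float)  # cells x genes
    n_cells, n_feats = X.shape
    if d > min(n_cells, n_feats):
        raise ValueError(f"d={d} exceeds min(n_cells={n_cells}, n_genes={n_feats})")
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(d):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            Vt[j] = -load
            U[:, j] = -U[:, j]
    return U[:, :d] * S[:d]


def build_metacells(
    embedding: np.ndarray, k: int = 20, include_self: bool = True, cell_ids: list[str] | None = None
) -> MetaCellMap:
    """Exact Euclidean k-NN in the embedding; ties broken by ascending index."""
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells (got {n}); use a smaller k")
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]
    dist = cdist(embedding, embedding)
    members: list[np.ndarray] = []
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))
        order = order[order != i]  # drop self regardless of zero-distance ties
        neighbors = order[:k]
        group = np.concatenate(([i], neighbors)) if include_self else neighbors
        members.append(np.sort(group))
    return MetaCellMap(cell_ids=list(cell_ids), members=members, k=k, include_self=include_self)


def adjacency_difference(
    map_a: MetaCellMap, map_b: MetaCellMap, convention: str = "replacements"
) -> float:
    """Fraction of changed neighbor edges relative to ``map_a``.

    ``replacements`` counts a neighbor swapped for another as one change
    (|edges(a) \\ edges(b)| / |edges(a)|); ``symmetric`` uses the full
    symmetric difference over twice the edge count. With equal k both
    coincide.
    """
    if map_a.cell_ids != map_b.cell_ids:
        raise ValueError("meta-cell maps cover different cell sets")
    if map_a.k != map_b.k:
        raise ValueError("meta-cell maps have different k")
    ea, eb = map_a.edges(), map_b.edges()
    if not ea:
        return 0.0
    if convention == "replacements":
        return len(ea - eb) / len(ea)
    if convention == "symmetric":
        return len(ea ^ eb) / (2 * len(ea))
    raise ValueError(f"unknown convention {convention!r}")
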