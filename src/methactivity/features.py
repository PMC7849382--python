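"""Per (gene, meta-cell) feature computation.

Two feature classes over a binned promoter window (default ±5 kb in 20 bins
of 500 bp): CpG-dinucleotide frequency per bin (gene-dependent,
cell-independent) and pooled meta-cell CpG methylation rate per bin (gene-
and cell-dependent). Bin order is always 5'->3' relative to the gene's
strand, so bin 1 is the farthest-upstream bin for every gene. Also provides
the mean-promoter-demethylation (MPD) single-cell baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneTSS, MethylationCalls
from .metacell import MetaCellMap

__all__ = [
    "PromoterModel",
    "FeatureTensor",
    "build_promoter_model",
    "cpg_frequency",
    "metacell_methylation_rate",
    "mpd",
    "mpd_matrix",
    "bin_call_counts",
    "assemble_features",
]


@dataclass
class PromoterModel:
    """Binned promoter window of a gene.

    ``bins`` are 0-based half-open genomic intervals listed 5'->3' relative to
    the gene (bin 1 = farthest upstream). For ``-`` strand genes the genomic
    coordinates therefore descend across the list.
    """

    gene_id: str
    chrom: str
    strand: str
    bins: list[tuple[int, int]]
    clipped: list[bool]  # True where a bin was truncated at a chromosome edge

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def window(self) -> tuple[int, int]:
        """Genomic (start, end), 0-based half-open, spanning all bins."""
        starts = [b[0] for b in self.bins]
        ends = [b[1] for b in self.bins]
        return min(starts), max(ends)


def build_promoter_model(
    gene: GeneTSS,
    flank: int = 5000,
    bin_size: int = 500,
    chrom_length: int | None = None,
) -> PromoterModel:
    """Tile [tss - flank, tss + flank) into equal bins, strand-oriented.

    The 1-based TSS maps to 0-based coordinate tss - 1; the window is the
    half-open interval [tss-1-flank, tss-1+flank). Bins falling past the
    chromosome start (or past ``chrom_length`` when given) are clipped and
    flagged.
    """
    if (2 * flank) % bin_size != 0:
        raise ValueError("bin_size must divide 2 * flank")
    n_bins = (2 * flank) // bin_size
    tss0 = gene.tss - 1
    raw = [
        (tss0 - flank + i * bin_size, tss0 - flank + (i + 1) * bin_size)
        for i in range(n_bins)
    ]
    bins: list[tuple[int, int]] = []
    clipped: list[bool] = []
    for start, end in raw:
        cs, ce = max(start, 0), max(end, 0)
        if chrom_length is not None:
            ce = min(ce, chrom_length)
        cs = min(cs, ce)  # fully out-of-range bins collapse to empty
        bins.append((cs, ce))
        clipped.append((cs, ce) != (start, end))
    if gene.strand == "-":
        bins = bins[::-1]
        clipped = clipped[::-1]
    return PromoterModel(
        gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand, bins=bins, clipped=clipped
    )


def cpg_frequency(model: PromoterModel, genome) -> np.ndarray:
    """Per-bin CpG frequency = 2 x (forward CG count) / bin width.

    ``genome`` is any mapping-style FASTA accessor (e.g. ``pyfaidx.Fasta``)
    supporting ``genome[chrom][start:end]``. CG is its own reverse complement,
    so doubling the forward count covers both strands. A CG straddling a bin
    boundary is credited to the bin containing the C. N bases never match.
    """
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} not in genome")
    freqs = np.zeros(model.n_bins)
    chrom_seq = genome[model.chrom]
    for i, (start, end) in enumerate(model.bins):
        width = end - start
        if width <= 0:
            continue
        # one extra base so a boundary-straddling CG (C at end-1) is seen
        seq = str(chrom_seq[start : end + 1]).upper()
        count = 0
        pos = seq.find("CG")
        while pos != -1 and pos < width:
            count += 1
            pos = seq.find("CG", pos + 1)
        freqs[i] = 2.0 * count / width
    return freqs


def metacell_methylation_rate(
    model: PromoterModel,
    members: Sequence[int],
    calls: Sequence[MethylationCalls],
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-bin methylation rate over all member cells' calls.

    Returns ``(rates, mask)``; ``mask`` is True where a bin received no calls
    from any member (rate left at 0.0 there — impute at assembly time).
    Pooling sums counts first (distinct from averaging per-cell ratios).
    """
    if len(members) == 0:
        raise ValueError("meta-cell must have at least one member")
    meth = np.zeros(model.n_bins)
    total = np.zeros(model.n_bins)
    for ci in members:
        cell = calls[ci]
        on_chrom = cell.chrom.astype(str) == model.chrom
        if not on_chrom.any():
            continue
        pos0 = cell.pos[on_chrom] - 1  # 0-based C coordinate
        m = cell.n_meth[on_chrom]
        u = cell.n_unmeth[on_chrom]
        for b, (start, end) in enumerate(model.bins):
            inside = (pos0 >= start) & (pos0 < end)
            if inside.any():
                meth[b] += m[inside].sum()
                total[b] += (m[inside] + u[inside]).sum()
    mask = total == 0
    rates = np.where(mask, 0.0, meth / np.where(total == 0, 1, total))
    return rates, mask


def mpd(gene: GeneTSS, calls: MethylationCalls, flank: int = 5000) -> float:
    """Mean promoter demethylation: unmethylated / total calls in ±flank.

    Single-cell (no meta-cell pooling). Returns NaN when the promoter has no
    calls; callers impute with the cell's mean MPD over covered promoters.
    """
    on_chrom = calls.chrom.astype(str) == gene.chrom
    pos = calls.pos[on_chrom]
    inside = (pos >= gene.tss - flank) & (pos <= gene.tss + flank)
    if not inside.any():
        return float("nan")
    m = calls.n_meth[on_chrom][inside].sum()
    u = calls.n_unmeth[on_chrom][inside].sum()
    return float(u / (m + u))


def mpd_matrix(
    tss: Sequence[GeneTSS], calls: Sequence[MethylationCalls], flank: int = 5000
) -> np.ndarray:
    """Genes x cells MPD with per-cell mean imputation of uncovered promoters."""
    out = np.full((len(tss), len(calls)), np.nan)
    by_chrom: dict[str, list[tuple[int, GeneTSS]]] = {}
    for gi, g in enumerate(tss):
        by_chrom.setdefault(g.chrom, []).append((gi, g))
    for ci, cell in enumerate(calls):
        if len(cell) == 0:
            continue
        chroms = cell.chrom.astype(str)
        order = np.lexsort((cell.pos, chroms))
        chrom_sorted = chroms[order]
        pos_sorted = cell.pos[order]
        m_sorted = cell.n_meth[order]
        u_sorted = cell.n_unmeth[order]
        uniq, starts = np.unique(chrom_sorted, return_index=True)
        blocks = dict(zip(uniq, zip(starts, list(starts[1:]) + [len(pos_sorted)])))
        for chrom, gene_list in by_chrom.items():
            if chrom not in blocks:
                continue
            lo, hi = blocks[chrom]
            cpos, cm, cu = pos_sorted[lo:hi], m_sorted[lo:hi], u_sorted[lo:hi]
            for gi, g in gene_list:
                a = np.searchsorted(cpos, g.tss - flank, side="left")
                b = np.searchsorted(cpos, g.tss + flank, side="right")
                if b > a:
                    total = (cm[a:b] + cu[a:b]).sum()
                    out[gi, ci] = cu[a:b].sum() / total
    cell_means = np.nanmean(out, axis=0)
    nan_rows = np.isnan(out)
    out[nan_rows] = np.broadcast_to(cell_means[None, :], out.shape)[nan_rows]
    return out


@dataclass
class FeatureTensor:
    """Feature rows per (gene, cell) pair: 20 cpg_ratio + 20 meth_rate columns."""

    gene_ids: list[str]
    cell_ids: list[str]
    pair_gene_idx: np.ndarray  # (n_pairs,) index into gene_ids
    pair_cell_idx: np.ndarray  # (n_pairs,) index into cell_ids
    cpg_ratio: np.ndarray  # (n_pairs, n_bins)
    meth_rate: np.ndarray  # (n_pairs, n_bins), imputed where masked
    meth_mask: np.ndarray  # (n_pairs, n_bins), True = bin had zero pooled calls

    @property
    def n_bins(self) -> int:
        return self.cpg_ratio.shape[1]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [
            (self.gene_ids[g], self.cell_ids[c])
            for g, c in zip(self.pair_gene_idx, self.pair_cell_idx)
        ]

    def __len__(self) -> int:
        return len(self.pair_gene_idx)

    @property
    def X(self) -> np.ndarray:
        """(n_pairs, 2 * n_bins) design matrix: cpg bins then meth_rate bins."""
        return np.hstack([self.cpg_ratio, self.meth_rate])

    @property
    def feature_names(self) -> list[str]:
        n = self.n_bins
        return [f"cpg_{i + 1:02d}" for i in range(n)] + [f"mr_{i + 1:02d}" for i in range(n)]

    def to_tsv(self, path: str | Path, include_mask: bool = False) -> None:
        cols = ["gene_id", "cell_id"] + self.feature_names
        if include_mask:
            cols += [f"mask_{i + 1:02d}" for i in range(self.n_bins)]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in range(len(self)):
                row = [
                    self.gene_ids[self.pair_gene_idx[r]],
                    self.cell_ids[self.pair_cell_idx[r]],
                ]
                row += [f"{v:.6f}" for v in self.cpg_ratio[r]]
                row += [f"{v:.6f}" for v in self.meth_rate[r]]
                if include_mask:
                    row += [str(int(v)) for v in self.meth_mask[r]]
                fh.write("\t".join(row) + "\n")


def bin_call_counts(
    models: Sequence[PromoterModel], calls: Sequence[MethylationCalls]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell binned call counts: (meth, total), each (n_cells, n_genes, n_bins).

    Vectorized per cell with a searchsorted over sorted bin boundaries; a call
    overlapped by several genes' promoters is credited to each of them.
    """
    n_bins = models[0].n_bins
    n_genes, n_cells = len(models), len(calls)
    meth = np.zeros((n_cells, n_genes, n_bins))
    total = np.zeros((n_cells, n_genes, n_bins))

    # per chromosome: flat sorted array of bin starts plus (gene, bin) ids
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {m.chrom for m in models}:
        starts, ends, gidx, bidx = [], [], [], []
        for gi, m in enumerate(models):
            if m.chrom != chrom:
                continue
            for b, (s, e) in enumerate(m.bins):
                if e > s:
                    starts.append(s)
                    ends.append(e)
                    gidx.append(gi)
                    bidx.append(b)
        order = np.argsort(np.asarray(starts), kind="stable")
        by_chrom[chrom] = (
            np.asarray(starts)[order],
            np.asarray(ends)[order],
            np.asarray(gidx)[order],
            np.asarray(bidx)[order],
        )

    for ci, cell in enumerate(calls):
        if len(cell) == 0:
            continue
        chroms = cell.chrom.astype(str)
        for chrom, (starts, ends, gidx, bidx) in by_chrom.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            pos0 = cell.pos[sel] - 1
            m = cell.n_meth[sel]
            u = cell.n_unmeth[sel]
            # bins may overlap across genes: check a bounded window of
            # candidate bins whose start is at or before the position
            hi = np.searchsorted(starts, pos0, side="right")
            max_span = int((ends - starts).max()) if len(starts) else 0
            lo = np.searchsorted(starts, pos0 - max_span, side="left")
            for p in range(len(pos0)):
                for j in range(lo[p], hi[p]):
                    if starts[j] <= pos0[p] < ends[j]:
                        meth[ci, gidx[j], bidx[j]] += m[p]
                        total[ci, gidx[j], bidx[j]] += m[p] + u[p]
    return meth, total


def assemble_features(
    models: Sequence[PromoterModel],
    metacells: MetaCellMap,
    calls: Sequence[MethylationCalls],
    genome,
    gene_subset: Sequence[str] | None = None,
    cell_subset: Sequence[str] | None = None,
) -> FeatureTensor:
    """Build the full (gene, cell) feature tensor, gene-major pair order.

    Masked meth_rate bins are imputed with the meta-cell's mean rate over the
    gene's non-empty bins, falling back to the meta-cell's mean over all
    genes, then to the global mean.
    """
    model_by_gene = {m.gene_id: m for m in models}
    call_idx = {c.cell_id: i for i, c in enumerate(calls)}
    if gene_subset is None:
        gene_ids = [m.gene_id for m in models]
    else:
        unknown = [g for g in gene_subset if g not in model_by_gene]
        if unknown:
            raise KeyError(f"unknown gene ids: {unknown[:5]}")
        gene_ids = list(gene_subset)
    if cell_subset is None:
        cell_ids = list(metacells.cell_ids)
    else:
        unknown = [c for c in cell_subset if c not in metacells.cell_ids]
        if unknown:
            raise KeyError(f"unknown cell ids: {unknown[:5]}")
        cell_ids = list(cell_subset)
    for cid in metacells.cell_ids:
        if cid not in call_idx:
            raise KeyError(f"no methylation calls for cell {cid!r}")

    used_models = [model_by_gene[g] for g in gene_ids]
    n_bins = used_models[0].n_bins

    cpg_by_gene = np.stack([cpg_frequency(m, genome) for m in used_models])

    # map metacell member indices (over metacells.cell_ids) onto calls order
    member_call_idx = [
        np.asarray([call_idx[metacells.cell_ids[int(j)]] for j in mem])
        for mem in metacells.members
    ]
    meth_c, total_c = bin_call_counts(used_models, calls)  # (n_calls, n_genes, n_bins)

    mc_rows = [metacells.cell_ids.index(c) for c in cell_ids]
    n_pairs = len(gene_ids) * len(cell_ids)
    pair_gene = np.repeat(np.arange(len(gene_ids)), len(cell_ids))
    pair_cell = np.tile(np.arange(len(cell_ids)), len(gene_ids))
    meth_rate = np.zeros((n_pairs, n_bins))
    mask = np.zeros((n_pairs, n_bins), dtype=bool)

    # pooled counts per meta-cell, (n_cells_out, n_genes, n_bins)
    pooled_m = np.stack([meth_c[member_call_idx[r]].sum(axis=0) for r in mc_rows])
    pooled_t = np.stack([total_c[member_call_idx[r]].sum(axis=0) for r in mc_rows])
    empty = pooled_t == 0
    rates = np.where(empty, np.nan, pooled_m / np.where(empty, 1, pooled_t))

    # imputation hierarchy: gene-local mean -> meta-cell mean -> global mean
    with np.errstate(invalid="ignore"):
        gene_local = np.nanmean(rates, axis=2)  # (cells, genes)
        cell_global = np.nanmean(rates.reshape(rates.shape[0], -1), axis=1)  # (cells,)
    overall = np.nanmean(rates)
    if np.isnan(overall):
        overall = 0.5
    cell_global = np.where(np.isnan(cell_global), overall, cell_global)
    fill = np.where(np.isnan(gene_local), cell_global[:, None], gene_local)
    filled = np.where(empty, fill[:, :, None], rates)

    for pi, (g, c) in enumerate(zip(pair_gene, pair_cell)):
        meth_rate[pi] = filled[c, g]
        mask[pi] = empty[c, g]

    cpg_ratio = cpg_by_gene[pair_gene]
    return FeatureTensor(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        pair_gene_idx=pair_gene,
        pair_cell_idx=pair_cell,
        cpg_ratio=cpg_ratio,
        meth_rate=meth_rate,
        meth_mask=mask,
    )
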