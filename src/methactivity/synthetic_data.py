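"""Desk-scale synthetic multi-omics generator.

Emits a genome FASTA, TSS annotation, CpG-island BED, sparse per-cell
methylation calls, and a matched expression count matrix, together with the
ground truth used to generate them. The planted structure mirrors what the
predictive pipeline assumes:

* cell subpopulations with distinct promoter methylation profiles;
* gene-dependent coupling between promoter methylation and expression —
  negative, positive, or absent — so a single monotone baseline cannot win;
* methylation signal concentrated in the bins just downstream of the TSS;
* promoter CpG-density classes emulating islands / shores / shelves / open
  sea, with weaker coupling for island-like genes;
* sparse observation: each CpG site is seen in a cell with a small
  probability, at a read depth of 1-3.

Latent (noise-free) bin methylation drives expression; the sparse calls are
an observation layer on top of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import build_promoter_model
from .io_formats import ExpressionMatrix, GeneTSS, MethylationCalls, write_bismark_cov

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedGenome",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_methylomes",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]

_CONTEXTS = ("island", "shore", "shelf", "open_sea")
_CLASSES = ("negative", "positive", "uncoupled")
# expression coupling is damped for island-like promoters, full strength in open sea
_CONTEXT_COUPLING = {"island": 0.15, "shore": 0.45, "shelf": 0.75, "open_sea": 1.0}


@dataclass
class SimulationConfig:
    n_genes: int = 300
    n_cells: int = 300
    n_cell_types: int = 2
    coverage_rate: float = 0.05
    gene_classes: dict = field(
        default_factory=lambda: {"negative": 0.4, "positive": 0.3, "uncoupled": 0.3}
    )
    cpg_context_mix: dict = field(
        default_factory=lambda: {"island": 0.25, "shore": 0.15, "shelf": 0.10, "open_sea": 0.50}
    )
    coupling_strength: dict = field(
        default_factory=lambda: {"negative": 6.0, "positive": 6.0, "uncoupled": 0.0}
    )
    expression_noise: float = 0.5  # NB over-dispersion; 0 -> Poisson
    flank: int = 5000
    bin_size: int = 500
    genes_per_chrom: int = 50
    type_shift_sd: float = 0.2  # between-cell-type promoter methylation shift
    expr_meth_trend: float = 3.0  # gene-level: demethylated promoters express more
    expr_baseline_sd: float = 0.6  # gene-level log-expression spread around the trend
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0 < self.coverage_rate <= 1):
            raise ValueError("coverage_rate must be in (0, 1]")
        for name, d, keys in (
            ("gene_classes", self.gene_classes, _CLASSES),
            ("cpg_context_mix", self.cpg_context_mix, _CONTEXTS),
        ):
            if set(d) != set(keys):
                raise ValueError(f"{name} must have keys {keys}")
            if not np.isclose(sum(d.values()), 1.0):
                raise ValueError(f"{name} proportions must sum to 1")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    tss: list[GeneTSS]
    islands: dict[str, list[tuple[int, int]]]  # 0-based half-open
    contexts: list[str]  # per gene
    # per gene: 1-based C positions of promoter CpG sites + strand-oriented bin index
    site_pos: list[np.ndarray]
    site_bin: list[np.ndarray]


@dataclass
class TruthTable:
    gene_ids: list[str]
    gene_class: list[str]
    sign: np.ndarray  # -1 / +1 / 0
    strength: np.ndarray  # effective (class x context) coupling strength
    context: list[str]
    bin_weights: np.ndarray  # (n_genes, n_bins) driver profile, rows sum to 1 or 0
    expr_baseline: np.ndarray  # (n_genes,) log-scale baseline expression
    cell_ids: list[str]
    cell_type: np.ndarray  # (n_cells,) int labels
    latent_bin_meth: np.ndarray  # (n_genes, n_bins, n_cells)
    latent_activity: np.ndarray | None = None  # (n_genes, n_cells), set by expression

    def driver_methylation(self) -> np.ndarray:
        """(n_genes, n_cells) weighted mean of latent bin methylation."""
        return np.einsum("gb,gbc->gc", self.bin_weights, self.latent_bin_meth)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: SimulatedGenome
    calls: list[MethylationCalls]
    counts: ExpressionMatrix
    truth: TruthTable


def _promoter_base_probs(context: str, bin_offset_kb: float) -> tuple[float, float]:
    """(P(C), P(G)) for a promoter bin at |offset| kb from the TSS."""
    if context == "island" and bin_offset_kb <= 1.0:
        return 0.30, 0.30
    if context == "island" and bin_offset_kb <= 2.0:
        return 0.15, 0.15
    return 0.08, 0.08


def _random_seq(rng: np.random.Generator, length: int, p_c: float, p_g: float) -> str:
    probs = np.array([(1 - p_c - p_g) / 2, p_c, p_g, (1 - p_c - p_g) / 2])
    bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
    return "".join(bases)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Synthesize chromosome sequences, TSSs, islands, and CpG site maps.

    One chromosome per ``genes_per_chrom`` genes; TSS spacing exceeds twice
    the flank so promoters never overlap. Island-class promoters get elevated
    CG density near the TSS and an island interval overlapping the promoter;
    shore/shelf classes get an island at 1 kb / 3 kb beyond the promoter edge.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    flank, bin_size = config.flank, config.bin_size
    gap = 2 * flank  # spacer between consecutive promoter windows
    margin = 1000

    contexts = [
        str(c)
        for c in rng.choice(
            np.array(_CONTEXTS, dtype=object),
            size=config.n_genes,
            p=[config.cpg_context_mix[c] for c in _CONTEXTS],
        )
    ]
    strands = ["+" if s else "-" for s in rng.random(config.n_genes) < 0.5]

    sequences: dict[str, str] = {}
    islands: dict[str, list[tuple[int, int]]] = {}
    tss_list: list[GeneTSS] = []
    site_pos: list[np.ndarray] = []
    site_bin: list[np.ndarray] = []

    n_chroms = int(np.ceil(config.n_genes / config.genes_per_chrom))
    gene_i = 0
    for ch in range(n_chroms):
        chrom = f"chr{ch + 1}"
        chunks: list[str] = []
        cursor = 0
        chrom_islands: list[tuple[int, int]] = []
        genes_here = min(config.genes_per_chrom, config.n_genes - gene_i)
        for _ in range(genes_here):
            gid = f"gene_{gene_i:04d}"
            ctx = contexts[gene_i]
            # leading spacer (CG-poor)
            lead = margin if cursor == 0 else gap
            chunks.append(_random_seq(rng, lead, 0.05, 0.05))
            cursor += lead
            window_start = cursor  # 0-based promoter window start
            tss0 = window_start + flank
            n_bins = config.n_bins
            for b in range(n_bins):
                center = window_start + b * bin_size + bin_size / 2
                off_kb = abs(center - tss0) / 1000.0
                p_c, p_g = _promoter_base_probs(ctx, off_kb)
                chunks.append(_random_seq(rng, bin_size, p_c, p_g))
            cursor += 2 * flank
            tss1 = tss0 + 1  # 1-based
            gene = GeneTSS(gene_id=gid, chrom=chrom, tss=tss1, strand=strands[gene_i])
            tss_list.append(gene)
            if ctx == "island":
                chrom_islands.append((tss0 - 1000, tss0 + 1000))
            elif ctx == "shore":
                edge = window_start + 2 * flank
                chrom_islands.append((edge + 1000, edge + 1600))
            elif ctx == "shelf":
                edge = window_start + 2 * flank
                chrom_islands.append((edge + 3000, edge + 3600))
            gene_i += 1
        chunks.append(_random_seq(rng, margin, 0.05, 0.05))
        sequences[chrom] = "".join(chunks)
        if chrom_islands:
            islands[chrom] = sorted(chrom_islands)

    # scan promoters for CpG sites and map them to strand-oriented bins
    for gene in tss_list:
        model = build_promoter_model(gene, flank=flank, bin_size=bin_size)
        w_start, w_end = model.window
        seq = sequences[gene.chrom][w_start:w_end].upper()
        positions = []
        p = seq.find("CG")
        while p != -1:
            positions.append(w_start + p + 1)  # 1-based C position
            p = seq.find("CG", p + 1)
        pos_arr = np.asarray(positions, dtype=np.int64)
        # genomic bin index, then reorient for strand
        genomic_bin = (pos_arr - 1 - w_start) // bin_size
        if gene.strand == "-":
            genomic_bin = config.n_bins - 1 - genomic_bin
        site_pos.append(pos_arr)
        site_bin.append(genomic_bin.astype(np.int64))

    return SimulatedGenome(
        sequences=sequences,
        tss=tss_list,
        islands=islands,
        contexts=contexts,
        site_pos=site_pos,
        site_bin=site_bin,
    )


def _signal_profile(n_bins: int) -> np.ndarray:
    """Driver-bin weights: the two bins just downstream of the TSS carry most
    of the signal, the bin immediately upstream a little."""
    p = np.zeros(n_bins)
    mid = n_bins // 2  # first downstream bin index
    p[mid] = 0.4
    p[min(mid + 1, n_bins - 1)] = 0.4
    p[mid - 1] = 0.2
    return p


def simulate_methylomes(
    config: SimulationConfig, genome: SimulatedGenome, cells_seed: int = 0
) -> tuple[list[MethylationCalls], TruthTable]:
    """Draw latent per-cell bin methylation, then sparse observed calls.

    Gene-level truth (classes, couplings, baselines, type profiles) depends
    only on ``config.seed``, so two datasets sharing a config but differing
    in ``cells_seed`` share a genome and gene biology while drawing
    independent cells — the structure cross-dataset validation assumes.
    """
    rng_g = np.random.default_rng(np.random.SeedSequence([config.seed, 21]))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22, cells_seed]))
    n_genes, n_cells, n_bins = config.n_genes, config.n_cells, config.n_bins

    gene_class = [
        str(c)
        for c in rng_g.choice(
            np.array(_CLASSES, dtype=object),
            size=n_genes,
            p=[config.gene_classes[c] for c in _CLASSES],
        )
    ]
    sign = np.array([{"negative": -1, "positive": 1, "uncoupled": 0}[c] for c in gene_class])
    strength = np.array(
        [
            config.coupling_strength[c] * _CONTEXT_COUPLING[genome.contexts[g]]
            for g, c in enumerate(gene_class)
        ]
    )
    profile = _signal_profile(n_bins)
    bin_weights = np.tile(profile, (n_genes, 1))
    gamma = profile / profile.max()  # per-bin susceptibility to the cell signal

    base = rng_g.uniform(0.3, 0.7, size=n_genes)
    type_shift = rng_g.normal(0, config.type_shift_sd, size=(n_genes, config.n_cell_types))
    # gene-level coupling between baseline demethylation and expression keeps
    # the single-cell MPD baseline informative rather than trivially noise;
    # island-like promoters are insensitive to methylation at the gene level
    # too, so their predictable expression variance shrinks with the context
    # multiplier and open-sea strata stay the most predictable
    ctx_mult = np.array([_CONTEXT_COUPLING[c] for c in genome.contexts])
    expr_baseline = (
        np.log(10.0)
        + ctx_mult * config.expr_meth_trend * (0.5 - base)
        + rng_g.normal(0, config.expr_baseline_sd, size=n_genes)
        * (0.25 + 0.75 * ctx_mult)
    )

    cell_type = rng.integers(0, config.n_cell_types, size=n_cells)
    shift = type_shift[:, cell_type] + rng.normal(0, 0.08, size=(n_genes, n_cells))
    extra = rng.normal(0, 0.15, size=(n_genes, n_cells))
    bin_noise = rng.normal(0, 0.03, size=(n_genes, n_bins, n_cells))

    latent = (
        base[:, None, None]
        + shift[:, None, :]
        + gamma[None, :, None] * extra[:, None, :]
        + bin_noise
    )
    latent = np.clip(latent, 0.02, 0.98)

    # flatten site maps for vectorized per-cell observation
    site_gene = np.concatenate(
        [np.full(len(p), g, dtype=np.int64) for g, p in enumerate(genome.site_pos)]
    )
    site_pos = np.concatenate(genome.site_pos)
    site_bin = np.concatenate(genome.site_bin)
    site_chrom = np.concatenate(
        [np.full(len(p), genome.tss[g].chrom, dtype=object) for g, p in enumerate(genome.site_pos)]
    )
    n_sites = len(site_pos)

    calls: list[MethylationCalls] = []
    for c in range(n_cells):
        observed = np.nonzero(rng.random(n_sites) < config.coverage_rate)[0]
        depth = rng.integers(1, 4, size=len(observed))
        probs = latent[site_gene[observed], site_bin[observed], c]
        n_meth = rng.binomial(depth, probs)
        calls.append(
            MethylationCalls(
                cell_id=f"cell_{c:04d}",
                chrom=site_chrom[observed],
                pos=site_pos[observed],
                n_meth=n_meth.astype(np.int64),
                n_unmeth=(depth - n_meth).astype(np.int64),
            )
        )

    truth = TruthTable(
        gene_ids=[g.gene_id for g in genome.tss],
        gene_class=gene_class,
        sign=sign,
        strength=strength,
        context=list(genome.contexts),
        bin_weights=bin_weights,
        expr_baseline=expr_baseline,
        cell_ids=[f"cell_{c:04d}" for c in range(n_cells)],
        cell_type=cell_type,
        latent_bin_meth=latent,
    )
    return calls, truth


def simulate_expression(
    config: SimulationConfig, truth: TruthTable, cells_seed: int = 0
) -> ExpressionMatrix:
    """Counts from latent activity = baseline + sign * strength * centered
    driver methylation; negative-binomial noise around exp(activity)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 33, cells_seed]))
    baseline = truth.expr_baseline
    driver = truth.driver_methylation()
    z = driver - driver.mean(axis=1, keepdims=True)
    activity = baseline[:, None] + truth.sign[:, None] * truth.strength[:, None] * z
    mu = np.exp(activity)
    if config.expression_noise > 0:
        r = 1.0 / config.expression_noise
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    truth.latent_activity = activity
    return ExpressionMatrix(
        genes=list(truth.gene_ids),
        cells=list(truth.cell_ids),
        values=counts.astype(float),
    )


def simulate_dataset(config: SimulationConfig, cells_seed: int = 0) -> SimulatedDataset:
    """One dataset; vary ``cells_seed`` (same config) for an independent
    dataset over the same genome and gene truth."""
    genome = simulate_genome(config)
    calls, truth = simulate_methylomes(config, genome, cells_seed=cells_seed)
    counts = simulate_expression(config, truth, cells_seed=cells_seed)
    return SimulatedDataset(config=config, genome=genome, calls=calls, counts=counts, truth=truth)


def write_dataset(
    dataset: SimulatedDataset, outdir: str | Path, gzip_cov: bool = False
) -> dict[str, Path]:
    """Write all artifacts; returns a name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fa = outdir / "genome.fa"
    with open(fa, "w") as fh:
        for chrom, seq in dataset.genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = fa

    bed = outdir / "genes.bed"
    with open(bed, "w") as fh:
        for g in dataset.genome.tss:
            start0 = g.tss - 1
            fh.write(f"{g.chrom}\t{start0}\t{g.tss}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["annotation"] = bed

    isl = outdir / "islands.bed"
    with open(isl, "w") as fh:
        for chrom, intervals in dataset.genome.islands.items():
            for s, e in intervals:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    paths["islands"] = isl

    cov_dir = outdir / "cov"
    cov_dir.mkdir(exist_ok=True)
    manifest = outdir / "manifest.tsv"
    suffix = ".cov.gz" if gzip_cov else ".cov"
    with open(manifest, "w") as fh:
        for cell in dataset.calls:
            cov_path = cov_dir / f"{cell.cell_id}{suffix}"
            write_bismark_cov(cell, cov_path)
            fh.write(f"{cell.cell_id}\t{cov_path.relative_to(outdir)}\n")
    paths["manifest"] = manifest

    counts_path = outdir / "counts.tsv"
    dataset.counts.to_frame().to_csv(counts_path, sep="\t", index_label="gene_id")
    paths["counts"] = counts_path

    truth = dataset.truth
    tg = outdir / "truth_genes.tsv"
    with open(tg, "w") as fh:
        fh.write("gene_id\tclass\tsign\tstrength\tcontext\n")
        for i, gid in enumerate(truth.gene_ids):
            fh.write(
                f"{gid}\t{truth.gene_class[i]}\t{int(truth.sign[i])}\t"
                f"{truth.strength[i]:.4f}\t{truth.context[i]}\n"
            )
    paths["truth_genes"] = tg
    tc = outdir / "truth_cells.tsv"
    with open(tc, "w") as fh:
        fh.write("cell_id\tcell_type\n")
        for cid, t in zip(truth.cell_ids, truth.cell_type):
            fh.write(f"{cid}\t{int(t)}\n")
    paths["truth_cells"] = tc

    cfg = outdir / "config.json"
    with open(cfg, "w") as fh:
        json.dump(asdict(dataset.config), fh, indent=2)
    paths["config"] = cfg
    return paths
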