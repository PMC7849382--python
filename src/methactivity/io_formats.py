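"""Readers and writers for the on-disk formats used by the pipeline.

Supported formats: Bismark coverage (COV) methylation-call files (optionally
gzip-compressed), GTF / BED6 gene annotations, genome FASTA (random access via
pyfaidx), expression matrices (TSV or MatrixMarket triplets), and the output
gene-activity TSV.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationCalls",
    "GeneTSS",
    "ExpressionMatrix",
    "CovParseError",
    "read_bismark_cov",
    "write_bismark_cov",
    "read_cell_manifest",
    "read_tss_annotation",
    "normalize_expression",
    "read_expression_tsv",
    "read_expression_mtx",
    "write_gene_activity",
    "read_gene_activity",
]


class CovParseError(ValueError):
    """Raised when a COV file line cannot be parsed."""


@dataclass
class MethylationCalls:
    """Per-cell CpG methylation calls with count semantics.

    Positions are 1-based genomic coordinates of the cytosine. Each record
    carries methylated / unmethylated read counts; the Bismark percentage
    column is never stored (it is redundant with the counts).
    """

    cell_id: str
    chrom: np.ndarray  # dtype=object, chromosome name per record
    pos: np.ndarray  # int64, 1-based
    n_meth: np.ndarray  # int64
    n_unmeth: np.ndarray  # int64

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.chrom) == len(self.n_meth) == len(self.n_unmeth) == n):
            raise ValueError("field lengths differ")
        if n and int(self.pos.min()) < 1:
            raise ValueError("positions must be >= 1")
        if n and (int(self.n_meth.min()) < 0 or int(self.n_unmeth.min()) < 0):
            raise ValueError("counts must be nonnegative")
        if n and int((self.n_meth + self.n_unmeth).min()) < 1:
            raise ValueError("every record needs at least one read")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def records(self) -> list[tuple[str, int, int, int]]:
        return [
            (str(c), int(p), int(m), int(u))
            for c, p, m, u in zip(self.chrom, self.pos, self.n_meth, self.n_unmeth)
        ]

    @classmethod
    def from_records(
        cls, cell_id: str, records: Sequence[tuple[str, int, int, int]]
    ) -> "MethylationCalls":
        if records:
            chrom, pos, m, u = zip(*records)
        else:
            chrom, pos, m, u = (), (), (), ()
        return cls(
            cell_id=cell_id,
            chrom=np.asarray(chrom, dtype=object),
            pos=np.asarray(pos, dtype=np.int64),
            n_meth=np.asarray(m, dtype=np.int64),
            n_unmeth=np.asarray(u, dtype=np.int64),
        )


@dataclass(frozen=True)
class GeneTSS:
    """A gene's transcription start site."""

    gene_id: str
    chrom: str
    tss: int  # 1-based
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.tss < 1:
            raise ValueError(f"TSS must be >= 1 for {self.gene_id}")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values (raw counts or normalized)."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # shape (n_genes, n_cells)
    norm_constant: float | None = None  # max log-CPM used for normalization
    _gene_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    def gene_idx(self, gene_id: str) -> int:
        return self._gene_index[gene_id]

    def cell_idx(self, cell_id: str) -> int:
        return self._cell_index[cell_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bismark_cov(path: str | Path, cell_id: str | None = None) -> MethylationCalls:
    """Read a Bismark coverage file into :class:`MethylationCalls`.

    Columns: chrom, start (1-based), end, methylation %, count methylated,
    count unmethylated. The percentage column is ignored; downstream code
    always recomputes rates from counts. ``.gz`` input is detected by suffix.
    """
    path = Path(path)
    if cell_id is None:
        cell_id = path.name
        for suffix in (".gz", ".cov", ".txt", ".tsv"):
            if cell_id.endswith(suffix):
                cell_id = cell_id[: -len(suffix)]
    chroms: list[str] = []
    positions: list[int] = []
    meths: list[int] = []
    unmeths: list[int] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CovParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            try:
                pos = int(fields[1])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise CovParseError(f"{path}:{lineno}: {exc}") from None
            if n_meth < 0 or n_unmeth < 0:
                raise CovParseError(f"{path}:{lineno}: negative count")
            chroms.append(fields[0])
            positions.append(pos)
            meths.append(n_meth)
            unmeths.append(n_unmeth)
    calls = MethylationCalls(
        cell_id=cell_id,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        n_meth=np.asarray(meths, dtype=np.int64),
        n_unmeth=np.asarray(unmeths, dtype=np.int64),
    )
    seen = set(zip(chroms, positions))
    if len(seen) != len(positions):
        raise CovParseError(f"{path}: duplicate (chrom, pos) records")
    return calls


def write_bismark_cov(calls: MethylationCalls, path: str | Path) -> None:
    """Write calls back to COV format (``.gz`` suffix triggers compression)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for c, p, m, u in zip(calls.chrom, calls.pos, calls.n_meth, calls.n_unmeth):
            total = m + u
            pct = 100.0 * m / total if total else 0.0
            fh.write(f"{c}\t{p}\t{p}\t{pct:g}\t{m}\t{u}\n")


def read_cell_manifest(path: str | Path) -> dict[str, Path]:
    """Read a 2-column TSV mapping cell_id -> COV file path.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    mapping: dict[str, Path] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            cell_id, cov_path = parts
            p = Path(cov_path)
            if not p.is_absolute():
                p = path.parent / p
            mapping[cell_id] = p
    if not mapping:
        raise ValueError(f"{path}: empty manifest")
    return mapping


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
        elif "=" in chunk:
            key, _, value = chunk.partition("=")
        else:
            continue
        out[key] = value.strip().strip('"')
    return out


def read_tss_annotation(path: str | Path, format: str | None = None) -> list[GeneTSS]:
    """Read gene TSSs from a GTF (``gene`` features) or BED6 file.

    TSS is the feature start for ``+``-strand genes and the feature end for
    ``-``-strand genes (GTF is 1-based inclusive; BED starts are converted to
    1-based). Duplicate gene_ids collapse to the first occurrence with a
    warning.
    """
    path = Path(path)
    if format is None:
        stem = path.name.lower()
        if stem.endswith((".gtf", ".gtf.gz")):
            format = "gtf"
        elif stem.endswith((".bed", ".bed.gz")):
            format = "bed"
        else:
            raise ValueError(f"cannot infer annotation format from {path.name}")
    if format not in ("gtf", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")

    genes: list[GeneTSS] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gtf":
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GTF needs 9 columns")
                if fields[2] != "gene":
                    continue
                chrom, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
                attrs = _parse_gtf_attributes(fields[8])
                gene_id = attrs.get("gene_id")
                if gene_id is None:
                    raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            else:
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
                chrom, gene_id, strand = fields[0], fields[3], fields[5]
                start, end = int(fields[1]) + 1, int(fields[2])
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            if gene_id in seen:
                logger.warning("duplicate gene_id %s at %s:%d; keeping first", gene_id, path, lineno)
                continue
            seen.add(gene_id)
            tss = start if strand == "+" else end
            genes.append(GeneTSS(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
    if not genes:
        raise ValueError(f"{path}: no gene records found")
    return genes


def normalize_expression(
    counts: ExpressionMatrix, max_log: float | None = None
) -> ExpressionMatrix:
    """CPM -> log2(CPM + 1) -> divide by the dataset max log value.

    Every cell must have a positive total count. When ``max_log`` is given
    (e.g. the constant learned on a training set) it is reused instead of the
    dataset's own maximum, so train and test live on the same scale.
    """
    values = np.asarray(counts.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    totals = values.sum(axis=0)
    zero_cells = [c for c, t in zip(counts.cells, totals) if t == 0]
    if zero_cells:
        raise ValueError(f"cells with zero total counts: {zero_cells}")
    cpm = values / totals * 1e6
    log_cpm = np.log2(cpm + 1.0)
    if max_log is None:
        max_log = float(log_cpm.max())
    if max_log <= 0:
        raise ValueError("normalization constant must be positive")
    return ExpressionMatrix(
        genes=list(counts.genes),
        cells=list(counts.cells),
        values=log_cpm / max_log,
        norm_constant=max_log,
    )


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes x cells TSV with a header row of cell ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        cells=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def read_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet matrix with separate row/column label files."""
    from scipy.io import mmread

    mat = mmread(os.fspath(mtx_path)).toarray()
    genes = [line.strip().split("\t")[0] for line in open(genes_path) if line.strip()]
    cells = [line.strip().split("\t")[0] for line in open(cells_path) if line.strip()]
    return ExpressionMatrix(genes=genes, cells=cells, values=np.asarray(mat, dtype=float))


def write_gene_activity(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes x cells activity matrix as TSV at 6-decimal precision."""
    if matrix.values.size == 0:
        raise ValueError("refusing to write an empty matrix")
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="gene_id")


def read_gene_activity(path: str | Path) -> ExpressionMatrix:
    return read_expression_tsv(path)
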