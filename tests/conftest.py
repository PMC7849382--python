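import numpy as np
import pytest

from methactivity.io_formats import GeneTSS, MethylationCalls
from methactivity.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but well-covered synthetic dataset shared across test modules."""
    cfg = SimulationConfig(n_genes=30, n_cells=30, coverage_rate=0.3, seed=101)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Mid-sized dataset with default (sparse) coverage."""
    cfg = SimulationConfig(n_genes=60, n_cells=80, coverage_rate=0.1, seed=202)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_calls(cell_id, records):
    """Shorthand for hand-built calls: records = [(chrom, pos, meth, unmeth)]."""
    return MethylationCalls.from_records(cell_id, records)


def make_gene(gene_id="gA", chrom="chr1", tss=10001, strand="+"):
    return GeneTSS(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand)


@pytest.fixture()
def gene_plus():
    return make_gene()


@pytest.fixture()
def gene_minus():
    return make_gene(gene_id="gB", strand="-")
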