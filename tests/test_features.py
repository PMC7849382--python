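import re

import numpy as np
import pytest

from methactivity.features import (
    assemble_features,
    bin_call_counts,
    build_promoter_model,
    cpg_frequency,
    metacell_methylation_rate,
    mpd,
    mpd_matrix,
)
from methactivity.io_formats import GeneTSS
from methactivity.metacell import MetaCellMap
from methactivity.metacell import compute_promoter_methylation_matrix

from conftest import make_calls, make_gene


class TestBuildPromoterModel:
    def test_default_bin_count(self, gene_plus):
        model = build_promoter_model(gene_plus, flank=5000, bin_size=500)
        assert model.n_bins == 20

    def test_plus_strand_first_bin(self, gene_plus):
        model = build_promoter_model(gene_plus)  # tss = 10001 -> tss0 = 10000
        assert model.bins[0] == (5000, 5500)
        assert model.bins[-1] == (14500, 15000)

    def test_minus_strand_reversed(self, gene_minus):
        model = build_promoter_model(gene_minus)
        assert model.bins[0] == (14500, 15000)
        assert model.bins[-1] == (5000, 5500)

    def test_bins_tile_window_exactly(self, gene_plus):
        model = build_promoter_model(gene_plus)
        intervals = sorted(model.bins)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 == s2
        assert sum(e - s for s, e in intervals) == 10000

    def test_clipping_at_chromosome_start(self):
        gene = make_gene(tss=3001)  # window would start at -2000
        model = build_promoter_model(gene)
        assert model.bins[0] == (0, 0)  # fully out of range -> empty
        assert model.clipped[0] and model.clipped[3]
        assert not model.clipped[4]

    def test_bin_size_must_divide_window(self, gene_plus):
        with pytest.raises(ValueError):
            build_promoter_model(gene_plus, flank=5000, bin_size=333)


class TestCpgFrequency:
    def _genome(self, seq, chrom="chr1"):
        return {chrom: seq}

    def test_all_a_is_zero(self):
        gene = make_gene(tss=5001)
        genome = self._genome("A" * 20000)
        model = build_promoter_model(gene, flank=500, bin_size=500)
        np.testing.assert_array_equal(cpg_frequency(model, genome), [0.0, 0.0])

    def test_saturated_cg_bin(self):
        gene = make_gene(tss=501)
        genome = self._genome("CG" * 10000)
        model = build_promoter_model(gene, flank=500, bin_size=500)
        np.testing.assert_allclose(cpg_frequency(model, genome), [1.0, 1.0])

    def test_matches_regex_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30000))
        genome = self._genome(seq)
        gene = make_gene(tss=10001)
        model = build_promoter_model(gene)
        freqs = cpg_frequency(model, genome)
        for i, (start, end) in enumerate(model.bins):
            # oracle: CG occurrences whose C lies in the bin
            count = len(re.findall("(?=CG)", seq[start : end + 1].upper())) - (
                1 if seq[end - 1 : end + 1].upper() == "CG" and False else 0
            )
            count = sum(
                1 for m in re.finditer("(?=CG)", seq[start : end + 1].upper()) if m.start() < 500
            )
            assert freqs[i] == pytest.approx(2 * count / 500)

    def test_case_insensitive_and_n_never_matches(self):
        seq = "cg" + "N" * 498 + "A" * 1000
        gene = make_gene(tss=501)
        model = build_promoter_model(gene, flank=500, bin_size=500)
        freqs = cpg_frequency(model, self._genome(seq))
        assert freqs[0] == pytest.approx(2 / 500)
        assert freqs[1] == 0.0

    def test_boundary_cg_credited_to_c_bin(self):
        # C at position 499 (last of bin 1), G at 500 (first of bin 2)
        seq = "A" * 499 + "CG" + "A" * 1499
        gene = make_gene(tss=501)
        model = build_promoter_model(gene, flank=500, bin_size=500)
        freqs = cpg_frequency(model, self._genome(seq))
        assert freqs[0] == pytest.approx(2 / 500)
        assert freqs[1] == 0.0

    def test_missing_chromosome_error(self, gene_plus):
        model = build_promoter_model(gene_plus)
        with pytest.raises(KeyError):
            cpg_frequency(model, {"chrX": "A" * 100})

    def test_strand_reversal_reverses_vector(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30000))
        fwd = build_promoter_model(make_gene(tss=10001, strand="+"))
        rev = build_promoter_model(make_gene(tss=10001, strand="-"))
        f1 = cpg_frequency(fwd, self._genome(seq))
        f2 = cpg_frequency(rev, self._genome(seq))
        np.testing.assert_allclose(f1, f2[::-1])


class TestMetacellMethylationRate:
    def test_single_member_ratio(self, gene_plus):
        model = build_promoter_model(gene_plus)
        calls = [make_calls("c0", [("chr1", 10050, 2, 2)])]
        rates, mask = metacell_methylation_rate(model, [0], calls)
        bin_of_tss = 10  # first downstream bin on + strand
        assert rates[bin_of_tss] == pytest.approx(0.5)
        assert not mask[bin_of_tss]

    def test_pooled_counts_not_mean_of_ratios(self, gene_plus):
        model = build_promoter_model(gene_plus)
        calls = [
            make_calls("c0", [("chr1", 10050, 3, 0)]),
            make_calls("c1", [("chr1", 10060, 0, 3)]),
        ]
        rates, mask = metacell_methylation_rate(model, [0, 1], calls)
        assert rates[10] == pytest.approx(0.5)  # (3+0)/(3+3)

    def test_empty_bin_masked(self, gene_plus):
        model = build_promoter_model(gene_plus)
        calls = [make_calls("c0", [("chr1", 10050, 1, 0)])]
        rates, mask = metacell_methylation_rate(model, [0], calls)
        assert mask.sum() == 19 and not mask[10]

    def test_empty_members_error(self, gene_plus):
        model = build_promoter_model(gene_plus)
        with pytest.raises(ValueError):
            metacell_methylation_rate(model, [], [])

    def test_minus_strand_bin_orientation(self):
        gene = make_gene(strand="-")  # tss0 = 10000
        model = build_promoter_model(gene)
        # position 9950 is genomically upstream of tss but DOWNSTREAM for "-"
        calls = [make_calls("c0", [("chr1", 9950, 1, 0)])]
        rates, mask = metacell_methylation_rate(model, [0], calls)
        assert not mask[10]  # first downstream bin


class TestMpd:
    def test_fully_methylated_is_zero(self, gene_plus):
        calls = make_calls("c", [("chr1", 10000, 5, 0)])
        assert mpd(gene_plus, calls) == 0.0

    def test_fully_unmethylated_is_one(self, gene_plus):
        calls = make_calls("c", [("chr1", 10000, 0, 5)])
        assert mpd(gene_plus, calls) == 1.0

    def test_complement_identity(self, gene_plus):
        recs = [("chr1", 10000, 3, 1)]
        calls = make_calls("c", recs)
        other = make_calls("c2", recs)
        m = compute_promoter_methylation_matrix([calls, other], [gene_plus])
        assert mpd(gene_plus, calls) == pytest.approx(0.25)
        assert mpd(gene_plus, calls) == pytest.approx(1 - m.values[0, 0])

    def test_no_calls_is_nan(self, gene_plus):
        calls = make_calls("c", [("chr2", 10, 1, 0)])
        assert np.isnan(mpd(gene_plus, calls))

    def test_matrix_imputes_with_cell_mean(self):
        genes = [make_gene("gA", tss=10001), make_gene("gB", tss=50001)]
        calls = [
            make_calls("c0", [("chr1", 10000, 1, 3)]),  # gA mpd=0.75, gB missing
            make_calls("c1", [("chr1", 10000, 1, 1), ("chr1", 50000, 0, 1)]),
        ]
        m = mpd_matrix(genes, calls)
        assert m[1, 0] == pytest.approx(0.75)  # imputed with c0's mean


@pytest.fixture(scope="module")
def assembled(tiny_dataset):
    from methactivity.metacell import (
        build_metacells,
        compute_pca_embedding,
    )

    ds = tiny_dataset
    pm = compute_promoter_methylation_matrix(ds.calls, ds.genome.tss)
    emb = compute_pca_embedding(pm, d=5)
    mc = build_metacells(emb, k=4, cell_ids=pm.cells)
    models = [build_promoter_model(g) for g in ds.genome.tss]
    tensor = assemble_features(models, mc, ds.calls, ds.genome.sequences)
    return ds, mc, models, tensor


class TestAssembleFeatures:
    def test_forty_columns(self, assembled):
        _, _, _, tensor = assembled
        assert tensor.X.shape[1] == 40
        assert len(tensor.feature_names) == 40

    def test_row_per_pair(self, assembled):
        ds, _, _, tensor = assembled
        assert len(tensor) == len(ds.genome.tss) * len(ds.calls)

    def test_cpg_block_cell_independent(self, assembled):
        _, _, _, tensor = assembled
        for g in np.unique(tensor.pair_gene_idx)[:5]:
            rows = tensor.cpg_ratio[tensor.pair_gene_idx == g]
            assert np.allclose(rows, rows[0])

    def test_identical_membership_gives_identical_rates(self, assembled):
        ds, mc, models, tensor = assembled
        # force cells 0 and 1 to share one membership set and re-assemble
        shared = np.arange(mc.k)
        members = [shared.copy(), shared.copy()] + [
            np.arange(i, i + mc.k) for i in range(2, len(mc))
        ]
        forced = MetaCellMap(
            cell_ids=mc.cell_ids,
            members=[m % len(mc) if m.max() >= len(mc) else m for m in members],
            k=mc.k,
            include_self=False,
        )
        t2 = assemble_features(models, forced, ds.calls, ds.genome.sequences)
        r0 = t2.meth_rate[t2.pair_cell_idx == 0]
        r1 = t2.meth_rate[t2.pair_cell_idx == 1]
        np.testing.assert_allclose(r0, r1)

    def test_count_conservation(self, assembled):
        """Call-count-weighted mean of non-empty bin rates == pooled promoter rate."""
        ds, mc, models, tensor = assembled
        meth_c, total_c = bin_call_counts(models, ds.calls)
        for cell_row in range(0, len(mc), 7):
            member_idx = mc.members[cell_row]
            pooled_m = meth_c[member_idx].sum(axis=0)  # (genes, bins)
            pooled_t = total_c[member_idx].sum(axis=0)
            for g in range(0, len(models), 5):
                tot = pooled_t[g].sum()
                if tot == 0:
                    continue
                rows = (tensor.pair_gene_idx == g) & (tensor.pair_cell_idx == cell_row)
                rates = tensor.meth_rate[rows][0]
                mask = tensor.meth_mask[rows][0]
                weighted = np.sum(rates[~mask] * pooled_t[g][~mask]) / tot
                assert weighted == pytest.approx(pooled_m[g].sum() / tot, abs=1e-12)

    def test_unknown_ids_rejected(self, assembled):
        ds, mc, models, _ = assembled
        with pytest.raises(KeyError):
            assemble_features(
                models, mc, ds.calls, ds.genome.sequences, gene_subset=["nope"]
            )
        with pytest.raises(KeyError):
            assemble_features(
                models, mc, ds.calls, ds.genome.sequences, cell_subset=["nope"]
            )

    def test_tsv_serialization(self, assembled, tmp_path):
        _, _, _, tensor = assembled
        tensor.to_tsv(tmp_path / "features.tsv", include_mask=True)
        header = (tmp_path / "features.tsv").read_text().splitlines()[0].split("\t")
        assert header[:2] == ["gene_id", "cell_id"]
        assert len(header) == 2 + 40 + 20
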