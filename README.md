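# methactivity

Predict per-cell gene activity from sparse single-cell DNA methylome data.

Single-cell bisulfite data covers only a few percent of CpG sites per cell,
and the relationship between promoter methylation and expression is gene
dependent (both negative and positive couplings occur), so no fixed summary
statistic of promoter methylation makes a good gene-activity proxy.
`methactivity` instead learns the mapping from promoter features to
expression on joint methylome + transcriptome (multi-omics) data and applies
it to methylome-only cells:

1. **Meta-cells** — each cell is pooled with its *k* = 20 nearest neighbors
   in a 10-dimensional PCA embedding of promoter mean methylation (top 5000
   most variable promoters), de-sparsifying per-bin methylation estimates
   while keeping one meta-cell per cell.
2. **Features** — the ±5 kb promoter window around each TSS is tiled into
   20 bins of 500 bp (ordered 5′→3′ relative to the gene). Per bin:
   CpG-dinucleotide frequency from the genome sequence (gene-dependent,
   cell-independent) and the pooled meta-cell CpG methylation rate (gene- and
   cell-dependent) — 40 features per (gene, cell) pair.
3. **Ensemble regression** — a random forest (500 trees, 80% subsampling),
   an elastic net (mix 0.5, penalty from 10-fold internal CV), and a small
   1-D CNN (50 filters, kernel 5, max-pool 4, dropout 0.2, early stopping
   with patience 10; implemented in numpy) are trained on up to 100,000
   subsampled (gene, cell) pairs against normalized expression
   (log2(CPM+1) scaled by the dataset maximum). The default combination rule
   is the unweighted average; weighted (by internal-CV correlation or
   accuracy) and stacking rules are available.
4. **Output** — a genes × cells activity matrix on the normalized-expression
   scale, plus the mean-promoter-demethylation (MPD) baseline, permutation
   feature importance, and an evaluation harness (global / per-cell Spearman,
   median squared error, internal 5-fold and external cross-dataset CV,
   CpG-context stratification).

A synthetic multi-omics generator (`methactivity.synthetic_data`) emits
desk-scale datasets — genome FASTA, TSS/island annotations, sparse per-cell
Bismark COV files, count matrices, and ground truth — with planted cell
types, mixed-sign methylation–expression couplings, and CpG-density context
classes, so the whole pipeline is testable without external downloads.

## CLI

```sh
# synthetic dataset with ground truth
methactivity simulate --out data/sim --n-genes 300 --n-cells 300 --seed 1

# train on matched methylome + expression
methactivity train \
    --manifest data/sim/manifest.tsv --annotation data/sim/genes.bed \
    --genome data/sim/genome.fa --expression data/sim/counts.tsv \
    --seed 1 --out models/run1

# predict gene activity for (new) methylome-only cells
methactivity predict \
    --manifest data/sim/manifest.tsv --annotation data/sim/genes.bed \
    --genome data/sim/genome.fa --bundle models/run1 \
    --out results/activity.tsv --with-mpd results/mpd.tsv

# evaluate against observed expression (with CpG-context stratification)
methactivity evaluate --pred results/activity.tsv --obs data/sim/counts.tsv \
    --normalize-obs --islands data/sim/islands.bed \
    --annotation data/sim/genes.bed --out results/report.json

# random-forest permutation feature importance
methactivity importance --manifest data/sim/manifest.tsv \
    --annotation data/sim/genes.bed --genome data/sim/genome.fa \
    --expression data/sim/counts.tsv --out results/importance.tsv
```

Exit codes: 0 success, 2 usage error, 3 data-validation error. All tunables
(flank, bin size, k, PCA dimensions, learner hyperparameters, ensemble rule,
seed) live in a JSON/YAML run config (`--config`); one seed deterministically
fans out to every stage.

## Layout

- `src/methactivity/io_formats.py` — Bismark COV, GTF/BED6, FASTA,
  TSV/MTX expression, activity-matrix I/O, expression normalization
- `src/methactivity/metacell.py` — promoter methylation matrix, variable
  promoter selection, PCA, exact k-NN meta-cells, adjacency difference
- `src/methactivity/features.py` — promoter binning, CpG frequency,
  pooled meta-cell methylation rates, MPD baseline, feature assembly
- `src/methactivity/predictors.py` / `cnn.py` — component learners,
  ensemble rules, permutation importance, model bundles
- `src/methactivity/evaluation.py` — metrics, CV harness, CpG-context
  classification
- `src/methactivity/synthetic_data.py` — simulator + ground truth
- `src/methactivity/cli.py`, `pipeline.py`, `config.py` — orchestration
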