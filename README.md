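# chromacal

Quantitative comparison of chromatin states between two cellular conditions —
spike-in calibrated CUT&RUN quantification with differential-region
classification, histone-PTM relative abundances from mass-spectrometry
peptidoform tables, chromatin-proteome (LFQ) differential screening, and
integration of modifier-protein and histone-mark fold changes over a
writer/eraser network. Built for epigenomics analysts comparing, e.g., naive
vs primed pluripotent stem cells, where *global* chromatin differences are
exactly what standard library-size normalisation destroys.

## The problem and the statistic at its core

Sequencing-based chromatin maps are normally normalised to equal read
totals, which forces every sample to the same genome-wide signal and makes a
true global difference (one condition's chromatin uniformly "coated" with a
mark, such as H3K27me3) invisible. Calibrated CUT&RUN adds a fixed number of
exogenous spike-in cells (e.g. *Drosophila*) per sample, so spike-in reads
measure sequencing effort per cell. With `spikein_s` the unique,
MAPQ-filtered spike-in fragment count of sample *s*, the calibration factor

&nbsp;&nbsp;&nbsp;&nbsp;`factor_s = min_t(spikein_t) / spikein_s`

downsamples each sample's target-genome fragments (uniformly at random,
exactly `round(factor_s · N_s)` kept) to a common per-cell depth. Calibrated
counts then support:

- genome-wide quantification: 1-kb bin counts, log2 KDE curves, FRiP
  (percentage of fragment midpoints in peaks), repeat-class fractions,
  replicate Pearson correlation on log(1+count);
- peak calling: top-1% of contiguous positive-coverage blocks by area,
  merged (gap < 300 bp), intersected across replicates, combined across
  conditions, exclusion-list filtered;
- differential regions: per-region negative-binomial Wald test on calibrated
  midpoint counts (pooled method-of-moments dispersion, size factors fixed
  at 1), BH-corrected, yielding the three-way classification
  {cond1-enriched, cond2-enriched, common} plus promoter/nearest-gene
  annotation (±3 kb promoter window, 10-kb marked-gene cutoff).

Two tabular analyses complement the sequencing arm: per-residue histone-PTM
relative abundances (each modification state as a percentage of all states
at its residue, summing to 100) with Student-t/BH differential testing, and
a Perseus-style LFQ screen (flag filtering, ≥3 valid values in a group,
down-shifted normal imputation, t-test with a fold-change gate). A sign rule
over a curated writer/eraser edge table then classifies each modifier–mark
pair as concordant, discordant or neutral — discordant edges flag marks
whose change cannot be explained by their enzymes' chromatin abundance.

## Worked example

Simulate a two-condition experiment with planted enriched regions, calibrate
it, and call peaks — everything below is actual output:

```sh
$ chromacal sim-cutrun --seed 7 --out sim --n-cells 30000 \
      --genome-size 5000000 --n-regions 15
wrote 4 samples to sim

$ chromacal calibrate --samples sim/manifest.tsv \
      --genome-map sim/genome_map.tsv --seed 1 --out cal
  sample  spikein_count   factor
cond1_r1          11744 0.986887
cond1_r2          11590 1.000000
cond2_r1          11624 0.997075
cond2_r2          11648 0.995021

$ chromacal track --fragments cal/cond1_r1.calibrated.bed \
      --genome-map sim/genome_map.tsv --out c1r1.bedgraph
wrote 115331 intervals to c1r1.bedgraph

$ chromacal callpeaks --track c1r1.bedgraph --retain 0.003 --out peaks.bed
retained 30 peaks

$ chromacal frip --fragments cal/cond1_r1.calibrated.bed \
      --genome-map sim/genome_map.tsv --peaks peaks.bed
10.41
```

The calibration table shows `cond1_r2` had the fewest spike-in fragments
(11,590) and anchors the group at factor 1; every other sample is
downsampled by its ratio to that minimum. All four samples were simulated at
equal depth and spike-in rate, so factors sit near 1. Of the coverage
blocks, the top 0.3% by area give 30 peaks — the 15 planted regions plus
background blocks — and 10.41% of calibrated fragments fall inside them
(FRiP). By default `sim-cutrun` gives condition 1 twice the global coating
of condition 2; the calibrated fragment files in `cal/` preserve that 2:1
ratio, which library-size normalisation would flatten to 1:1.

The histone-PTM arm works the same way from TSV tables:

```sh
$ chromacal sim-hptm --seed 7 --out hsim --cv 0.1
wrote peptidoform table (22 rows) to hsim

$ chromacal hptm --table hsim/peptidoforms.tsv --design hsim/design.tsv \
      --out hptm.tsv
13 significant states
```

`hptm.tsv` carries, per histone:residue:state, the per-sample relative
abundances (summing to 100 per residue), the log2 fold change between
conditions, and BH-adjusted q-values — e.g. H3K27un at mean 9.8% in
condition 1 vs 26.0% in condition 2 (log2FC −1.40, p = 3.1e−10), reflecting
the planted shift toward higher K27 methylation in condition 1.

Integration of protein and mark fold changes:

```sh
$ chromacal integrate --protein-fc protein_fc.tsv --mark-fc mark_fc.tsv \
      --out scored.tsv
{"missing": 36, "discordant": 2, "neutral": 1, "concordant": 1}
```

With DOT1L up (+1.5) and H3K79me2 up (+1.2) the writes edge is concordant;
with the erasers KDM6A/B up (+0.8/+0.9) while their substrate H3K27me3 is
also up (+2.2), both erases edges are discordant — the abundance/activity
decoupling signature. Edges whose modifier was not measured are reported as
missing.

See `docs/methods.md` for the models, defaults and their rationale.

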