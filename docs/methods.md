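# Methods

`chromacal` quantifies chromatin differences between two cellular states from
four data modalities and validates every stage against synthetic data with
known ground truth. This note records the models, the defaults and why, the
numerical choices, and what the synthetic validation does and does not show.

## Spike-in calibration of CUT&RUN fragment sets

**Model.** Each sample is a set of mapped fragments from two genomes: the
target genome under study and an exogenous spike-in genome added at a
constant amount per cell. Because the spike-in material scales with cell
number and not with the biology of the target chromatin, the spike-in
fragment count is a per-sample unit of sequencing effort per cell. The
calibration factor for sample *s* is

    factor_s = min_t(spikein_t) / spikein_s

so the sample with the fewest spike-in fragments anchors the group at 1 and
every other sample is randomly downsampled to the same spike-in-implied
depth. After calibration, target fragment counts are comparable across
samples on a per-cell scale, so a genuine global difference in chromatin
coating between conditions survives — whereas normalising to equal target
library sizes erases it by construction. This is the property the package is
built around, and it is asserted directly: a simulated 2x coating difference
confounded with depth scales {0.5, 2} is recovered to within 10% by
calibration and collapses to 1.0 under library-size normalisation.

**Choices.**
- MAPQ filter is strictly greater than 20, matching standard practice.
- "Unique" spike-in fragments are deduplicated by exact
  (chrom, start, end, genome) coordinates after the MAPQ filter; whether
  counting should dedupe at all is genuinely ambiguous in the field, so
  `dedupe` is a flag (default on).
- Downsampling keeps exactly `round(factor x N)` fragments (round half to
  even for cross-platform determinism), sampled uniformly without
  replacement with a seeded generator — not Bernoulli thinning — so output
  cardinality is assertable exactly.
- Calibration groups are whatever sample set is passed in one call; samples
  that should not share an anchor (e.g. different antibodies, or IgG
  controls) belong in separate calls.

## Signal quantification

Fragments are assigned to intervals by their **midpoint** everywhere (bins,
peaks, repeat classes, region counts). Midpoint assignment is unambiguous
and never double-counts; the alternative any-overlap rule inflates counts
near interval edges. Coordinates are 0-based half-open throughout, so a
midpoint landing exactly on a bin boundary belongs to the right-hand bin.

- **1-kb bins**: each contig is tiled with fixed-width bins; the last,
  possibly short, bin is kept so that total counts are conserved exactly.
- **log2 density**: a Gaussian KDE with Silverman bandwidth over the log2 of
  nonzero bin counts, evaluated on a 512-point grid spanning the data range
  ±4 bandwidths (so the curve integrates to 1 within 1%). Zero bins are
  excluded by default because log2(0) is undefined; a pseudocount policy is
  available and recorded in the call.
- **Replicate correlation**: Pearson r of log(1 + count) across identical
  bin frames.
- **FRiP**: the percentage of fragment midpoints inside the (coalesced) peak
  set — a focality measure. A condition with high genome-wide coating but
  weak peaks shows high total signal and low FRiP; a condition with low
  coating and strong peaks shows the reverse. The synthetic end-to-end test
  asserts this signature directionally.
- **Coverage tracks**: exact base-resolution depth from a sweep over
  fragment endpoints, emitted as maximal constant-value bedGraph intervals;
  `sum(value x width)` equals the scaled total fragment length exactly.

## Peak calling and differential regions

**Sparse-enrichment caller.** Candidate peaks are maximal contiguous runs of
positive coverage in the calibrated track; each block is scored by its area
under the coverage curve, and blocks scoring at or above the
`1 - retain_fraction` quantile (default top 1%) are retained, ties included.
Block area rather than block maximum is used because broad domains (the
typical shape of repressive marks) are area-dominated. IgG tracks are
carried for display and QC but are not subtracted — retention is purely by
the numeric top fraction.

**Peak-set algebra.** Peaks closer than 300 bp (strict) are merged
transitively with scores summed; replicate peak sets are intersected
(≥ 1 bp overlap, first set's coordinates kept); per-condition sets are
concatenated and coalesced into a disjoint combined list ("de-duplication"
interpreted as interval union, since downstream per-region counting needs
disjoint regions); regions touching an exclusion-list interval are removed
entirely. All four operations are tested against independent O(n²)
brute-force oracles on hundreds of random instances.

**Differential test.** Per region, calibrated midpoint counts per sample
feed a negative-binomial Wald test with size factors fixed at 1 —
calibration has already equalised depth, and re-estimating size factors
would partially undo it. With two replicates per condition a per-region
dispersion is not estimable, so a single dispersion is pooled across all
(region, condition) cells by the method of moments
(`alpha = sum(s² - m) / sum(m²)`, floored at 1e-8). The Wald statistic is
the log2 fold change of condition means (pseudocount 1) over its delta-method
standard error; p-values are BH-adjusted across regions, and a region is
classed toward the condition with the larger mean when q < 0.05, otherwise
"common". On planted truth (fold 4, two replicates per condition, ≥ 50
expected counts per region) ≥ 90% of regions receive their true class, and
permuting condition labels on null data keeps the q < 0.05 fraction at the
nominal rate. The engine is intentionally simpler than a full
shrinkage-based RNA-seq model; with thousands of regions and a common
dispersion the method-of-moments estimate is stable, but per-region
dispersion outliers (e.g. copy-number artifacts in real data) are not
modelled — the exclusion list is the mitigation.

**Annotation.** A region is a promoter region if it overlaps ±3 kb of any
TSS (half-open window); its marked gene is the nearest gene by TSS distance,
recorded only within 10 kb. TSS is `start` on the + strand and `end - 1` on
the − strand.

## Histone-PTM relative abundance

The relative abundance of state *m* at residue *r* in a sample is

    100 x sum(intensity of peptidoforms carrying r:m)
        / sum(intensity of peptidoforms covering r in any state)

so abundances sum to 100 per residue per sample (asserted to 1e-6). A
co-modified peptidoform contributes its full intensity to each residue it
annotates — the quantity is a per-residue marginal, not a joint
distribution. Relative abundances are invariant to any per-sample scaling,
so total-intensity normalisation (each sample scaled to the grand mean
total) matters only for raw-intensity displays; this invariance is tested.
Missed-cleavage peptides covering a residue twice are outside the synthetic
model and would need explicit handling on real data.

Differential marks use a two-sided equal-variance Student t-test per state
(Welch available via `equal_var=False`) on the percentage abundances, log2
fold changes with a pseudocount of 0.01 percentage points, and BH correction
across all states in the comparison. Cross-dataset comparison is OLS of one
dataset's per-state log2FCs on the other's over the shared-state
intersection, with the pointwise 95% confidence band of the mean response.

## Chromatin-proteome screening

Rows flagged reverse/contaminant/only-identified-by-site are dropped, then
rows need ≥ 3 valid values in at least one group. Missing values are imputed
column-wise from `Normal(mu - 1.8 sigma, (0.3 sigma)²)` of each sample's
observed values — the conventional defaults for detection-limit imputation;
the numbers are pinned here for reproducibility. Imputation never alters
observed values and is seeded. Differential proteins use a two-sided Student
t-test with a fold-change gate (p < 0.05 AND |log2FC| > 1); no
multiple-testing correction is applied by default, mirroring common
volcano-plot practice for this assay — a BH option exists (`adjust=True`)
but is off by default. The joint p-and-FC gate keeps the realised false-call
rate on null matrices below the nominal t-test level (checked against a
permutation oracle).

## Writer/eraser concordance

Each edge links a modifier protein to a mark it writes or erases. With one
fold change per node, a correlation is not definable, so concordance is a
sign rule with a neutrality band: edges where either |log2FC| < 0.5 are
neutral (0.5 matching the package's high-change convention); otherwise a
writes edge is concordant iff the mark and modifier fold changes share a
sign, an erases edge iff they oppose. Edges with an unmeasured endpoint are
carried as "missing". Discordant edges are the biologically interesting
output: a mark moving against its writer/eraser abundance implies regulation
of enzyme activity rather than abundance. The shipped edge table is a small
curated writer/eraser list; it is user-replaceable and makes no claim to
completeness.

## Synthetic data: what it emulates and what it does not

- **CUT&RUN generator**: Poisson totals, multinomial placement between a
  uniform background and planted regions (uniform midpoints inside a region
  give an exact inside/outside density ratio equal to the fold), fixed
  fragment length, constant per-cell spike-in rate, per-sample depth scales,
  optional IgG mode (background only). Defaults: 50,000 target
  cell-equivalents, 150-bp fragments, two replicates per condition. It does
  not model PCR duplicates, fragment-size mixtures, mappability or GC bias,
  or read-level sequences — so passing tests demonstrate the statistics of
  the pipeline, not robustness to alignment artifacts.
- **Peptidoform generator**: mean-preserving lognormal intensities around
  `total x proportion` with a chosen CV; single-residue peptidoforms only
  (co-modification is covered by a hand-built fixture in the tests).
- **Proteome generator**: per-protein baselines Normal(25, 2) on the log2
  scale, replicate noise with SD `cv` (the parameter is the log2-scale SD),
  a planted subset shifted by a fixed log2FC in the first group, values
  censored below a global intensity quantile (missing-not-at-random), and a
  small fraction of appended flagged decoy rows.

All generators are byte-identical under a fixed seed.

## Problem sizes used in the shipped validation

The test suite and the acceptance script run entirely on synthetic data at
desk scale, chosen to keep every stage's statistical assertion well-powered:
calibration recovery on a 10-Mb genome with ~1.5 x 10⁵ fragments; peak
recovery with 20 planted fold-5 regions among 2 x 10⁵ fragments;
differential classification with 30 planted regions, fold 4, two replicates
per condition and ≥ 50 expected counts per region; hPTM recovery at
n = 6 + 6 samples, CV 10%; proteome recovery at 1,000 proteins, triplicates,
10% planted differentials. The full suite completes in well under a minute
per stage.

## Known limitations

- The NB dispersion is global; strong per-region overdispersion is not
  shrunk region-wise.
- The peak caller has no control-track mode; IgG is QC-only.
- The hPTM rollup assumes each peptidoform annotation names a residue at
  most once.
- Concordance is a sign rule on point estimates; it ignores uncertainty in
  the fold changes.
- bedGraph is the only track output (no binary bigWig).
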