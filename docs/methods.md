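# Methods

This note documents the models behind `dosagex`, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was open.

## FISH territory volumes

A nucleus image is a two-channel anisotropic voxel grid (DNA counterstain +
chromosome paint) with physical voxel size in µm (z, y, x). Masks are
"voxels strictly above an intensity threshold"; the threshold method is
per-nucleus Otsu by default (parameter-free and reproducible), with fixed
and fraction-of-max alternatives, and the threshold used is recorded on the
mask. The nucleus volume is the DAPI mask; the territory mask is derived
with its threshold estimated *within* the DAPI mask and is intersected with
the nucleus when the percentage is computed, so percent volume is always in
[0, 100]. Group summaries report mean, sample standard deviation (a single
nucleus reports sd 0) and n; group differences use the unpaired
equal-variance Student's t-test (the classical test, not Welch).

The generator plants an ellipsoidal nucleus (radii jittered ±8% per axis)
and a territory built as a spherical cap in physical coordinates: the k
nucleus voxels furthest along a random direction, with k = round(occupancy ×
nucleus voxels). The cap is connected and realizes the requested occupancy
exactly up to voxel discretization (< 0.1 percentage points at the default
radii); the truth table records the realized value per nucleus. Intensities
are background 100, in-signal 800 (signal-to-background 8) with additive
Gaussian noise sd 25 — at that separation the Otsu mask equals the planted
region, so pipeline error is dominated by discretization. Between-nucleus
biological spread is off by default (each scenario plants one true
occupancy per group) and available as `occupancy_sd` where group variance
matters (e.g. power checks of the t-test). Real FISH features *not*
emulated: partial-volume voxels, chromatic shift, optical PSF anisotropy
beyond the voxel grid, and segmentation errors from touching nuclei —
passing recovery tests therefore demonstrates correctness of the
measurement chain, not robustness to those artifacts.

## Probe distances

Spots are isotropic 3D Gaussians (σ = 0.12 µm) rendered at voxel centers on
an anisotropic grid, two channels, one or two homolog pairs per nucleus
(two in tetraploid hypodermal nuclei). Homolog pair centers are kept at
least separation + 1.5 µm apart so the pairing is unambiguous, and spots
are re-drawn if they fall within one voxel of the stack boundary. Detection
is 26-connected components above a fraction-of-max threshold (components
< 2 voxels discarded), with intensity-weighted centroids converted to µm
(voxel centers at (i + 0.5) × voxel size). Channel-to-channel pairing is a
minimum-total-distance assignment (`linear_sum_assignment`); on
well-separated pairs this coincides with repeatedly taking the closest
pair, and unlike the greedy rule it always matches the exhaustive
minimum-weight matching that the test suite uses as oracle. Localization
error at the default noise is ≈ 0.01 µm, far below the 0.05 µm recovery
tolerance used for the planted 1.06 / 0.67 µm medians.

## ChIP-seq chain

Reads are placed per chromosome with expected counts ∝ copy number × length
× per-copy density, multiplied by `island_fold` inside planted enrichment
islands; input reads follow copy number × length only. Islands are placed
on a jittered grid (exact count = round(density × Mb), never overlapping).
Coverage is the count of read midpoints per bin (default 50 bp, 0-based
half-open, short last bin). Normalization: XX — every bin divided by the
genome-wide median bin coverage, mitochondrial bins excluded from the
median; XO — autosomal bins divided by the autosomal median and X bins by
half that median, because the single X contributes half the reads of a
diploid autosome. The same rule is applied to ChIP and input, and the
normalized input is subtracted bin-wise; the order (normalize each, then
subtract) is recorded in the track metadata together with the medians used.

"Presumed background" for the z-score is, by default, the robust
median/MAD estimate over all non-mitochondrial bins (insensitive to the
minority of enriched bins); an alternative estimates σ from the mirrored
distribution of non-positive enrichment values with µ fixed at 0. The
broad-peak caller takes maximal runs of bins with z ≥ z_min, merges runs
separated by < merge_gap bp, and drops peaks shorter than min_len bp.
Defaults: z_min 3.0, merge_gap 500 bp, min_len 200 bp. z_min 3.0 was chosen
analytically: at the packaged coverage (~10 reads/bin background) the
Skellam tail of the input-subtracted background at z = 2.5 produces enough
above-threshold singleton bins that pairs within the merge gap form
spurious ≥ 200 bp peaks at a non-negligible fraction of the planted island
density; at z = 3.0 that false-pair rate is < 2% of the planted density
while 8-fold islands sit at z ≈ 13–15 and are never missed. All three
parameters are exposed.

Read-fraction ratios divide each chromosome's read fraction by its
*copy-weighted* genome fraction (copies × length over the copy-weighted
total, mito excluded everywhere); only copy weighting makes a uniform
per-copy XO simulation come out at 1.0 for the single X. Peak annotation
paints a per-bp category raster with precedence promoter > exon > intron >
intergenic (promoter = 1 kb upstream of the TSS on the gene's strand,
configurable) and assigns peak bp by overlap; genome category fractions are
reported alongside.

The packaged island-recovery scenario uses a reduced genome — a 15 Mb X
plus one 10 Mb autosome at ~0.3 reads/bp for ChIP and input (≈ 7.5M reads
each) — which preserves the per-bin statistics of a full-genome run while
keeping a full normalize → z-score → call → density chain around two
seconds.

## Metagene profiles

Gene bodies are resampled to a fixed number of bins (default 100) with 1 kb
flanks in 20 fixed-width bins; per-segment values are length-weighted means
of the underlying binned signal, computed exactly from the cumulative
integral of the piecewise-constant track (the integral is piecewise linear,
so `np.interp` evaluates it without materializing per-bp arrays).
Minus-strand genes are reversed so the TSS is always on the left; genes
shorter than one bp per body bin are skipped and logged; flank segments
clipped by a chromosome edge contribute NaN and are excluded from the
stratum mean. Genes are averaged unweighted within a stratum; overlapping
genes both contribute. Expression-quartile stratification computes quartile
boundaries within each chromosome set, with boundary ties assigned to the
lower quartile. The TSS-upstream score is the mean z over 500 bp upstream
of the TSS, strand-aware and flagged when clipped.

## Expression statistics

RPKM = count × 10⁹ / (exonic length × library size); library sizes default
to column sums. The X:A ratio is median X over median autosomal mean RPKM
among genes with mean RPKM > 1. Contrasts scale each replicate to the
geometric-mean library size, average replicates per condition, and take
log2((A + pc)/(B + pc)) with pseudocount 1 on the normalized-count scale —
at the packaged depths (median ≈ 1000 counts) the pseudocount shrinkage of
a 0.447 median is < 0.003, whereas a 1-RPKM-equivalent pseudocount would
shrink it by ~0.017. Shift tests are one-sided Wilcoxon rank-sum, X versus
pooled autosomes and X versus each autosome: exact enumeration over all
label assignments when both groups have ≤ 8 values (correct under ties),
normal approximation with tie and continuity corrections otherwise.
Quadrant classification requires |log2 ratio| > 0.1 on both axes, with all
genes of a class (classified + unclassified) as denominator; top-percentile
sets rank X genes by descending reference ratio with gene-id tie-breaks.

### Count generator

Baseline means follow a log-normal expression distribution (median count
configurable, log2 sd 1.5, deviates clipped at ±6 log2) sampled on a
stratified per-chromosome quantile grid and shuffled along the chromosome.
Stratification preserves the marginal distribution while pinning each
chromosome's true median to the distribution median, so planted median
ratios are not drowned by baseline-median sampling noise (iid sampling
would put 2–4% sampling error on a median over ~3000 genes — larger than
the skews being planted). X means are multiplied by the configured X:A
ratio. Counts are NB(µ, µ + αµ²) with per-replicate library factors jittered
±10%.

Condition effects are per-gene log2 shifts: normal distributions with
configurable medians/sds for X and autosomes, or a joint two-condition
quadrant scheme planting sign patterns with |log2| magnitudes uniform on
[0.25, 0.8] (clear of the ±0.1 classification threshold relative to the
measurement noise). Because a median log2 ratio is only identifiable up to
the library-normalization constant, the generator balances total expected
transcriptome mass against the control by stretching the autosomal effect
tails asymmetrically around the configured autosomal median (the inner
quartile band — and with it the sample median — is left untouched; X
effects are never modified). This models compensatory redistribution of
transcription and makes the planted medians the quantities the total-count
normalization actually measures. With a tiny gene set or an extreme X mass
share the band constraint can be infeasible; the generator then falls back
to whole-tail stretching with a warning.

Packaged depths/dispersions were set by variance analysis so the sampling
error of the recovered medians sits well inside the recovery tolerances:
X:A scenario α = 0.005 at median count 2000 (X:A median sd ≈ 0.006 vs
tolerance 0.02); contrast scenarios α = 0.01 at median count 1000 (X median
sd ≈ 0.003–0.006 vs tolerances 0.01 / 0.02); quadrant scenario α = 0.002 at
median count 2000 (per-gene ratio sd ≈ 0.06, so quadrant leakage across the
±0.1 threshold is < 1%). Three replicates per condition, ~3200 X and
~14800 autosomal genes (180 genes/Mb on the packaged karyotype). What the
generator does not emulate: GC/length biases, isoform structure, batch
effects, outlier genes with condition-specific dispersion, and germline
contamination — recovery results certify the statistics, not robustness to
those.

## Scenario layer

Scenario configs are pydantic-validated (unknown keys rejected) before any
computation; `run_scenario` is deterministic given the config seed, and the
report's checksum covers every value and table. The packaged scenarios
encode the study's printed effect sizes: territory occupancies 15.74 / 9.87
/ 9.41 / 17.11%, probe separations 1.06 / 0.67 µm, an XX ChIP read-set with
the X per-copy density solved analytically for an expected read-fraction
ratio of 0.33 and an XO set at exact per-copy parity, X islands at 52/Mb
(autosomes 95/Mb), X:A 0.88, X contrast medians +0.447 (sd 0.25, autosomes
−0.080) and −0.021 (sd 0.05, autosomes −0.008), a 24% concordant X
quadrant, and brood survival 98% (n = 2090) vs 54% (n = 1071). The default
karyotype uses WS235-like chromosome lengths, giving an X length fraction
of ≈ 17.7% and an XO copy-weighted X fraction of ≈ 9.7%.

## Known limitations

* The peak caller is a thresholding scan, not a Poisson model: no duplicate
  filtering, local lambda, or multi-replicate handling; it is calibrated on
  planted-island truth.
* Differential expression is a ratio analysis, not an inference engine: no
  per-gene significance, shrinkage, or multiple-testing control.
* The FISH segmentation assumes one nucleus per stack and binary
  territories; percent-volume accuracy on real images depends on threshold
  choices this package deliberately makes explicit and records.
* The XO copy-weighted genome fraction treats the whole genome as exactly
  diploid-but-X; aneuploidies or partial duplications are out of scope.
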