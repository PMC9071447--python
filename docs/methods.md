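# Methods

`axisislands` analyzes where meiotic chromosome-axis proteins (Red1,
Hop1, Rec8-cohesin in *S. cerevisiae*) are enriched along the genome.
Its core procedure segments a ChIP-seq fold-enrichment track into
**islands** (contiguous over-enriched regions) and **deserts**
(everything else), then characterizes the two region classes
genomically and statistically. This note documents the models,
parameters, and numerical choices.

## Segmentation model

The genome is tiled with fixed, non-overlapping bins (default
`bin_size = 5000` bp; the terminal bin of each chromosome may be short
and is scored by the mean over its available base pairs). Each bin's
score is the arithmetic mean of the per-bp fold-enrichment signal.
A bin is *enriched* iff

    score >= k * SD,

where SD is the **population** standard deviation of all bin scores
genome-wide and `k = 1.75` by default. Maximal runs of enriched bins
within one chromosome become islands; runs never join across
chromosome boundaries; the remainder forms deserts. The resulting
`RegionPartition` is validated on construction: regions tile every
chromosome exactly, and adjacent regions alternate labels.

Choices worth flagging:

* The threshold has **no mean offset** by default. This matches how the
  rule behaves on a fold-enrichment track, whose dynamic range starts
  near zero: deserts sit below 1, so `1.75 * SD` lands between the two
  classes. An alternative mode `threshold_mode="mean_plus_sd"` is
  provided for tracks whose values float on a large common offset
  (see "Known limitations").
* SD is computed over bin scores, not per-bp values — bins are the unit
  of classification — and short terminal bins participate like any bin.
* Ties at the threshold count as enriched; a single enriched bin is an
  island (no minimum size); constant scores degenerate to one island
  per chromosome and emit a warning.
* Features (hotspots, anchors, bins) are assigned to regions by the
  region containing `floor((start + end) / 2)`; a feature straddling a
  boundary therefore gets exactly one label.

## Region and group statistics

Per-region statistics are means of per-bp signal (computed from
cumulative sums, exact to float addition), feature counts, and features
per kb; group (island vs desert) summaries are medians and quartiles.
Empty groups are flagged undefined rather than reported as zero.

Two-group comparisons offer the Mann-Whitney U test (two-sided) and
Welch's unequal-variance t-test. The Mann-Whitney p-value is computed
by **exact enumeration of all group assignments** when `n1 + n2 <= 12`
— ties are handled by recomputing midranks on the pooled sample, and
the null distribution of U is symmetric about `n1*n2/2`, so the
two-sided p is the probability of a U at least as extreme — and by the
normal approximation with tie correction otherwise. Degenerate inputs
(a single distinct value overall) return p = 1 with a warning.

## Profiles and bootstrap confidence bands

`anchor_matrix` extracts `[pos - flank, pos + flank)` windows of per-bp
signal around anchors (axis sites, hotspot midpoints, ATGs), reversing
minus-strand rows so columns read 5'→3'. Windows running off a
chromosome end are dropped and counted, keeping every column at the
same sample size. `genescaled_matrix` is the length-scaled metagene
variant: gene bodies are rescaled to a fixed number of equal
sub-intervals (scored by mean), flanks stay in real bp.

Mean profiles carry a percentile bootstrap confidence band: rows
(anchors) are resampled with replacement `n_boot = 1000` times and the
band at each column is the (2.5%, 97.5%) percentile interval of the
resampled column means, clipped to contain the sample mean (with small
`n_boot` a raw percentile interval can exclude the point estimate).
The resampling unit is the anchor, so between-locus variability drives
the interval width. Percentile intervals slightly undercover at small
row counts (empirically ~93–95% at n = 25); BCa-style corrections are
out of scope.

## Coding-density logistic predictor

Each 5-kb bin gets a coding density x (fraction of bp covered by the
union of gene intervals — overlapping genes counted once) and a label y
from the partition. The model

    P(island | x) = 1 / (1 + exp(-(b0 + b1 * x)))

is fit by IRLS (Newton steps on the log-likelihood), converging when
the log-likelihood change drops below `tol = 1e-8`. Under perfect
separation the MLE does not exist; a saturated likelihood is detected
and reported as `converged = False` with coefficients capped at the
last iterate (an optional ridge term, default 0, regularizes if
wanted). The slope's significance is a Wald test from the inverse
observed information. The train/test split is 80/20, stratified by
label by default, deterministic given a seed. Evaluation reports
accuracy at a 0.5 probability cutoff (ties predicted as island), the
ROC over all distinct scores, and the trapezoidal AUC, which equals the
pair-concordance statistic with ties counting one half.

## Synthetic data generator

The generator plants a known island/desert structure so every pipeline
stage can be tested against ground truth.

* **Genome layout.** Chromosomes alternate island and desert blocks
  with exponential lengths; the island-block mean (default 20 kb, with
  a 5 kb floor) and island fraction (default 0.4) set the desert-block
  mean. Genes are placed left-to-right inside blocks and never cross a
  block boundary. Gene lengths are log-normal parameterized by median
  (islands 1433 bp, deserts 1218 bp; log-SD 0.55), intergenic gaps
  log-normal with medians per (region, pair class): islands
  convergent/tandem/divergent 187/315/326 bp, deserts 242/439/605 bp
  (log-SD 0.6). Strands are i.i.d. A gene drawn for a block it no
  longer fits in is carried to the next block of the same label;
  discarding it would length-bias the realized distribution, since the
  draws that fail to fit are the long ones.
* **Axis track.** Expected signal = region baseline (island 1.5,
  desert 1.0 — free parameters; the real island/desert fold-ratio is
  not printed anywhere) + Gaussian peaks (sigma 200 bp, amplitude 1.0)
  at every gene 3' end, multiplied by i.i.d. gamma noise with mean 1
  and CV 0.3. The two components mimic the two recruitment pathways:
  a broad island-level elevation (Hop1-dependent) and gene-end peaks
  (cohesin-dependent).
* **Expression.** Log-normal per gene with desert mean = island mean ×
  1.161. The log-SD default is 0.6 so that, at n ≈ 5000 genes, the
  sampling band of the desert/island mean ratio is about ±5% — the
  scale at which the configured uplift is a detectable but noisy
  effect, as in the data being emulated.
* **Nucleosomes.** An MNase-like track adds, along each gene from its
  ATG, a cosine train of period 165 bp whose amplitude decays per
  nucleosome by a region-specific factor (island 0.92, desert 0.75):
  islands keep ordered arrays longer.

All generators are pure functions of (params, seed).

What the generator does **not** emulate: mappability artifacts, copy
number (rDNA, Ty elements), centromere/telomere effects, replication
timing, read-level noise, and — importantly — the near-zero desert
background of a real fold-enrichment track (see below). Passing
recovery tests therefore show the pipeline machinery is correct under
the planted model, not that the thresholds are tuned for any
particular real dataset.

## Known limitations

* **The k·SD rule needs strong contrast.** With no mean offset, the
  threshold `1.75 * SD` can only separate the classes if typical
  non-enriched scores are *below* it. For a two-level mixture with
  desert level μ_d, contrast Δ and island fraction f, the bin-score SD
  is at most `sqrt(f(1-f)) * Δ` plus noise, so separation requires
  roughly `μ_d < 0.875 * Δ * sqrt(f(1-f))` — a contrast ratio above ~3
  even at f = 0.5. Real fold-enrichment tracks satisfy this because
  deserts sit well below 1 while islands are strongly enriched; the
  generator's default baselines (1.5 vs 1.0) deliberately do not, and
  segmentation of the default synthetic track collapses to one island
  per chromosome (bin-level Jaccard ≈ island fraction ≈ 0.4). The
  planted-recovery acceptance test documents this failure honestly
  rather than hiding it; the `mean_plus_sd` mode with a smaller k
  segments such offset-dominated tracks correctly and is what the
  end-to-end pipeline tests use.
* Sub-bin resolution: island boundaries are quantized to the bin grid;
  bins straddling a true boundary dilute region contrasts (this is
  visible as a gap between the per-region coding-density means and
  their bin-level separability).
* The exact Mann-Whitney enumerates `C(n1+n2, n1)` assignments and is
  capped at `n1 + n2 <= 12` by default.
* Wiggle/bedGraph reading materializes dense per-bp arrays (8 bytes/bp
  per track); a 12 Mb yeast genome costs ~100 MB per track, which is
  the intended scale.

## Problem sizes in the test suite

Statistical checks run at fixed seeds with sizes chosen to make the
assertions sharp: 200 random mini-genomes for segmentation-oracle
equivalence; full enumeration for all Mann-Whitney sizes up to
`n1 + n2 = 10`; 500 bootstrap-coverage matrices of 25 rows × 4 columns
at `n_boot = 1000`; 50 seeds × ~1 Mb genomes for planted-island
recovery; ~2000 genes (4 Mb) for generator-fidelity medians; 50 seeds
× ~4 Mb genomes for predictor recovery (small test sets make per-seed
AUC estimates unstable, so the bar is on the 50-seed mean).
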