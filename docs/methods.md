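# Methods

## The analysis model

MeDIP-seq enriches methylcytosine-bearing DNA fragments, so local read
density is a semiquantitative methylation signal whose resolution is set by
fragment size, not by individual cytosines. The pipeline therefore works at
bin resolution throughout: the genome is tiled into fixed-width bins
(default 200 bp), reads are counted into bins, and all downstream statistics
are functions of per-bin counts.

**Coverage rule.** A read increments every bin it overlaps by at least half
of its own length (`min_overlap_fraction = 0.5`, with `>=` at the boundary,
matching bedtools `-f` semantics). With 150 bp reads on 200 bp bins a read
lands in at most one bin except for an exact 50/50 straddle, which counts in
both. Coordinates are 0-based half-open everywhere; strand is ignored for
coverage (MeDIP is strand-agnostic); duplicate reads are retained
(deduplication is assumed upstream).

**Depth normalization.** Two modes: `subsample` (default) randomly downsizes
the larger read set without replacement to the smaller set's size, seeded;
`scale` returns the multiplicative factor smaller/larger. Normalization
precedes bin filtering.

**Diff/Sum.** `(KD − CT)/(KD + CT)` per bin, defined only where
`CT + KD >= 3` reads. GoM ⇔ positive, LoM ⇔ negative. The histogram uses
0.1-wide intervals on centers −1.0 … 1.0 (values assigned to the nearest
center). The "expected" no-net-change distribution mirrors the observed one
(mean of the ±b frequencies; mass-preserving, idempotent). The deviation
statistic is the maximum |CDF difference| of the two normalized histograms
over the ordered bins; its p-value uses the asymptotic two-sample
Kolmogorov–Smirnov formula with the number of histogram bins as the
effective sample size. This is deliberately approximate — the underlying
data are bin-wise paired frequencies, not two independent samples — and is
reported alongside the signed mean over histogram bins of
(observed − expected), a left/right shift diagnostic.

**Stochasticity entropy.** Regions kept for the profile are sequenced at
least 3 times in CT and KD combined and at least twice in either sample
(implemented as `max(CT, KD) >= 2`). At each |Diff/Sum| magnitude bin the
binary entropy of the GoM/LoM split is reported; a region at exactly
Diff/Sum = 0 belongs to neither state and is excluded from the split (its
magnitude bin still reports n). The two calibration points — H = 1 at an
equal GoM/LoM presence, H = 0 at exclusivity — pin this binary reading of
stochasticity; magnitude bins with no GoM+LoM regions report H as missing
rather than 0.

**Methylation signal levels.** The per-location read-count level ("
methylation bin") histogram splits levels 1–4 (low tier) from 5–30 (main
tier); levels above 30 and zero-count bins are excluded from the tier
histograms.

**TFBS enrichment.** PFM counts become probabilities with a flat
per-cell pseudocount (default 0.1): `p = (n + c)/(N + 4c)`. Scores are
log₂-odds against a 0-order background (uniform by default; estimable from
the scanned sequences). The null score distribution is computed exactly by
dynamic programming over per-position scores discretised at 10⁻³ bits,
giving `p(s) = P(score ≥ s)`; scanning evaluates both strands, skips windows
containing N, and reports hits at `p ≤ threshold` (10⁻⁶ stringent for the
JASPAR-wide analysis, 10⁻⁴ default for single-motif scans) in forward-strand
coordinates. Differential bins are those with |Diff/Sum| > 0.2. Per TF, the
2×2 table (motif-positive vs motif-negative) × (differential vs background)
is tested by chi-square with 1 df and no continuity correction (Yates
available behind a flag); the background may be all covered bins (default)
or shuffled coordinates, and the output records which. Multiple testing
across TFs is Bonferroni-corrected by default. A bin is motif-positive if it
contains at least one hit midpoint; overlapping hits are all retained.

**CTCF-site classes and flanks.** RFM = ≥1 motif hit and no repeat overlap;
MFR = ≥1 repeat overlap and no motif; both = mixed (excluded from RFM/MFR
contrasts); neither otherwise. Peaks are unstranded, so "upstream/
downstream" are genome-coordinate left/right; the peak center is the
interval midpoint (summit positions are not available from BED input).
Flank windows are `[start − flank, start)` and `[end, end + flank)` — they
never overlap the peak. The per-flank summary is the **sum** of normalized
counts (a read contributes to the 200 bp position bin holding its midpoint,
so meta-profile matrix rows sum exactly to the per-peak flank signal);
asymmetry is the signed difference upstream − downstream, with a
Diff/Sum-style normalized variant behind a flag. Peaks whose flanks would
cross a chromosome end are flagged and excluded from asymmetry statistics.

**Allelic imbalance.** Allele counts come from per-read base observations at
listed SNP sites; bases matching neither Ref nor Alt are tallied separately
and excluded. Sites need `Ref + Alt >= 5` per sample. The AIM sign
convention is `(Ref − Alt)/(Ref + Alt)` (listing order; configurable — the
mirror-image choice only reflects the distributions). Parent-of-origin is
resolved at loci where both parents are homozygous for different alleles;
with `m(x) = sign(x)·1{|x| > 0.5}` on the CT and KD `(Pat − Mat)/(Pat +
Mat)` values, the five categories (biallelic-stable, monoallelic-stable,
loss, gain, flip) partition the plane exhaustively and exclusively; |x|
exactly 0.5 is biallelic (inclusive interval). The %Mat − %Pat frequency
difference plot uses normalized per-sample histograms (10-point bins) and
reports KD − CT per bin.

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every planted feature recorded as ground truth:

* **Genome.** Equal-length random-nucleotide chromosomes (default 2 × 1 Mb),
  tiled into 200 bp bins. A small built-in library of synthetic PFMs
  (CTCF-like 19-mer first) supplies consensus sequences for embedding;
  any JASPAR PFM set can be substituted.
* **Baseline methylation.** Per-bin capture probability = per-10 kb-domain
  level drawn U(0.1, 0.3) plus per-bin jitter U(−0.05, 0.05), shared by both
  alleles and both conditions. The domain term gives the methylome its
  large-scale structure — it is what makes coarse-bin CT/KD correlation
  exceed fine-bin correlation, as in real multiscale comparisons.
* **Stochastic component.** Each non-protected bin flips with probability
  0.3; a flip displaces the two conditions symmetrically about the baseline,
  `ct = b(1 − s·d)`, `kd = b(1 + s·d)` with magnitude d ~ U(0.05, 0.35) and
  a fair sign. The expected Diff/Sum of a flipped bin is exactly ±d, so gain
  and loss are mirrored in magnitude and frequency. (One-sided multiplicative
  flips were rejected: under fixed-depth sampling they provably shift the
  whole Diff/Sum distribution negative and tilt the GoM/LoM ratio per
  magnitude bin.)
* **Directional component.** `n_tfbs_planted` bins (default 50) carry an
  embedded motif consensus and receive `kd = clip(ct + deterministic_shift)`
  (default +0.4) instead of a flip. Background consensus plants for every
  library TF (default 40 each) populate non-differential bins so enrichment
  ranking is meaningful.
* **Peaks.** RFM peaks contain the planted consensus; MFR peaks contain a CA
  repeat recorded in the repeat annotation. Peaks alternate along the genome
  spaced so 10 kb flanks never overlap. One flank side per peak (recorded)
  is raised by `flank_asymmetry_delta` (default 0.3); the knockdown side is
  re-drawn at RFM peaks only (`rerandomize_rfm_flank_kd`), which is what
  makes CT-vs-KD asymmetry correlation high at MFR and low at RFM.
* **SNPs.** One per chosen bin, at the bin center so every read of the bin
  covers it. Categories are drawn independently per SNP (no linkage):
  biallelic-stable (remainder), monoallelic-stable (0.3), loss (0.15), gain
  (0.15), flip (0.1); the methylated allele is at 0.5, the silenced one at
  0.02 capture probability. Parental phase is drawn per SNP and emitted as a
  homozygous-discordant parental genotype table.
* **Reads.** Single-end, fixed 150 bp (fragment-length variation collapsed
  for determinism), placed uniformly inside their bin; the (bin, allele)
  of origin is drawn multinomially with weight proportional to the
  methylation probability. The base written at an overlapped SNP follows the
  allele of origin; allele tags live only in a ground-truth sidecar, while
  observed bases form a legitimate analysis input. One cell type per run —
  a cell-type contrast is emulated by two configs differing in flip
  probability and shift.

What the generator does **not** model: sequencing errors, PCR duplicates,
per-cytosine states, bisulfite chemistry, fragment-length variation,
chromatin marks, linkage between SNPs, and mappability structure. Passing
recovery tests therefore show that the statistics recover the planted
bin-level structure under idealized sampling noise — not that they are
robust to alignment artifacts or per-cytosine heterogeneity in real data.

## Numerical choices and degenerate inputs

* Random state: `numpy` Generator seeded as `[seed, stage]` (genome, states,
  reads), so stages are individually reproducible; the pipeline threads one
  root seed through simulation, subsampling and shuffling.
* PWM p-value discretisation at 10⁻³ bits; exact agreement with exhaustive
  enumeration at widths ≤ 8 is part of the test suite.
* Diff/Sum at `CT = KD = 0` is undefined; such bins are excluded by the
  combined-count filter. Mean Diff/Sum over an empty TF bin set, correlations
  of constant vectors, and correlations over < 3 peaks are reported as
  missing rather than raised.
* Spearman correlations use all bins of the grid at each scale; PCA is
  covariance PCA via SVD with variance fractions over the informative
  dimensions.
* Histogram assignment uses round-to-nearest-center; ties at `.5` follow
  IEEE round-half-to-even, which is immaterial at the default 0.1 width.

## Scale of the shipped configurations

The default simulation (2 Mb, 10⁶ reads per condition, ≈100 reads per bin
per condition) runs the full pipeline in ~15 s. The test suite uses a
400 kb configuration (~60 reads per bin) with 2 kb flanks and 15 peaks per
class, chosen so ten-seed recovery sweeps complete in well under a minute
while keeping per-bin depth high enough that Poisson noise does not swamp
the planted Diff/Sum magnitudes.

## Known limitations

* The KS p-value on histogram CDFs is approximate by construction (see
  above); it is a deviation diagnostic, not a calibrated test.
* The enrichment background "all covered bins" includes the differential
  bins themselves (as a genome-wide expectation should); with very large
  differential fractions the test is conservative.
* `peaks_by_methylation_level` is an interval-tree scan, suitable for peak
  panels, not for genome-scale read sets.
* Motif hits are binarised per bin for enrichment; hit multiplicity within
  a bin is ignored by design.
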