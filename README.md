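# medipdiff

Bin-level analysis of differential cytosine methylation from MeDIP-seq, built
around the question of *stochastic* versus *directional* methylation change
between a control (CT) and a knockdown (KD) condition — the analytic setting
of CGGBP1-depletion methylome studies. The package implements the full
analysis as a tested, reusable pipeline, and ships a synthetic diploid
MeDIP-read generator with known ground truth so that every stage runs and can
be validated without any deposited sequencing data.

Intended users: epigenomics researchers and methods developers who want to
run, extend or sanity-check this family of analyses — binned MeDIP signal
comparison, methylation-stochasticity quantification, TFBS enrichment in
differential bins, CTCF-site flank asymmetry, and allele-specific methylation
with parent-of-origin resolution.

## The statistics at the core

* **Diff/Sum.** For each 0.2 kb genomic bin with depth-normalized read counts
  `CT` and `KD`, the change statistic is `(KD − CT) / (KD + CT)` ∈ [−1, 1],
  computed for bins with a combined signal of at least 3 reads. Positive
  values are gain of methylation (GoM), negative are loss (LoM). The observed
  frequency distribution is compared against a mirrored "expected" no-net-
  change distribution (frequency at ±b replaced by their mean) with a
  Kolmogorov–Smirnov statistic over the ordered histogram bins.
* **Stochasticity entropy.** At each |Diff/Sum| magnitude, with
  `p = #GoM / (#GoM + #LoM)`, the binary Shannon entropy
  `H = −p·log₂p − (1−p)·log₂(1−p)` is 1 when regions are equally likely to
  gain or lose methylation (pure stochastic change) and 0 when the change is
  exclusively directional.
* **TFBS enrichment.** Position weight matrices (JASPAR PFM format) are
  scanned FIMO-style: log-odds scores against a 0-order background with
  *exact* p-values from a dynamic program over discretised per-position
  scores. Per TF, motif-positive bins among differential bins
  (|Diff/Sum| > 0.2) versus background bins form a 2×2 chi-square test
  (1 df, no continuity correction; Bonferroni across TFs).
* **Flank asymmetry.** Binding-site peaks are classified into repeat-free
  motif-containing (RFM) and motif-free repeat-overlapping (MFR) exclusive
  classes; the summed MeDIP signal in the 10 kb flanks left/right of each
  peak gives a signed asymmetry whose CT-vs-KD Pearson r² measures whether
  the asymmetric side is conserved on knockdown.
* **Allelic imbalance (AIM).** At heterozygous SNPs covered ≥5× per sample,
  `AIM = (Ref − Alt) / (Ref + Alt)` over allele-resolved read counts. At
  obligate-heterozygote loci (parents homozygous for different alleles) the
  statistic becomes `(Pat − Mat)/(Pat + Mat)`, and each locus is classified
  with threshold 0.5 into biallelic-stable, monoallelic-stable, loss, gain,
  or allelic-flip.

## Worked example

Run the whole pipeline on a simulated experiment (2 Mb diploid genome,
10,000 bins, one million 150 bp reads per condition, 30 RFM + 30 MFR peaks,
500 phased SNPs; ~15 s):

```python
from medipdiff.pipeline import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(outdir="demo_run", seed=7))
for stage in manifest["stages"]:
    print(stage["name"], stage["counts"])
```

```
simulate {'n_reads_ct': 1000000, 'n_reads_kd': 1000000, 'n_peaks': 60, 'n_snps': 500}
bin {'n_bins': 10000, 'reads_used_ct': 1000000, 'reads_used_kd': 1000000}
diffsum {'n_records': 10000, 'ks_statistic': 0.006100000000000001}
entropy {'n_magnitude_bins': 11, 'populated': 10}
enrich {'n_hits': 327, 'n_differential_bins': 2622, 'top_tf': 'CTCF'}
sites {'n_peaks': 60, 'class_counts': {'RFM': 30, 'MFR': 30}}
aim {'n_sites_ct': 500, 'n_sites_kd': 500, 'n_classified': 500}
```

What the numbers say: the Diff/Sum distribution of this stochastic-dominated
simulation is symmetric (KS D = 0.006 against its mirrored expectation, i.e.
no net methylation change), yet 2,622 bins individually change by more than
|Diff/Sum| = 0.2. The entropy profile stays near 1 at stochastic magnitudes
(e.g. H = 0.9996 at |Diff/Sum| = 0.1 with 3,349 regions) — change is equally
split between gain and loss. The planted CTCF-like motif ranks first in the
differential-bin chi-square enrichment (`top_tf: CTCF`), recovering the
directional component hidden inside the stochastic background. Flank
asymmetry correlation (`demo_run/asymmetry_correlation.json`) contrasts
r² = 0.056 at RFM (knockdown re-randomizes the asymmetric side) with
r² = 0.995 at MFR; and the parent-of-origin summary
(`demo_run/aim_summary.json`) recovers the planted allelic categories
(167 biallelic-stable, 151 monoallelic-stable, 74 loss, 72 gain, 36 flip of
500 loci).

The same run is available from the shell:

```bash
medipdiff run-all --seed 7 --outdir demo_run
medipdiff simulate --seed 7 --outdir sim        # just the generator
medipdiff scan --fasta sim/genome.fa --pfm my_motifs.jaspar \
    --threshold 1e-6 --out hits.bed             # stand-alone PWM scan
```

Every emitted table carries a `# key=value` provenance header with the
thresholds used.

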