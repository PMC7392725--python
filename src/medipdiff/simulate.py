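"""Synthetic diploid MeDIP experiment with known ground truth.

The generator emulates the statistical structure a two-condition (control
vs knockdown) MeDIP comparison assumes, at bin resolution — MeDIP capture
depends on local methylcytosine density, so each 200 bp bin of each parental
allele carries a capture probability rather than per-cytosine states:

* a random diploid genome tiled into bins, each with a baseline methylation
  probability shared by both alleles;
* a dominant *stochastic* knockdown component: a random subset of bins flips
  its methylation up or down by a symmetric multiplicative factor, producing
  a symmetric Diff/Sum distribution (equal gain and loss of methylation);
* a *deterministic* directional component confined to planted TFBS bins
  carrying an embedded motif consensus: knockdown probability = control
  probability + ``deterministic_shift`` (clipped);
* binding-site peaks of two exclusive classes — repeat-free motif-containing
  (RFM) and repeat-overlapping motif-free (MFR) — whose 10 kb flanks are
  asymmetrically methylated on one recorded side; the knockdown side is
  re-randomized at RFM peaks only, so flank asymmetry decorrelates between
  conditions at RFM but not MFR;
* heterozygous SNPs with known maternal/paternal phase and planted allelic
  methylation categories (biallelic/monoallelic stable, loss, gain, flip).

Reads are single-end, fixed length, placed uniformly inside their bin with
per-(bin, allele) sampling weight proportional to the methylation
probability; the base at an overlapped SNP is written according to the
allele of origin, and the allele tag is kept only in a ground-truth sidecar.
All coordinates are 0-based half-open; everything is seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .binning import BinGrid, make_windows
from .demo import demo_pfms
from .motifs import ALPHABET, PWM

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MAT, PAT = 0, 1
CT, KD = 0, 1

CATEGORIES = (
    "biallelic_stable",
    "monoallelic_stable",
    "loss_of_monoallelic",
    "gain_of_monoallelic",
    "allelic_flip",
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated two-condition MeDIP experiment.

    ``genome_length`` is the total length, split into equal chromosomes.
    Probabilities are in [0, 1]; the SNP category fractions must sum to at
    most 1 (the remainder is biallelic-stable).
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    bin_size: int = 200
    read_length: int = 150
    n_reads_ct: int = 1_000_000
    n_reads_kd: int = 1_000_000
    stochastic_flip_prob: float = 0.3
    flip_diffsum_range: tuple[float, float] = (0.05, 0.35)
    deterministic_shift: float = 0.4
    n_tfbs_planted: int = 50
    n_rfm_peaks: int = 30
    n_mfr_peaks: int = 30
    peak_width: int = 400
    flank_size: int = 10_000
    flank_asymmetry_delta: float = 0.3
    rerandomize_rfm_flank_kd: bool = True
    n_snps: int = 500
    fraction_monoallelic_ct: float = 0.3
    fraction_gain_kd: float = 0.15
    fraction_loss_kd: float = 0.15
    fraction_flip_kd: float = 0.1
    baseline_range: tuple[float, float] = (0.1, 0.3)
    domain_size: int = 10_000
    baseline_jitter: float = 0.05
    snp_meth_high: float = 0.5
    snp_meth_low: float = 0.02
    n_background_motifs_per_tf: int = 40
    seed: int = 0

    def __post_init__(self):
        fracs = (
            self.fraction_monoallelic_ct,
            self.fraction_gain_kd,
            self.fraction_loss_kd,
            self.fraction_flip_kd,
        )
        probs = fracs + (self.stochastic_flip_prob,)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError("SNP category fractions must sum to <= 1")
        if self.genome_length % self.n_chromosomes:
            raise ValueError("genome_length must split evenly across chromosomes")
        if self.chrom_length % self.bin_size:
            raise ValueError("bin_size must divide the per-chromosome length")
        if self.read_length > self.bin_size:
            raise ValueError("read_length must not exceed bin_size")
        for name in ("peak_width", "flank_size"):
            if getattr(self, name) % self.bin_size:
                raise ValueError(f"{name} must be a multiple of bin_size")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be a non-negative 31-bit integer")

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chromosomes

    @property
    def genome_table(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)}

    def category_fractions(self) -> dict[str, float]:
        rest = 1.0 - (
            self.fraction_monoallelic_ct
            + self.fraction_gain_kd
            + self.fraction_loss_kd
            + self.fraction_flip_kd
        )
        return {
            "biallelic_stable": rest,
            "monoallelic_stable": self.fraction_monoallelic_ct,
            "loss_of_monoallelic": self.fraction_loss_kd,
            "gain_of_monoallelic": self.fraction_gain_kd,
            "allelic_flip": self.fraction_flip_kd,
        }


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    config: SimulationConfig
    grid: BinGrid
    bins: pd.DataFrame
    tfbs_bins: np.ndarray
    tfbs_tf: str
    peaks: pd.DataFrame
    repeats: pd.DataFrame
    motif_plants: pd.DataFrame
    snps: pd.DataFrame
    flank_bins: dict[str, tuple[np.ndarray, np.ndarray]]
    # filled by simulate_methylation_states: (n_bins, allele, condition)
    meth: np.ndarray | None = None

    @property
    def snp_bin_ids(self) -> np.ndarray:
        return self.snps["bin_id"].to_numpy(dtype=np.int64)


@dataclass
class SimulatedReads:
    """Read sets plus the ground-truth sidecar and parental genotype table."""

    reads_ct: pd.DataFrame
    reads_kd: pd.DataFrame
    # observed base at each overlapped SNP (legitimate analysis input)
    snp_base_annotations: pd.DataFrame
    # allele of origin per read (ground truth only)
    read_alleles: pd.DataFrame
    parental_table: pd.DataFrame


def _random_sequences(rng: np.random.Generator, genome_table: dict[str, int]) -> dict[str, np.ndarray]:
    return {c: rng.integers(0, 4, size=n, dtype=np.int8) for c, n in genome_table.items()}


def _embed(seq_codes: np.ndarray, pos: int, word: str, strand: str) -> None:
    if strand == "-":
        word = "".join(_COMPLEMENT[b] for b in reversed(word))
    seq_codes[pos : pos + len(word)] = [ALPHABET.index(b) for b in word]


def simulate_genome(
    config: SimulationConfig, pfms: list[PWM] | None = None
) -> tuple[dict[str, str], GroundTruth]:
    """Generate the genome and plant peaks, repeats, TFBS bins and SNPs.

    The first PWM in ``pfms`` is the planted TF whose consensus is embedded
    in RFM peaks and in the designated TFBS bins; every PWM additionally gets
    background consensus plants in non-differential bins. Raises a sizing
    error when the genome cannot host the requested plants.
    """
    if pfms is None:
        pfms = demo_pfms()
    planted = pfms[0]
    rng = np.random.default_rng([config.seed, 0])
    genome_table = config.genome_table
    grid = make_windows(genome_table, config.bin_size)
    bins = grid.to_frame()
    seqs = _random_sequences(rng, genome_table)

    used = np.zeros(grid.n_bins, dtype=bool)
    peak_rows, repeat_rows, plant_rows = [], [], []
    flank_bins: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # --- peaks: alternate RFM/MFR, spaced so 10 kb flanks never overlap ---
    classes = ["RFM", "MFR"]
    wanted = {"RFM": config.n_rfm_peaks, "MFR": config.n_mfr_peaks}
    placed = {"RFM": 0, "MFR": 0}
    spacing = 2 * config.flank_size + config.peak_width
    turn = 0
    for chrom, length in genome_table.items():
        pos = config.flank_size
        while pos + config.peak_width + config.flank_size <= length:
            for _ in range(2):
                cls = classes[turn % 2]
                turn += 1
                if placed[cls] < wanted[cls]:
                    break
            else:
                cls = None
            if cls is None or placed[cls] >= wanted[cls]:
                if all(placed[c] >= wanted[c] for c in classes):
                    break
                pos += spacing
                continue
            start, end = pos, pos + config.peak_width
            name = f"{cls}_{placed[cls]}"
            placed[cls] += 1
            center = (start + end) // 2
            if cls == "RFM":
                mstart = center - planted.width // 2
                strand = "+" if rng.random() < 0.5 else "-"
                _embed(seqs[chrom], mstart, planted.consensus, strand)
                plant_rows.append(
                    (planted.tf_name, chrom, mstart, mstart + planted.width, strand, "rfm_peak")
                )
            else:
                rep_len = config.bin_size
                rstart = center - rep_len // 2
                _embed(seqs[chrom], rstart, "CA" * (rep_len // 2), "+")
                repeat_rows.append((chrom, rstart, rstart + rep_len))
            peak_rows.append((chrom, start, end, name, cls, center))
            up = grid.bin_id(chrom, np.arange(start - config.flank_size, start, config.bin_size))
            down = grid.bin_id(chrom, np.arange(end, end + config.flank_size, config.bin_size))
            flank_bins[name] = (up, down)
            lo = grid.bin_id(chrom, start - config.flank_size)
            hi = grid.bin_id(chrom, end + config.flank_size - 1)
            used[lo : hi + 1] = True
            pos += spacing
    if any(placed[c] < wanted[c] for c in classes):
        raise ValueError(
            "genome too short to host the requested peaks with non-overlapping flanks"
        )

    def _take_free(n: int, label: str) -> np.ndarray:
        free = np.nonzero(~used)[0]
        if len(free) < n:
            raise ValueError(f"genome too short to host {n} {label} bins")
        chosen = rng.choice(free, size=n, replace=False)
        used[chosen] = True
        return np.sort(chosen)

    # --- planted TFBS bins (deterministic-shift targets) ---
    tfbs_bins = _take_free(config.n_tfbs_planted, "planted TFBS")
    for b in tfbs_bins:
        chrom, bstart = bins.loc[b, "chrom"], int(bins.loc[b, "start"])
        mstart = bstart + (config.bin_size - planted.width) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        _embed(seqs[chrom], mstart, planted.consensus, strand)
        plant_rows.append(
            (planted.tf_name, chrom, mstart, mstart + planted.width, strand, "tfbs_bin")
        )

    # --- background consensus plants for every TF in the library ---
    for pwm in pfms:
        bg_bins = _take_free(config.n_background_motifs_per_tf, "background motif")
        for b in bg_bins:
            chrom, bstart = bins.loc[b, "chrom"], int(bins.loc[b, "start"])
            mstart = bstart + (config.bin_size - pwm.width) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            _embed(seqs[chrom], mstart, pwm.consensus, strand)
            plant_rows.append(
                (pwm.tf_name, chrom, mstart, mstart + pwm.width, strand, "background")
            )

    # --- heterozygous SNPs at bin centres (covered by every read of the bin) ---
    snp_bins = _take_free(config.n_snps, "SNP")
    snp_rows = []
    for i, b in enumerate(snp_bins):
        chrom, bstart = bins.loc[b, "chrom"], int(bins.loc[b, "start"])
        pos = bstart + config.bin_size // 2
        ref = ALPHABET[seqs[chrom][pos]]
        alt = rng.choice([x for x in ALPHABET if x != ref])
        snp_rows.append((f"snp_{i}", chrom, pos, ref, alt, int(b)))

    sequences = {
        c: "".join(ALPHABET[i] for i in codes) for c, codes in seqs.items()
    }
    gt = GroundTruth(
        config=config,
        grid=grid,
        bins=bins,
        tfbs_bins=tfbs_bins,
        tfbs_tf=planted.tf_name,
        peaks=pd.DataFrame(
            peak_rows, columns=["chrom", "start", "end", "name", "site_class", "center"]
        ),
        repeats=pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"]),
        motif_plants=pd.DataFrame(
            plant_rows, columns=["tf_name", "chrom", "start", "end", "strand", "context"]
        ),
        snps=pd.DataFrame(
            snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "bin_id"]
        ),
        flank_bins=flank_bins,
    )
    return sequences, gt


def simulate_methylation_states(config: SimulationConfig, gt: GroundTruth) -> GroundTruth:
    """Assign per-bin, per-allele methylation probabilities for CT and KD.

    Knockdown bins flip up/down symmetrically (multiplicative factor, equal
    probability each direction) with ``stochastic_flip_prob``; planted TFBS
    bins instead receive the deterministic shift; one flank side of every
    peak is raised by ``flank_asymmetry_delta`` (the knockdown side is
    re-drawn at RFM peaks when configured); SNP bins get per-allele levels
    according to their drawn category.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_bins = gt.grid.n_bins
    # methylation has domain-scale structure: the baseline is a per-domain
    # level (shared by both conditions) plus small per-bin jitter
    bins_per_domain = max(config.domain_size // config.bin_size, 1)
    domain_of_bin = np.arange(n_bins) // bins_per_domain
    levels = rng.uniform(*config.baseline_range, size=domain_of_bin[-1] + 1)
    jitter = rng.uniform(-config.baseline_jitter, config.baseline_jitter, size=n_bins)
    base = np.clip(levels[domain_of_bin] + jitter, 0.02, 1.0)

    base_ct = base.copy()
    base_kd = base.copy()
    sides_ct, sides_kd = [], []
    for _, peak in gt.peaks.iterrows():
        up, down = gt.flank_bins[peak["name"]]
        side_ct = "up" if rng.random() < 0.5 else "down"
        if peak["site_class"] == "RFM" and config.rerandomize_rfm_flank_kd:
            side_kd = "up" if rng.random() < 0.5 else "down"
        else:
            side_kd = side_ct
        base_ct[up if side_ct == "up" else down] += config.flank_asymmetry_delta
        base_kd[up if side_kd == "up" else down] += config.flank_asymmetry_delta
        sides_ct.append(side_ct)
        sides_kd.append(side_kd)
    gt.peaks["flank_side_ct"] = sides_ct
    gt.peaks["flank_side_kd"] = sides_kd

    np.clip(base_ct, 0.0, 1.0, out=base_ct)
    np.clip(base_kd, 0.0, 1.0, out=base_kd)

    # stochastic flips everywhere except planted TFBS and SNP bins
    protected = np.zeros(n_bins, dtype=bool)
    protected[gt.tfbs_bins] = True
    protected[gt.snp_bin_ids] = True
    flip = (rng.random(n_bins) < config.stochastic_flip_prob) & ~protected
    # a flip displaces the two conditions symmetrically about the baseline:
    # ct = b(1 - s*d), kd = b(1 + s*d), so the expected Diff/Sum is exactly
    # s*d — gain and loss are mirrored in magnitude and frequency, and the
    # total capture weight of each condition is unchanged in expectation
    d = rng.uniform(*config.flip_diffsum_range, size=n_bins)
    sign = np.where(rng.random(n_bins) < 0.5, 1.0, -1.0)
    disp = np.where(flip, sign * d, 0.0)
    m_ct = np.clip(base_ct * (1 - disp), 0.0, 1.0)
    m_kd = np.clip(base_kd * (1 + disp), 0.0, 1.0)
    m_kd[gt.tfbs_bins] = np.clip(m_ct[gt.tfbs_bins] + config.deterministic_shift, 0.0, 1.0)

    meth = np.empty((n_bins, 2, 2))
    meth[:, MAT, CT] = meth[:, PAT, CT] = m_ct
    meth[:, MAT, KD] = meth[:, PAT, KD] = m_kd

    # SNP allelic categories
    fracs = config.category_fractions()
    cats = rng.choice(CATEGORIES, size=len(gt.snps), p=[fracs[c] for c in CATEGORIES])
    hi, lo = config.snp_meth_high, config.snp_meth_low
    biased_ct, biased_kd = [], []
    mat_name, pat_name = "maternal", "paternal"
    for i, (b, cat) in enumerate(zip(gt.snp_bin_ids, cats)):
        allele = MAT if rng.random() < 0.5 else PAT
        other = 1 - allele
        levels = np.full((2, 2), hi)  # (allele, condition)
        bct = bkd = None
        if cat == "monoallelic_stable":
            levels[other, :] = lo
            bct = bkd = allele
        elif cat == "loss_of_monoallelic":
            levels[other, CT] = lo
            bct = allele
        elif cat == "gain_of_monoallelic":
            levels[other, KD] = lo
            bkd = allele
        elif cat == "allelic_flip":
            levels[other, CT] = lo
            levels[allele, KD] = lo
            bct, bkd = allele, other
        meth[b] = levels
        biased_ct.append(None if bct is None else (mat_name if bct == MAT else pat_name))
        biased_kd.append(None if bkd is None else (mat_name if bkd == MAT else pat_name))
    gt.snps["category"] = cats
    gt.snps["biased_allele_ct"] = biased_ct
    gt.snps["biased_allele_kd"] = biased_kd

    # parental phase: assign which parental haplotype carries ref vs alt
    ref_is_maternal = rng.random(len(gt.snps)) < 0.5
    gt.snps["maternal_allele"] = np.where(ref_is_maternal, gt.snps["ref"], gt.snps["alt"])
    gt.snps["paternal_allele"] = np.where(ref_is_maternal, gt.snps["alt"], gt.snps["ref"])

    gt.meth = meth
    return gt


def sample_medip_reads(config: SimulationConfig, gt: GroundTruth) -> SimulatedReads:
    """Draw the CT and KD read sets from the per-(bin, allele) weights."""
    if gt.meth is None:
        raise ValueError("methylation states not simulated yet")
    rng = np.random.default_rng([config.seed, 2])
    bins = gt.bins
    bin_chrom = bins["chrom"].to_numpy()
    bin_start = bins["start"].to_numpy()
    snp_by_bin = gt.snps.set_index("bin_id")

    frames, annot_rows, allele_rows = {}, [], []
    for cond, label, n_reads in ((CT, "CT", config.n_reads_ct), (KD, "KD", config.n_reads_kd)):
        weights = gt.meth[:, :, cond].ravel()
        total = weights.sum()
        if total <= 0:
            raise ValueError("all sampling weights are zero; cannot place reads")
        counts = rng.multinomial(n_reads, weights / total)
        flat_idx = np.repeat(np.arange(len(weights)), counts)
        b_idx = flat_idx // 2
        alleles = flat_idx % 2
        offsets = rng.integers(0, config.bin_size - config.read_length + 1, size=n_reads)
        starts = bin_start[b_idx] + offsets
        names = np.array([f"{label.lower()}_read_{i}" for i in range(n_reads)])
        reads = pd.DataFrame(
            {
                "chrom": bin_chrom[b_idx],
                "start": starts,
                "end": starts + config.read_length,
                "name": names,
                "score": 0,
                "strand": ".",
            }
        )
        frames[label] = reads.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )
        allele_rows.append(
            pd.DataFrame({"sample": label, "read_name": names,
                          "allele": np.where(alleles == MAT, "maternal", "paternal")})
        )
        in_snp = np.isin(b_idx, gt.snp_bin_ids)
        if in_snp.any():
            sub = snp_by_bin.loc[b_idx[in_snp]]
            mat_base = sub["maternal_allele"].to_numpy()
            pat_base = sub["paternal_allele"].to_numpy()
            bases = np.where(alleles[in_snp] == MAT, mat_base, pat_base)
            annot_rows.append(
                pd.DataFrame(
                    {
                        "sample": label,
                        "read_name": names[in_snp],
                        "chrom": sub["chrom"].to_numpy(),
                        "pos": sub["pos"].to_numpy(),
                        "base": bases,
                    }
                )
            )
    annotations = (
        pd.concat(annot_rows, ignore_index=True)
        if annot_rows
        else pd.DataFrame(columns=["sample", "read_name", "chrom", "pos", "base"])
    )
    parental = gt.snps[
        ["chrom", "pos", "ref", "alt", "maternal_allele", "paternal_allele"]
    ].copy()
    return SimulatedReads(
        reads_ct=frames["CT"],
        reads_kd=frames["KD"],
        snp_base_annotations=annotations,
        read_alleles=pd.concat(allele_rows, ignore_index=True),
        parental_table=parental,
    )


def simulate_experiment(
    config: SimulationConfig, pfms: list[PWM] | None = None
) -> tuple[dict[str, str], GroundTruth, SimulatedReads]:
    """Run genome generation, state assignment and read sampling in order."""
    sequences, gt = simulate_genome(config, pfms)
    gt = simulate_methylation_states(config, gt)
    reads = sample_medip_reads(config, gt)
    return sequences, gt, reads


def write_simulation(
    outdir: str | Path,
    sequences: dict[str, str],
    gt: GroundTruth,
    reads: SimulatedReads,
) -> dict[str, str]:
    """Write the simulated experiment as FASTA/BED/TSV/JSON files.

    Read BED files are stripped of allele tags; the tags live in the
    ground-truth sidecar JSON/TSV. Returns a manifest of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(outdir / name)
        return outdir / name

    mio.write_fasta(sequences, _p("genome.fa"))
    mio.write_genome_table(gt.grid.genome_table, _p("genome.tsv"))
    mio.write_bed(reads.reads_ct, _p("reads_CT.bed"))
    mio.write_bed(reads.reads_kd, _p("reads_KD.bed"))
    mio.write_bed(gt.peaks, _p("peaks.bed"))
    if len(gt.repeats):
        mio.write_bed(gt.repeats, _p("repeats.bed"))
    tf_bins = gt.bins.iloc[gt.tfbs_bins][["chrom", "start", "end"]]
    mio.write_bed(tf_bins, _p("tfbs_bins.bed"))
    mio.write_snp_table(
        gt.snps[["chrom", "pos", "ref", "alt", "maternal_allele", "paternal_allele"]],
        _p("snps.tsv"),
    )
    reads.snp_base_annotations.to_csv(_p("snp_base_annotations.tsv"), sep="\t", index=False)
    reads.read_alleles.to_csv(_p("ground_truth_read_alleles.tsv"), sep="\t", index=False)
    sidecar = {
        "config": asdict(gt.config),
        "tfbs_tf": gt.tfbs_tf,
        "tfbs_bins": [int(b) for b in gt.tfbs_bins],
        "peaks": gt.peaks.to_dict(orient="records"),
        "snp_categories": gt.snps[
            ["snp_id", "chrom", "pos", "category", "biased_allele_ct", "biased_allele_kd"]
        ].to_dict(orient="records"),
    }
    with open(_p("ground_truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=str)
    return paths
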