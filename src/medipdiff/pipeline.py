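"""End-to-end orchestration: simulate → bin → diffsum → entropy → enrich → sites → aim.

Each stage writes its tables under the output directory with a provenance
header (the threshold values used) and logs one line with input/output
record counts. A manifest JSON records package version, seed, parameters and
the stages run. Stages declare dependencies; asking for a stage without its
upstream stage fails fast with a :class:`PipelineDependencyError`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .allelic import (
    aim_values,
    obligate_het_loci,
    parental_contribution_delta,
    pileup_allele_counts,
    poo_classify,
)
from .binning import coverage_fractional, make_windows, normalize_depth
from .ctcf import asymmetry_correlation, classify_peaks, flank_profiles
from .demo import demo_pfms
from .diffsum import (
    compare_observed_expected,
    compute_diff_sum,
    diffsum_histogram,
    mirrored_expected,
    multiscale_correlation,
    shannon_entropy_profile,
)
from .motifs import (
    motif_positive_bins,
    scan_sequences,
    score_pvalue_table,
    tf_diffsum_matrix,
    tfbs_enrichment,
)
from .simulate import SimulationConfig, simulate_experiment, write_simulation

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "bin", "diffsum", "entropy", "enrich", "sites", "aim")

_DEPENDENCIES = {
    "simulate": (),
    "bin": ("simulate",),
    "diffsum": ("bin",),
    "entropy": ("diffsum",),
    "enrich": ("diffsum",),
    "sites": ("bin",),
    "aim": ("simulate",),
}


class PipelineDependencyError(RuntimeError):
    """A requested stage's upstream stage is not part of the run."""


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run (defaults follow the analysis)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bin_size: int = 200
    min_overlap_fraction: float = 0.5
    min_combined: int = 3
    min_either: int = 2
    histogram_bin_width: float = 0.1
    diffsum_threshold: float = 0.2
    motif_pvalue: float = 1e-6
    min_coverage: int = 5
    poo_threshold: float = 0.5
    flank: int = 10_000
    normalize_mode: str = "subsample"
    outdir: str = "medipdiff_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.diffsum_threshold < 1 and 0 < self.motif_pvalue < 1
                and 0 <= self.poo_threshold <= 1):
            raise ValueError("threshold outside its documented range")
        # the simulation and the analysis share one seed root
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _check_dependencies(stages: tuple[str, ...]) -> None:
    for stage in stages:
        missing = [d for d in _DEPENDENCIES[stage] if d not in stages]
        if missing:
            raise PipelineDependencyError(
                f"stage {stage!r} requires {missing} in the stage list"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Outputs are deterministic given a fixed seed.
    """
    _check_dependencies(config.stages)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "medipdiff",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("simulation", "stages")
        },
        "simulation": asdict(config.simulation),
        "stages": [],
    }
    state: dict = {}
    prov = {
        "bin_size": config.simulation.bin_size,
        "min_combined": config.min_combined,
        "diffsum_threshold": config.diffsum_threshold,
        "motif_pvalue": config.motif_pvalue,
        "min_coverage": config.min_coverage,
        "poo_threshold": config.poo_threshold,
        "flank": config.flank,
        "seed": config.seed,
    }

    for stage in [s for s in ALL_STAGES if s in config.stages]:
        try:
            counts = _STAGE_FUNCS[stage](config, state, outdir, prov)
        except Exception:
            manifest["stages"].append({"name": stage, "status": "failed"})
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise
        logger.info("stage %s: %s", stage, counts)
        manifest["stages"].append({"name": stage, "status": "ok", "counts": counts})

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _stage_simulate(config, state, outdir, prov):
    pfms = demo_pfms()
    sequences, gt, reads = simulate_experiment(config.simulation, pfms)
    write_simulation(outdir / "simulation", sequences, gt, reads)
    state.update(sequences=sequences, gt=gt, reads=reads, pfms=pfms)
    return {
        "n_reads_ct": len(reads.reads_ct),
        "n_reads_kd": len(reads.reads_kd),
        "n_peaks": len(gt.peaks),
        "n_snps": len(gt.snps),
    }


def _stage_bin(config, state, outdir, prov):
    gt, reads = state["gt"], state["reads"]
    reads_ct, reads_kd = normalize_depth(
        reads.reads_ct, reads.reads_kd, mode=config.normalize_mode, seed=config.seed
    ) if config.normalize_mode == "subsample" else (reads.reads_ct, reads.reads_kd)
    grid = gt.grid
    counts_ct = coverage_fractional(reads_ct, grid, config.min_overlap_fraction)
    counts_kd = coverage_fractional(reads_kd, grid, config.min_overlap_fraction)
    state.update(grid=grid, counts_ct=counts_ct, counts_kd=counts_kd,
                 norm_reads=(reads_ct, reads_kd))
    signal = gt.bins[["chrom", "start", "end"]].copy()
    signal["count_ct"] = counts_ct
    signal["count_kd"] = counts_kd
    mio.write_tsv(signal, outdir / "bin_signal.tsv", prov)
    return {"n_bins": grid.n_bins, "reads_used_ct": len(reads_ct), "reads_used_kd": len(reads_kd)}


def _stage_diffsum(config, state, outdir, prov):
    records = compute_diff_sum(state["counts_ct"], state["counts_kd"], config.min_combined)
    hist = diffsum_histogram(records["diff_sum"].to_numpy(), config.histogram_bin_width)
    expected = mirrored_expected(hist)
    cmp = compare_observed_expected(hist, expected)
    state.update(records=records, hist=hist)
    mio.write_tsv(records, outdir / "diffsum_records.tsv", prov)
    combined = hist.rename(columns={"freq": "observed"})
    combined["expected"] = expected["freq"]
    mio.write_tsv(combined, outdir / "diffsum_histogram.tsv", prov)
    with open(outdir / "diffsum_ks.json", "w") as fh:
        json.dump(asdict(cmp), fh, indent=1)
    return {"n_records": len(records), "ks_statistic": cmp.ks_statistic}


def _stage_entropy(config, state, outdir, prov):
    profile = shannon_entropy_profile(
        state["records"], config.histogram_bin_width, config.min_combined, config.min_either
    )
    state["entropy_profile"] = profile
    mio.write_tsv(profile, outdir / "entropy_profile.tsv", prov)
    populated = int(profile["n"].gt(0).sum())
    return {"n_magnitude_bins": len(profile), "populated": populated}


def _stage_enrich(config, state, outdir, prov):
    gt, sequences, pfms = state["gt"], state["sequences"], state["pfms"]
    records, grid = state["records"], state["grid"]
    hits = pd.concat(
        [scan_sequences(sequences, pwm, threshold=config.motif_pvalue) for pwm in pfms],
        ignore_index=True,
    )
    mio.write_bed(hits.assign(strand=hits["strand"]), outdir / "motif_hits.bed")
    tf_bins = motif_positive_bins(hits, grid)
    covered = set(records["bin_id"].tolist())
    differential = set(
        records.loc[records["diff_sum"].abs() > config.diffsum_threshold, "bin_id"]
    )
    obs = {tf: len(b & differential) for tf, b in tf_bins.items()}
    bg = {tf: len(b & covered) for tf, b in tf_bins.items()}
    enrichment = tfbs_enrichment(obs, bg, len(differential), len(covered))
    enrichment["background"] = "all_covered_bins"
    state["enrichment"] = enrichment
    state["hits"] = hits
    mio.write_tsv(enrichment, outdir / "tfbs_enrichment.tsv", prov)
    matrix = tf_diffsum_matrix(
        {tf: b & covered for tf, b in tf_bins.items()},
        {"dataset": (state["counts_ct"], state["counts_kd"])},
    )
    matrix.index.name = "tf_name"
    mio.write_tsv(matrix.reset_index(), outdir / "tf_diffsum_matrix.tsv", prov)
    return {"n_hits": len(hits), "n_differential_bins": len(differential),
            "top_tf": enrichment.iloc[0]["tf_name"] if len(enrichment) else None}


def _stage_sites(config, state, outdir, prov):
    gt = state["gt"]
    reads_ct, reads_kd = state["norm_reads"]
    hits = state.get("hits")
    if hits is None:
        planted = state["pfms"][0]
        hits = scan_sequences(state["sequences"], planted, threshold=config.motif_pvalue)
    ctcf_hits = hits[hits["name"] == gt.tfbs_tf]
    peaks = classify_peaks(gt.peaks.drop(columns="site_class"), ctcf_hits, gt.repeats)
    genome_table = gt.grid.genome_table
    prof_ct, _ = flank_profiles(peaks, reads_ct, genome_table, flank=config.flank)
    prof_kd, _ = flank_profiles(peaks, reads_kd, genome_table, flank=config.flank)
    corr = [asymmetry_correlation(prof_ct, prof_kd, cls) for cls in ("RFM", "MFR")]
    mio.write_tsv(peaks, outdir / "peak_classification.tsv", prov)
    mio.write_tsv(
        prof_ct.merge(prof_kd, on="name", suffixes=("_ct", "_kd")),
        outdir / "flank_asymmetry.tsv", prov,
    )
    with open(outdir / "asymmetry_correlation.json", "w") as fh:
        json.dump(corr, fh, indent=1)
    state.update(peak_classes=peaks, asym_corr=corr)
    return {"n_peaks": len(peaks),
            "class_counts": peaks["site_class"].value_counts().to_dict()}


def _stage_aim(config, state, outdir, prov):
    gt, reads = state["gt"], state["reads"]
    annotations = reads.snp_base_annotations
    sites = reads.parental_table
    counts = {
        label: pileup_allele_counts(
            annotations[annotations["sample"] == label], sites, config.min_coverage
        )
        for label in ("CT", "KD")
    }
    het = obligate_het_loci(sites)
    records = aim_values(counts["CT"], counts["KD"], sites=het)
    classified = poo_classify(records, threshold=config.poo_threshold)
    delta = parental_contribution_delta(classified)
    summary = classified["category"].value_counts().to_dict()
    mio.write_tsv(classified, outdir / "aim_poo.tsv", prov)
    mio.write_tsv(delta, outdir / "parental_contribution_delta.tsv", prov)
    with open(outdir / "aim_summary.json", "w") as fh:
        json.dump({"n_loci": len(classified), "categories": summary}, fh, indent=1)
    state["aim_records"] = classified
    return {"n_sites_ct": len(counts["CT"]), "n_sites_kd": len(counts["KD"]),
            "n_classified": len(classified)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "bin": _stage_bin,
    "diffsum": _stage_diffsum,
    "entropy": _stage_entropy,
    "enrich": _stage_enrich,
    "sites": _stage_sites,
    "aim": _stage_aim,
}
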