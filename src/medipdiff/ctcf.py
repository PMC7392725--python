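"""Binding-site peak classification and flank methylation asymmetry.

Peaks are partitioned into four exclusive classes from two annotations:
repeat-free motif-containing peaks (RFM: >=1 motif hit, no repeat overlap),
motif-free repeat-overlapping peaks (MFR: >=1 repeat overlap, no motif),
``mixed`` (both) and ``neither``. RFM and MFR are exclusive sets by
construction; mixed peaks are excluded from RFM/MFR contrasts.

Flank analysis sums the normalized MeDIP signal over the 10 kb windows
immediately left (upstream) and right (downstream) of each peak — peaks are
unstranded, so the orientation is genome-coordinate order — and reports the
signed asymmetry (upstream - downstream). The per-class Pearson correlation
of CT vs KD asymmetries quantifies whether the asymmetric side is conserved
on knockdown.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


def _build_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int))
        )
    return trees


def classify_peaks(
    peaks: pd.DataFrame,
    motif_hits: pd.DataFrame,
    repeat_intervals: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each peak a ``site_class`` in {RFM, MFR, mixed, neither}."""
    motif_trees = _build_trees(motif_hits) if len(motif_hits) else {}
    repeat_trees = _build_trees(repeat_intervals) if len(repeat_intervals) else {}
    classes = []
    for _, peak in peaks.iterrows():
        chrom, start, end = peak["chrom"], int(peak["start"]), int(peak["end"])
        has_motif = chrom in motif_trees and bool(motif_trees[chrom].overlap(start, end))
        has_repeat = chrom in repeat_trees and bool(repeat_trees[chrom].overlap(start, end))
        if has_motif and not has_repeat:
            classes.append("RFM")
        elif has_repeat and not has_motif:
            classes.append("MFR")
        elif has_motif and has_repeat:
            classes.append("mixed")
        else:
            classes.append("neither")
    out = peaks.copy()
    out["site_class"] = classes
    if "center" not in out.columns:
        out["center"] = (out["start"] + out["end"]) // 2
    return out


def peaks_by_methylation_level(
    reads: pd.DataFrame,
    peaks: pd.DataFrame,
    regions: pd.DataFrame,
    levels: tuple[int, int] = (5, 30),
    motif_hits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Distributions over methylation signal levels.

    ``regions`` carries methylated regions with an integer ``level`` column
    (reads at that location in the MeDIP data). For each level s in
    ``levels`` the function counts (i) binding-site reads lying *entirely
    within* a level-s region, (ii) peaks whose center falls in a level-s
    region, and (iii) motif-positive peaks among those (when ``motif_hits``
    is given).
    """
    lo, hi = levels
    level_trees: dict[int, dict[str, IntervalTree]] = {}
    for level, sub in regions.groupby("level"):
        if lo <= level <= hi:
            level_trees[int(level)] = _build_trees(sub)
    motif_trees = _build_trees(motif_hits) if motif_hits is not None and len(motif_hits) else {}

    rows = []
    for level in range(lo, hi + 1):
        trees = level_trees.get(level, {})
        n_reads = 0
        for _, read in reads.iterrows():
            tree = trees.get(read["chrom"])
            if tree is None:
                continue
            # entirely overlapped: the read lies fully within a region
            if any(
                iv.begin <= read["start"] and read["end"] <= iv.end
                for iv in tree.overlap(int(read["start"]), int(read["end"]))
            ):
                n_reads += 1
        n_peaks = n_motif_peaks = 0
        for _, peak in peaks.iterrows():
            tree = trees.get(peak["chrom"])
            center = int(peak.get("center", (peak["start"] + peak["end"]) // 2))
            if tree is None or not tree.overlap(center, center + 1):
                continue
            n_peaks += 1
            mt = motif_trees.get(peak["chrom"])
            if mt is not None and mt.overlap(int(peak["start"]), int(peak["end"])):
                n_motif_peaks += 1
        rows.append((level, n_reads, n_peaks, n_motif_peaks))
    return pd.DataFrame(rows, columns=["level", "n_reads", "n_peaks", "n_motif_peaks"])


def flank_profiles(
    peaks: pd.DataFrame,
    reads: pd.DataFrame,
    genome_table: dict[str, int],
    flank: int = 10_000,
    step: int = 200,
    scale: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-peak flank signal and a position-binned meta-profile matrix.

    Upstream window = ``[start - flank, start)``, downstream = ``[end, end +
    flank)``; the windows never overlap the peak. A read contributes to the
    position bin holding its midpoint, so each matrix row (upstream bins then
    downstream bins, ``step`` bp each) sums to the peak's total flank signal.
    ``scale`` is a depth-normalization factor applied multiplicatively.
    Peaks whose flanks would run off the chromosome are flagged ``clipped``
    and should be excluded from asymmetry statistics.
    """
    if flank % step:
        raise ValueError("flank must be a multiple of step")
    n_side = flank // step
    mids: dict[str, np.ndarray] = {}
    for chrom, sub in reads.groupby("chrom", sort=False):
        mids[chrom] = np.sort(
            ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        )
    rows = []
    matrix = np.zeros((len(peaks), 2 * n_side))
    for i, (_, peak) in enumerate(peaks.iterrows()):
        chrom, start, end = peak["chrom"], int(peak["start"]), int(peak["end"])
        clipped = start - flank < 0 or end + flank > genome_table.get(chrom, np.inf)
        m = mids.get(chrom, np.empty(0, dtype=np.int64))
        edges_up = np.arange(start - flank, start + 1, step)
        edges_down = np.arange(end, end + flank + 1, step)
        up_counts = np.histogram(m, bins=edges_up)[0] * scale
        down_counts = np.histogram(m, bins=edges_down)[0] * scale
        matrix[i, :n_side] = up_counts
        matrix[i, n_side:] = down_counts
        up, down = float(up_counts.sum()), float(down_counts.sum())
        rows.append(
            (peak.get("name", f"peak_{i}"), chrom, start, end,
             peak.get("site_class", "NA"), up, down, up - down, clipped)
        )
    profiles = pd.DataFrame(
        rows,
        columns=["name", "chrom", "start", "end", "site_class",
                 "upstream_signal", "downstream_signal", "asymmetry", "clipped"],
    )
    return profiles, matrix


def asymmetry_correlation(
    profiles_ct: pd.DataFrame,
    profiles_kd: pd.DataFrame,
    site_class: str | None = None,
) -> dict:
    """Pearson r and r^2 of per-peak CT vs KD flank asymmetries.

    Clipped peaks are dropped; with fewer than 3 peaks the correlation is
    undefined (NaN).
    """
    merged = profiles_ct.merge(
        profiles_kd, on="name", suffixes=("_ct", "_kd"), validate="one_to_one"
    )
    merged = merged[~merged["clipped_ct"] & ~merged["clipped_kd"]]
    if site_class is not None:
        merged = merged[merged["site_class_ct"] == site_class]
    n = len(merged)
    if n < 3:
        return {"site_class": site_class, "n": n, "r": np.nan, "r2": np.nan}
    r = stats.pearsonr(merged["asymmetry_ct"], merged["asymmetry_kd"]).statistic
    return {"site_class": site_class, "n": n, "r": float(r), "r2": float(r**2)}
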