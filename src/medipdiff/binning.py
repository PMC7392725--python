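"""Genome bin grids and read-to-bin coverage counting.

The MeDIP signal of a sample is the number of reads assigned to each
fixed-width genomic bin (default 200 bp). A read is assigned to every bin it
overlaps by at least ``min_overlap_fraction`` of its own length (default 0.5,
the bedtools ``coverage -f`` rule with ``>=`` at the boundary); with 150 bp
reads on 200 bp bins this is at most one bin per read except for exact 50/50
straddles, which count in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome.

    Bins are disjoint, sorted by (chromosome, start) and all have width
    ``bin_size`` except possibly the terminal bin of each chromosome, which
    is truncated at the chromosome end.
    """

    genome_table: Mapping[str, int]
    bin_size: int
    chrom_offsets: dict[str, int] = field(init=False, repr=False)
    n_bins: int = field(init=False)

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not self.genome_table:
            raise ValueError("empty genome table")
        offsets: dict[str, int] = {}
        total = 0
        for chrom, length in self.genome_table.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            offsets[chrom] = total
            total += self.n_bins_for(chrom)
        object.__setattr__(self, "chrom_offsets", offsets)
        object.__setattr__(self, "n_bins", total)

    def n_bins_for(self, chrom: str) -> int:
        return -(-self.genome_table[chrom] // self.bin_size)

    def to_frame(self) -> pd.DataFrame:
        """Materialise the grid as a BED-like DataFrame with a ``bin_id``."""
        frames = []
        for chrom, length in self.genome_table.items():
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        df = pd.concat(frames, ignore_index=True)
        df["bin_id"] = np.arange(len(df))
        return df

    def bin_id(self, chrom: str, pos) -> np.ndarray:
        """Global bin index for position(s) on ``chrom``."""
        return self.chrom_offsets[chrom] + np.asarray(pos) // self.bin_size


def make_windows(genome_table: Mapping[str, int], bin_size: int) -> BinGrid:
    """Tile every chromosome with ``bin_size`` windows (terminal bin truncated)."""
    return BinGrid(genome_table=dict(genome_table), bin_size=bin_size)


def coverage_fractional(
    reads: pd.DataFrame,
    grid: BinGrid,
    min_overlap_fraction: float = 0.5,
) -> np.ndarray:
    """Count reads into bins under the fractional-overlap rule.

    A read increments every bin where ``overlap / read_length >=
    min_overlap_fraction``. Reads on chromosomes absent from the grid are
    skipped with a warning and tallied in ``coverage_fractional.last_skipped``.

    Returns an array of raw counts indexed by global bin id.
    """
    if not 0 < min_overlap_fraction <= 1:
        raise ValueError("min_overlap_fraction must be in (0, 1]")
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    skipped = 0
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in grid.genome_table:
            skipped += len(sub)
            continue
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        lengths = ends - starts
        if np.any(lengths <= 0):
            raise ValueError("read with non-positive length")
        chrom_len = grid.genome_table[chrom]
        offset = grid.chrom_offsets[chrom]
        n_chrom_bins = grid.n_bins_for(chrom)
        first = starts // grid.bin_size
        last = (ends - 1) // grid.bin_size
        # a read spans at most max(last-first)+1 candidate bins; loop over
        # that small offset range with vectorised accumulation
        for k in range(int(np.max(last - first)) + 1):
            b = first + k
            valid = (b <= last) & (b < n_chrom_bins)
            if not valid.any():
                continue
            bin_start = b * grid.bin_size
            bin_end = np.minimum(bin_start + grid.bin_size, chrom_len)
            overlap = np.minimum(ends, bin_end) - np.maximum(starts, bin_start)
            hit = valid & (overlap / lengths >= min_overlap_fraction)
            np.add.at(counts, offset + b[hit], 1)
    if skipped:
        warnings.warn(f"skipped {skipped} reads on chromosomes absent from the grid")
    coverage_fractional.last_skipped = skipped
    return counts


coverage_fractional.last_skipped = 0


def normalize_depth(
    reads_a: pd.DataFrame,
    reads_b: pd.DataFrame,
    mode: str = "subsample",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[float, float]:
    """Equalise sequencing depth between two read sets.

    ``subsample`` randomly downsizes the larger set (without replacement,
    seeded) to the smaller set's size and returns the two read frames.
    ``scale`` returns multiplicative factors ``(f_a, f_b)`` with
    ``f = smaller/larger`` on the larger set and 1.0 on the other.
    """
    if len(reads_a) == 0 or len(reads_b) == 0:
        raise ValueError("both read sets must be non-empty")
    n_a, n_b = len(reads_a), len(reads_b)
    if mode == "scale":
        if n_a == n_b:
            return 1.0, 1.0
        if n_a > n_b:
            return n_b / n_a, 1.0
        return 1.0, n_a / n_b
    if mode != "subsample":
        raise ValueError(f"unknown mode {mode!r}")
    if n_a == n_b:
        return reads_a, reads_b
    rng = np.random.default_rng(seed)
    if n_a > n_b:
        keep = np.sort(rng.choice(n_a, size=n_b, replace=False))
        return reads_a.iloc[keep].reset_index(drop=True), reads_b
    keep = np.sort(rng.choice(n_b, size=n_a, replace=False))
    return reads_a, reads_b.iloc[keep].reset_index(drop=True)
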