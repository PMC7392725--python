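"""Bin-level methylation-change statistics.

The central quantity is the Diff/Sum ratio ``(KD - CT) / (KD + CT)`` of
normalized MeDIP read counts at each genomic bin, bounded in [-1, 1]. A bin
with a positive ratio gains methylation on knockdown (GoM), a negative one
loses it (LoM). Downstream summaries:

* the frequency distribution of Diff/Sum values and its mirrored "expected"
  counterpart (no net change), compared by a Kolmogorov-Smirnov statistic;
* the binary Shannon entropy of the GoM-vs-LoM state as a function of
  |Diff/Sum| magnitude — the stochasticity profile;
* read-density ("methylation bin") histograms, multiscale CT-vs-KD Spearman
  correlations, and a sample-level PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA

from .binning import BinGrid, coverage_fractional, make_windows


def compute_diff_sum(
    counts_ct: np.ndarray,
    counts_kd: np.ndarray,
    min_combined: int = 3,
) -> pd.DataFrame:
    """Per-bin Diff/Sum records for bins with ``ct + kd >= min_combined``.

    Returns a frame with columns ``bin_id``, ``ct``, ``kd``, ``diff_sum``.
    """
    counts_ct = np.asarray(counts_ct, dtype=float)
    counts_kd = np.asarray(counts_kd, dtype=float)
    if counts_ct.shape != counts_kd.shape:
        raise ValueError("CT and KD count vectors must be paired per bin")
    total = counts_ct + counts_kd
    keep = total >= min_combined
    bin_id = np.nonzero(keep)[0]
    ct, kd = counts_ct[keep], counts_kd[keep]
    return pd.DataFrame(
        {"bin_id": bin_id, "ct": ct, "kd": kd, "diff_sum": (kd - ct) / (kd + ct)}
    )


def diffsum_histogram(values: np.ndarray, bin_width: float = 0.1) -> pd.DataFrame:
    """Frequency histogram of Diff/Sum values on a symmetric grid about 0.

    Bin centers run from -1 to 1 in steps of ``bin_width``; each value is
    assigned to the nearest center (the layout of a frequency plot with the
    given interval).
    """
    values = np.asarray(values, dtype=float)
    if np.any(np.abs(values) > 1 + 1e-12):
        raise ValueError("Diff/Sum values must lie in [-1, 1]")
    n_side = int(round(1 / bin_width))
    centers = np.arange(-n_side, n_side + 1) * bin_width
    idx = np.clip(np.round(values / bin_width).astype(int) + n_side, 0, len(centers) - 1)
    freq = np.bincount(idx, minlength=len(centers))
    return pd.DataFrame({"center": centers, "freq": freq})


def mirrored_expected(observed: pd.DataFrame) -> pd.DataFrame:
    """Expected no-net-change distribution: mean of the +b and -b frequencies.

    The frequency at 0 is unchanged; total mass is preserved; the operation
    is idempotent and fixes any symmetric histogram.
    """
    centers = observed["center"].to_numpy()
    freq = observed["freq"].to_numpy(dtype=float)
    if not np.allclose(centers, -centers[::-1]):
        raise ValueError("histogram layout must be symmetric about 0")
    expected = 0.5 * (freq + freq[::-1])
    return pd.DataFrame({"center": centers, "freq": expected})


@dataclass(frozen=True)
class HistogramComparison:
    mean_of_differences: float
    ks_statistic: float
    p_value: float


def compare_observed_expected(
    observed: pd.DataFrame, expected: pd.DataFrame
) -> HistogramComparison:
    """Compare two histograms on the same layout.

    ``mean_of_differences`` is the mean over histogram bins of the signed
    (observed - expected) frequency difference — a left/right shift
    diagnostic. The KS statistic is the maximum |CDF difference| of the two
    normalized histograms over the ordered bins, with an asymptotic p-value
    using the number of histogram bins as the effective sample size (an
    approximation, since the underlying pairing is bin-wise).
    """
    if not np.allclose(observed["center"], expected["center"]):
        raise ValueError("histograms must share a layout")
    obs = observed["freq"].to_numpy(dtype=float)
    exp = expected["freq"].to_numpy(dtype=float)
    if obs.sum() == 0 or exp.sum() == 0:
        raise ValueError("zero total mass")
    mean_diff = float(np.mean(obs - exp))
    cdf_obs = np.cumsum(obs) / obs.sum()
    cdf_exp = np.cumsum(exp) / exp.sum()
    d = float(np.max(np.abs(cdf_obs - cdf_exp)))
    n = len(obs)
    en = np.sqrt(n * n / (2 * n))
    p = float(np.clip(special.kolmogorov(d * (en + 0.12 + 0.11 / en)), 0.0, 1.0))
    if d == 0:
        p = 1.0
    return HistogramComparison(mean_of_differences=mean_diff, ks_statistic=d, p_value=p)


def binary_entropy(p) -> np.ndarray | float:
    """H(p) = -p log2 p - (1-p) log2 (1-p), with 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    for q in (p, 1 - p):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(q > 0, -q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
        out = out + term
    return out if out.ndim else float(out)


def shannon_entropy_profile(
    records: pd.DataFrame,
    magnitude_bin_width: float = 0.1,
    min_combined: int = 3,
    min_either: int = 2,
) -> pd.DataFrame:
    """Stochasticity profile: GoM/LoM entropy per |Diff/Sum| magnitude bin.

    Records must carry ``ct``, ``kd`` and ``diff_sum``. Bins kept for the
    profile satisfy ``ct + kd >= min_combined`` and ``max(ct, kd) >=
    min_either``. At each magnitude bin, ``p_gom`` is the fraction of regions
    in GoM among GoM + LoM (records at exactly 0 belong to neither) and H is
    the binary Shannon entropy of that split: 1 at an equal GoM/LoM presence,
    0 at exclusivity. Empty magnitude bins have H = NaN (masked).
    """
    ct = records["ct"].to_numpy(dtype=float)
    kd = records["kd"].to_numpy(dtype=float)
    ds = records["diff_sum"].to_numpy(dtype=float)
    keep = (ct + kd >= min_combined) & (np.maximum(ct, kd) >= min_either)
    ds = ds[keep]
    n_side = int(round(1 / magnitude_bin_width))
    centers = np.arange(0, n_side + 1) * magnitude_bin_width
    idx = np.clip(np.round(np.abs(ds) / magnitude_bin_width).astype(int), 0, n_side)
    gom = np.bincount(idx[ds > 0], minlength=n_side + 1)
    lom = np.bincount(idx[ds < 0], minlength=n_side + 1)
    n = gom + lom
    with np.errstate(invalid="ignore"):
        p_gom = np.where(n > 0, gom / np.maximum(n, 1), np.nan)
    entropy = np.where(n > 0, binary_entropy(np.where(n > 0, gom / np.maximum(n, 1), 0.5)), np.nan)
    return pd.DataFrame(
        {"magnitude": centers, "n_gom": gom, "n_lom": lom, "n": n,
         "p_gom": p_gom, "entropy": entropy}
    )


def methylation_bin_density(
    counts: np.ndarray,
    low_range: tuple[int, int] = (1, 4),
    main_range: tuple[int, int] = (5, 30),
) -> pd.DataFrame:
    """Histogram of genomic bins by integer read-count level.

    Levels in ``low_range`` form the low-methylation tier, ``main_range`` the
    main tier; levels above the main range (and zero) are excluded.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("methylation-bin density requires raw integer counts")
        counts = np.round(counts).astype(int)
    levels = np.arange(low_range[0], main_range[1] + 1)
    freq = np.bincount(counts[counts >= 0], minlength=main_range[1] + 1)
    tier = np.where(levels <= low_range[1], "low", "main")
    return pd.DataFrame({"level": levels, "n_bins": freq[levels], "tier": tier})


def multiscale_correlation(
    reads_ct: pd.DataFrame,
    reads_kd: pd.DataFrame,
    genome_table: dict[str, int],
    bin_sizes: tuple[int, ...] = (10_000, 5_000, 1_000, 200),
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Spearman rho between CT and KD per-bin counts at several bin sizes."""
    rows = []
    for size in bin_sizes:
        grid = make_windows(genome_table, size)
        ct = coverage_fractional(reads_ct, grid, min_overlap_fraction)
        kd = coverage_fractional(reads_kd, grid, min_overlap_fraction)
        if np.ptp(ct) == 0 or np.ptp(kd) == 0:
            rows.append((size, np.nan, np.nan, grid.n_bins))
            continue
        rho, p = stats.spearmanr(ct, kd)
        rows.append((size, float(rho), float(p), grid.n_bins))
    return pd.DataFrame(rows, columns=["bin_size", "spearman_rho", "p_value", "n_bins"])


def pca_samples(matrix: np.ndarray, sample_names: list[str]) -> dict:
    """Covariance PCA of a samples x bins signal matrix.

    Returns sample scores, per-component variance fractions (descending,
    summing to 1 over the informative dimensions) and bin loadings.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 bins")
    if not np.any(matrix):
        raise ValueError("all-zero signal matrix")
    n_comp = min(matrix.shape[0], matrix.shape[1])
    pca = PCA(n_components=n_comp)
    with np.errstate(invalid="ignore"):  # identical samples: zero total variance
        scores = pca.fit_transform(matrix)
    return {
        "samples": list(sample_names),
        "scores": scores,
        "variance_fraction": pca.explained_variance_ratio_,
        "loadings": pca.components_,
    }
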