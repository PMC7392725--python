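"""PWM scanning with calibrated p-values and TFBS enrichment statistics.

The scanner mirrors FIMO's model: a position frequency matrix is smoothed
with a pseudocount into a probability matrix, scored as log-odds against a
0-order background, and the null distribution of the score is computed
exactly by dynamic programming over discretised per-position scores, giving
``p(s) = P(score >= s)`` under the background. Hits on either strand are
reported in forward-strand coordinates; windows containing N are skipped.

Enrichment of motif-positive bins among differentially methylated bins is a
2x2 chi-square association test (no continuity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHABET = "ACGT"
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes A,C,G,T -> 0..3; other bases -> -1."""
    return _BASE_INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix with log-odds scores against a background.

    ``probs`` is 4 x width (rows A, C, G, T); every column sums to 1 and all
    entries are positive after pseudocount smoothing.
    """

    tf_name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError("probability matrix must be 4 x width")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(probs <= 0):
            raise ValueError("PWM entries must be positive (apply a pseudocount)")
        if bg.shape != (4,) or np.any(bg <= 0):
            raise ValueError("background must be a positive 4-vector")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg / bg.sum())

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.tf_name, self.probs[::-1, ::-1], self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())


def pwm_from_pfm(
    counts: np.ndarray,
    tf_name: str = "motif",
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> PWM:
    """Convert a 4 x width count matrix to a PWM.

    Each cell receives the flat pseudocount: ``p = (n + c) / (N + 4c)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("PFM must be 4 x width")
    if np.any(counts < 0):
        raise ValueError("PFM counts must be non-negative")
    totals = counts.sum(axis=0)
    if np.any(totals + 4 * pseudocount <= 0):
        raise ValueError("all-zero PFM column with zero pseudocount")
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    return PWM(tf_name, probs, bg)


def pwm_from_bio_motif(motif, pseudocount: float = 0.1, background=None) -> PWM:
    """Build a PWM from a Bio.motifs object (e.g. parsed JASPAR PFM)."""
    counts = np.array([motif.counts[b] for b in ALPHABET], dtype=float)
    return pwm_from_pfm(counts, tf_name=motif.name or motif.matrix_id,
                        pseudocount=pseudocount, background=background)


class ScorePValueTable:
    """Exact null distribution of the PWM log-odds score.

    Per-position scores are discretised to a grid of step ``granularity``
    (bits) and convolved across positions weighted by the background base
    probabilities, yielding ``P(score >= s)`` for every attainable
    discretised score. ``pvalue`` is monotone non-increasing in the score.
    """

    def __init__(self, pwm: PWM, granularity: float = 1e-3):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.pwm = pwm
        self.granularity = granularity
        scaled = np.round(pwm.log_odds / granularity).astype(np.int64)
        # DP: start with a point mass, add one position at a time
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(pwm.width):
            col = scaled[:, j]
            new_lo = cur_lo + int(col.min())
            new = np.zeros(len(cur) + int(col.max() - col.min()))
            for base in range(4):
                off = int(col[base]) - int(col.min())
                new[off : off + len(cur)] += pwm.background[base] * cur
            cur, cur_lo = new, new_lo
        self._offset = cur_lo
        self._pmf = cur
        # survival function: P(score >= s) over the discretised grid
        self._sf = np.cumsum(cur[::-1])[::-1]
        self._scaled = scaled

    def _index(self, score: float) -> int:
        return int(np.round(score / self.granularity)) - self._offset

    def pvalue(self, score) -> np.ndarray | float:
        """P(score >= s) under the background model."""
        scores = np.atleast_1d(np.asarray(score, dtype=float))
        idx = np.round(scores / self.granularity).astype(np.int64) - self._offset
        above_max = idx >= len(self._sf)
        idx = np.clip(idx, 0, len(self._sf) - 1)
        out = np.where(above_max, 0.0, self._sf[idx])
        return out if np.ndim(score) else float(out[0])

    def score_threshold(self, pvalue: float) -> float:
        """Smallest discretised score s with P(score >= s) <= pvalue."""
        idx = np.searchsorted(-self._sf, -pvalue, side="left")
        if idx >= len(self._sf):
            return float("inf")
        return (idx + self._offset) * self.granularity


def score_pvalue_table(pwm: PWM, granularity: float = 1e-3) -> ScorePValueTable:
    """Build the exact score -> p-value map for ``pwm``."""
    return ScorePValueTable(pwm, granularity=granularity)


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    w = log_odds.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    lo = np.vstack([log_odds, np.full(log_odds.shape[1], -np.inf)])  # row 4 = N
    safe = np.where(codes < 0, 4, codes)
    scores = np.zeros(n)
    for j in range(w):
        scores += lo[safe[j : j + n], j]
    return scores


def scan_sequences(
    sequences: dict[str, str],
    pwm: PWM,
    threshold: float = 1e-4,
    granularity: float = 1e-3,
    table: ScorePValueTable | None = None,
) -> pd.DataFrame:
    """Scan both strands of each sequence for PWM hits at p <= threshold.

    Returns a BED-like frame (chrom, start, end, name, score, strand,
    p_value) with forward-strand coordinates.
    """
    if table is None:
        table = score_pvalue_table(pwm, granularity)
    min_score = table.score_threshold(threshold)
    rc = pwm.reverse_complement()
    rows = []
    for chrom, seq in sequences.items():
        codes = encode(seq)
        for strand, matrix in (("+", pwm.log_odds), ("-", rc.log_odds)):
            scores = _window_scores(codes, matrix)
            hits = np.nonzero(scores >= min_score)[0]
            for i in hits:
                rows.append(
                    (chrom, int(i), int(i) + pwm.width, pwm.tf_name,
                     float(scores[i]), strand, table.pvalue(float(scores[i])))
                )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand", "p_value"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def shuffle_intervals(
    intervals: pd.DataFrame,
    genome_table: dict[str, int],
    seed: int = 0,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Place the intervals at uniformly random non-overlapping positions.

    Lengths are preserved exactly; chromosomes are chosen with probability
    proportional to the placeable positions for each length. Raises after
    ``max_tries`` failed rejection rounds per interval.
    """
    rng = np.random.default_rng(seed)
    lengths = (intervals["end"] - intervals["start"]).to_numpy()
    chroms = list(genome_table)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out = []
    for L in lengths:
        room = np.array([max(genome_table[c] - L + 1, 0) for c in chroms], dtype=float)
        if room.sum() == 0:
            raise ValueError(f"no chromosome can host an interval of length {L}")
        for _ in range(max_tries):
            c = chroms[rng.choice(len(chroms), p=room / room.sum())]
            s = int(rng.integers(0, genome_table[c] - L + 1))
            if all(s + L <= a or s >= b for a, b in placed[c]):
                placed[c].append((s, s + L))
                out.append((c, s, s + int(L)))
                break
        else:
            raise RuntimeError("could not place interval without overlap")
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


@dataclass(frozen=True)
class EnrichmentResult:
    tf_name: str
    observed_hit_bins: int
    n_differential_bins: int
    background_hit_bins: int
    n_background_bins: int
    expected_rate: float
    chi2: float
    p_value: float
    direction: str
    low_count: bool


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Chi-square association test on the 2x2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0:
        return 0.0, 1.0
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def tfbs_enrichment(
    hit_bins_differential: dict[str, int],
    hit_bins_background: dict[str, int],
    n_differential_bins: int,
    n_background_bins: int,
    yates: bool = False,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Per-TF chi-square enrichment of motif-positive bins in differential bins.

    ``hit_bins_*`` map TF name -> number of motif-positive bins in the
    differential set and in the background (all covered bins or shuffled
    coordinates). Returns a frame sorted by chi2 descending with a
    ``significant`` column (Bonferroni-corrected across tested TFs by
    default).
    """
    tfs = sorted(set(hit_bins_differential) | set(hit_bins_background))
    rows = []
    for tf in tfs:
        obs = int(hit_bins_differential.get(tf, 0))
        bg = int(hit_bins_background.get(tf, 0))
        a, b = obs, n_differential_bins - obs
        c, d = bg, n_background_bins - bg
        chi2, p = chi2_2x2(a, b, c, d, yates=yates)
        exp_rate = bg / n_background_bins if n_background_bins else np.nan
        obs_rate = obs / n_differential_bins if n_differential_bins else np.nan
        expected = stats.contingency.expected_freq(np.array([[a, b], [c, d]], float))
        rows.append(
            EnrichmentResult(
                tf_name=tf,
                observed_hit_bins=obs,
                n_differential_bins=n_differential_bins,
                background_hit_bins=bg,
                n_background_bins=n_background_bins,
                expected_rate=exp_rate,
                chi2=chi2,
                p_value=p,
                direction="enriched" if obs_rate >= exp_rate else "depleted",
                low_count=bool(np.any(expected < 1)),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        "chi2", ascending=False, kind="stable"
    ).reset_index(drop=True)
    n_tests = max(len(df), 1)
    cutoff = alpha / n_tests if bonferroni else alpha
    df["alpha_used"] = cutoff
    df["significant"] = (df["p_value"] <= cutoff) & (df["direction"] == "enriched")
    return df


def motif_positive_bins(hits: pd.DataFrame, grid) -> dict[str, set[int]]:
    """Map TF name -> set of global bin ids containing >=1 hit midpoint."""
    out: dict[str, set[int]] = {}
    for tf, sub in hits.groupby("name", sort=False):
        ids = set()
        for chrom, chrom_sub in sub.groupby("chrom", sort=False):
            if chrom not in grid.genome_table:
                continue
            mids = ((chrom_sub["start"] + chrom_sub["end"]) // 2).to_numpy()
            ids.update(grid.bin_id(chrom, mids).tolist())
        out[tf] = ids
    return out


def tf_diffsum_matrix(
    tf_bins: dict[str, set[int]],
    signals: dict[str, tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Diff/Sum of the average CT and KD signal over each TF's motif bins.

    ``signals`` maps dataset name -> (counts_ct, counts_kd) arrays indexed by
    global bin id. Entries for empty bin sets are NaN (masked).
    """
    rows = {}
    for tf, bins in tf_bins.items():
        idx = np.fromiter(bins, dtype=np.int64) if bins else np.empty(0, np.int64)
        row = {}
        for ds, (ct, kd) in signals.items():
            if len(idx) == 0:
                row[ds] = np.nan
                continue
            mean_ct, mean_kd = float(np.mean(ct[idx])), float(np.mean(kd[idx]))
            denom = mean_ct + mean_kd
            row[ds] = (mean_kd - mean_ct) / denom if denom > 0 else np.nan
        rows[tf] = row
    return pd.DataFrame.from_dict(rows, orient="index")
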