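"""PWM construction, exact p-values, scanning, shuffling and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medipdiff.motifs import (
    ALPHABET,
    chi2_2x2,
    pwm_from_pfm,
    scan_sequences,
    score_pvalue_table,
    shuffle_intervals,
    tf_diffsum_matrix,
    tfbs_enrichment,
)


class TestPwmFromPfm:
    def test_pure_column_without_pseudocount(self):
        pwm = pwm_from_pfm(np.array([[10, 10], [0, 0], [0, 0], [0, 0]]), pseudocount=1e-12)
        np.testing.assert_allclose(pwm.probs[0], 1.0, atol=1e-9)

    def test_uniform_counts_give_zero_log_odds(self):
        pwm = pwm_from_pfm(np.full((4, 3), 5.0), pseudocount=0.1)
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)

    def test_pseudocount_arithmetic(self):
        # (8 + 0.1) / (10 + 0.4)
        pwm = pwm_from_pfm(np.array([[8.0], [2.0], [0.0], [0.0]]), pseudocount=0.1)
        assert pwm.probs[0, 0] == pytest.approx(8.1 / 10.4)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_pfm(np.zeros((4, 2)), pseudocount=0.0)


class TestScorePValueTable:
    def test_width_one_best_base_pvalue_is_background_probability(self):
        pwm = pwm_from_pfm(np.array([[9.0], [1.0], [1.0], [1.0]]))
        table = score_pvalue_table(pwm)
        assert table.pvalue(pwm.max_score()) == pytest.approx(0.25)

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_matches_exhaustive_enumeration(self, width):
        """DP survival function equals brute force over all 4^w words."""
        rng = np.random.default_rng(width)
        counts = rng.integers(1, 50, size=(4, width)).astype(float)
        pwm = pwm_from_pfm(counts)
        table = score_pvalue_table(pwm, granularity=1e-3)
        scaled = np.round(pwm.log_odds / 1e-3)
        words = list(itertools.product(range(4), repeat=width))
        word_scores = np.array(
            [sum(scaled[b, j] for j, b in enumerate(word)) for word in words]
        )
        for q in (0.1, 0.5, 0.9):
            s = float(np.quantile(word_scores, q)) * 1e-3
            exact = np.mean(word_scores >= np.round(s / 1e-3)) / 1.0
            # uniform background: each word has probability 0.25^w
            assert table.pvalue(s) == pytest.approx(exact, abs=1e-12)

    def test_pvalue_monotone_nonincreasing(self):
        pwm = pwm_from_pfm(np.random.default_rng(1).integers(1, 20, (4, 5)).astype(float))
        table = score_pvalue_table(pwm)
        grid = np.linspace(-10, pwm.max_score(), 200)
        ps = table.pvalue(grid)
        assert (np.diff(ps) <= 1e-15).all()

    def test_max_score_attainable(self):
        pwm = pwm_from_pfm(np.random.default_rng(2).integers(1, 20, (4, 6)).astype(float))
        table = score_pvalue_table(pwm)
        assert table.pvalue(pwm.max_score()) >= 0.25**6


class TestScanSequences:
    def test_planted_consensus_found(self, pfms):
        pwm = pfms[0]
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(ALPHABET), 500)) + pwm.consensus
        hits = scan_sequences({"chr1": seq}, pwm, threshold=1e-2)
        spans = set(zip(hits["start"], hits["end"]))
        assert (500, 500 + pwm.width) in spans

    def test_all_n_sequence_yields_no_hits(self, pfms):
        hits = scan_sequences({"chr1": "N" * 300}, pfms[0], threshold=1.0)
        assert len(hits) == 0

    def test_reverse_complement_symmetry(self, pfms):
        pwm = pfms[1]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(pwm.consensus))
        background = "ATATATATATATATATATATATAT"
        fwd = scan_sequences({"c": background + pwm.consensus + background}, pwm, 1e-2)
        rev = scan_sequences({"c": background + rc + background}, pwm, 1e-2)
        assert fwd["score"].max() == pytest.approx(rev["score"].max())
        assert rev.loc[rev["score"].idxmax(), "strand"] == "-"

    def test_sequence_shorter_than_width_ok(self, pfms):
        assert len(scan_sequences({"c": "ACG"}, pfms[0], 1.0)) == 0


class TestShuffleIntervals:
    GENOME = {"chr1": 10_000, "chr2": 5_000}

    def _intervals(self):
        return pd.DataFrame(
            {"chrom": ["chr1"] * 5, "start": [0, 300, 900, 2000, 4000],
             "end": [200, 450, 1100, 2600, 4050]}
        )

    def test_lengths_preserved(self):
        iv = self._intervals()
        out = shuffle_intervals(iv, self.GENOME, seed=0)
        assert sorted(out["end"] - out["start"]) == sorted(iv["end"] - iv["start"])

    def test_seeded_determinism(self):
        a = shuffle_intervals(self._intervals(), self.GENOME, seed=5)
        b = shuffle_intervals(self._intervals(), self.GENOME, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_placements_non_overlapping(self):
        out = shuffle_intervals(self._intervals(), self.GENOME, seed=2)
        for _, sub in out.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_start_positions_uniform(self):
        """1000 shuffles of one 200 bp interval on a 10 kb chromosome."""
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200]})
        starts = [
            shuffle_intervals(iv, {"chr1": 10_000}, seed=s)["start"].iloc[0]
            for s in range(1000)
        ]
        observed = np.histogram(starts, bins=10, range=(0, 9801))[0]
        assert stats.chisquare(observed).pvalue > 0.01

    def test_impossible_placement_rejected(self):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20_001]})
        with pytest.raises(ValueError):
            shuffle_intervals(iv, self.GENOME, seed=0)


class TestEnrichment:
    def test_hand_computed_chi_square(self):
        chi2, _ = chi2_2x2(30, 970, 100, 9900)
        assert chi2 == pytest.approx(31.14, abs=0.01)

    def test_equal_rates_give_zero(self):
        chi2, p = chi2_2x2(10, 90, 100, 900)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula_on_random_tables(self):
        """chi2 equals sum((O-E)^2 / E) on 100 random 2x2 tables."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 10_000, size=4)
            chi2, _ = chi2_2x2(int(a), int(b), int(c), int(d))
            table = np.array([[a, b], [c, d]], dtype=float)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            oracle = ((table - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(oracle, rel=1e-9)

    def test_result_table_fields(self):
        df = tfbs_enrichment({"TF1": 30, "TF2": 10}, {"TF1": 100, "TF2": 120},
                             1000, 10_000)
        assert df.iloc[0]["tf_name"] == "TF1"
        assert df.iloc[0]["direction"] == "enriched"
        assert (df["chi2"] >= 0).all()
        assert df["alpha_used"].iloc[0] == pytest.approx(0.025)


class TestTfDiffsumMatrix:
    def test_mean_signal_ratio(self):
        ct = np.array([2.0, 2.0, 9.0])
        kd = np.array([6.0, 6.0, 9.0])
        m = tf_diffsum_matrix({"TFA": {0, 1}, "TFB": {2}, "TFC": set()},
                              {"ds": (ct, kd)})
        assert m.loc["TFA", "ds"] == pytest.approx(0.5)
        assert m.loc["TFB", "ds"] == 0.0
        assert np.isnan(m.loc["TFC", "ds"])
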