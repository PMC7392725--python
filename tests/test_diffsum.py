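"""Diff/Sum records, mirrored expectation, entropy and summary statistics."""

import numpy as np
import pandas as pd
import pytest

from medipdiff.diffsum import (
    binary_entropy,
    compare_observed_expected,
    compute_diff_sum,
    diffsum_histogram,
    methylation_bin_density,
    mirrored_expected,
    multiscale_correlation,
    pca_samples,
    shannon_entropy_profile,
)

from conftest import reads_frame


class TestComputeDiffSum:
    def test_examples_and_combined_filter(self):
        ct = np.array([3, 1, 3, 1, 2])
        kd = np.array([3, 3, 0, 1, 0])
        rec = compute_diff_sum(ct, kd, min_combined=3)
        # (1,1) and (2,0) are excluded: combined signal 2 < 3
        assert rec["bin_id"].tolist() == [0, 1, 2]
        np.testing.assert_allclose(rec["diff_sum"], [0.0, 0.5, -1.0])

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(3)
        ct = rng.integers(0, 50, size=500)
        kd = rng.integers(0, 50, size=500)
        fwd = compute_diff_sum(ct, kd)
        rev = compute_diff_sum(kd, ct)
        np.testing.assert_allclose(fwd["diff_sum"], -rev["diff_sum"])

    def test_bounds(self):
        rng = np.random.default_rng(4)
        rec = compute_diff_sum(rng.integers(0, 9, 300), rng.integers(0, 9, 300))
        assert rec["diff_sum"].between(-1, 1).all()


class TestMirroredExpected:
    def _hist(self, mapping):
        centers = np.round(np.arange(-10, 11) * 0.1, 10)
        freq = [mapping.get(round(c, 1), 0) for c in centers]
        return pd.DataFrame({"center": centers, "freq": freq})

    def test_pair_mean(self):
        exp = mirrored_expected(self._hist({0.3: 10, -0.3: 20}))
        lookup = dict(zip(np.round(exp["center"], 1), exp["freq"]))
        assert lookup[0.3] == lookup[-0.3] == 15

    def test_symmetric_histogram_is_fixed_point(self):
        sym = self._hist({0.2: 5, -0.2: 5, 0.0: 9})
        pd.testing.assert_frame_equal(mirrored_expected(sym), sym.astype({"freq": float}))

    def test_mass_preserved_and_idempotent(self):
        rng = np.random.default_rng(5)
        hist = self._hist({})
        hist["freq"] = rng.integers(0, 100, size=len(hist))
        exp = mirrored_expected(hist)
        assert exp["freq"].sum() == hist["freq"].sum()
        pd.testing.assert_frame_equal(mirrored_expected(exp), exp)


class TestCompareObservedExpected:
    def _hist(self, mapping):
        centers = np.round(np.arange(-10, 11) * 0.1, 10)
        freq = [float(mapping.get(round(c, 1), 0)) for c in centers]
        return pd.DataFrame({"center": centers, "freq": freq})

    def test_identity(self):
        h = self._hist({0.1: 4, -0.2: 6, 0.0: 3})
        cmp = compare_observed_expected(h, h)
        assert cmp.mean_of_differences == 0
        assert cmp.ks_statistic == 0
        assert cmp.p_value == 1

    def test_disjoint_supports_give_d_one(self):
        cmp = compare_observed_expected(self._hist({-1.0: 7}), self._hist({1.0: 7}))
        assert cmp.ks_statistic == pytest.approx(1.0)

    def test_single_sided_vs_mirror_hand_cdf(self):
        """Observed all at -0.5 vs its mirrored expectation: D = 0.5.

        CDFs at the -0.5 bin are 1.0 (observed) and 0.5 (expected)."""
        obs = self._hist({-0.5: 4})
        exp = mirrored_expected(obs)
        cmp = compare_observed_expected(obs, exp)
        assert cmp.ks_statistic == pytest.approx(0.5)
        assert cmp.mean_of_differences == pytest.approx(0.0)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            compare_observed_expected(self._hist({}), self._hist({}))


class TestEntropyProfile:
    def _records(self, diff_sums, ct=10, kd=10):
        return pd.DataFrame(
            {"ct": ct, "kd": kd, "diff_sum": np.asarray(diff_sums, dtype=float)}
        )

    def test_equal_split_gives_entropy_one(self):
        rec = self._records([0.42] * 20 + [-0.42] * 20)
        profile = shannon_entropy_profile(rec)
        row = profile[profile["magnitude"].round(1) == 0.4].iloc[0]
        assert row["p_gom"] == 0.5
        assert row["entropy"] == 1.0

    def test_exclusive_state_gives_entropy_zero(self):
        for sign in (+1, -1):
            rec = self._records([sign * 0.52] * 15)
            profile = shannon_entropy_profile(rec)
            row = profile[profile["magnitude"].round(1) == 0.5].iloc[0]
            assert row["entropy"] == 0.0

    def test_quarter_split_matches_binary_entropy_formula(self):
        rec = self._records([0.3] * 5 + [-0.3] * 15)
        profile = shannon_entropy_profile(rec)
        row = profile[profile["magnitude"].round(1) == 0.3].iloc[0]
        assert row["p_gom"] == 0.25
        assert row["entropy"] == pytest.approx(0.811278, abs=1e-6)
        assert binary_entropy(0.25) == pytest.approx(-(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75)))

    def test_read_filters_applied(self):
        # combined < 3 and max < 2 records must be dropped
        rec = pd.DataFrame(
            {"ct": [1, 1, 1, 8], "kd": [1, 0, 2, 4], "diff_sum": [0.25, -1.0, 0.25, -0.25]}
        )
        profile = shannon_entropy_profile(rec)
        assert profile["n"].sum() == 2  # only (1,2) and (8,4) survive

    def test_zero_diff_sum_belongs_to_neither_state(self):
        rec = self._records([0.0] * 10)
        profile = shannon_entropy_profile(rec)
        assert profile.loc[0, "n"] == 0
        assert np.isnan(profile.loc[0, "entropy"])


class TestMethylationBinDensity:
    def test_tier_assignment_and_exclusions(self):
        dens = methylation_bin_density(np.array([0, 5, 5, 30, 31]))
        lookup = dens.set_index("level")["n_bins"]
        assert lookup[5] == 2 and lookup[30] == 1
        assert 31 not in lookup.index and 0 not in lookup.index
        assert dens[dens["tier"] == "low"]["n_bins"].sum() == 0

    def test_all_zero_counts_empty(self):
        assert methylation_bin_density(np.zeros(50, dtype=int))["n_bins"].sum() == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 40, size=200)
        a = methylation_bin_density(counts)
        b = methylation_bin_density(rng.permutation(counts))
        pd.testing.assert_frame_equal(a, b)


class TestMultiscaleCorrelation:
    def test_identical_read_sets_give_rho_one(self):
        rng = np.random.default_rng(7)
        rows = [("chr1", int(s), int(s) + 150) for s in rng.integers(0, 99_000, 3000)]
        reads = reads_frame(rows)
        corr = multiscale_correlation(reads, reads, {"chr1": 100_000}, (10_000, 1_000))
        np.testing.assert_allclose(corr["spearman_rho"], 1.0)

    def test_independent_reads_near_zero_at_fine_bins(self):
        rng = np.random.default_rng(8)
        genome = {"chr1": 1_000_000}
        mk = lambda: reads_frame(
            [("chr1", int(s), int(s) + 150) for s in rng.integers(0, 999_000, 20_000)]
        )
        corr = multiscale_correlation(mk(), mk(), genome, (200,))
        assert abs(corr["spearman_rho"].iloc[0]) < 0.1


class TestPCASamples:
    def test_identical_samples_have_zero_scatter(self):
        m = np.tile(np.arange(5.0), (2, 1))
        res = pca_samples(m, ["a", "b"])
        np.testing.assert_allclose(res["scores"], 0, atol=1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        res = pca_samples(rng.normal(size=(4, 30)), list("abcd"))
        assert res["variance_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res["variance_fraction"]) <= 1e-12).all()

    def test_matches_eigendecomposition_oracle(self):
        m = np.array(
            [[2.0, 0.0, 1.0], [0.0, 1.0, 3.0], [4.0, 2.0, 0.0], [1.0, 1.0, 1.0]]
        )
        res = pca_samples(m, list("abcd"))
        evals = np.sort(np.linalg.eigvalsh(np.cov(m.T, ddof=1)))[::-1]
        expected = evals[: len(res["variance_fraction"])] / evals.sum()
        np.testing.assert_allclose(res["variance_fraction"], expected, atol=1e-9)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_samples(np.zeros((3, 4)), list("abc"))


def test_histogram_rejects_out_of_range_values():
    with pytest.raises(ValueError):
        diffsum_histogram(np.array([1.5]))
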