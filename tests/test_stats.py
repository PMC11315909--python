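import itertools
import math

import numpy as np
import pytest

from pchtools.genome import (
    BoundaryWindowSpec,
    GenomeLayout,
    GenomicInterval,
    tile_genome,
)
from pchtools.stats import (
    boundary_profile,
    call_bin_changes,
    mann_whitney_u,
    permutation_median_test,
    wilcoxon_signed_rank,
)
from pchtools.tracks import CPM, SignalTrack, quantify


class TestBoundaryProfile:
    def _track(self, layout, grid, values):
        return SignalTrack.from_bin_values(grid, values, kind=CPM)

    def test_constant_track_flat_profile_zero_se(self):
        layout = GenomeLayout(tuple((f"chr{i}", 8_000_000) for i in range(1, 5)))
        grid = tile_genome(layout, 10_000)
        t = self._track(layout, grid, np.full(len(grid), 2.5))
        spec = BoundaryWindowSpec(chromosomes=tuple(layout.names))
        prof = boundary_profile(t, spec)
        np.testing.assert_allclose(prof.cross_mean, 2.5)
        np.testing.assert_allclose(prof.cross_se, 0.0, atol=1e-12)
        # 2.5-5 Mb at 10 kb = 250 offsets
        assert len(prof.offsets) == 250

    def test_planted_bump_elevates_exactly_window_offsets(self):
        layout = GenomeLayout(tuple((f"chr{i}", 8_000_000) for i in range(1, 4)))
        grid = tile_genome(layout, 10_000)
        values = np.ones(len(grid))
        for i, b in enumerate(grid.bins):
            if 3_000_000 <= b.start < 3_500_000:
                values[i] = 5.0
        t = self._track(layout, grid, values)
        prof = boundary_profile(
            t, BoundaryWindowSpec(chromosomes=tuple(layout.names))
        )
        in_window = (prof.offsets >= 3_000_000) & (prof.offsets < 3_500_000)
        np.testing.assert_allclose(prof.cross_mean[in_window], 5.0)
        np.testing.assert_allclose(prof.cross_mean[~in_window], 1.0)

    def test_per_chromosome_rows_match_quantify_on_offset_bins(self, rng):
        layout = GenomeLayout((("chrA", 6_000_000), ("chrB", 6_000_000)))
        grid = tile_genome(layout, 10_000)
        t = self._track(layout, grid, rng.normal(size=len(grid)))
        spec = BoundaryWindowSpec(chromosomes=("chrA", "chrB"))
        prof = boundary_profile(t, spec)
        for chrom in ("chrA", "chrB"):
            bins = [
                GenomicInterval(chrom, int(o), int(o) + 10_000)
                for o in prof.offsets
            ]
            np.testing.assert_allclose(
                prof.per_chromosome.loc[chrom].to_numpy(),
                quantify(t, bins),
                atol=1e-12,
            )

    def test_short_chromosomes_dropped_then_error(self, caplog):
        layout = GenomeLayout((("chrA", 6_000_000), ("chrS", 4_000_000)))
        grid = tile_genome(layout, 10_000)
        t = self._track(layout, grid, np.ones(len(grid)))
        spec = BoundaryWindowSpec(chromosomes=("chrA", "chrS"))
        with caplog.at_level("WARNING"):
            prof = boundary_profile(t, spec)
        assert list(prof.per_chromosome.index) == ["chrA"]
        with pytest.raises(ValueError, match="no chromosome"):
            boundary_profile(t, BoundaryWindowSpec(chromosomes=("chrS",)))


def exhaustive_median_p(a, b, alternative):
    """Oracle: enumerate every labeling of the pooled values."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    obs = np.median(a) - np.median(b)
    diffs = []
    for idx in itertools.combinations(range(n), n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        diffs.append(np.median(pooled[sel]) - np.median(pooled[~sel]))
    diffs = np.array(diffs)
    if alternative == "greater":
        count = np.sum(diffs >= obs)
    elif alternative == "less":
        count = np.sum(diffs <= obs)
    else:
        count = np.sum(np.abs(diffs) >= abs(obs))
    return count / len(diffs)


class TestPermutationMedianTest:
    def test_identical_constant_groups_p_one(self):
        r = permutation_median_test([1.0] * 5, [1.0] * 5, alternative="two_sided")
        assert r.observed_diff == 0.0
        assert r.p_value == 1.0

    def test_minimum_attainable_p_with_large_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(100.0, 1.0, 200)
        b = rng.normal(0.0, 1.0, 200)
        r = permutation_median_test(a, b, n_permutations=10_000, seed=1)
        assert r.p_value == pytest.approx(1 / 10_001)

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    @pytest.mark.parametrize("case_seed", [0, 1, 2])
    def test_exhaustive_path_matches_enumeration_oracle(self, alternative, case_seed):
        rng = np.random.default_rng(case_seed)
        a, b = rng.normal(1, 1, 4), rng.normal(0, 1, 4)
        r = permutation_median_test(a, b, alternative=alternative)
        assert r.exhaustive
        assert r.n_permutations == math.comb(8, 4) == 70
        assert r.p_value == pytest.approx(
            exhaustive_median_p(a, b, alternative), abs=1e-15
        )

    def test_exhaustive_two_sided_symmetric_in_groups(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 1, 4), rng.normal(0, 1, 5)
        r1 = permutation_median_test(a, b, alternative="two_sided")
        r2 = permutation_median_test(b, a, alternative="two_sided")
        assert r1.exhaustive and r2.exhaustive
        assert r1.p_value == r2.p_value
        assert r1.observed_diff == -r2.observed_diff

    def test_sampled_observed_diff_negates_on_swap(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        r1 = permutation_median_test(a, b, seed=1, n_permutations=200)
        r2 = permutation_median_test(b, a, seed=1, n_permutations=200)
        assert r1.observed_diff == -r2.observed_diff

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        r1 = permutation_median_test(a, b, seed=42, n_permutations=500)
        r2 = permutation_median_test(a, b, seed=42, n_permutations=500)
        np.testing.assert_array_equal(r1.null_diffs, r2.null_diffs)
        assert r1.p_value == r2.p_value

    def test_missing_values_dropped_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            permutation_median_test([np.nan, np.nan], [1.0, 2.0])

    def test_null_p_values_super_uniform(self):
        # both groups from one distribution: rejection rate at 0.05 stays
        # near (never much above) nominal
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            x, y = rng.normal(size=40), rng.normal(size=40)
            r = permutation_median_test(
                x, y, n_permutations=499, rng=rng, alternative="two_sided"
            )
            rejections += r.p_value <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.08


def wilcoxon_sign_enumeration_p(d):
    """Oracle: exact two-sided p over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    n = len(d)
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    mean_w = n * (n + 1) / 4
    # two-sided: statistic at least as far from its null mean
    p = np.mean(np.abs(w_all - mean_w) >= abs(w_plus - mean_w) - 1e-12)
    return p


class TestWilcoxonSignedRank:
    def test_constant_positive_shift_exact_p(self):
        a = np.arange(10, dtype=float)
        b = a + 5.0
        stat, p = wilcoxon_signed_rank(a, b)
        assert stat == 0.0  # all differences one-signed: extreme statistic
        assert p == pytest.approx(2 / 2**10)

    @pytest.mark.parametrize("case_seed", [0, 1, 2, 3])
    def test_exact_p_matches_sign_enumeration_oracle(self, case_seed):
        rng = np.random.default_rng(case_seed)
        a = rng.normal(0.3, 1.0, 6)
        b = rng.normal(0.0, 1.0, 6)
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(wilcoxon_sign_enumeration_p(a - b), abs=1e-12)

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=15), rng.normal(size=15)
        perm = rng.permutation(15)
        assert wilcoxon_signed_rank(a, b) == wilcoxon_signed_rank(a[perm], b[perm])

    def test_all_zero_differences_warns_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            stat, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0
        assert "all differences zero" in caplog.text

    def test_zero_differences_dropped(self):
        # ties-with-self removed before ranking
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 1.0, 1.0, 4.0])
        stat, p = wilcoxon_signed_rank(a, b)
        stat2, p2 = wilcoxon_signed_rank(a[1:3], b[1:3])
        assert (stat, p) == (stat2, p2)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.5, 1, 1000)
        b = rng.normal(0.0, 1, 1000)
        _, p = wilcoxon_signed_rank(a, b)
        assert p < 1e-10


def mann_whitney_split_enumeration_p(a, b):
    """Oracle: exact two-sided p over all C(n_a+n_b, n_a) splits."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)

    def u_of(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    u_obs = u_of(a, b)
    mean_u = n_a * (n - n_a) / 2
    us = []
    for idx in itertools.combinations(range(n), n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        us.append(u_of(pooled[sel], pooled[~sel]))
    us = np.array(us)
    return np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)


class TestMannWhitneyU:
    def test_complete_separation_three_vs_three(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([10.0, 11.0, 12.0])
        u, p = mann_whitney_u(a, b)
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 3!3!/6!

    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        u, p = mann_whitney_u(x, x + 1e-9)
        assert p > 0.5
        assert u == pytest.approx(len(x) ** 2 / 2, rel=0.5)

    @pytest.mark.parametrize("sizes", [(3, 3), (4, 5), (6, 4)])
    def test_exact_p_matches_split_enumeration_oracle(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        a = rng.normal(0.5, 1.0, sizes[0])
        b = rng.normal(0.0, 1.0, sizes[1])
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(mann_whitney_split_enumeration_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestCallBinChanges:
    def test_zero_delta_no_calls(self):
        x = np.arange(10, dtype=float)
        calls = call_bin_changes(x, x.copy())
        assert (calls.n_gain, calls.n_loss) == (0, 0)

    def test_shift_invariance(self, rng):
        ct = rng.normal(size=500)
        kd = ct + rng.normal(size=500)
        base = call_bin_changes(ct, kd)
        shifted = call_bin_changes(ct + 100.0, kd + 100.0)
        assert (base.n_gain, base.n_loss) == (shifted.n_gain, shifted.n_loss)
        np.testing.assert_array_equal(base.labels, shifted.labels)

    def test_abs_delta_thresholding(self):
        ct = np.zeros(5)
        kd = np.array([0.0, 2.0, -2.0, 0.5, -0.5])
        calls = call_bin_changes(ct, kd, method="abs_delta", tau=1.0)
        assert list(calls.labels) == ["unchanged", "gain", "loss", "unchanged", "unchanged"]

    def test_mad_zero_falls_back_with_warning(self, caplog):
        ct = np.zeros(10)
        kd = np.zeros(10)
        kd[3] = 5.0
        with caplog.at_level("WARNING"):
            calls = call_bin_changes(ct, kd)
        assert "MAD is 0" in caplog.text
        assert calls.threshold_spec["method"] == "abs_delta"
        assert calls.n_gain == 1

    def test_robust_z_calls_extreme_bins_only(self, rng):
        delta = rng.normal(size=1000)
        ct = np.zeros(1000)
        kd = delta.copy()
        kd[:5] += 50.0
        calls = call_bin_changes(ct, kd, k=3.0)
        assert set(np.flatnonzero(calls.labels == "gain")) >= set(range(5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            call_bin_changes([1.0], [1.0, 2.0])

    def test_bed_export_contains_only_calls(self):
        layout = GenomeLayout((("c", 50_000),))
        grid = tile_genome(layout, 10_000)
        ct = np.zeros(5)
        kd = np.array([0.0, 3.0, 0.0, -3.0, 0.0])
        calls = call_bin_changes(ct, kd, method="abs_delta", tau=1.0)
        bed = calls.to_bed(grid.bins)
        assert bed.count("\n") == 2
        assert "gain" in bed and "loss" in bed
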