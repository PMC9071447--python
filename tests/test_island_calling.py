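"""Segmentation, region assignment, summaries, and two-group tests."""

import itertools

import numpy as np
import pytest

from axisislands.genome_model import GenomicInterval
from axisislands.island_calling import (
    RegionPartition,
    assign_regions,
    call_islands,
    compare_groups,
    region_summary,
)
from axisislands.signal_io import BinnedSignal, CoverageTrack

from conftest import make_binned


def brute_force_islands(scores_by_chrom, bin_size, k):
    """Independent re-derivation: SD, flags, run scan, label list per chrom."""
    pooled = np.concatenate(list(scores_by_chrom.values()))
    thr = k * np.sqrt(np.mean((pooled - pooled.mean()) ** 2))
    out = {}
    for chrom, scores in scores_by_chrom.items():
        labels = ["island" if s >= thr else "desert" for s in scores]
        regions = []
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            start = i * bin_size
            end = min(j * bin_size, len(scores) * bin_size)
            regions.append((start, end, labels[i]))
            i = j
        out[chrom] = regions
    return thr, out


def multi_chrom_binned(scores_by_chrom, bin_size=1000):
    intervals, scores, lengths = [], [], {}
    for chrom, s in scores_by_chrom.items():
        lengths[chrom] = bin_size * len(s)
        for i, v in enumerate(s):
            intervals.append(GenomicInterval(chrom, i * bin_size, (i + 1) * bin_size))
            scores.append(v)
    return BinnedSignal(bin_size, intervals, np.array(scores), lengths)


class TestCallIslands:
    def test_worked_example(self):
        binned = make_binned([0.5, 2.0, 2.2, 0.4])
        part = call_islands(binned, k=1.75)
        assert part.threshold_value == pytest.approx(1.4504, abs=1e-4)
        regions = [(iv.start, iv.end, lab) for iv, lab in part.regions]
        assert regions == [
            (0, 5000, "desert"),
            (5000, 15000, "island"),
            (15000, 20000, "desert"),
        ]

    def test_constant_scores_degenerate_warns(self):
        binned = make_binned([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="constant"):
            part = call_islands(binned)
        assert [(iv.start, iv.end, lab) for iv, lab in part.regions] == [
            (0, 15000, "island")
        ]

    def test_islands_never_merge_across_chromosomes(self):
        binned = multi_chrom_binned(
            {"chrI": np.array([0.1, 5.0]), "chrII": np.array([5.0, 0.1])}
        )
        part = call_islands(binned, k=1.0)
        islands = part.islands()
        assert len(islands) == 2
        assert {iv.chrom for iv in islands} == {"chrI", "chrII"}

    def test_matches_brute_force_on_random_genomes(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            scores_by_chrom = {
                f"chr{c}": rng.gamma(2.0, 1.0, size=rng.integers(1, 20))
                for c in range(rng.integers(1, 4))
            }
            if sum(len(s) for s in scores_by_chrom.values()) < 2:
                continue
            binned = multi_chrom_binned(scores_by_chrom)
            part = call_islands(binned, k=1.75)
            thr, expected = brute_force_islands(scores_by_chrom, 1000, 1.75)
            assert part.threshold_value == pytest.approx(thr, rel=1e-12)
            got = {}
            for iv, lab in part.regions:
                got.setdefault(iv.chrom, []).append((iv.start, iv.end, lab))
            assert got == expected

    def test_raising_k_shrinks_islands(self):
        rng = np.random.default_rng(5)
        scores = rng.gamma(2.0, 1.0, size=40)
        binned = make_binned(scores, bin_size=1000)
        prev = None
        for k in (0.5, 1.0, 1.75, 2.5):
            bp = sum(iv.length for iv in call_islands(binned, k=k).islands())
            if prev is not None:
                assert bp <= prev
            prev = bp

    def test_empty_signal_rejected(self):
        binned = make_binned([1.0])
        with pytest.raises(ValueError, match="2 bins"):
            call_islands(binned)


class TestPartitionInvariants:
    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            RegionPartition(
                [(GenomicInterval("c", 0, 5000), "island"),
                 (GenomicInterval("c", 6000, 10000), "desert")],
                5000, 1.75, 1.0, {"c": 10000},
            )

    def test_incomplete_tiling_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            RegionPartition(
                [(GenomicInterval("c", 0, 5000), "island")],
                5000, 1.75, 1.0, {"c": 10000},
            )

    def test_unmerged_adjacent_labels_rejected(self):
        with pytest.raises(ValueError, match="not merged"):
            RegionPartition(
                [(GenomicInterval("c", 0, 5000), "island"),
                 (GenomicInterval("c", 5000, 10000), "island")],
                5000, 1.75, 1.0, {"c": 10000},
            )


class TestAssignRegions:
    def test_midpoint_rule(self, two_region_partition):
        labels = assign_regions(
            [
                GenomicInterval("chrI", 4900, 5100),  # midpoint 5000 -> desert
                GenomicInterval("chrI", 1000, 2000),
                GenomicInterval("chrI", 9999, 10000),  # last bp of genome
            ],
            two_region_partition,
        )
        assert labels == ["desert", "island", "desert"]


class TestRegionSummary:
    def test_region_means(self, two_region_partition):
        v = np.concatenate([np.full(5000, 2.0), np.full(5000, 1.0)])
        track = CoverageTrack({"chrI": 10000}, {"chrI": v})
        stats = region_summary(two_region_partition, track=track)
        means = dict(zip(stats.per_region["label"], stats.per_region["mean_signal"]))
        assert means == {"island": pytest.approx(2.0), "desert": pytest.approx(1.0)}

    def test_features_per_kb(self):
        part = RegionPartition(
            [(GenomicInterval("c", 0, 15000), "island"),
             (GenomicInterval("c", 15000, 30000), "desert")],
            5000, 1.75, 1.0, {"c": 30000},
        )
        feats = [GenomicInterval("c", s, s + 100) for s in (1000, 5000, 9000)]
        stats = region_summary(part, features=feats)
        row = stats.per_region.set_index("label").loc["island"]
        assert row["feature_count"] == 3
        assert row["features_per_kb"] == pytest.approx(0.2)

    def test_empty_group_flagged_not_zero(self, two_region_partition):
        # partition with only one label present: build a desert-only genome
        part = RegionPartition(
            [(GenomicInterval("c", 0, 10000), "desert")],
            5000, 1.75, 1.0, {"c": 10000},
        )
        track = CoverageTrack({"c": 10000}, {"c": np.ones(10000)})
        stats = region_summary(part, track=track)
        isl = stats.group_summary.set_index("label").loc["island"]
        assert not isl["defined"] and np.isnan(isl["mean_signal_median"])

    def test_means_match_per_bp_loop_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n_bins = int(rng.integers(2, 12))
            binned = make_binned(rng.gamma(2, 1, n_bins), bin_size=100)
            part = call_islands(binned, k=1.0)
            v = rng.gamma(2, 1, n_bins * 100)
            track = CoverageTrack({"chrI": n_bins * 100}, {"chrI": v})
            stats = region_summary(part, track=track)
            for _, row in stats.per_region.iterrows():
                expected = v[row["start"] : row["end"]].mean()
                assert row["mean_signal"] == pytest.approx(expected, rel=1e-12)


def enumeration_p(a, b):
    """Oracle: two-sided exact Mann-Whitney p by pairwise-win counting."""
    pooled = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)

    def u_of(idx):
        inside = set(idx)
        u = 0.0
        for i in inside:
            for j in range(n):
                if j in inside:
                    continue
                if pooled[i] > pooled[j]:
                    u += 1.0
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    center = n1 * (n - n1) / 2
    obs = abs(u_of(range(n1)) - center)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestCompareGroups:
    def test_exact_example(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], "mann_whitney")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        res = compare_groups([1, 2, 3], [3, 1, 2], "mann_whitney")
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_constant_groups_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            res = compare_groups([2, 2], [2, 2, 2], "mann_whitney")
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n1 = int(rng.integers(1, 5))
            n2 = int(rng.integers(1, 5))
            a = rng.integers(0, 4, n1).astype(float)
            b = rng.integers(0, 4, n2).astype(float)
            if len(np.unique(np.concatenate([a, b]))) == 1:
                continue
            res = compare_groups(a, b, "mann_whitney")
            assert res.p_value == pytest.approx(enumeration_p(a, b), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        res = compare_groups(a, b, "mann_whitney")
        from scipy import stats as ss

        ref = ss.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_welch_t(self):
        res = compare_groups([1.0, 2.0, 3.0], [2.0, 4.0, 6.0, 8.0], "welch_t")
        from scipy import stats as ss

        t, p = ss.ttest_ind([1, 2, 3], [2, 4, 6, 8], equal_var=False)
        assert res.statistic == pytest.approx(float(t))
        assert res.p_value == pytest.approx(float(p))

    def test_welch_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="variance"):
            res = compare_groups([0.0, 0.0], [0.0, 0.0], "welch_t")
        assert res.p_value == 1.0
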