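"""Island/desert segmentation and region-level statistics.

The genome is tiled with fixed bins (5 kb by default) scored by mean
signal. Bins scoring at or above ``k`` times the genome-wide standard
deviation of bin scores (k = 1.75 by default) are *enriched*; maximal
runs of enriched bins form **islands** (axis-protein over-enriched
regions) and everything else forms **deserts**. The partition is
exhaustive and disjoint, and island joining never crosses a chromosome
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomicInterval
from .signal_io import BinnedSignal, CoverageTrack

ISLAND = "island"
DESERT = "desert"


@dataclass
class RegionPartition:
    """Exhaustive, disjoint island/desert labeling of a genome.

    Invariants (checked on construction): per chromosome the regions are
    sorted, contiguous, tile [0, length) exactly, and adjacent regions
    carry different labels (maximality).
    """

    regions: list[tuple[GenomicInterval, str]]
    bin_size: int
    k: float
    threshold_value: float
    chrom_lengths: dict[str, int]
    _starts: dict[str, np.ndarray] = field(init=False, repr=False)
    _labels: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {
            c: [] for c in self.chrom_lengths
        }
        for iv, label in self.regions:
            if label not in (ISLAND, DESERT):
                raise ValueError(f"unknown region label {label!r}")
            by_chrom[iv.chrom].append((iv, label))
        self._starts = {}
        self._labels = {}
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: r[0].start)
            pos = 0
            for i, (iv, label) in enumerate(rs):
                if iv.start != pos:
                    raise ValueError(f"partition gap/overlap at {chrom}:{pos}")
                if i > 0 and rs[i - 1][1] == label:
                    raise ValueError(f"adjacent {label} regions on {chrom} not merged")
                pos = iv.end
            if pos != self.chrom_lengths[chrom]:
                raise ValueError(f"partition does not tile {chrom} (ends at {pos})")
            self._starts[chrom] = np.array([iv.start for iv, _ in rs], dtype=np.int64)
            self._labels[chrom] = [label for _, label in rs]

    def label_at(self, chrom: str, pos: int) -> str:
        if chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        return self._labels[chrom][i]

    def islands(self) -> list[GenomicInterval]:
        return [iv for iv, label in self.regions if label == ISLAND]

    def deserts(self) -> list[GenomicInterval]:
        return [iv for iv, label in self.regions if label == DESERT]


@dataclass
class RegionStats:
    """Per-region table plus island/desert group summaries."""

    per_region: pd.DataFrame
    group_summary: pd.DataFrame


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int


def call_islands(
    binned: BinnedSignal, k: float = 1.75, threshold_mode: str = "sd"
) -> RegionPartition:
    """Segment the genome into islands and deserts by thresholding bin scores.

    threshold = k * population SD of all bin scores genome-wide
    (``threshold_mode="mean_plus_sd"`` adds the genome-wide mean).
    A bin is enriched iff score >= threshold; maximal runs of enriched
    bins within a chromosome become islands.
    """
    scores = binned.scores
    if scores.size < 2:
        raise ValueError("need at least 2 bins genome-wide")
    if not k > 0:
        raise ValueError("k must be > 0")
    sd = float(scores.std(ddof=0))
    threshold = k * sd
    if threshold_mode == "mean_plus_sd":
        threshold += float(scores.mean())
    elif threshold_mode != "sd":
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    if sd == 0.0:
        warnings.warn(
            "bin scores are constant (SD = 0); every bin is enriched and each "
            "chromosome becomes a single island",
            stacklevel=2,
        )

    regions: list[tuple[GenomicInterval, str]] = []
    for chrom, (ivs, chrom_scores) in binned.by_chrom().items():
        if not ivs:
            continue
        enriched = chrom_scores >= threshold
        run_start = 0
        for i in range(1, len(ivs) + 1):
            if i == len(ivs) or enriched[i] != enriched[run_start]:
                iv = GenomicInterval(chrom, ivs[run_start].start, ivs[i - 1].end)
                regions.append((iv, ISLAND if enriched[run_start] else DESERT))
                run_start = i
    return RegionPartition(
        regions, binned.bin_size, k, threshold, dict(binned.chrom_lengths)
    )


def assign_regions(
    features: Sequence[GenomicInterval], partition: RegionPartition
) -> list[str]:
    """Label each feature by the region containing its midpoint."""
    return [partition.label_at(f.chrom, f.midpoint) for f in features]


def _region_means(track: CoverageTrack, partition: RegionPartition) -> np.ndarray:
    cums = {c: np.concatenate(([0.0], np.cumsum(v))) for c, v in track.values.items()}
    means = np.empty(len(partition.regions))
    for i, (iv, _) in enumerate(partition.regions):
        cs = cums[iv.chrom]
        means[i] = (cs[iv.end] - cs[iv.start]) / iv.length
    return means


def region_summary(
    partition: RegionPartition,
    track: CoverageTrack | None = None,
    features: Sequence[GenomicInterval] | None = None,
    feature_values: Sequence[float] | None = None,
) -> RegionStats:
    """Region-level means, feature counts/densities, and group summaries.

    With a track: mean per-bp signal per region. With features: count and
    features-per-kb per region; with ``feature_values`` additionally the
    mean of the per-feature values assigned to each region (midpoint
    rule). Empty groups are flagged ``defined = False`` with NaN
    summaries rather than silent zeros.
    """
    rows = []
    for iv, label in partition.regions:
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "label": label,
                "length": iv.length,
            }
        )
    df = pd.DataFrame(rows)

    if track is not None:
        df["mean_signal"] = _region_means(track, partition)

    if features is not None:
        counts = np.zeros(len(partition.regions), dtype=int)
        vsums = np.zeros(len(partition.regions))
        # map region -> index for assignment by midpoint
        index: dict[tuple[str, int], int] = {
            (iv.chrom, iv.start): i for i, (iv, _) in enumerate(partition.regions)
        }
        starts = partition._starts
        for j, f in enumerate(features):
            mid = f.midpoint
            i = int(np.searchsorted(starts[f.chrom], mid, side="right")) - 1
            ridx = index[(f.chrom, int(starts[f.chrom][i]))]
            counts[ridx] += 1
            if feature_values is not None:
                vsums[ridx] += feature_values[j]
        df["feature_count"] = counts
        df["features_per_kb"] = counts / (df["length"] / 1000.0)
        if feature_values is not None:
            with np.errstate(invalid="ignore"):
                df["feature_value_mean"] = np.where(counts > 0, vsums / counts, np.nan)

    summaries = []
    value_cols = [c for c in ("mean_signal", "features_per_kb", "feature_value_mean") if c in df]
    for label in (ISLAND, DESERT):
        sub = df[df["label"] == label]
        row = {
            "label": label,
            "n_regions": len(sub),
            "total_length": int(sub["length"].sum()),
            "defined": len(sub) > 0,
        }
        for col in value_cols:
            vals = sub[col].dropna()
            row[f"{col}_median"] = vals.median() if len(vals) else np.nan
            row[f"{col}_q1"] = vals.quantile(0.25) if len(vals) else np.nan
            row[f"{col}_q3"] = vals.quantile(0.75) if len(vals) else np.nan
        summaries.append(row)
    return RegionStats(df, pd.DataFrame(summaries))


def _mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for group a, ties counting one half."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2)


def _exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group assignments.

    The null distribution of U is symmetric about n1*n2/2 (swapping the
    groups maps U to n1*n2 - U), so the two-sided p-value is the
    probability of a U at least as far from n1*n2/2 as observed; ties
    are handled because ranks are recomputed on the pooled sample.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    center = n1 * (n - n1) / 2
    offset = n1 * (n1 + 1) / 2
    obs = abs(_mannwhitney_u(a, b) - center)
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - center) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def compare_groups(a, b, test: str = "mann_whitney", exact_max_n: int = 12) -> TestResult:
    """Two-sided two-group comparison.

    ``mann_whitney``: exact enumeration when n1+n2 <= ``exact_max_n``
    (handles ties), otherwise the normal approximation with tie
    correction. ``welch_t``: unequal-variance t-test. Degenerate inputs
    (all values identical across both groups) return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if test == "mann_whitney":
        if n1 < 1 or n2 < 1:
            raise ValueError("mann_whitney requires n1, n2 >= 1")
        u = _mannwhitney_u(a, b)
        if np.unique(np.concatenate([a, b])).size == 1:
            warnings.warn("all values identical in both groups; p = 1", stacklevel=2)
            return TestResult(test, u, 1.0, n1, n2)
        if n1 + n2 <= exact_max_n:
            p = _exact_mannwhitney_p(a, b)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            p = float(res.pvalue)
        return TestResult(test, u, min(p, 1.0), n1, n2)
    if test == "welch_t":
        if n1 < 2 or n2 < 2:
            raise ValueError("welch_t requires n1, n2 >= 2")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            warnings.warn("zero variance in both groups", stacklevel=2)
            p = 1.0 if a.mean() == b.mean() else 0.0
            return TestResult(test, 0.0 if a.mean() == b.mean() else np.inf, p, n1, n2)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return TestResult(test, float(t), float(p), n1, n2)
    raise ValueError(f"unknown test {test!r}")


def write_partition_bed(
    partition: RegionPartition, path, track: CoverageTrack | None = None
) -> None:
    """Write the partition as BED6 (name = label, score = mean signal)."""
    from .genome_model import write_regions_bed

    scores = _region_means(track, partition) if track is not None else None
    write_regions_bed(path, partition.regions, scores)
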