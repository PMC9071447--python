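"""Anchor-centered profiles, metagenes, bootstrap CIs, hotspot statistics.

The workhorse object is the :class:`ProfileMatrix`: one row of per-bp
signal per retained anchor (axis site, hotspot midpoint, gene ATG, ...),
columns at fixed positions relative to the anchor. Mean profiles carry
95% confidence bands from bootstrap resampling of anchors (1000
resamples by default), the resampling unit being the anchor so that
between-locus variation drives the interval width.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome_model import Gene, GenomicInterval
from .island_calling import RegionPartition, assign_regions
from .signal_io import CoverageTrack

logger = logging.getLogger(__name__)


class Anchor(NamedTuple):
    id: str
    chrom: str
    pos: int
    strand: str = "."


@dataclass
class AnchorSet:
    anchors: list[Anchor]
    kind: str = "custom"

    def __len__(self) -> int:
        return len(self.anchors)


def read_anchors_bed(path, kind: str = "custom") -> AnchorSet:
    """BED6 -> anchors at interval midpoints (BED4 accepted, unstranded)."""
    anchors: list[Anchor] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"anchor{lineno}"
            strand = f[5] if len(f) > 5 else "."
            anchors.append(Anchor(name, chrom, (start + end) // 2, strand))
    return AnchorSet(anchors, kind)


@dataclass
class ProfileMatrix:
    """Anchors x relative positions signal matrix with row metadata."""

    values: np.ndarray  # (n_anchors, n_positions)
    positions: np.ndarray  # relative coordinates of columns
    row_meta: pd.DataFrame  # at least column "id"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("profile values must be 2-D")
        if len(self.row_meta) != self.values.shape[0]:
            raise ValueError("row_meta/values row mismatch")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset(self, mask) -> "ProfileMatrix":
        mask = np.asarray(mask)
        return ProfileMatrix(
            self.values[mask],
            self.positions,
            self.row_meta[mask].reset_index(drop=True),
            self.n_dropped,
        )


@dataclass
class MeanProfileCI:
    positions: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_boot: int
    level: float
    seed: int | None
    n_rows: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean": self.mean,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


@dataclass
class HotspotStats:
    per_hotspot: pd.DataFrame
    group_medians: pd.DataFrame


def anchor_matrix(
    track: CoverageTrack,
    anchors: AnchorSet,
    flank: int,
    strand_aware: bool = True,
    region_labels: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Extract [pos - flank, pos + flank) windows around each anchor.

    Rows for minus-strand anchors are reversed when ``strand_aware``.
    Windows extending past a chromosome end are dropped (counted and
    logged) so that every column keeps the same sample size.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    rows, meta, dropped = [], [], 0
    for i, a in enumerate(anchors.anchors):
        L = track.chrom_lengths.get(a.chrom)
        if L is None:
            raise ValueError(f"anchor {a.id} on unknown chromosome {a.chrom!r}")
        lo, hi = a.pos - flank, a.pos + flank
        if lo < 0 or hi > L:
            dropped += 1
            continue
        row = track.values[a.chrom][lo:hi]
        if strand_aware and a.strand == "-":
            row = row[::-1]
        rows.append(row)
        m = {"id": a.id, "chrom": a.chrom, "pos": a.pos, "strand": a.strand}
        if region_labels is not None:
            m["region"] = region_labels[i]
        meta.append(m)
    if dropped:
        logger.info("anchor_matrix: dropped %d out-of-bounds windows", dropped)
    if not rows:
        raise ValueError("no anchors retained (all windows out of bounds)")
    return ProfileMatrix(
        np.vstack(rows), np.arange(-flank, flank), pd.DataFrame(meta), dropped
    )


def genescaled_matrix(
    track: CoverageTrack,
    genes: Sequence[Gene],
    body_bins: int,
    flank: int,
) -> ProfileMatrix:
    """Length-scaled metagene rows: real-bp flanks around a rescaled body.

    Each gene body is divided into ``body_bins`` equal sub-intervals
    scored by mean signal; flanks are taken in real bp. Minus-strand
    genes are reversed so rows read 5' -> 3'. Genes shorter than
    ``body_bins`` or with out-of-bounds flanks are dropped (logged).
    """
    if body_bins < 2:
        raise ValueError("body_bins must be >= 2")
    rows, meta, dropped = [], [], 0
    for g in genes:
        iv = g.interval
        L = track.chrom_lengths[iv.chrom]
        if iv.length < body_bins or iv.start - flank < 0 or iv.end + flank > L:
            dropped += 1
            continue
        v = track.values[iv.chrom]
        edges = np.linspace(iv.start, iv.end, body_bins + 1)
        body = np.empty(body_bins)
        for j in range(body_bins):
            s, e = int(np.floor(edges[j])), int(np.floor(edges[j + 1]))
            e = max(e, s + 1)
            body[j] = v[s:e].mean()
        row = np.concatenate([v[iv.start - flank : iv.start], body, v[iv.end : iv.end + flank]])
        if iv.strand == "-":
            row = row[::-1]
        rows.append(row)
        meta.append({"id": g.id, "chrom": iv.chrom, "strand": iv.strand, "width": iv.length})
    if dropped:
        logger.info("genescaled_matrix: dropped %d genes", dropped)
    if not rows:
        raise ValueError("no genes retained")
    positions = np.arange(-flank, body_bins + flank)  # body columns are bin indices
    return ProfileMatrix(np.vstack(rows), positions, pd.DataFrame(meta), dropped)


def mean_profile_ci(
    matrix: ProfileMatrix,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> MeanProfileCI:
    """Column means with percentile bootstrap confidence bands.

    Rows (anchors) are resampled with replacement ``n_boot`` times; the
    CI at each column is the (alpha/2, 1 - alpha/2) percentile interval
    of the resampled column means, clipped to contain the sample mean.
    Deterministic given ``seed``.
    """
    n = matrix.n_rows
    if n < 1:
        raise ValueError("need at least one row")
    mean = matrix.values.mean(axis=0)
    if n == 1:
        warnings.warn("single row: CI degenerates to the row itself", stacklevel=2)
        return MeanProfileCI(
            matrix.positions, mean, mean.copy(), mean.copy(), n_boot, level, seed, n
        )
    rng = np.random.default_rng(seed)
    ncol = matrix.values.shape[1]
    boot = np.empty((n_boot, ncol))
    # chunked so the (chunk, n, ncol) gather stays small
    chunk = max(1, int(5e7 // max(1, n * ncol)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        boot[done : done + b] = matrix.values[idx].mean(axis=1)
        done += b
    alpha = 1.0 - level
    lo = np.quantile(boot, alpha / 2, axis=0)
    hi = np.quantile(boot, 1 - alpha / 2, axis=0)
    return MeanProfileCI(
        matrix.positions,
        mean,
        np.minimum(lo, mean),
        np.maximum(hi, mean),
        n_boot,
        level,
        seed,
        n,
    )


def hotspot_stats(
    track: CoverageTrack,
    hotspots: Sequence[GenomicInterval],
    partition: RegionPartition | None = None,
) -> HotspotStats:
    """Width, total signal, and per-bp signal density for each hotspot.

    With a partition, hotspots are labeled island/desert (midpoint rule)
    and per-group medians are reported.
    """
    cums = {c: np.concatenate(([0.0], np.cumsum(v))) for c, v in track.values.items()}
    rows = []
    for i, h in enumerate(hotspots):
        cs = cums[h.chrom]
        total = float(cs[h.end] - cs[h.start])
        rows.append(
            {
                "id": f"hs{i}",
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "width": h.length,
                "total_signal": total,
                "signal_per_bp": total / h.length,
            }
        )
    df = pd.DataFrame(rows)
    if partition is not None and len(df):
        df["region"] = assign_regions(hotspots, partition)
        med = (
            df.groupby("region")[["width", "total_signal", "signal_per_bp"]]
            .median()
            .reset_index()
        )
    else:
        med = pd.DataFrame()
    return HotspotStats(df, med)


def sort_rows_by_width(matrix: ProfileMatrix) -> ProfileMatrix:
    """Rows in ascending width order; width ties broken by anchor id."""
    if "width" not in matrix.row_meta:
        raise ValueError("row_meta lacks a 'width' column")
    meta = matrix.row_meta
    order = np.lexsort((meta["id"].to_numpy(), meta["width"].to_numpy()))
    return ProfileMatrix(
        matrix.values[order],
        matrix.positions,
        meta.iloc[order].reset_index(drop=True),
        matrix.n_dropped,
    )
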