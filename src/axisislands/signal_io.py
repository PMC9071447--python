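"""Per-bp coverage tracks: bedGraph/wiggle IO, binning, scaling, ratios.

A :class:`CoverageTrack` stores dense per-bp, finite, non-negative signal
for every chromosome — typically a ChIP/input fold-enrichment track.
Positions not covered by any input record are 0. Binning into fixed
windows (5 kb by default) produces the :class:`BinnedSignal` consumed by
island/desert segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .genome_model import GenomicInterval, read_chrom_sizes


@dataclass
class CoverageTrack:
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.chrom_lengths) != set(self.values):
            raise ValueError("values and chrom_lengths cover different chromosomes")
        for chrom, L in self.chrom_lengths.items():
            v = np.asarray(self.values[chrom], dtype=np.float64)
            if v.shape != (L,):
                raise ValueError(
                    f"{chrom}: {v.shape[0]} values for a {L} bp chromosome"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{chrom}: non-finite signal values")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative signal values")
            self.values[chrom] = v

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    def genome_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.values.values())
        return total / self.genome_size


@dataclass
class BinnedSignal:
    """Fixed-width tiling of the genome with mean per-bp signal per bin.

    The last bin of each chromosome may be short; its score is the mean
    over the available base pairs.
    """

    bin_size: int
    intervals: list[GenomicInterval]
    scores: np.ndarray
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.intervals) != len(self.scores):
            raise ValueError("intervals/scores length mismatch")

    def by_chrom(self) -> dict[str, tuple[list[GenomicInterval], np.ndarray]]:
        out: dict[str, tuple[list[GenomicInterval], np.ndarray]] = {}
        for chrom in self.chrom_lengths:
            idx = [i for i, iv in enumerate(self.intervals) if iv.chrom == chrom]
            out[chrom] = ([self.intervals[i] for i in idx], self.scores[idx])
        return out


def _resolve_sizes(chrom_sizes) -> dict[str, int]:
    if isinstance(chrom_sizes, (str, Path)):
        return read_chrom_sizes(chrom_sizes)
    return dict(chrom_sizes)


def zero_track(chrom_sizes: Mapping[str, int] | str | Path) -> CoverageTrack:
    sizes = _resolve_sizes(chrom_sizes)
    return CoverageTrack(sizes, {c: np.zeros(L) for c, L in sizes.items()})


def read_track(path: str | Path, chrom_sizes) -> CoverageTrack:
    """Read a bedGraph or wiggle file into a dense per-bp track.

    Unspecified positions are filled with 0. Overlapping bedGraph records,
    negative values and unknown chromosomes are hard errors. The wiggle
    reader supports fixedStep and variableStep with span.
    """
    sizes = _resolve_sizes(chrom_sizes)
    values = {c: np.zeros(L) for c, L in sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}

    def put(chrom: str, start: int, end: int, value: float, lineno: int) -> None:
        if chrom not in sizes:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if value < 0:
            raise ValueError(f"{path}:{lineno}: negative signal value {value}")
        if start < 0 or end > sizes[chrom] or start >= end:
            raise ValueError(
                f"{path}:{lineno}: interval {chrom}:{start}-{end} out of bounds"
            )
        if covered[chrom][start:end].any():
            raise ValueError(f"{path}:{lineno}: overlapping records at {chrom}:{start}")
        covered[chrom][start:end] = True
        values[chrom][start:end] = value

    mode = "bedgraph"
    chrom = ""
    step = span = 1
    pos = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    step = int(fields.get("step", 1))
                    pos = int(fields["start"]) - 1  # wiggle is 1-based
                else:
                    mode = "variable"
                continue
            f = line.split()
            if mode == "fixed":
                put(chrom, pos, pos + span, float(f[0]), lineno)
                pos += step
            elif mode == "variable":
                p = int(f[0]) - 1
                put(chrom, p, p + span, float(f[1]), lineno)
            else:
                if len(f) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                put(f[0], int(f[1]), int(f[2]), float(f[3]), lineno)
    return CoverageTrack(sizes, values)


def write_track(track: CoverageTrack, path: str | Path) -> None:
    """Write as sorted 4-column bedGraph, merging equal-value runs.

    Zero runs are omitted; the reader's fill-with-0 rule restores them.
    """
    with open(path, "w") as fh:
        for chrom in track.chrom_lengths:
            v = track.values[chrom]
            if v.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(v) != 0) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [v.size]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.10g}\n")


def bin_signal(track: CoverageTrack, bin_size: int = 5000) -> BinnedSignal:
    """Tile each chromosome with ``bin_size`` windows scored by mean signal."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    intervals: list[GenomicInterval] = []
    scores: list[float] = []
    for chrom, L in track.chrom_lengths.items():
        v = track.values[chrom]
        starts = np.arange(0, L, bin_size)
        sums = np.add.reduceat(v, starts)
        ends = np.minimum(starts + bin_size, L)
        widths = ends - starts
        for s, e, total, w in zip(starts, ends, sums, widths):
            intervals.append(GenomicInterval(chrom, int(s), int(e)))
            scores.append(float(total) / int(w))
    return BinnedSignal(bin_size, intervals, np.asarray(scores), dict(track.chrom_lengths))


def scale_track(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Multiply every value by a positive factor (e.g. a spike-in scalar)."""
    if not factor > 0:
        raise ValueError("scale factor must be > 0")
    return CoverageTrack(
        dict(track.chrom_lengths),
        {c: v * factor for c, v in track.values.items()},
    )


def ratio_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    pseudocount: float = 0.0,
) -> CoverageTrack:
    """Per-bp fold enrichment (num + pc) / (den + pc).

    With the default pseudocount of 0, any zero in the denominator is a
    hard error — an explicit pseudocount is an analysis decision, not a
    silent default.
    """
    if numerator.chrom_lengths != denominator.chrom_lengths:
        raise ValueError("tracks are on different genomes")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    out = {}
    for chrom in numerator.chrom_lengths:
        den = denominator.values[chrom] + pseudocount
        if np.any(den == 0):
            raise ValueError(
                f"zero denominator on {chrom} with pseudocount {pseudocount}"
            )
        out[chrom] = (numerator.values[chrom] + pseudocount) / den
    return CoverageTrack(dict(numerator.chrom_lengths), out)
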