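"""Genome annotations: intervals, genes, gene pairs, coding density, GC content.

All coordinates are 0-based, half-open (BED convention). GFF3 input
(1-based, inclusive) is converted on read. A :class:`GenomeAnnotation`
is the substrate for every region- and gene-level statistic in the
package: coding density of windows, convergent/tandem/divergent
intergenic classification, and gene anchors for profile analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

# pair_class is determined solely by the strands of the flanking genes:
# (+,-) converge head-to-head, (-,+) diverge, equal strands read in tandem.
_PAIR_CLASS = {
    ("+", "-"): "convergent",
    ("-", "+"): "divergent",
    ("+", "+"): "tandem",
    ("-", "-"): "tandem",
}


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Gene:
    """A stranded gene (ORF-level; no exon structure)."""

    id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id} must be stranded (+ or -)")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus genes sorted by (chrom, start).

    Chromosome order follows insertion order of ``chrom_lengths``; genes
    are kept sorted within each chromosome.
    """

    chrom_lengths: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            L = self.chrom_lengths.get(g.interval.chrom)
            if L is None:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.interval.chrom}")
            if g.interval.end > L:
                raise ValueError(
                    f"gene {g.id} extends past end of {g.interval.chrom} ({L} bp)"
                )
        order = {c: i for i, c in enumerate(self.chrom_lengths)}
        self.genes.sort(key=lambda g: (order[g.interval.chrom], g.interval.start, g.id))

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {c: [] for c in self.chrom_lengths}
        for g in self.genes:
            out[g.interval.chrom].append(g)
        return out


@dataclass(frozen=True)
class GenePair:
    """Adjacent gene pair and the intergenic region between them.

    ``intergenic`` is None when the genes touch or overlap; such pairs
    keep their class but are excluded from intergenic-size statistics.
    """

    left: Gene
    right: Gene
    pair_class: str
    intergenic: GenomicInterval | None

    @property
    def intergenic_length(self) -> int:
        return 0 if self.intergenic is None else self.intergenic.length


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected 'chrom<TAB>length'")
            chrom, length = parts[0], parts[1]
            if chrom in sizes:
                raise ValueError(f"{path}:{i}: duplicate chromosome {chrom}")
            sizes[chrom] = int(length)
    return sizes


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().rstrip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(
    path: str | Path,
    chrom_sizes: str | Path | Mapping[str, int],
    feature_type: str = "gene",
    id_filter=None,
) -> GenomeAnnotation:
    """Read a GFF3 or BED6 gene annotation against a chrom.sizes file.

    Parameters
    ----------
    path
        GFF3 (``.gff``/``.gff3``) or BED (anything else). GFF3 records are
        filtered to ``feature_type`` (column 3) and must carry an ``ID`` or
        ``Name`` attribute; coordinates are converted to 0-based half-open.
    chrom_sizes
        chrom.sizes path or a mapping chromosome -> length.
    feature_type
        GFF3 feature type to retain ("gene" by default; use "ORF" etc. for
        other annotation styles). Ignored for BED input.
    id_filter
        Optional predicate on the gene id; records for which it returns
        False are dropped (e.g. to exclude dubious ORFs).
    """
    if isinstance(chrom_sizes, (str, Path)):
        sizes = read_chrom_sizes(chrom_sizes)
    else:
        sizes = dict(chrom_sizes)

    path = Path(path)
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if is_gff:
                    if len(f) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    if f[2] != feature_type:
                        continue
                    chrom, strand = f[0], f[6]
                    start = int(f[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(f[4])
                    attrs = _parse_gff3_attributes(f[8])
                    gid = attrs.get("ID") or attrs.get("Name")
                    if gid is None:
                        raise ValueError("record lacks ID/Name attribute")
                else:
                    if len(f) < 6:
                        raise ValueError("expected 6 BED columns")
                    chrom, gid, strand = f[0], f[3], f[5]
                    start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed line ({e})") from e
            if chrom not in sizes:
                raise ValueError(
                    f"{path}:{lineno}: record {gid!r} on chromosome {chrom!r} "
                    "absent from chrom.sizes"
                )
            if id_filter is not None and not id_filter(gid):
                continue
            genes.append(Gene(gid, GenomicInterval(chrom, start, end, strand)))
    return GenomeAnnotation(sizes, genes)


def gene_pairs(annotation: GenomeAnnotation) -> list[GenePair]:
    """All consecutive same-chromosome gene pairs with intergenic class.

    Adjacency is by start-coordinate order; overlapping/touching pairs are
    retained with ``intergenic=None``.
    """
    pairs: list[GenePair] = []
    for genes in annotation.genes_by_chrom().values():
        for left, right in zip(genes, genes[1:]):
            cls = _PAIR_CLASS[(left.interval.strand, right.interval.strand)]
            if left.interval.end < right.interval.start:
                inter = GenomicInterval(
                    left.interval.chrom, left.interval.end, right.interval.start
                )
            else:
                inter = None
            pairs.append(GenePair(left, right, cls, inter))
    return pairs


def merged_gene_intervals(annotation: GenomeAnnotation) -> dict[str, np.ndarray]:
    """Union of gene intervals per chromosome as an (n, 2) int array."""
    out: dict[str, np.ndarray] = {}
    for chrom, genes in annotation.genes_by_chrom().items():
        merged: list[list[int]] = []
        for g in genes:
            s, e = g.interval.start, g.interval.end
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64).reshape(-1, 2)
    return out


def coding_density(
    annotation: GenomeAnnotation, bins: Sequence[GenomicInterval]
) -> np.ndarray:
    """Fraction of each bin's base pairs covered by the union of genes.

    Overlapping genes are counted once. Bins on chromosomes absent from
    the annotation's chrom_lengths raise.
    """
    merged = merged_gene_intervals(annotation)
    dens = np.empty(len(bins), dtype=float)
    for i, b in enumerate(bins):
        if b.chrom not in annotation.chrom_lengths:
            raise ValueError(f"bin on unknown chromosome {b.chrom!r}")
        if b.end > annotation.chrom_lengths[b.chrom]:
            raise ValueError(f"bin {b.chrom}:{b.start}-{b.end} out of bounds")
        iv = merged.get(b.chrom)
        if iv is None or len(iv) == 0:
            dens[i] = 0.0
            continue
        covered = np.minimum(iv[:, 1], b.end) - np.maximum(iv[:, 0], b.start)
        dens[i] = covered[covered > 0].sum() / b.length
    return dens


def gc_content(sequence, regions: Sequence[GenomicInterval]) -> np.ndarray:
    """GC fraction of each region, ambiguous bases excluded from the denominator.

    ``sequence`` is a FASTA path, a ``pyfaidx.Fasta``, or a mapping
    chromosome -> sequence string. Case-insensitive.
    """
    if isinstance(sequence, (str, Path)):
        import pyfaidx

        sequence = pyfaidx.Fasta(str(sequence))

    def fetch(chrom: str, start: int, end: int) -> str:
        rec = sequence[chrom]
        if isinstance(rec, str):
            seq, chrom_len = rec[start:end], len(rec)
        else:  # pyfaidx record
            chrom_len = len(rec)
            seq = rec[start:end].seq
        if end > chrom_len:
            raise ValueError(f"region {chrom}:{start}-{end} beyond sequence length")
        return seq

    out = np.empty(len(regions), dtype=float)
    for i, r in enumerate(regions):
        seq = fetch(r.chrom, r.start, r.end).upper()
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        out[i] = np.nan if gc + at == 0 else gc / (gc + at)
    return out


def write_regions_bed(path: str | Path, regions: Iterable, scores=None) -> None:
    """Write (GenomicInterval, name) pairs as BED6; score column optional."""
    regions = list(regions)
    if scores is None:
        scores = [0.0] * len(regions)
    with open(path, "w") as fh:
        for (iv, name), score in zip(regions, scores):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:.6g}\t{iv.strand}\n"
            )
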