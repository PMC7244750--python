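"""Interval algebra, gene models and closest-gene annotation.

All in-memory coordinates are 0-based, half-open (BED convention). GTF on
disk is 1-based inclusive and converted on read/write.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace

__all__ = [
    "Interval",
    "GeneModel",
    "GenomeAnnotation",
    "overlaps",
    "overlap_length",
    "merge_intervals",
    "nearest_tss",
    "annotate_feature",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval (0-based start, half-open end)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene with a single TSS; exons lie within the gene body."""

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.gene_start < self.gene_end):
            raise ValueError(f"invalid gene body for {self.gene_id}")
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.start < self.gene_start or ex.end > self.gene_end:
                raise ValueError(f"exon {ex} outside gene body of {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.gene_start, self.gene_end, name=self.gene_id)


class GenomeAnnotation:
    """Chromosome lengths plus gene models; indexes TSS positions per chrom."""

    def __init__(self, chrom_lengths: dict[str, int], genes: list[GeneModel]):
        self.chrom_lengths = dict(chrom_lengths)
        self.genes = list(genes)
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.gene_end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in annotation")
        # per-chrom (tss, gene_id) sorted for nearest-TSS queries; ties resolved
        # by lexicographically smaller gene_id so results are order independent
        self._tss_index: dict[str, tuple[list[int], list[str]]] = {}
        for chrom in self.chrom_lengths:
            entries = sorted(
                (g.tss, g.gene_id) for g in self.genes if g.chrom == chrom
            )
            self._tss_index[chrom] = (
                [t for t, _ in entries],
                [i for _, i in entries],
            )

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self.genes)


def overlaps(a: Interval, b: Interval, min_bp: int = 1) -> bool:
    """True iff a and b share at least ``min_bp`` bases."""
    return overlap_length(a, b) >= min_bp


def overlap_length(a: Interval, b: Interval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(regions: list[Interval], max_gap: int) -> list[Interval]:
    """Merge intervals chained by gaps strictly smaller than ``max_gap``.

    A gap of exactly ``max_gap`` keeps the intervals separate ("closer than"
    semantics). ``max_gap=0`` merges only book-ended or overlapping intervals.
    Output is sorted and non-overlapping; idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if not regions:
        return []
    out: list[Interval] = []
    for iv in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and iv.chrom == out[-1].chrom:
            gap = iv.start - out[-1].end
            if gap <= 0 or gap < max_gap:
                prev = out.pop()
                out.append(replace(prev, end=max(prev.end, iv.end)))
                continue
        out.append(Interval(iv.chrom, iv.start, iv.end))
    return out


def nearest_tss(
    region: Interval, annotation: GenomeAnnotation
) -> tuple[str, int] | None:
    """Gene whose TSS is closest to the region midpoint, with signed distance.

    The distance is signed by gene strand: negative means the region midpoint
    lies upstream of the TSS. Ties on |distance| go to the lexicographically
    smaller gene_id. Returns ``None`` if the chromosome carries no genes.
    """
    positions, ids = annotation._tss_index.get(region.chrom, ([], []))
    if not positions:
        return None
    mid = region.midpoint
    i = bisect.bisect_left(positions, mid)
    best: tuple[int, str] | None = None
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(positions):
            cand = (abs(mid - positions[j]), ids[j])
            if best is None or cand < best:
                best = cand
    # ties within the index share a TSS position; scan neighbours with equal
    # distance to honour the lexicographic rule
    dist = best[0]
    for j in range(len(positions)):
        if abs(mid - positions[j]) == dist and ids[j] < best[1]:
            best = (dist, ids[j])
    gene = annotation.gene(best[1])
    signed = mid - gene.tss
    if gene.strand == "-":
        signed = -signed
    return gene.gene_id, signed


def annotate_feature(
    region: Interval, annotation: GenomeAnnotation, promoter_window: int = 1000
) -> str:
    """Assign one of {promoter, exon, intron, intergenic} to the region midpoint.

    Precedence promoter > exon > intron > intergenic. Promoter means the
    midpoint lies within +/- promoter_window of any TSS (inclusive).
    """
    mid = region.midpoint
    positions, _ = annotation._tss_index.get(region.chrom, ([], []))
    i = bisect.bisect_left(positions, mid)
    for j in (i - 1, i):
        if 0 <= j < len(positions) and abs(mid - positions[j]) <= promoter_window:
            return "promoter"
    label = "intergenic"
    for g in annotation.genes:
        if g.chrom != region.chrom or not (g.gene_start <= mid < g.gene_end):
            continue
        if any(ex.start <= mid < ex.end for ex in g.exons):
            return "exon"
        label = "intron"
    return label
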