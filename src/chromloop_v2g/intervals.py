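"""Coordinate-bearing record types and overlap machinery.

All coordinates are 0-based half-open internally.  BED-family writers emit
0-based half-open; the VCF-like proxy tables carry 1-based positions and are
converted on load.  Overlap everywhere means >= 1 bp shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class Peak:
    """An ATAC-seq open chromatin region (OCR) of one cell type."""

    interval: GenomicInterval
    cell_type: str
    source: str = "bulk"  # bulk | single-cell
    name: str = "."


@dataclass(frozen=True)
class LoopCall:
    """A significant pairwise chromatin contact (Hi-C or promoter Capture-C).

    Inputs are assumed pre-filtered for significance; ``score`` and
    ``resolution`` are carried as metadata.  Only intra-chromosomal loops
    are representable.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    cell_type: str
    score: float = 0.0
    resolution: int = 0  # bases per bin; smaller = finer
    assay: str = "hic"  # hic | capture-c
    name: str = "."

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError(
                "loop anchors must be on the same chromosome "
                f"({self.anchor_a.chrom} vs {self.anchor_b.chrom})"
            )


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter window (-1500/+500 around the TSS)."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")


# Mechanism topologies a cRE can use to implicate a gene.
TOPOLOGY_PROMOTER = "promoter_overlap"
TOPOLOGY_DISTAL = "distal_loop"
TOPOLOGY_P2P = "promoter_to_promoter_loop"


@dataclass(frozen=True)
class GeneLink:
    """One gene implicated by a cRE, with the topology that implicates it."""

    gene_id: str
    topology: str
    via_loop: LoopCall | None = None

    def __post_init__(self) -> None:
        if self.topology not in (TOPOLOGY_PROMOTER, TOPOLOGY_DISTAL, TOPOLOGY_P2P):
            raise ValueError(f"unknown topology {self.topology!r}")
        if (self.topology == TOPOLOGY_PROMOTER) != (self.via_loop is None):
            raise ValueError("via_loop must be absent iff topology is promoter_overlap")


@dataclass(frozen=True)
class CRE:
    """A candidate cis-regulatory element: an OCR tied to >= 1 gene promoter."""

    interval: GenomicInterval
    cell_type: str
    links: frozenset[GeneLink] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.links:
            raise ValueError("a CRE must carry at least one gene link")


class IntervalIndex:
    """Per-chromosome interval index over payload-carrying intervals.

    Thin wrapper around :mod:`intervaltree` so callers never touch tree
    internals; queries return payloads in deterministic (sorted) order.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv, payload in items:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlapping(self, iv: GenomicInterval) -> list[object]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = tree.overlap(iv.start, iv.end)
        return [h.data for h in sorted(hits, key=lambda h: (h.begin, h.end, repr(h.data)))]

    def at_point(self, chrom: str, pos0: int) -> list[object]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.at(pos0)
        return [h.data for h in sorted(hits, key=lambda h: (h.begin, h.end, repr(h.data)))]

    def has_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def has_point(self, chrom: str, pos0: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.at(pos0))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent-by-overlap intervals (>=1 bp rule)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def iter_unique_sorted(intervals: Iterable[GenomicInterval]) -> Iterator[GenomicInterval]:
    seen: set[GenomicInterval] = set()
    for iv in sorted(intervals):
        if iv not in seen:
            seen.add(iv)
            yield iv
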