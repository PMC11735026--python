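"""Construction of candidate cis-regulatory elements (cREs).

A cRE is an open chromatin region (ATAC-seq peak) tied to at least one gene
promoter in the same cell type, through one of three topologies:

* ``promoter_overlap`` -- the peak overlaps the promoter window itself;
* ``distal_loop``      -- the peak overlaps one anchor of a chromatin loop
  whose other anchor overlaps the gene's promoter;
* ``promoter_to_promoter_loop`` -- the peak sits in gene A's promoter while a
  loop connects A's promoter region to gene B's promoter, implicating B.

Promoter windows are -1500/+500 bp around the TSS, strand-aware.  The overlap
predicate is >= 1 bp everywhere.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import (
    CRE,
    GeneLink,
    GenomicInterval,
    IntervalIndex,
    LoopCall,
    Peak,
    PromoterWindow,
    TOPOLOGY_DISTAL,
    TOPOLOGY_P2P,
    TOPOLOGY_PROMOTER,
    merge_intervals,
)

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


def make_promoters(
    genes: pd.DataFrame,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[PromoterWindow]:
    """Build strand-aware promoter windows from a gene table.

    ``genes`` needs columns ``gene_id, chrom, tss, strand``.  On the + strand
    the window is [tss-upstream, tss+downstream); on the - strand it mirrors
    to [tss-downstream, tss+upstream).  Windows are clipped at 0 and, when
    ``chrom_sizes`` is given, at the chromosome end.
    """
    windows: list[PromoterWindow] = []
    for row in genes.itertuples(index=False):
        strand = str(row.strand)
        if strand == "+":
            start, end = row.tss - upstream, row.tss + downstream
        elif strand == "-":
            start, end = row.tss - downstream, row.tss + upstream
        else:
            raise ValueError(f"unknown strand {strand!r} for gene {row.gene_id}")
        start = max(0, int(start))
        end = int(end)
        if chrom_sizes is not None and str(row.chrom) in chrom_sizes:
            end = min(end, chrom_sizes[str(row.chrom)])
        windows.append(
            PromoterWindow(
                gene_id=str(row.gene_id),
                interval=GenomicInterval(str(row.chrom), start, end),
                strand=strand,
                tss=int(row.tss),
            )
        )
    return windows


def _anchors_reciprocally_overlap(a: LoopCall, b: LoopCall) -> bool:
    """Both anchors overlap >= 1 bp, in either anchor orientation."""
    return (
        a.anchor_a.overlaps(b.anchor_a) and a.anchor_b.overlaps(b.anchor_b)
    ) or (
        a.anchor_a.overlaps(b.anchor_b) and a.anchor_b.overlaps(b.anchor_a)
    )


def merge_loops(loops: Iterable[LoopCall]) -> list[LoopCall]:
    """Merge multi-resolution loop calls, preferring the finer resolution.

    A loop is dropped when any loop at a strictly smaller (finer) resolution
    reciprocally overlaps it (both anchors >= 1 bp).  Non-overlapping loops
    from all resolutions are kept.  The rule is applied pairwise, so a chain
    of overlaps (4 kb over 2 kb over 1 kb) retains only the finest call, and
    the operation is idempotent.
    """
    loops = list(loops)
    kept: list[LoopCall] = []
    for loop in loops:
        superseded = any(
            other.resolution < loop.resolution
            and other.cell_type == loop.cell_type
            and _anchors_reciprocally_overlap(loop, other)
            for other in loops
        )
        if not superseded:
            kept.append(loop)
    return kept


def call_cres(
    peaks: Sequence[Peak],
    loops: Sequence[LoopCall],
    promoters: Sequence[PromoterWindow],
    cell_type: str,
) -> list[CRE]:
    """Call cREs for one cell type from its peaks, loops and promoters.

    Every peak that links to >= 1 gene becomes a cRE whose interval is the
    whole peak; peaks with no link are discarded.  Distal-loop links require
    the peak to overlap a loop anchor whose partner anchor overlaps the target
    promoter.  When the peak itself lies in gene A's promoter and the loop
    runs from A's promoter region to gene B's promoter, the link to B is
    classified promoter-to-promoter instead of distal (self-contacts with
    A == B are recorded the same way).
    """
    for p in peaks:
        if p.cell_type != cell_type:
            raise ValueError(f"peak cell type {p.cell_type!r} != {cell_type!r}")
    for l in loops:
        if l.cell_type != cell_type:
            raise ValueError(f"loop cell type {l.cell_type!r} != {cell_type!r}")

    prom_index = IntervalIndex((pw.interval, pw) for pw in promoters)

    cres: list[CRE] = []
    for peak in peaks:
        links: set[GeneLink] = set()
        peak_proms: list[PromoterWindow] = prom_index.overlapping(peak.interval)
        peak_prom_ids = {pw.gene_id for pw in peak_proms}

        for pw in peak_proms:
            links.add(GeneLink(pw.gene_id, TOPOLOGY_PROMOTER))

        for loop in loops:
            for near, far in (
                (loop.anchor_a, loop.anchor_b),
                (loop.anchor_b, loop.anchor_a),
            ):
                far_genes = [pw.gene_id for pw in prom_index.overlapping(far)]
                if not far_genes:
                    continue
                near_genes = {pw.gene_id for pw in prom_index.overlapping(near)}
                if peak_prom_ids & near_genes:
                    # peak in a promoter that the near anchor also touches:
                    # promoter-to-promoter contact implicating the far gene(s)
                    for g in far_genes:
                        links.add(GeneLink(g, TOPOLOGY_P2P, via_loop=loop))
                elif peak.interval.overlaps(near):
                    for g in far_genes:
                        links.add(GeneLink(g, TOPOLOGY_DISTAL, via_loop=loop))

        if links:
            cres.append(
                CRE(interval=peak.interval, cell_type=cell_type, links=frozenset(links))
            )
    return cres


def call_cres_bruteforce(
    peaks: Sequence[Peak],
    loops: Sequence[LoopCall],
    promoters: Sequence[PromoterWindow],
    cell_type: str,
) -> list[CRE]:
    """Quadratic all-pairs reference implementation of :func:`call_cres`.

    Uses direct pairwise interval comparisons only; kept deliberately free of
    the interval index so it can serve as an independent oracle.
    """

    def ov(a: GenomicInterval, b: GenomicInterval) -> bool:
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    cres: list[CRE] = []
    for peak in peaks:
        if peak.cell_type != cell_type:
            raise ValueError("mixed cell types")
        links: set[GeneLink] = set()
        in_proms = [pw for pw in promoters if ov(peak.interval, pw.interval)]
        for pw in in_proms:
            links.add(GeneLink(pw.gene_id, TOPOLOGY_PROMOTER))
        for loop in loops:
            if loop.cell_type != cell_type:
                raise ValueError("mixed cell types")
            for near, far in (
                (loop.anchor_a, loop.anchor_b),
                (loop.anchor_b, loop.anchor_a),
            ):
                far_genes = [pw.gene_id for pw in promoters if ov(far, pw.interval)]
                if not far_genes:
                    continue
                near_genes = {
                    pw.gene_id for pw in promoters if ov(near, pw.interval)
                }
                if {pw.gene_id for pw in in_proms} & near_genes:
                    for g in far_genes:
                        links.add(GeneLink(g, TOPOLOGY_P2P, via_loop=loop))
                elif ov(peak.interval, near):
                    for g in far_genes:
                        links.add(GeneLink(g, TOPOLOGY_DISTAL, via_loop=loop))
        if links:
            cres.append(CRE(peak.interval, cell_type, frozenset(links)))
    return cres


def build_annotation_sets(
    peaks: Sequence[Peak],
    promoters: Sequence[PromoterWindow],
    cres: Sequence[CRE],
    flank: int = 500,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Emit the four heritability-annotation region sets.

    ``total_ocr``     all peak intervals;
    ``promoter_ocr``  peaks overlapping any promoter window;
    ``cre``           cRE intervals;
    ``cre_flank``     cRE intervals extended by ``flank`` bases both ways,
                      clipped at chromosome bounds and merged if overlapping.
    """
    prom_index = IntervalIndex((pw.interval, pw) for pw in promoters)
    total = sorted({p.interval for p in peaks})
    promoter_ocr = [iv for iv in total if prom_index.has_overlap(iv)]
    cre_ivs = sorted({c.interval for c in cres})

    flanked: list[GenomicInterval] = []
    for iv in cre_ivs:
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        flanked.append(GenomicInterval(iv.chrom, start, end))

    return {
        "total_ocr": total,
        "promoter_ocr": promoter_ocr,
        "cre": cre_ivs,
        "cre_flank": merge_intervals(flanked),
    }


def cres_to_frame(cres: Iterable[CRE]) -> pd.DataFrame:
    """Flatten cREs into a tidy (interval, cell_type, gene_id, topology) table."""
    rows = []
    for cre in cres:
        for link in sorted(cre.links, key=lambda l: (l.gene_id, l.topology)):
            rows.append(
                {
                    "chrom": cre.interval.chrom,
                    "start": cre.interval.start,
                    "end": cre.interval.end,
                    "cell_type": cre.cell_type,
                    "gene_id": link.gene_id,
                    "topology": link.topology,
                }
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cell_type", "gene_id", "topology"]
    )
    return df.sort_values(list(df.columns)).reset_index(drop=True)


def group_loops_by_cell_type(loops: Iterable[LoopCall]) -> dict[str, list[LoopCall]]:
    out: dict[str, list[LoopCall]] = defaultdict(list)
    for loop in loops:
        out[loop.cell_type].append(loop)
    return dict(out)
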