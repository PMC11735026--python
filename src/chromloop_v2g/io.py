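"""Readers and writers for the plain-text formats the pipeline touches.

BED-family files are 0-based half-open; proxy and summary-statistic tables
carry 1-based positions.  All writers emit deterministic, sorted output so a
fixture regenerated from the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval, LoopCall, Peak
from .tfbind import PWM

# ---------------------------------------------------------------- peaks (BED)


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak (BED6+4); summit column set to -1."""
    rows = []
    for i, p in enumerate(sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))):
        rows.append(
            (
                p.interval.chrom, p.interval.start, p.interval.end,
                p.name if p.name != "." else f"peak_{i}",
                1000, ".", 1.0, -1.0, -1.0, -1,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path, cell_type: str, source: str = "bulk") -> list[Peak]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        Peak(
            GenomicInterval(str(r[0]), int(r[1]), int(r[2])),
            cell_type=cell_type,
            source=source,
            name=str(r[3]) if df.shape[1] > 3 else ".",
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- loops


def write_bedpe(loops: Sequence[LoopCall], path: str | Path) -> None:
    """10-column BEDPE: both anchors, name, score (col 8), assay, resolution (col 10)."""
    rows = []
    for i, l in enumerate(
        sorted(loops, key=lambda l: (l.anchor_a.chrom, l.anchor_a.start, l.anchor_b.start))
    ):
        rows.append(
            (
                l.anchor_a.chrom, l.anchor_a.start, l.anchor_a.end,
                l.anchor_b.chrom, l.anchor_b.start, l.anchor_b.end,
                l.name if l.name != "." else f"loop_{i}",
                l.score, l.assay, l.resolution,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path, cell_type: str) -> list[LoopCall]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    loops = []
    for r in df.itertuples(index=False):
        loops.append(
            LoopCall(
                anchor_a=GenomicInterval(str(r[0]), int(r[1]), int(r[2])),
                anchor_b=GenomicInterval(str(r[3]), int(r[4]), int(r[5])),
                cell_type=cell_type,
                name=str(r[6]) if df.shape[1] > 6 else ".",
                score=float(r[7]) if df.shape[1] > 7 else 0.0,
                assay=str(r[8]) if df.shape[1] > 8 else "hic",
                resolution=int(r[9]) if df.shape[1] > 9 else 0,
            )
        )
    return loops


def read_ibed(path: str | Path, cell_type: str, resolution: int = 0) -> list[LoopCall]:
    """Read promoter-capture interactions in CHiCAGO-style ibed layout.

    Columns: bait_chr bait_start bait_end bait_name otherEnd_chr
    otherEnd_start otherEnd_end otherEnd_name N_reads score.  Inter-
    chromosomal rows are skipped (the loop model is intra-chromosomal).
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0].lower() not in ("bait_chr", "bait_chrom"):
        df = pd.read_csv(path, sep="\t", header=None)
        df.columns = [
            "bait_chr", "bait_start", "bait_end", "bait_name",
            "otherEnd_chr", "otherEnd_start", "otherEnd_end", "otherEnd_name",
            "N_reads", "score",
        ][: df.shape[1]]
    loops = []
    for r in df.itertuples(index=False):
        if str(r.bait_chr) != str(r.otherEnd_chr):
            continue
        loops.append(
            LoopCall(
                anchor_a=GenomicInterval(str(r.bait_chr), int(r.bait_start), int(r.bait_end)),
                anchor_b=GenomicInterval(
                    str(r.otherEnd_chr), int(r.otherEnd_start), int(r.otherEnd_end)
                ),
                cell_type=cell_type,
                score=float(getattr(r, "score", 0.0)),
                resolution=resolution,
                assay="capture-c",
                name=str(getattr(r, "bait_name", ".")),
            )
        )
    return loops


# ---------------------------------------------------------------- genes


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if missing := required - set(df.columns):
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def read_genes_gtf(path: str | Path) -> pd.DataFrame:
    """Derive a gene table (gene_id, chrom, tss, strand) from GTF transcripts.

    The TSS is the strand-respecting transcript start (GTF is 1-based
    inclusive; the returned tss is 0-based).  One row per gene_id, keeping
    the first transcript seen.
    """
    rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip('"')
                    break
            if gene_id is None or gene_id in rows:
                continue
            tss = start - 1 if strand == "+" else end - 1
            rows[gene_id] = {
                "gene_id": gene_id, "chrom": chrom, "tss": tss, "strand": strand
            }
    return pd.DataFrame(list(rows.values()), columns=["gene_id", "chrom", "tss", "strand"])


# ---------------------------------------------------------------- intervals / tables


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    rows = [(iv.chrom, iv.start, iv.end) for iv in sorted(intervals)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [GenomicInterval(str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- pathways


def write_pathways(pathways, nodes_path: str | Path, edges_path: str | Path) -> None:
    node_rows = [
        {"pathway_id": pw.pathway_id, "gene_id": g}
        for pw in pathways
        for g in pw.genes
    ]
    edge_rows = [
        {"pathway_id": pw.pathway_id, "source": s, "target": t, "sign": w}
        for pw in pathways
        for (s, t, w) in pw.edges
    ]
    pd.DataFrame(node_rows, columns=["pathway_id", "gene_id"]).to_csv(
        nodes_path, sep="\t", index=False
    )
    pd.DataFrame(edge_rows, columns=["pathway_id", "source", "target", "sign"]).to_csv(
        edges_path, sep="\t", index=False
    )


def read_pathways(nodes_path: str | Path, edges_path: str | Path):
    from .spia import PathwayGraph

    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t")
    pathways = []
    for pid, group in nodes.groupby("pathway_id", sort=True):
        e = edges[edges["pathway_id"] == pid]
        pathways.append(
            PathwayGraph(
                pathway_id=str(pid),
                genes=tuple(group["gene_id"].astype(str)),
                edges=tuple(
                    (str(r.source), str(r.target), float(r.sign))
                    for r in e.itertuples(index=False)
                ),
            )
        )
    return pathways


# ---------------------------------------------------------------- motifs


def write_jaspar_pfm(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR pfm count blocks (probabilities scaled)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.tf_name or pwm.motif_id}\n")
            arr = pwm.array * scale
            for base, row in zip("ACGT", arr):
                vals = " ".join(f"{v:.2f}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


def read_jaspar_pfm(path: str | Path, pseudocount: float = 0.8) -> list[PWM]:
    """Read JASPAR-format pfm motifs into PWMs (pseudocount-normalized)."""
    import numpy as np

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        out = []
        for m in records:
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append(
                PWM.from_counts(
                    motif_id=m.matrix_id or m.name,
                    counts=counts,
                    pseudocount=pseudocount,
                    tf_name=m.name or "",
                )
            )
    return out


# ---------------------------------------------------------------- fixture sets


def write_fixture_set(dataset, outdir: str | Path) -> dict:
    """Write a full synthetic dataset to ``outdir`` and return the manifest."""
    from .synthetic import config_to_dict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "config": config_to_dict(dataset.config)}

    def record(key: str, path: Path) -> None:
        manifest["files"][key] = path.name

    write_genes(dataset.genes, outdir / "genes.tsv")
    record("genes", outdir / "genes.tsv")

    for assets in dataset.assets:
        ct = assets.cell_type
        write_narrowpeak(list(assets.peaks), outdir / f"peaks_{ct}.narrowPeak")
        write_bedpe(list(assets.loops), outdir / f"loops_{ct}.bedpe")
        record(f"peaks_{ct}", outdir / f"peaks_{ct}.narrowPeak")
        record(f"loops_{ct}", outdir / f"loops_{ct}.bedpe")

    tpm = dataset.tpm.reset_index()
    write_table(tpm, outdir / "tpm.tsv")
    record("tpm", outdir / "tpm.tsv")

    write_table(dataset.sentinels, outdir / "sentinels.tsv")
    write_table(dataset.proxies, outdir / "proxies.tsv")
    record("sentinels", outdir / "sentinels.tsv")
    record("proxies", outdir / "proxies.tsv")

    for locus_id, df in sorted(dataset.sumstats.items()):
        write_table(df, outdir / f"sumstats_{locus_id}.tsv")
        record(f"sumstats_{locus_id}", outdir / f"sumstats_{locus_id}.tsv")

    write_pathways(
        dataset.pathways, outdir / "pathway_nodes.tsv", outdir / "pathway_edges.tsv"
    )
    record("pathway_nodes", outdir / "pathway_nodes.tsv")
    record("pathway_edges", outdir / "pathway_edges.tsv")
    de = dataset.delta_e.rename("lfc").rename_axis("gene_id").reset_index()
    de["de_flag"] = de["gene_id"].isin(dataset.de_set)
    write_table(de, outdir / "differential_expression.tsv")
    record("differential_expression", outdir / "differential_expression.tsv")

    write_table(dataset.truth.links, outdir / "truth_links.tsv")
    write_table(dataset.truth.strata, outdir / "truth_strata.tsv")
    write_table(dataset.truth.coloc_pairs, outdir / "truth_coloc.tsv")
    write_table(dataset.truth.perturbed_pathways, outdir / "truth_pathways.tsv")
    record("truth_links", outdir / "truth_links.tsv")
    record("truth_strata", outdir / "truth_strata.tsv")
    record("truth_coloc", outdir / "truth_coloc.tsv")
    record("truth_pathways", outdir / "truth_pathways.tsv")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
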