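"""Internally consistent multi-cell-type synthetic fixtures.

The generator emulates the data triads (ATAC-seq peaks, chromatin loops,
RNA-seq expression) of a multi-cell-type variant-to-gene study at desk
scale: a toy genome with non-overlapping promoter windows, per-cell-type
peak/loop sets realizing a configurable number of planted variant-to-gene
regulatory links through the three cRE topologies, LD blocks of proxies
around sentinel SNPs with strata covering the whole proxy Venn diagram,
GWAS/eQTL summary statistics per locus that share (or not) a causal
variant, and signed pathway graphs with planted expression perturbations.
An explicit planted-truth table is emitted alongside every fixture so each
downstream stage is testable without any external download.

Everything is driven by a single seeded generator: identical
(config, seed) pairs give byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .cre import call_cres, make_promoters
from .intervals import (
    GenomicInterval,
    LoopCall,
    Peak,
    PromoterWindow,
    TOPOLOGY_DISTAL,
    TOPOLOGY_P2P,
    TOPOLOGY_PROMOTER,
)
from .spia import PathwayGraph
from .v2g import (
    CellTypeAssets,
    STRATUM_CONTACT_ONLY,
    STRATUM_CRE,
    STRATUM_NONE,
    STRATUM_OPEN_CONTACT,
    STRATUM_OPEN_ONLY,
)

PROMOTER_SPAN = 2000  # -1500/+500 window length
_DECOY_STRATA_CYCLE = (
    STRATUM_CONTACT_ONLY,
    STRATUM_OPEN_ONLY,
    STRATUM_NONE,
    STRATUM_OPEN_CONTACT,
)
_TOPOLOGY_CYCLE = (TOPOLOGY_DISTAL, TOPOLOGY_PROMOTER, TOPOLOGY_P2P)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale knobs for the synthetic fixture generator."""

    n_chromosomes: int = 2
    chrom_length: int = 4_000_000
    n_genes: int = 80
    n_cell_types: int = 10
    n_sentinels: int = 8
    proxies_per_sentinel: int = 12
    r2_min: float = 0.8
    planted_links: int = 50
    decoy_loop_rate: float = 0.3
    peak_width: int = 300
    loop_anchor_width: int = 2000
    noise_expression_sd: float = 1.0
    seed: int = 0
    # pathway / summary-statistic sub-generator parameters
    n_pathways: int = 6
    pathway_size: int = 10
    n_pathway_genes: int = 200
    n_perturbed_pathways: int = 2
    de_effect: float = 2.0
    sumstats_n: int = 10_000
    sumstats_maf: float = 0.3
    sumstats_var_explained: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "n_genes", "n_cell_types",
            "n_sentinels", "proxies_per_sentinel",
            "peak_width", "loop_anchor_width",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.planted_links < 0 or self.decoy_loop_rate < 0:
            raise ValueError("planted_links and decoy_loop_rate must be >= 0")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must be in (0, 1]")
        if self.noise_expression_sd < 0:
            raise ValueError("noise_expression_sd must be non-negative")
        if self.planted_links > self.n_sentinels * self.proxies_per_sentinel:
            raise ValueError(
                "planted_links exceeds the total number of proxies "
                "(n_sentinels * proxies_per_sentinel)"
            )

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chroms}


@dataclass
class PlantedTruth:
    """The ground truth planted into a fixture set."""

    links: pd.DataFrame  # rsid, gene_id, cell_type, topology
    strata: pd.DataFrame  # rsid, stratum
    coloc_pairs: pd.DataFrame  # locus_id, gene_id, shared_causal, causal_rsid
    perturbed_pathways: pd.DataFrame  # pathway_id, direction
    unexpressed_genes: tuple[str, ...] = ()


@dataclass
class SyntheticDataset:
    """Everything one simulated study holds, in memory."""

    config: SyntheticConfig
    genes: pd.DataFrame
    promoters: list[PromoterWindow]
    assets: list[CellTypeAssets]
    tpm: pd.DataFrame
    sentinels: pd.DataFrame
    proxies: pd.DataFrame
    sumstats: dict[str, pd.DataFrame]
    pathways: list[PathwayGraph]
    delta_e: pd.Series
    de_set: tuple[str, ...]
    truth: PlantedTruth


class _Allocator:
    """Sequential block allocator over the free space between promoters.

    Hands out disjoint intervals separated by ``gap`` bases, never touching
    a reserved region, so independently allocated features can only overlap
    if the generator placed them together on purpose.
    """

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        reserved: Iterable[GenomicInterval],
        gap: int = 2000,
        start: int = 2000,
    ) -> None:
        self._free: dict[str, list[list[int]]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
        for iv in reserved:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, size in chrom_sizes.items():
            segs: list[list[int]] = []
            cursor = start
            for iv in sorted(by_chrom.get(chrom, [])):
                lo = max(0, iv.start - gap)
                if lo > cursor:
                    segs.append([cursor, lo])
                cursor = max(cursor, iv.end + gap)
            if cursor < size - gap:
                segs.append([cursor, size - gap])
            self._free[chrom] = segs
        self._gap = gap

    def alloc(self, chrom: str, size: int) -> GenomicInterval:
        for seg in self._free.get(chrom, []):
            if seg[1] - seg[0] >= size:
                iv = GenomicInterval(chrom, seg[0], seg[0] + size)
                seg[0] += size + self._gap
                return iv
        raise ValueError(
            f"cannot allocate {size} bases on {chrom}: chromosome too "
            "crowded; increase chrom_length or reduce feature counts"
        )


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Place genes with non-overlapping promoter windows.

    Genes are distributed round-robin over chromosomes; each gene receives
    an equal slot and a TSS jittered within it so that every -1500/+500
    promoter window stays inside its own slot (hence windows are pairwise
    disjoint).  Raises when the chromosome cannot fit its genes' promoter
    windows without overlap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per_chrom: dict[str, list[int]] = {c: [] for c in config.chroms}
    for i in range(config.n_genes):
        per_chrom[config.chroms[i % config.n_chromosomes]].append(i)

    rows = []
    for chrom, gene_ids in per_chrom.items():
        if not gene_ids:
            continue
        slot = config.chrom_length // len(gene_ids)
        if slot < PROMOTER_SPAN:
            raise ValueError(
                f"cannot place {len(gene_ids)} non-overlapping 2000-base "
                f"promoter windows on {chrom} of length {config.chrom_length}"
            )
        for j, i in enumerate(gene_ids):
            slot_start = j * slot
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            up, down = (1500, 500) if strand == "+" else (500, 1500)
            lo, hi = slot_start + up, slot_start + slot - down
            # keep away from chromosome edges when there is room
            if max(lo, 2000) <= min(hi, config.chrom_length - 2000):
                lo, hi = max(lo, 2000), min(hi, config.chrom_length - 2000)
            tss = int(rng.integers(lo, hi + 1))
            rows.append(
                {"gene_id": f"G{i:04d}", "chrom": chrom, "tss": tss, "strand": strand}
            )
    genes = pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
    return genes


@dataclass
class _ProxySlot:
    rsid: str
    chrom: str
    pos0: int
    sentinel_rsid: str
    locus_id: str
    stratum: str
    links: list[tuple[str, str, str]] = field(default_factory=list)
    # links: (gene_id, cell_type, topology)


@dataclass
class _AssetPlan:
    peaks: dict[str, list[Peak]]
    loops: dict[str, list[LoopCall]]
    slots: list[_ProxySlot]
    sentinel_pos: dict[str, tuple[str, int]]  # sentinel rsid -> (chrom, pos0)
    tpm: pd.DataFrame
    unexpressed: tuple[str, ...]


def generate_cell_type_assets(
    genes: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> _AssetPlan:
    """Emit per-cell-type peaks, loops and expression realizing the plan.

    Every planted link gets dedicated geometry in exactly one cell type (a
    gene is consumed by at most one planted link so links never alias across
    cell types); non-causal proxy slots cycle through the remaining Venn
    strata; decoy loops have no open anchor -- half of them dangle off a
    real gene promoter so the open-anchor requirement of cRE calling is
    what rejects them, not mere distance.
    """
    promoters = make_promoters(genes, chrom_sizes=config.chrom_sizes)
    prom_by_gene = {p.gene_id: p for p in promoters}
    alloc = _Allocator(
        config.chrom_sizes, [p.interval for p in promoters], gap=2000
    )
    cell_types = [f"CT{i:02d}" for i in range(config.n_cell_types)]
    peaks: dict[str, list[Peak]] = {ct: [] for ct in cell_types}
    loops: dict[str, list[LoopCall]] = {ct: [] for ct in cell_types}

    genes_by_chrom: dict[str, list[str]] = {}
    for row in genes.itertuples(index=False):
        genes_by_chrom.setdefault(row.chrom, []).append(row.gene_id)
    gene_cursor = {c: 0 for c in genes_by_chrom}

    def take_gene(chrom: str) -> str:
        lst = genes_by_chrom[chrom]
        cur = gene_cursor[chrom]
        if cur >= len(lst):
            raise ValueError(
                f"not enough genes on {chrom} to realize all planted links; "
                "increase n_genes"
            )
        gene_cursor[chrom] = cur + 1
        return lst[cur]

    def centered_peak(iv: GenomicInterval, width: int, ct: str) -> Peak:
        width = min(width, len(iv))
        mid = (iv.start + iv.end) // 2
        return Peak(
            GenomicInterval(iv.chrom, mid - width // 2, mid - width // 2 + width),
            cell_type=ct,
        )

    n_prox_total = config.n_sentinels * config.proxies_per_sentinel
    slots: list[_ProxySlot] = []
    sentinel_pos: dict[str, tuple[str, int]] = {}
    resolutions = (1000, 2000, 4000)
    w_a = config.loop_anchor_width
    causal_budget = config.planted_links
    causal_idx = 0
    decoy_cursor = 0
    n_loops_planted = {ct: 0 for ct in cell_types}

    for s in range(config.n_sentinels):
        chrom = config.chroms[s % config.n_chromosomes]
        locus_id = f"L{s:02d}"
        sent_rsid = f"rs9{s:04d}"
        sent_block = alloc.alloc(chrom, 200)
        sentinel_pos[sent_rsid] = (chrom, (sent_block.start + sent_block.end) // 2)

        for k in range(config.proxies_per_sentinel):
            rsid = f"rs{s:02d}{k:03d}"
            global_i = s * config.proxies_per_sentinel + k
            ct = cell_types[global_i % config.n_cell_types]
            if causal_idx < causal_budget:
                topology = _TOPOLOGY_CYCLE[causal_idx % len(_TOPOLOGY_CYCLE)]
                causal_idx += 1
                if topology == TOPOLOGY_PROMOTER:
                    g = take_gene(chrom)
                    prom = prom_by_gene[g].interval
                    pk = centered_peak(prom, config.peak_width, ct)
                    peaks[ct].append(pk)
                    # promoters are baited contact regions: emit the bait's
                    # interaction to a closed distal fragment (links nothing)
                    bait_far = alloc.alloc(chrom, w_a)
                    loops[ct].append(
                        LoopCall(
                            GenomicInterval(
                                chrom, prom.start, prom.start + min(w_a, len(prom))
                            ),
                            bait_far, cell_type=ct,
                            score=float(np.round(rng.uniform(5, 15), 3)),
                            resolution=resolutions[global_i % 3],
                            assay="capture-c",
                            name=f"bait_{rsid}",
                        )
                    )
                    n_loops_planted[ct] += 1
                    pos0 = (pk.interval.start + pk.interval.end) // 2
                    slots.append(
                        _ProxySlot(
                            rsid, chrom, pos0, sent_rsid, locus_id,
                            STRATUM_CRE, [(g, ct, TOPOLOGY_PROMOTER)],
                        )
                    )
                elif topology == TOPOLOGY_DISTAL:
                    g = take_gene(chrom)
                    prom = prom_by_gene[g].interval
                    block = alloc.alloc(chrom, w_a + 2000)
                    pk = centered_peak(block, config.peak_width, ct)
                    peaks[ct].append(pk)
                    anchor_a = centered_peak(block, w_a, ct).interval
                    anchor_b = GenomicInterval(
                        chrom, prom.start, prom.start + min(w_a, len(prom))
                    )
                    loops[ct].append(
                        LoopCall(
                            anchor_a, anchor_b, cell_type=ct,
                            score=float(np.round(rng.uniform(5, 15), 3)),
                            resolution=resolutions[global_i % 3],
                            assay="hic" if global_i % 2 == 0 else "capture-c",
                            name=f"loop_{rsid}",
                        )
                    )
                    n_loops_planted[ct] += 1
                    pos0 = (pk.interval.start + pk.interval.end) // 2
                    slots.append(
                        _ProxySlot(
                            rsid, chrom, pos0, sent_rsid, locus_id,
                            STRATUM_CRE, [(g, ct, TOPOLOGY_DISTAL)],
                        )
                    )
                else:  # promoter-to-promoter contact
                    g_host = take_gene(chrom)
                    g_target = take_gene(chrom)
                    prom_h = prom_by_gene[g_host].interval
                    prom_t = prom_by_gene[g_target].interval
                    pk = centered_peak(prom_h, config.peak_width, ct)
                    peaks[ct].append(pk)
                    loops[ct].append(
                        LoopCall(
                            prom_h, prom_t, cell_type=ct,
                            score=float(np.round(rng.uniform(5, 15), 3)),
                            resolution=resolutions[global_i % 3],
                            assay="capture-c",
                            name=f"loop_{rsid}",
                        )
                    )
                    n_loops_planted[ct] += 1
                    pos0 = (pk.interval.start + pk.interval.end) // 2
                    slots.append(
                        _ProxySlot(
                            rsid, chrom, pos0, sent_rsid, locus_id,
                            STRATUM_CRE,
                            [
                                (g_target, ct, TOPOLOGY_P2P),
                                (g_host, ct, TOPOLOGY_PROMOTER),
                            ],
                        )
                    )
            else:
                stratum = _DECOY_STRATA_CYCLE[decoy_cursor % len(_DECOY_STRATA_CYCLE)]
                decoy_cursor += 1
                if stratum == STRATUM_CONTACT_ONLY:
                    a = alloc.alloc(chrom, w_a)
                    b = alloc.alloc(chrom, w_a)
                    loops[ct].append(
                        LoopCall(
                            a, b, cell_type=ct,
                            score=float(np.round(rng.uniform(5, 15), 3)),
                            resolution=resolutions[global_i % 3],
                            assay="hic",
                            name=f"contact_{rsid}",
                        )
                    )
                    pos0 = (a.start + a.end) // 2
                elif stratum == STRATUM_OPEN_ONLY:
                    block = alloc.alloc(chrom, config.peak_width + 200)
                    pk = centered_peak(block, config.peak_width, ct)
                    peaks[ct].append(pk)
                    pos0 = (pk.interval.start + pk.interval.end) // 2
                elif stratum == STRATUM_OPEN_CONTACT:
                    block = alloc.alloc(chrom, w_a + 2000)
                    pk = centered_peak(block, config.peak_width, ct)
                    peaks[ct].append(pk)
                    far = alloc.alloc(chrom, w_a)
                    loops[ct].append(
                        LoopCall(
                            centered_peak(block, w_a, ct).interval, far,
                            cell_type=ct,
                            score=float(np.round(rng.uniform(5, 15), 3)),
                            resolution=resolutions[global_i % 3],
                            assay="hic",
                            name=f"oc_{rsid}",
                        )
                    )
                    pos0 = (pk.interval.start + pk.interval.end) // 2
                else:  # none
                    block = alloc.alloc(chrom, 200)
                    pos0 = (block.start + block.end) // 2
                slots.append(
                    _ProxySlot(rsid, chrom, pos0, sent_rsid, locus_id, stratum)
                )

    # decoy loops: closed anchors at decoy_loop_rate of the planted loop count
    all_genes = list(genes["gene_id"])
    for ct in cell_types:
        n_decoy = int(round(config.decoy_loop_rate * n_loops_planted[ct]))
        for d in range(n_decoy):
            chrom = config.chroms[(decoy_cursor + d) % config.n_chromosomes]
            a = alloc.alloc(chrom, w_a)
            if d % 2 == 0:
                # dangle off a real promoter: only the closed far anchor
                # stops this loop from minting a cRE
                g = all_genes[int(rng.integers(0, len(all_genes)))]
                prom = prom_by_gene[g]
                if prom.interval.chrom != chrom:
                    b = alloc.alloc(chrom, w_a)
                else:
                    b = prom.interval
            else:
                b = alloc.alloc(chrom, w_a)
            loops[ct].append(
                LoopCall(
                    a, b, cell_type=ct,
                    score=float(np.round(rng.uniform(5, 15), 3)),
                    resolution=resolutions[d % 3],
                    assay="hic",
                    name=f"decoy_{ct}_{d}",
                )
            )

    # background peaks: a shared set (all cell types) plus private ones
    for i in range(10):
        chrom = config.chroms[i % config.n_chromosomes]
        block = alloc.alloc(chrom, config.peak_width + 200)
        iv = centered_peak(block, config.peak_width, cell_types[0]).interval
        for ct in cell_types:
            peaks[ct].append(Peak(iv, cell_type=ct))
    for j, ct in enumerate(cell_types):
        for i in range(3):
            chrom = config.chroms[(i + j) % config.n_chromosomes]
            block = alloc.alloc(chrom, config.peak_width + 200)
            peaks[ct].append(centered_peak(block, config.peak_width, ct))

    # expression: planted genes always expressed; a slice of untouched genes
    # has TPM exactly 0 in every cell type
    planted_genes = {
        g for slot in slots for (g, _, _) in slot.links
    }
    unexpressed = tuple(
        g for i, g in enumerate(all_genes) if i % 7 == 6 and g not in planted_genes
    )
    vals = np.round(
        2.0 ** rng.normal(3.0, config.noise_expression_sd,
                          size=(len(all_genes), len(cell_types))),
        3,
    )
    tpm = pd.DataFrame(vals, index=all_genes, columns=cell_types)
    tpm.loc[list(unexpressed), :] = 0.0
    tpm.index.name = "gene_id"

    return _AssetPlan(
        peaks=peaks, loops=loops, slots=slots, sentinel_pos=sentinel_pos,
        tpm=tpm, unexpressed=unexpressed,
    )


def generate_gwas_loci(
    plan: _AssetPlan, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Format sentinel and proxy tables (1-based positions, r2 metadata)."""
    alleles = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
    sent_rows = []
    for rsid, (chrom, pos0) in plan.sentinel_pos.items():
        sent_rows.append({"rsid": rsid, "chrom": chrom, "pos": pos0 + 1})
    sentinels = pd.DataFrame(sent_rows)

    rows = []
    for i, slot in enumerate(plan.slots):
        ref, alt = alleles[i % len(alleles)]
        r2 = config.r2_min + (1 - config.r2_min) * float(rng.uniform(0.01, 1.0))
        rows.append(
            {
                "rsid": slot.rsid,
                "chrom": slot.chrom,
                "pos": slot.pos0 + 1,
                "ref": ref,
                "alt": alt,
                "sentinel_rsid": slot.sentinel_rsid,
                "r2": round(r2, 4),
                "locus_id": slot.locus_id,
            }
        )
    proxies = pd.DataFrame(rows)
    return sentinels, proxies


def simulate_locus_sumstats(
    n_snps: int,
    mode: str,
    n: int = 10_000,
    maf: float = 0.3,
    var_explained: float = 0.01,
    rng: np.random.Generator | int | None = None,
    snp_ids: list[str] | None = None,
    positions: list[int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate aligned GWAS/eQTL summary statistics for one locus.

    ``mode`` is ``shared`` (one SNP causal for both traits), ``distinct``
    (different causal SNPs) or ``null`` (no association).  Standard errors
    use the GWAS approximation se = 1/sqrt(2*N*maf*(1-maf)), so a causal
    variant explaining ``var_explained`` of trait variance has expected
    |z| = sqrt(var_explained * N).
    """
    if mode not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "distinct" and n_snps < 2:
        raise ValueError("mode='distinct' needs at least 2 SNPs")
    rng = np.random.default_rng(rng)
    se = 1.0 / np.sqrt(2 * n * maf * (1 - maf))
    beta_true = np.sqrt(var_explained / (2 * maf * (1 - maf)))

    mu1 = np.zeros(n_snps)
    mu2 = np.zeros(n_snps)
    info: dict = {"mode": mode, "causal_1": None, "causal_2": None}
    if mode == "shared":
        c = int(rng.integers(0, n_snps))
        mu1[c] = mu2[c] = beta_true
        info["causal_1"] = info["causal_2"] = c
    elif mode == "distinct":
        c1 = int(rng.integers(0, n_snps))
        c2 = int(rng.integers(0, n_snps - 1))
        if c2 >= c1:
            c2 += 1
        mu1[c1] = beta_true
        mu2[c2] = beta_true
        info["causal_1"], info["causal_2"] = c1, c2

    snp_ids = snp_ids or [f"snp{i:04d}" for i in range(n_snps)]
    positions = positions or list(range(1, n_snps + 1))
    df = pd.DataFrame(
        {
            "snp": snp_ids,
            "pos": positions,
            "beta_1": np.round(mu1 + rng.normal(0, se, n_snps), 8),
            "se_1": se,
            "beta_2": np.round(mu2 + rng.normal(0, se, n_snps), 8),
            "se_2": se,
            "n": n,
            "maf": maf,
        }
    )
    info["causal_snp_1"] = snp_ids[info["causal_1"]] if info["causal_1"] is not None else ""
    info["causal_snp_2"] = snp_ids[info["causal_2"]] if info["causal_2"] is not None else ""
    return df, info


def generate_sumstats(
    proxies: pd.DataFrame,
    plan: _AssetPlan,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-locus GWAS/eQTL summary statistics plus the coloc truth table.

    Loci cycle through shared / distinct / null causal configurations.  In a
    shared locus the causal SNP is the locus' first planted cRE proxy when
    one exists, so downstream concordance between colocalization credible
    sets and chromatin-based implications is exercised end to end.
    """
    modes = ("shared", "distinct", "null")
    sumstats: dict[str, pd.DataFrame] = {}
    truth_rows = []
    slot_by_locus: dict[str, list[_ProxySlot]] = {}
    for slot in plan.slots:
        slot_by_locus.setdefault(slot.locus_id, []).append(slot)

    for li, (locus_id, slots) in enumerate(sorted(slot_by_locus.items())):
        mode = modes[li % 3]
        snp_ids = [s.rsid for s in slots]
        positions = [s.pos0 + 1 for s in slots]
        causal_slot = next(
            (s for s in slots if s.stratum == STRATUM_CRE and s.links), None
        )
        df, info = simulate_locus_sumstats(
            len(slots), mode,
            n=config.sumstats_n, maf=config.sumstats_maf,
            var_explained=config.sumstats_var_explained,
            rng=rng, snp_ids=snp_ids, positions=positions,
        )
        if mode == "shared" and causal_slot is not None:
            # re-anchor the shared causal variant on the planted cRE proxy
            c_old = info["causal_1"]
            c_new = snp_ids.index(causal_slot.rsid)
            for col in ("beta_1", "beta_2"):
                v = df[col].to_numpy().copy()
                v[c_old], v[c_new] = v[c_new], v[c_old]
                df[col] = v
            info["causal_1"] = info["causal_2"] = c_new
            info["causal_snp_1"] = info["causal_snp_2"] = causal_slot.rsid
        gene_id = (
            causal_slot.links[0][0]
            if causal_slot is not None
            else ""
        )
        sumstats[locus_id] = df
        truth_rows.append(
            {
                "locus_id": locus_id,
                "gene_id": gene_id,
                "shared_causal": mode == "shared",
                "mode": mode,
                "causal_rsid": info["causal_snp_1"] if mode == "shared" else "",
            }
        )
    return sumstats, pd.DataFrame(truth_rows)


def chain_pathway(
    n: int = 5, pathway_id: str = "chain", sign: float = 1.0
) -> PathwayGraph:
    """A linear n-gene cascade A->B->...->with all edge signs ``sign``."""
    genes = tuple(f"{pathway_id}_g{i}" for i in range(n))
    edges = tuple(
        (genes[i], genes[i + 1], sign) for i in range(n - 1)
    )
    return PathwayGraph(pathway_id=pathway_id, genes=genes, edges=edges)


def planted_chain_scenario(
    seed: int = 0,
    effect: float = 5.0,
    n_background_genes: int = 200,
    chain_length: int = 5,
    de_fraction: float = 0.1,
) -> tuple[PathwayGraph, pd.Series, tuple[str, ...], list[str]]:
    """A positive-control cascade with an unambiguous planted perturbation.

    All ``chain_length`` genes of a +1-signed linear cascade receive a
    coherent differential shift of ``effect`` (log2 units) against an
    N(0, 1) background universe whose top |dE| decile forms the background
    DE set.  The shift is deliberately extreme -- a pathway-level positive
    control, not a typical biological effect -- so the permutation test on
    the short cascade resolves it below its granularity floor.

    Returns (chain pathway, delta_e, de_set, universe).
    """
    rng = np.random.default_rng(seed)
    chain = chain_pathway(chain_length)
    background = [f"BG{i:04d}" for i in range(n_background_genes)]
    universe = background + list(chain.genes)
    delta = pd.Series(rng.normal(0.0, 1.0, len(universe)), index=universe)
    delta.loc[list(chain.genes)] = rng.normal(effect, 0.5, chain_length)
    n_de = max(2, int(round(de_fraction * n_background_genes)))
    de_set = tuple(
        sorted(
            set(delta.abs().sort_values(ascending=False).index[:n_de])
            | set(chain.genes)
        )
    )
    return chain, delta, de_set, universe


def generate_pathways(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[PathwayGraph], pd.Series, tuple[str, ...], pd.DataFrame]:
    """Signed pathway graphs plus a per-gene differential statistic.

    Pathways sample disjoint-ish member sets from a dedicated gene universe;
    edges form a random DAG with +/-1 signs.  The first
    ``n_perturbed_pathways`` pathways have their members' dE shifted by
    ``de_effect`` in alternating directions; everything else is centered
    noise.  The DE set holds the genes with the largest |dE|.
    """
    universe = [f"PG{i:04d}" for i in range(config.n_pathway_genes)]
    delta = pd.Series(rng.normal(0.0, 1.0, len(universe)), index=universe)

    pathways: list[PathwayGraph] = []
    perturbed_rows = []
    for p in range(config.n_pathways):
        members = [
            universe[int(i)]
            for i in rng.choice(len(universe), size=config.pathway_size, replace=False)
        ]
        edges = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.uniform() < 0.3:
                    sign = 1.0 if rng.uniform() < 0.8 else -1.0
                    edges.append((members[i], members[j], sign))
        pathways.append(
            PathwayGraph(
                pathway_id=f"PW{p:02d}", genes=tuple(members), edges=tuple(edges),
                background_size=len(universe),
            )
        )
        if p < config.n_perturbed_pathways:
            direction = 1.0 if p % 2 == 0 else -1.0
            delta.loc[members] = delta.loc[members] + direction * config.de_effect
            perturbed_rows.append(
                {"pathway_id": f"PW{p:02d}", "direction": "up" if direction > 0 else "down"}
            )

    n_de = max(2, len(universe) // 10)
    de_set = tuple(delta.abs().sort_values(ascending=False).index[:n_de])
    return (
        pathways,
        delta,
        de_set,
        pd.DataFrame(perturbed_rows, columns=["pathway_id", "direction"]),
    )


def simulate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full internally consistent synthetic study."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    genes = generate_genome(config, rng)
    promoters = make_promoters(genes, chrom_sizes=config.chrom_sizes)
    plan = generate_cell_type_assets(genes, config, rng)
    sentinels, proxies = generate_gwas_loci(plan, config, rng)
    sumstats, coloc_truth = generate_sumstats(proxies, plan, config, rng)
    pathways, delta_e, de_set, perturbed = generate_pathways(config, rng)

    assets = []
    for ct in sorted(plan.peaks):
        cres = call_cres(plan.peaks[ct], plan.loops[ct], promoters, ct)
        assets.append(
            CellTypeAssets(
                cell_type=ct,
                peaks=tuple(plan.peaks[ct]),
                loops=tuple(plan.loops[ct]),
                cres=tuple(cres),
            )
        )

    link_rows = [
        {"rsid": s.rsid, "gene_id": g, "cell_type": ct, "topology": topo}
        for s in plan.slots
        for (g, ct, topo) in s.links
    ]
    links = pd.DataFrame(
        link_rows, columns=["rsid", "gene_id", "cell_type", "topology"]
    ).sort_values(["rsid", "gene_id", "cell_type"]).reset_index(drop=True)
    strata = pd.DataFrame(
        [{"rsid": s.rsid, "stratum": s.stratum} for s in plan.slots]
    )

    truth = PlantedTruth(
        links=links,
        strata=strata,
        coloc_pairs=coloc_truth,
        perturbed_pathways=perturbed,
        unexpressed_genes=plan.unexpressed,
    )
    return SyntheticDataset(
        config=config,
        genes=genes,
        promoters=promoters,
        assets=assets,
        tpm=plan.tpm,
        sentinels=sentinels,
        proxies=proxies,
        sumstats=sumstats,
        pathways=pathways,
        delta_e=delta_e,
        de_set=de_set,
        truth=truth,
    )


def config_to_dict(config: SyntheticConfig) -> dict:
    return dataclasses.asdict(config)
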