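"""LD-proxy classification and effector-gene implication.

Proxies of GWAS sentinel signals (r2 > 0.8) are mapped onto each cell type's
open chromatin, loop anchors and cREs.  Each proxy receives one global Venn
stratum; proxies inside cREs implicate genes with a mechanism label
(promoter / loop / double), and the records feed per-locus, per-variant and
per-gene summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    CRE,
    GenomicInterval,
    IntervalIndex,
    LoopCall,
    Peak,
    TOPOLOGY_PROMOTER,
)

R2_FILTER = 0.8

STRATUM_CRE = "cre"
STRATUM_OPEN_CONTACT = "open_contact"
STRATUM_CONTACT_ONLY = "contact_only"
STRATUM_OPEN_ONLY = "open_only"
STRATUM_NONE = "none"

STRATA = (
    STRATUM_CRE,
    STRATUM_OPEN_CONTACT,
    STRATUM_CONTACT_ONLY,
    STRATUM_OPEN_ONLY,
    STRATUM_NONE,
)

MECH_PROMOTER = "promoter"
MECH_LOOP = "loop"
MECH_DOUBLE = "double"


@dataclass(frozen=True)
class CellTypeAssets:
    """One cell type's interval assets used for proxy classification."""

    cell_type: str
    peaks: tuple[Peak, ...]
    loops: tuple[LoopCall, ...]
    cres: tuple[CRE, ...]


def load_proxies(proxies: pd.DataFrame, r2_filter: float = R2_FILTER) -> pd.DataFrame:
    """Apply the LD r2 filter and sanity-check the proxy table.

    Expects columns ``rsid, chrom, pos, sentinel_rsid, r2, locus_id`` with
    1-based positions.  Proxies at r2 <= ``r2_filter`` are dropped.
    """
    required = {"rsid", "chrom", "pos", "sentinel_rsid", "r2", "locus_id"}
    missing = required - set(proxies.columns)
    if missing:
        raise ValueError(f"proxy table missing columns: {sorted(missing)}")
    if (proxies["pos"] < 1).any():
        raise ValueError("proxy positions must be 1-based (>= 1)")
    out = proxies[proxies["r2"] > r2_filter].copy()
    return out.reset_index(drop=True)


def _proxy_point(row) -> tuple[str, int]:
    """1-based proxy position -> 0-based point coordinate."""
    return str(row.chrom), int(row.pos) - 1


def classify_proxies(
    proxies: pd.DataFrame,
    assets: Sequence[CellTypeAssets],
) -> pd.DataFrame:
    """Assign each proxy its global Venn stratum (and per-cell-type strata).

    A proxy is *in contact* if it falls inside any loop anchor of any cell
    type (regardless of chromatin state), *in open* if inside any peak, and
    *open_contact* when a peak and an anchor cover it in the same cell type.
    Precedence for the mutually exclusive global stratum:
    cre > open_contact > contact_only > open_only > none, where contact
    membership regardless of openness wins over open-only when the two
    co-occur only across different cell types.

    Returns the proxy table with added boolean columns ``in_open``,
    ``in_contact`` and a ``stratum`` column, plus one ``stratum__<cell
    type>`` column per cell type.
    """
    peak_idx: dict[str, IntervalIndex] = {}
    anchor_idx: dict[str, IntervalIndex] = {}
    cre_idx: dict[str, IntervalIndex] = {}
    for a in assets:
        peak_idx[a.cell_type] = IntervalIndex(
            (p.interval, p) for p in a.peaks
        )
        anchor_idx[a.cell_type] = IntervalIndex(
            (anc, l) for l in a.loops for anc in (l.anchor_a, l.anchor_b)
        )
        cre_idx[a.cell_type] = IntervalIndex((c.interval, c) for c in a.cres)

    known_chroms = {
        iv.chrom
        for a in assets
        for iv in (
            [p.interval for p in a.peaks]
            + [anc for l in a.loops for anc in (l.anchor_a, l.anchor_b)]
        )
    }
    unknown = sorted(set(proxies["chrom"].astype(str)) - known_chroms)
    if unknown:
        warnings.warn(
            f"proxy chromosome(s) absent from assets: {unknown}; "
            "affected proxies fall in stratum 'none'",
            stacklevel=2,
        )

    cell_types = [a.cell_type for a in assets]
    records = []
    for row in proxies.itertuples(index=False):
        chrom, pos0 = _proxy_point(row)
        rec: dict[str, object] = {"rsid": row.rsid}
        any_open = any_contact = any_cre = same_ct_oc = False
        for ct in cell_types:
            o = peak_idx[ct].has_point(chrom, pos0)
            c = anchor_idx[ct].has_point(chrom, pos0)
            e = cre_idx[ct].has_point(chrom, pos0)
            any_open |= o
            any_contact |= c
            any_cre |= e
            same_ct_oc |= o and c
            rec[f"stratum__{ct}"] = _stratum(e, o and c, c, o)
        rec["in_open"] = any_open
        rec["in_contact"] = any_contact
        rec["stratum"] = _stratum(any_cre, same_ct_oc, any_contact, any_open)
        records.append(rec)

    extra = pd.DataFrame(records)
    out = proxies.reset_index(drop=True).merge(extra, on="rsid", how="left")
    return out


def _stratum(is_cre: bool, is_oc: bool, in_contact: bool, in_open: bool) -> str:
    if is_cre:
        return STRATUM_CRE
    if is_oc:
        return STRATUM_OPEN_CONTACT
    if in_contact:
        return STRATUM_CONTACT_ONLY
    if in_open:
        return STRATUM_OPEN_ONLY
    return STRATUM_NONE


def map_variants_to_genes(
    proxies: pd.DataFrame,
    assets: Sequence[CellTypeAssets],
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Implicate effector genes for proxies residing inside cREs.

    For each proxy located inside a cRE of a cell type, one record per gene
    link is emitted.  ``promoter_overlap`` maps to mechanism ``promoter``;
    loop topologies map to ``loop`` with the topology detail retained.  When
    the same (rsid, gene, cell type) gathers both promoter and loop evidence
    the records collapse into one with mechanism ``double``.

    ``expression`` (optional) is a 0-100 scaled gene x cell-type matrix from
    :func:`scale_expression`; implicated genes absent from it are flagged
    ``undetected``.
    """
    cre_idx: dict[str, IntervalIndex] = {
        a.cell_type: IntervalIndex((c.interval, c) for c in a.cres) for a in assets
    }

    raw: list[dict[str, object]] = []
    for row in proxies.itertuples(index=False):
        chrom, pos0 = _proxy_point(row)
        for ct, idx in cre_idx.items():
            for cre in idx.at_point(chrom, pos0):
                for link in cre.links:
                    raw.append(
                        {
                            "rsid": str(row.rsid),
                            "gene_id": link.gene_id,
                            "cell_type": ct,
                            "topology": link.topology,
                            "locus_id": str(getattr(row, "locus_id", "")),
                        }
                    )
    if not raw:
        return pd.DataFrame(
            columns=[
                "rsid", "gene_id", "cell_type", "locus_id",
                "mechanism", "topologies", "expression_scaled",
            ]
        )

    df = pd.DataFrame(raw).drop_duplicates()

    def collapse(group: pd.DataFrame) -> pd.Series:
        topos = sorted(set(group["topology"]))
        has_prom = TOPOLOGY_PROMOTER in topos
        has_loop = any(t != TOPOLOGY_PROMOTER for t in topos)
        if has_prom and has_loop:
            mech = MECH_DOUBLE
        elif has_prom:
            mech = MECH_PROMOTER
        else:
            mech = MECH_LOOP
        return pd.Series(
            {
                "locus_id": group["locus_id"].iloc[0],
                "mechanism": mech,
                "topologies": ",".join(topos),
            }
        )

    out = (
        df.groupby(["rsid", "gene_id", "cell_type"], sort=True)
        .apply(collapse, include_groups=False)
        .reset_index()
    )

    if expression is not None:
        def lookup(r) -> object:
            if r.gene_id in expression.index and r.cell_type in expression.columns:
                return float(expression.loc[r.gene_id, r.cell_type])
            return "undetected"

        out["expression_scaled"] = [lookup(r) for r in out.itertuples(index=False)]
    else:
        out["expression_scaled"] = np.nan

    return out.sort_values(["rsid", "gene_id", "cell_type"]).reset_index(drop=True)


def summarize(
    records: pd.DataFrame,
    proxies: pd.DataFrame,
    cell_type_systems: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Aggregate implication records into locus / variant / gene summaries.

    Returns a dict of three tidy tables:

    * ``locus``   -- per locus: proxies in cREs, distinct genes, cell types;
    * ``variant`` -- per variant: cell types where it lies in a cRE, genes
      contacted, and whether it is single- or multi-cell-type;
    * ``gene``    -- per gene: implicating cell types and the physiological
      system(s) those cell types belong to (metabolic/immune/neural/other).

    ``cell_type_systems`` maps cell type -> system; unknown cell types are
    labelled ``other``.
    """
    if records.empty:
        empty = pd.DataFrame()
        return {"locus": empty, "variant": empty.copy(), "gene": empty.copy()}

    locus = (
        records.groupby("locus_id")
        .agg(
            n_proxies=("rsid", "nunique"),
            n_genes=("gene_id", "nunique"),
            n_cell_types=("cell_type", "nunique"),
        )
        .reset_index()
        .sort_values("locus_id")
        .reset_index(drop=True)
    )

    variant = (
        records.groupby("rsid")
        .agg(
            n_cell_types=("cell_type", "nunique"),
            n_genes=("gene_id", "nunique"),
        )
        .reset_index()
    )
    variant["multi_cell_type"] = variant["n_cell_types"] > 1
    variant = variant.sort_values("rsid").reset_index(drop=True)

    systems = cell_type_systems or {}

    def system_of(ct: str) -> str:
        return systems.get(ct, "other")

    gene = (
        records.assign(system=records["cell_type"].map(system_of))
        .groupby("gene_id")
        .agg(
            n_cell_types=("cell_type", "nunique"),
            systems=("system", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
        .sort_values("gene_id")
        .reset_index(drop=True)
    )

    return {"locus": locus, "variant": variant, "gene": gene}


def scale_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """Rescale a gene x cell-type TPM matrix to 0-100 per cell type.

    x' = 100 * (x - min) / (max - min) column-wise over genes; a constant
    column maps to all zeros.  Negative TPM is rejected.
    """
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    arr = tpm.to_numpy(dtype=float)
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = 100.0 * (arr - lo) / span
    scaled[:, span == 0] = 0.0
    return pd.DataFrame(scaled, index=tpm.index, columns=tpm.columns)
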