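"""Approximate-Bayes-factor colocalization of GWAS and eQTL signals.

For a locus window of aligned summary statistics (one row per SNP, effect and
standard error for each trait), five hypotheses are weighed:

* H0 -- no causal variant for either trait;
* H1 / H2 -- a causal variant for trait 1 / trait 2 only;
* H3 -- distinct causal variants;
* H4 -- one shared causal variant.

Per SNP i the Wakefield approximate Bayes factor against the null is, with
z = beta/se and r = W/(se^2 + W),

    log ABF_i = 0.5*log(1 - r) + 0.5*r*z^2

where W is the prior variance of the true effect (0.15^2 for quantitative
traits by default).  Hypothesis sums run over causal configurations in log
space; posteriors use single-causal-variant priors p1, p2, p12 per SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
DEFAULT_W_QUANT = 0.15**2
DEFAULT_W_CC = 0.2**2  # case-control traits

PP_H4_THRESHOLD = 0.8


def wakefield_log_abf(
    beta: np.ndarray | float, se: np.ndarray | float, W: float = DEFAULT_W_QUANT
) -> np.ndarray | float:
    """Log approximate Bayes factor for association at one or more SNPs."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    if W < 0:
        raise ValueError("prior effect variance W must be non-negative")
    z2 = (beta / se) ** 2
    r = W / (se**2 + W)
    out = 0.5 * np.log1p(-r) + 0.5 * r * z2
    return out if out.ndim else float(out)


@dataclass
class ColocResult:
    """Posterior summary of a two-trait colocalization analysis."""

    pp: dict[str, float]  # keys pp_h0..pp_h4
    snp_pp_h4: pd.Series  # per-SNP posterior of being the shared causal SNP
    credible_set: list[str]
    priors: dict[str, float] = field(default_factory=dict)
    n_snps: int = 0

    @property
    def pp_h4(self) -> float:
        return self.pp["pp_h4"]

    @property
    def pp_h3(self) -> float:
        return self.pp["pp_h3"]


def coloc_abf(
    data: pd.DataFrame,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    W1: float = DEFAULT_W_QUANT,
    W2: float = DEFAULT_W_QUANT,
    credible_mass: float = 0.95,
) -> ColocResult:
    """Run ABF colocalization on aligned summary statistics.

    ``data`` needs columns ``snp, beta_1, se_1, beta_2, se_2`` with one row
    per SNP, both traits aligned on the same effect allele.  All hypothesis
    sums are computed with log-sum-exp so extreme z-scores do not overflow.
    """
    required = {"snp", "beta_1", "se_1", "beta_2", "se_2"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(data) < 1:
        raise ValueError("at least one SNP is required")
    for col in ("beta_1", "se_1", "beta_2", "se_2"):
        bad = ~np.isfinite(data[col].to_numpy(dtype=float))
        if bad.any():
            snp = data.loc[bad, "snp"].iloc[0]
            raise ValueError(f"non-finite {col} at SNP {snp}")

    l1 = np.asarray(
        wakefield_log_abf(data["beta_1"].to_numpy(), data["se_1"].to_numpy(), W1)
    )
    l2 = np.asarray(
        wakefield_log_abf(data["beta_2"].to_numpy(), data["se_2"].to_numpy(), W2)
    )

    s1 = logsumexp(l1)  # sum over configurations with one causal SNP, trait 1
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)  # shared causal SNP

    # H3 sums BF1_i * BF2_j over i != j = exp(s1 + s2) - exp(s12)
    if len(data) > 1:
        log_h3_sum = s1 + s2 + _log1mexp(s12 - (s1 + s2))
    else:
        log_h3_sum = -np.inf

    with np.errstate(divide="ignore"):
        log_terms = np.array(
            [
                0.0,
                np.log(p1) + s1 if p1 > 0 else -np.inf,
                np.log(p2) + s2 if p2 > 0 else -np.inf,
                (np.log(p1) + np.log(p2) + log_h3_sum)
                if (p1 > 0 and p2 > 0 and np.isfinite(log_h3_sum))
                else -np.inf,
                np.log(p12) + s12 if p12 > 0 else -np.inf,
            ]
        )
    log_norm = logsumexp(log_terms)
    pp = np.exp(log_terms - log_norm)
    pp_dict = {f"pp_h{i}": float(pp[i]) for i in range(5)}

    snp_log = l1 + l2
    snp_pp = pd.Series(
        np.exp(snp_log - logsumexp(snp_log)),
        index=data["snp"].astype(str).to_numpy(),
        name="snp_pp_h4",
    )

    return ColocResult(
        pp=pp_dict,
        snp_pp_h4=snp_pp,
        credible_set=credible_set(snp_pp, mass=credible_mass),
        priors={"p1": p1, "p2": p2, "p12": p12, "W1": W1, "W2": W2},
        n_snps=len(data),
    )


def _log1mexp(x: float) -> float:
    """log(1 - exp(x)) for x <= 0, numerically careful near 0."""
    if x >= 0:
        # exp(x) >= 1 can only arise from rounding when the H4 term carries
        # all of the H3 mass; the off-diagonal sum is then numerically zero.
        return -np.inf
    if x > -math.log(2):
        return math.log(-math.expm1(x))
    return math.log1p(-math.exp(x))


def credible_set(snp_pp: pd.Series, mass: float = 0.95) -> list[str]:
    """Minimal descending-probability prefix with cumulative mass >= ``mass``.

    Ties in probability are broken by SNP id lexicographic order.
    """
    if len(snp_pp) == 0:
        raise ValueError("empty per-SNP posterior")
    order = sorted(snp_pp.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[str] = []
    cum = 0.0
    for snp, p in order:
        out.append(str(snp))
        cum += p
        if cum >= mass - 1e-12:
            break
    return out


def concordance(
    results: pd.DataFrame,
    implications: pd.DataFrame,
    pp_h4_threshold: float = PP_H4_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """Overlap SNP-gene pairs found by colocalization and by chromatin mapping.

    ``results`` has one row per (locus_id, gene_id) colocalization with
    columns ``locus_id, gene_id, pp_h4, credible_set`` (credible_set a list
    or comma-joined string of rsids); ``implications`` is the record table
    from :func:`chromloop_v2g.v2g.map_variants_to_genes`.  Colocalizations
    below the PP.H4 threshold are removed before matching; pairs match on
    (rsid in credible set, gene_id).
    """
    kept = results[results["pp_h4"] >= pp_h4_threshold]
    coloc_pairs: set[tuple[str, str]] = set()
    for row in kept.itertuples(index=False):
        cs = row.credible_set
        if isinstance(cs, str):
            cs = [s for s in cs.split(",") if s]
        for rsid in cs:
            coloc_pairs.add((str(rsid), str(row.gene_id)))

    v2g_pairs = (
        {
            (str(r.rsid), str(r.gene_id))
            for r in implications.itertuples(index=False)
        }
        if len(implications)
        else set()
    )

    def frame(pairs: set[tuple[str, str]]) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(pairs), columns=["rsid", "gene_id"]
        ).reset_index(drop=True)

    return {
        "shared": frame(coloc_pairs & v2g_pairs),
        "coloc_only": frame(coloc_pairs - v2g_pairs),
        "v2g_only": frame(v2g_pairs - coloc_pairs),
    }
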