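"""Customized signaling-pathway impact analysis.

The classic pathway-topology statistic propagates per-gene differential
expression over the signed pathway adjacency: each gene's perturbation
factor PF satisfies

    PF(g) = dE(g) + sum_j beta_jg * PF(j) / N_ds(j)

with N_ds(j) the out-degree of gene j, solved as a linear system; the net
accumulated perturbation tA = sum_g (PF(g) - dE(g)) is tested by permuting
the observed dE values over the pathway's genes.  Over-representation of the
significant (DE) gene set is tested hypergeometrically, and three
network-importance metrics weight the DE genes by (a) how many pathways they
appear in, (b) the fraction of the pathway reachable downstream of them, and
(c) their betweenness centrality.

Two ways of evidence -- perturbance and enrichment -- are then combined per
pathway with the inverse-normal (Stouffer) method, followed by Bonferroni
and Benjamini-Hochberg adjustment across pathways.  The enrichment side is a
single permutation-calibrated p-value for a joint statistic blending the DE
count with the three importance scores; the individual metric p-values are
reported alongside but are mutually dependent (all driven by the DE overlap)
and therefore are not naively averaged into the combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

P_CLIP = 1e-16


@dataclass(frozen=True)
class PathwayGraph:
    """A signed, directed pathway graph.

    ``edges`` are (source, target, sign) with sign in {+1, -1} (real-valued
    weights are accepted).  Cycles are allowed.
    """

    pathway_id: str
    genes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...] = ()
    background_size: int | None = None

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for s, t, _ in self.edges:
            if s not in gene_set or t not in gene_set:
                raise ValueError(
                    f"edge ({s},{t}) references a gene outside pathway "
                    f"{self.pathway_id}"
                )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for s, t, w in self.edges:
            g.add_edge(s, t, sign=w)
        return g


@dataclass
class PerturbationResult:
    pf: pd.Series
    acc: pd.Series
    ta: float
    damped: bool = False

    @property
    def weights(self) -> pd.Series:
        """Linear weights w with tA = w . dE (used by the permutation test)."""
        return self._weights

    _weights: pd.Series = field(default=None, repr=False)  # type: ignore[assignment]


def _propagation_matrix(pathway: PathwayGraph) -> np.ndarray:
    genes = list(pathway.genes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    out_deg = np.zeros(n)
    for s, _, _ in pathway.edges:
        out_deg[idx[s]] += 1
    m = np.zeros((n, n))
    for s, t, w in pathway.edges:
        m[idx[t], idx[s]] += w / out_deg[idx[s]]
    return m


def perturbation(
    pathway: PathwayGraph, delta_e: Mapping[str, float], damp: float = 0.99
) -> PerturbationResult:
    """Solve the perturbation-factor system for one pathway.

    dE defaults to 0 for pathway genes absent from ``delta_e``.  When
    (I - M) is singular (a propagation cycle with unit eigenvalue), the
    system is re-solved with M scaled by ``damp`` and the result flagged.
    """
    genes = list(pathway.genes)
    n = len(genes)
    de = np.array([float(delta_e.get(g, 0.0)) for g in genes])
    m = _propagation_matrix(pathway)

    damped = False
    a = np.eye(n) - m
    try:
        inv = np.linalg.inv(a)
        if not np.all(np.isfinite(inv)) or np.linalg.cond(a) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        damped = True
        inv = np.linalg.inv(np.eye(n) - damp * m)

    pf = inv @ de
    acc = pf - de
    weights = (inv - np.eye(n)).sum(axis=0)  # tA = weights . dE
    res = PerturbationResult(
        pf=pd.Series(pf, index=genes),
        acc=pd.Series(acc, index=genes),
        ta=float(acc.sum()),
        damped=damped,
    )
    res._weights = pd.Series(weights, index=genes)
    return res


def p_pert(
    pathway: PathwayGraph,
    delta_e: Mapping[str, float],
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Empirical perturbation p-value by permuting observed dE over the
    pathway's genes.

    The null keeps the observed number k of differential genes on the
    pathway fixed, draws k values from the pool of observed non-zero dE
    values (all measured differential genes), places them on k random
    pathway positions and recomputes tA.  Conditioning on k makes this
    evidence independent of the enrichment evidence, which only sees how
    many (and which) differential genes hit the pathway.  Uses the add-one
    estimator p = (1 + #{|tA_perm| >= |tA_obs|}) / (n_boot + 1); a pathway
    with no differential signal scores p = 1.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(rng)
    pert = perturbation(pathway, delta_e)
    de = np.array([float(delta_e.get(g, 0.0)) for g in pathway.genes])
    k = int(np.count_nonzero(de))
    if k == 0:
        return 1.0
    w = pert.weights.to_numpy()
    pool = np.array(
        [float(v) for _, v in sorted(delta_e.items()) if v != 0.0]
    )
    n = len(pathway.genes)
    vals = rng.permuted(np.tile(pool, (n_boot, 1)), axis=1)[:, :k]
    pos = rng.permuted(np.tile(np.arange(n), (n_boot, 1)), axis=1)[:, :k]
    ta_perm = np.einsum("ij,ij->i", w[pos], vals)
    hits = int(np.sum(np.abs(ta_perm) >= abs(pert.ta) - 1e-12))
    return (1 + hits) / (n_boot + 1)


def p_ora(
    pathway: PathwayGraph, de_set: Iterable[str], universe: Iterable[str]
) -> float:
    """Hypergeometric upper-tail over-representation p-value P(X >= k)."""
    universe = set(universe)
    de = set(de_set) & universe
    members = set(pathway.genes) & universe
    k = len(de & members)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(de)))


def gene_importance_scores(
    pathways: Sequence[PathwayGraph],
) -> dict[str, pd.DataFrame]:
    """Per-gene importance scores within each pathway.

    * ``impact``       -- fraction of the supplied pathways containing the gene;
    * ``neighborhood`` -- |downstream reachable genes| / (|pathway| - 1);
    * ``betweenness``  -- normalized betweenness centrality on the directed
      pathway graph.

    Returns {pathway_id: DataFrame indexed by gene with those three columns}.
    """
    n_path = len(pathways)
    counts: dict[str, int] = {}
    for pw in pathways:
        for g in set(pw.genes):
            counts[g] = counts.get(g, 0) + 1

    out: dict[str, pd.DataFrame] = {}
    for pw in pathways:
        g = pw.to_networkx()
        n = len(pw.genes)
        impact = {gene: counts[gene] / n_path for gene in pw.genes}
        if n > 1:
            neigh = {
                gene: len(nx.descendants(g, gene)) / (n - 1) for gene in pw.genes
            }
            betw = nx.betweenness_centrality(g, normalized=True)
        else:
            neigh = {gene: 0.0 for gene in pw.genes}
            betw = {gene: 0.0 for gene in pw.genes}
        out[pw.pathway_id] = pd.DataFrame(
            {"impact": impact, "neighborhood": neigh, "betweenness": betw}
        ).loc[list(pw.genes)]
    return out


def _permutation_p(
    score_by_gene: Mapping[str, float],
    de_set: set[str],
    universe: list[str],
    perm_idx: np.ndarray,
) -> float:
    """p for the sum of scores over de_set against random same-size sets."""
    scores = np.array([score_by_gene.get(g, 0.0) for g in universe])
    obs = float(sum(score_by_gene.get(g, 0.0) for g in de_set))
    stat_perm = scores[perm_idx].sum(axis=1)
    hits = int(np.sum(stat_perm >= obs - 1e-12))
    return (1 + hits) / (len(perm_idx) + 1)


def centrality_evidence(
    pathways: Sequence[PathwayGraph],
    de_set: Iterable[str],
    universe: Iterable[str],
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Permutation p-values for the three importance metrics plus the joint
    enrichment statistic, per pathway.

    The per-pathway statistic for a metric is the summed score of the DE
    genes inside the pathway; its null resamples same-size DE sets uniformly
    from the universe.  The joint enrichment statistic adds 1 per DE member
    gene (the over-representation count) to the three scores, giving one
    calibrated enrichment p-value per pathway.  Singleton pathways score 1
    for the topology-based metrics; an empty DE set scores 1 everywhere.
    """
    if len(pathways) < 2:
        raise ValueError("cross-network impact needs >= 2 pathways")
    rng = np.random.default_rng(rng)
    universe = sorted(set(universe))
    de = set(de_set) & set(universe)
    k = len(de)
    scores = gene_importance_scores(pathways)

    rows = []
    for pw in pathways:
        if k == 0:
            rows.append(
                {
                    "pathway_id": pw.pathway_id,
                    "p_impact": 1.0,
                    "p_neighborhood": 1.0,
                    "p_betweenness": 1.0,
                    "p_enrichment": 1.0,
                }
            )
            continue
        perm_idx = rng.permuted(
            np.tile(np.arange(len(universe)), (n_boot, 1)), axis=1
        )[:, :k]
        sc = scores[pw.pathway_id]
        singleton = len(pw.genes) <= 1
        member = {g: 1.0 for g in pw.genes}
        joint = {
            g: 1.0 + sc.loc[g, "impact"] + sc.loc[g, "neighborhood"]
            + sc.loc[g, "betweenness"]
            for g in pw.genes
        }
        rows.append(
            {
                "pathway_id": pw.pathway_id,
                "p_impact": _permutation_p(
                    sc["impact"].to_dict(), de, universe, perm_idx
                ),
                "p_neighborhood": 1.0
                if singleton
                else _permutation_p(
                    sc["neighborhood"].to_dict(), de, universe, perm_idx
                ),
                "p_betweenness": 1.0
                if singleton
                else _permutation_p(
                    sc["betweenness"].to_dict(), de, universe, perm_idx
                ),
                "p_enrichment": _permutation_p(
                    member if singleton else joint, de, universe, perm_idx
                ),
            }
        )
    return pd.DataFrame(rows)


def stouffer_combine(ps: Sequence[float]) -> float:
    """Inverse-normal (Stouffer) combination of k >= 1 p-values.

    Z = sum Phi^-1(1 - p_i) / sqrt(k); p_combined = 1 - Phi(Z).  Inputs are
    clipped to [1e-16, 1 - 1e-16] before the normal quantile.
    """
    ps = np.clip(np.asarray(list(ps), dtype=float), P_CLIP, 1 - P_CLIP)
    if ps.size == 0:
        raise ValueError("at least one p-value is required")
    z = stats.norm.isf(ps).sum() / np.sqrt(ps.size)
    return float(stats.norm.sf(z))


def combine_and_adjust(
    results: pd.DataFrame,
    evidence: Sequence[str] = ("p_pert", "p_enrichment"),
) -> pd.DataFrame:
    """Combine per-pathway evidence p-values and adjust across pathways.

    Adds ``p_combined`` (Stouffer over the ``evidence`` columns),
    ``p_bonferroni`` and ``p_fdr`` (Benjamini-Hochberg) columns.
    """
    if not evidence:
        raise ValueError("no evidence columns given")
    missing = set(evidence) - set(results.columns)
    if missing:
        raise ValueError(f"missing evidence columns: {sorted(missing)}")
    out = results.copy()
    out["p_combined"] = [
        stouffer_combine([row[c] for c in evidence])
        for _, row in out.iterrows()
    ]
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_combined"] * m)
    if m:
        out["p_fdr"] = multipletests(out["p_combined"], method="fdr_bh")[1]
    else:
        out["p_fdr"] = []
    return out


def run_spia(
    pathways: Sequence[PathwayGraph],
    delta_e: Mapping[str, float] | pd.Series,
    de_set: Iterable[str],
    universe: Iterable[str],
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full customized-SPIA run over a pathway collection.

    ``delta_e`` holds the signed differential statistic (log fold change) per
    measured gene; genes outside ``de_set`` contribute 0 to the perturbation.
    Returns one row per pathway with tA, the individual evidence p-values,
    the combined p, and Bonferroni / FDR adjusted values, sorted by p_fdr.
    """
    universe = sorted(set(universe))
    uni_set = set(universe)
    delta_e = dict(delta_e)
    stray = sorted(set(delta_e) - uni_set)
    if stray:
        raise ValueError(f"dE genes absent from universe: {stray[:5]}")
    de = set(de_set) & uni_set
    de_effective = {g: (delta_e.get(g, 0.0) if g in de else 0.0) for g in uni_set}

    rng = np.random.default_rng(seed)
    rows = []
    for pw in pathways:
        pert = perturbation(pw, de_effective)
        rows.append(
            {
                "pathway_id": pw.pathway_id,
                "ta": pert.ta,
                "damped": pert.damped,
                "p_pert": p_pert(pw, de_effective, n_boot=n_boot, rng=rng),
                "p_ora": p_ora(pw, de, universe),
            }
        )
    base = pd.DataFrame(rows)
    cent = centrality_evidence(pathways, de, universe, n_boot=n_boot, rng=rng)
    merged = base.merge(cent, on="pathway_id")
    out = combine_and_adjust(merged)
    return out.sort_values("p_fdr").reset_index(drop=True)
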