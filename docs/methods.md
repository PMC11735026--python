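# Methods

This note documents the models and procedures implemented in `chromloop_v2g`,
the parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions taken where the design was open.

## Interval conventions

All coordinates are 0-based half-open internally.  BED-family files are read
and written 0-based half-open; proxy and summary-statistic tables carry
1-based positions and are converted on load (a proxy at 1-based position p is
tested as the single base [p−1, p)).  The overlap predicate is ≥ 1 bp shared,
applied uniformly to peaks, anchors, promoters and variants.  Promoter windows
are −1500/+500 bp around the TSS and strand-aware: on the minus strand the
window mirrors to [tss−500, tss+1500).

## cRE construction

A peak becomes a cRE when it links to at least one gene; the cRE's interval is
the whole peak, not the intersection fragment, because the open region is the
regulatory unit being annotated.  Link topologies:

1. *promoter_overlap* — the peak overlaps a promoter window;
2. *distal_loop* — the peak overlaps one anchor of an intra-chromosomal loop
   whose partner anchor overlaps the target promoter;
3. *promoter_to_promoter_loop* — the peak overlaps gene A's promoter and a loop
   connects A's promoter region (anchor overlapping A's promoter) to gene B's
   promoter; B is implicated.  When A = B (a self-contact between transcript
   promoters of one gene) the link is recorded with the same topology.

When a peak inside a promoter also touches the anchor of such a
promoter-to-promoter loop, the link to the far gene is classified as
promoter-to-promoter, not distal: the contact originates from the promoter,
and double counting one loop under two topologies would inflate loop-mechanism
tallies.

Loop calls arriving at several resolutions are merged pairwise with preference
for the finer call: a loop is dropped when any strictly finer-resolution loop
reciprocally overlaps it (both anchors, ≥ 1 bp, in either anchor orientation).
The pairwise rule makes the merge idempotent and resolves overlap chains
(4 kb over 2 kb over 1 kb) down to the finest call.  Loop scores and
significance filters are treated as upstream metadata: inputs are assumed
already filtered.

The four annotation sets for heritability partitioning are: all peaks; peaks
overlapping a promoter; cRE intervals; and cRE intervals extended ±500 bp,
clipped at chromosome bounds and merged when the extensions overlap (merging
avoids double-counting bases in the annotation; the choice is ours — region
sets are used as annotation masks, where duplicated bases have no meaning).

## Proxy classification and implication

Proxies are loaded with the r² > 0.8 filter; LD is metadata, never recomputed.
The global Venn stratum of a proxy uses the precedence
cre > open_contact > contact_only > open_only > none, where *open_contact*
requires a peak and a loop anchor covering the position in the *same* cell
type, while contact and open membership are evaluated across all cell types.
When openness and contact co-occur only in different cell types, contact wins
(contact regions are defined regardless of chromatin state).  Per-cell-type
strata are also reported.

A proxy inside a cRE emits one record per gene link; promoter_overlap maps to
mechanism `promoter`, both loop topologies map to `loop` (the topology detail
is retained), and a (variant, gene, cell type) with both promoter and loop
evidence collapses to a single `double` record.  Summaries are pure
aggregations (group-bys) and are invariant to record order.

Expression is rescaled per cell type as x′ = 100·(x − min)/(max − min) over
genes on raw TPM (no log transform; configurable upstream of this function by
transforming the input).  A constant column maps to zero.  Implicated genes
missing from the matrix are flagged `undetected`.

## Colocalization

Per SNP and trait the Wakefield approximate Bayes factor is computed from
(β, se) with prior effect variance W = 0.15² for quantitative traits (0.2²
offered for case–control): log ABF = ½log(1 − r) + ½ r z², r = W/(se² + W).
Five hypothesis sums run over single-causal-variant configurations with priors
p1 = p2 = 1e-4, p12 = 1e-5 per SNP; the H3 sum over ordered distinct pairs is
obtained as exp(S1 + S2) − exp(S12) evaluated with log1mexp, and all sums use
log-sum-exp so z-scores of 40+ cannot overflow.  Per-SNP H4 posteriors are
normalized exp(lABF1 + lABF2); the 95% credible set is the minimal
descending-probability prefix reaching 0.95, ties broken by SNP id.
Multi-signal conditioning is out of scope: a conditional PP.H4 from an
upstream tool is treated as the PP.H4 of a single-signal analysis, a known
limitation.  Concordance with chromatin mapping filters results at
PP.H4 ≥ 0.8 and matches (credible-set SNP, gene) pairs.

## Customized pathway impact analysis

Perturbation factors solve PF(g) = ΔE(g) + Σ_j β_jg PF(j)/N_ds(j) over the
signed pathway adjacency (N_ds = out-degree); Acc = PF − ΔE and tA = ΣAcc.
Because the solution is linear in ΔE, tA = w·ΔE for a fixed weight vector w,
which the permutation test exploits.  When I − M is singular (propagation
cycle with unit eigenvalue) the system is re-solved with M scaled by 0.99 and
flagged.

Two ways of evidence are combined per pathway:

* *Perturbance* p_pert: holds k = #DE genes on the pathway fixed, draws k
  values from the pool of observed non-zero ΔE values, places them on random
  pathway positions, and compares |tA|.  Conditioning on k keeps this evidence
  independent of the enrichment side, which sees only how many and which DE
  genes hit the pathway.  The add-one estimator (1 + hits)/(n_boot + 1) avoids
  zero p-values; a pathway with no DE member scores 1.
* *Enrichment* p_enrichment: permutation p for the joint statistic
  Σ_{g∈DE∩pathway} (1 + impact(g) + neighborhood(g) + betweenness(g)), where
  impact is the fraction of pathways containing g, neighborhood the fraction
  of the pathway reachable downstream of g, and betweenness the normalized
  betweenness centrality of the directed graph.  The null resamples same-size
  DE sets uniformly from the measured universe.

The three metric-specific p-values (p_impact, p_neighborhood, p_betweenness)
and the hypergeometric over-representation p (p_ora) are reported individually
for inspection, but are *not* averaged into the combination: they are all
driven by the same DE-overlap draw and hence mutually dependent, and a naive
k-way inverse-normal combination of dependent p-values is anti-conservative.
The combination is the 2-way Stouffer Z = Σ Φ⁻¹(1 − p_i)/√2 over
(p_pert, p_enrichment), clipped to [1e-16, 1 − 1e-16], followed by Bonferroni
and Benjamini–Hochberg across pathways.  Under an i.i.d. null ΔE with random
DE sets this construction rejects at 5.0–5.4% at α = 0.05 (recomputed by the
acceptance script at every run).

Singleton pathways score 1 on the topology-based metrics; the enrichment
statistic then reduces to the DE count.

## PWM allele-disruption scoring

Position probability matrices (pseudocount-normalized; columns sum to 1) are
scored with information-content weighting under a uniform background:
position i contributes IC_i·log2(p_{b,i}/0.25) with IC_i = 2 + Σ_b p log2 p,
and the total is min-max normalized against the motif's best/worst attainable
scores.  Match p-values are exact over a discretized score distribution:
per-position contributions are rounded to 1e-3-wide integer bins and the full
distribution of a background k-mer's binned score is built by convolution.
The observed window is binned identically, so the DP agrees exactly with
brute-force enumeration of all 4^L k-mers at any motif length (verified for
L ≤ 8 where enumeration is feasible).

For a variant, every motif placement covering it is scored on both strands
for both alleles; `passes_filter` requires the better allele's match p-value
to reach 0.0005, and |Δ normalized score| ≥ 0.4 / ≥ 0.1 classifies
strong/weak effects (configurable; the filter threshold is the stated
analysis parameter, the effect bands are display conventions).  Δ is
antisymmetric under ref/alt exchange by construction.  Footprint overlap
annotates variants with motif-predicted binding sites (≥ 1 bp), and agreement
between disrupted and footprinted motif sets per variant feeds a 2×2 Fisher
exact test (scipy's hypergeometric implementation; odds ratio with Haldane
+0.5 correction when a cell is zero).

## Synthetic data generator

The generator emulates the *structure* of a multi-cell-type 3D-genomics study:
several chromosomes; genes placed in equal slots so promoter windows are
pairwise disjoint (an explicit error names the constraint when they cannot
be); per-cell-type peak and loop sets in which every planted
(variant, gene, cell type, topology) link is realized by dedicated geometry;
sentinel loci whose proxies carry r² labels in (0.8, 1]; locus-level
GWAS/eQTL summary statistics with se = 1/√(2·N·maf·(1−maf)) so a causal
variant explaining v of trait variance has E|z| = √(v·N); and signed pathway
graphs with planted expression shifts.  Defaults describe the study scale
used throughout the tests: 2 chromosomes × 4 Mb, 80 genes, 10 cell types,
8 sentinels × 12 proxies, 50 planted links cycling the three topologies,
decoy loops at 0.3 of the planted loop count, peak width 300 bp, anchor width
2 kb, pathway ΔE shift 2.0 against unit noise.

Design points worth knowing:

* Each planted link consumes its gene(s) exclusively and exists in exactly one
  cell type, so the truth table is exact — recovery really is precision =
  recall = 1, not approximately so.  Promoter-to-promoter links implicate both
  the host (promoter mechanism) and the target gene, and the truth table
  records both.
* Promoters with a planted open peak also emit a bait interaction to a closed
  distal fragment, mirroring promoter-capture designs where every bait is a
  contact region; this keeps cRE-resident variants inside the open∩contact
  Venn region.
* Decoy loops have no open anchor; half of them dangle off a real gene
  promoter so that the open-anchor requirement — not mere distance — is what
  rejects them.
* Non-causal proxies cycle through contact-only, open-only, none and
  open-contact slots, each realized by dedicated geometry, so the Venn
  partition is fully exercised.
* LD is simulated as r² labels only (no haplotypes): the pipeline uses r² only
  as a filter.  Summary statistics have independent noise across SNPs (no LD
  correlation), which makes the shared/distinct causal regimes cleanly
  separable; real loci with extensive LD would give flatter per-SNP
  posteriors and larger credible sets.
* Expression values are independent lognormal draws; no count noise, no
  batch structure, no mean–variance relationship.

Consequently, passing tests demonstrate the correctness of the interval
logic, the probability machinery and the bookkeeping — not robustness to the
noise, LD structure, or data-quality heterogeneity of real studies.

A separate positive control, `planted_chain_scenario`, perturbs a 5-gene
+1-signed cascade by a coherent +5 log2 shift (sd 0.5) against an N(0, 1)
background.  The shift is deliberately extreme: a 5-position permutation test
has a granularity floor near 1/5! ≈ 0.008, so only a pathway signal that
dominates the background DE pool can reach p ≤ 0.01; the scenario documents
the statistic's behavior when it does.

## Problem sizes and numerical choices

The acceptance script uses: 200 random instances for the cRE oracle
comparison (≤ ~10² intervals each; the reference is quadratic), 100
shared-causal and 100 distinct-causal loci at 200 SNPs, N = 10,000, maf 0.3,
1% variance explained; 1000 null datasets of 3 pathways × 10 genes over a
200-gene universe at 500 permutations each (the add-one estimator is valid at
any permutation count; the API default stays at 2000); and brute-force k-mer
enumeration up to motif length 8.  Posterior normalization is exact to 1e-12;
the H3 complement uses log1mexp to avoid catastrophic cancellation; the
perturbation solve falls back to the damped system above condition number
1e12.  All randomness flows from numpy Generators seeded explicitly;
identical (config, seed) pairs produce byte-identical fixture files (sorted
writers, fixed float formatting).

## Known limitations

* Single-signal colocalization only; no conditioning, no fine-mapping priors
  beyond the single-causal-variant assumption.
* The three gene-importance scores are concrete, swappable stand-ins behind
  one interface (`gene_importance_scores`); other operationalizations of
  "importance among networks / downstream effects / gateway" slot in without
  touching the evidence machinery.
* The PWM scanner handles {A, C, G, T} only; ambiguous bases must be masked
  by the caller.
* No peak calling, loop calling, liftover, read-level processing, or
  heritability regression — those stages consume or produce this package's
  inputs and outputs but live upstream/downstream of it.
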