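"""Allele-specific disruption of transcription-factor binding motifs.

A PWM match is scored with information-content weighting under a uniform
nucleotide background: position i contributes IC_i * log2(p[b,i]/0.25) with
IC_i = 2 + sum_b p log2 p, and the total is min-max normalized against the
motif's best and worst attainable scores.  Match p-values (the probability a
random background k-mer scores at least as high) come from an exact dynamic
program over the discretized score distribution, so variants can be filtered
at the motif-match threshold (0.0005 by default) before their ref/alt score
difference is interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_P_THRESHOLD = 0.0005
EFFECT_STRONG = 0.4
EFFECT_WEAK = 0.1
PVALUE_BIN = 1e-3  # score discretization for the exact match-p DP


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position probability matrix over {A, C, G, T}.

    ``matrix`` has shape (4, L) with rows in A, C, G, T order; columns sum to
    1 after pseudocount normalization.  The background defaults to uniform.
    """

    motif_id: str
    matrix: tuple[tuple[float, ...], ...]
    tf_name: str = ""
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray | Sequence[Sequence[float]],
        pseudocount: float = 0.8,
        tf_name: str = "",
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> "PWM":
        """Build a PWM from a 4 x L count (or frequency) matrix."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (A, C, G, T)")
        probs = (counts + pseudocount / 4.0) / (
            counts.sum(axis=0) + pseudocount
        )
        return cls(
            motif_id=motif_id,
            matrix=tuple(map(tuple, probs)),
            tf_name=tf_name,
            background=tuple(background),  # type: ignore[arg-type]
        )

    def __post_init__(self) -> None:
        arr = self.array
        if arr.shape[0] != 4 or arr.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x L with L >= 1")
        if not np.allclose(arr.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id} columns must sum to 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def __len__(self) -> int:
        return self.array.shape[1]

    @property
    def information_content(self) -> np.ndarray:
        p = self.array
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + h.sum(axis=0)

    @property
    def contributions(self) -> np.ndarray:
        """Per-(base, position) raw score contributions IC_i*log2(p/bkg)."""
        p = self.array
        bkg = np.asarray(self.background)[:, None]
        return self.information_content[None, :] * np.log2(p / bkg)

    def reverse_complement(self) -> "PWM":
        rc = self.array[::-1, ::-1]
        return PWM(
            motif_id=self.motif_id,
            matrix=tuple(map(tuple, rc)),
            tf_name=self.tf_name,
            background=self.background,
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.array.argmax(axis=0))


def pwm_score(window: str, pwm: PWM) -> float:
    """IC-weighted log-odds score of a window, min-max normalized to [0, 1]."""
    raw = pwm_score_raw(window, pwm)
    c = pwm.contributions
    smin, smax = c.min(axis=0).sum(), c.max(axis=0).sum()
    if smax == smin:
        return 0.0
    return float((raw - smin) / (smax - smin))


def pwm_score_raw(window: str, pwm: PWM) -> float:
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != motif length {len(pwm)}"
        )
    c = pwm.contributions
    total = 0.0
    for i, base in enumerate(window.upper()):
        if base not in BASE_INDEX:
            raise ValueError(f"ambiguous base {base!r} at offset {i}")
        total += c[BASE_INDEX[base], i]
    return float(total)


def _binned_contributions(pwm: PWM, bin_width: float) -> np.ndarray:
    """Per-(base, position) contributions rounded to integer score bins."""
    return np.round(pwm.contributions / bin_width).astype(np.int64)


def match_pvalue(pwm: PWM, window: str, bin_width: float = PVALUE_BIN) -> float:
    """P(random background k-mer scores >= the window's score), by exact DP.

    Per-position contributions are discretized to ``bin_width`` bins; the
    window's own score and the full background score distribution are both
    computed in the same integer bin space, so the DP is exact over the
    discretized distribution (and agrees with direct enumeration of all 4^L
    k-mers at any motif length).
    """
    if len(window) != len(pwm):
        raise ValueError("window length must equal motif length")
    bins = _binned_contributions(pwm, bin_width)
    bkg = np.asarray(pwm.background)
    observed = 0
    for i, base in enumerate(window.upper()):
        if base not in BASE_INDEX:
            raise ValueError(f"ambiguous base {base!r} at offset {i}")
        observed += int(bins[BASE_INDEX[base], i])

    dist = np.array([1.0])
    offset = 0  # score value (in bins) of dist[0]
    for i in range(bins.shape[1]):
        col = bins[:, i]
        lo, hi = int(col.min()), int(col.max())
        step = np.zeros(hi - lo + 1)
        for b in range(4):
            step[col[b] - lo] += bkg[b]
        dist = np.convolve(dist, step)
        offset += lo
    thr = max(0, observed - offset)
    if thr >= len(dist):
        return 0.0
    return float(dist[thr:].sum())


def allele_disruption(
    rsid: str,
    flank: str,
    variant_offset: int,
    ref: str,
    alt: str,
    pwms: Iterable[PWM],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    strong: float = EFFECT_STRONG,
    weak: float = EFFECT_WEAK,
) -> pd.DataFrame:
    """Score ref/alt allele motif matches at every placement over a variant.

    ``flank`` is the reference-allele sequence context, with the variant base
    at ``variant_offset`` (0-based); both strands are scanned for every motif
    placement covering the variant.  ``passes_filter`` requires the better
    allele's exact match p-value to reach ``p_threshold``; the effect class
    is strong/weak/neutral on the normalized score difference
    |score_alt - score_ref| at thresholds ``strong`` and ``weak``.
    """
    flank = flank.upper()
    ref, alt = ref.upper(), alt.upper()
    if not (0 <= variant_offset < len(flank)):
        raise ValueError("variant not covered by the provided flank")
    if flank[variant_offset] != ref:
        raise ValueError(
            f"flank has {flank[variant_offset]!r} at the variant position, "
            f"expected ref allele {ref!r}"
        )
    alt_flank = flank[:variant_offset] + alt + flank[variant_offset + 1 :]

    rows = []
    for pwm in pwms:
        L = len(pwm)
        c = pwm.contributions
        smin, smax = c.min(axis=0).sum(), c.max(axis=0).sum()
        span = smax - smin
        for start in range(variant_offset - L + 1, variant_offset + 1):
            if start < 0 or start + L > len(flank):
                continue
            win_ref = flank[start : start + L]
            win_alt = alt_flank[start : start + L]
            for strand in ("+", "-"):
                if strand == "+":
                    wr, wa, motif = win_ref, win_alt, pwm
                else:
                    wr, wa, motif = revcomp(win_ref), revcomp(win_alt), pwm
                raw_ref = pwm_score_raw(wr, motif)
                raw_alt = pwm_score_raw(wa, motif)
                score_ref = (raw_ref - smin) / span if span else 0.0
                score_alt = (raw_alt - smin) / span if span else 0.0
                delta = score_alt - score_ref
                best_window = wr if raw_ref >= raw_alt else wa
                p_best = match_pvalue(motif, best_window)
                if abs(delta) >= strong:
                    effect = "strong"
                elif abs(delta) >= weak:
                    effect = "weak"
                else:
                    effect = "neutral"
                offset_in_motif = (
                    variant_offset - start if strand == "+" else
                    start + L - 1 - variant_offset
                )
                rows.append(
                    {
                        "rsid": rsid,
                        "motif_id": pwm.motif_id,
                        "strand": strand,
                        "offset": offset_in_motif,
                        "score_ref": float(score_ref),
                        "score_alt": float(score_alt),
                        "delta": float(delta),
                        "effect": effect,
                        "match_p": p_best,
                        "passes_filter": p_best <= p_threshold,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid", "motif_id", "strand", "offset", "score_ref", "score_alt",
            "delta", "effect", "match_p", "passes_filter",
        ],
    )


def footprint_overlap(
    variants: pd.DataFrame, mpbs: pd.DataFrame
) -> pd.DataFrame:
    """Annotate variants with overlapping motif-predicted binding sites.

    ``variants`` needs ``rsid, chrom, pos`` (1-based); ``mpbs`` needs
    ``chrom, start, end, motif_id, cell_type`` (0-based half-open).  Returns
    one row per (variant, MPBS) overlap (>= 1 bp, i.e. the variant base falls
    inside the site).
    """
    idx = IntervalIndex(
        (
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            (str(r.motif_id), str(r.cell_type)),
        )
        for r in mpbs.itertuples(index=False)
    )
    rows = []
    for r in variants.itertuples(index=False):
        for motif_id, cell_type in idx.at_point(str(r.chrom), int(r.pos) - 1):
            rows.append(
                {
                    "rsid": str(r.rsid),
                    "motif_id": motif_id,
                    "cell_type": cell_type,
                }
            )
    return pd.DataFrame(rows, columns=["rsid", "motif_id", "cell_type"])


def annotate_agreement(
    disruption: pd.DataFrame, footprints: pd.DataFrame
) -> pd.DataFrame:
    """Flag variants where the same motif is both disrupted and footprinted.

    Returns one row per variant seen in either table, with the sets of
    disrupted motifs (filter-passing only) and footprint motifs, and an
    ``agree`` flag set when they intersect.
    """
    disrupted = (
        disruption[disruption["passes_filter"]]
        .groupby("rsid")["motif_id"]
        .agg(lambda s: sorted(set(s)))
        if len(disruption)
        else pd.Series(dtype=object)
    )
    footprinted = (
        footprints.groupby("rsid")["motif_id"].agg(lambda s: sorted(set(s)))
        if len(footprints)
        else pd.Series(dtype=object)
    )
    rsids = sorted(set(disrupted.index) | set(footprinted.index))
    rows = []
    for rsid in rsids:
        d = set(disrupted.get(rsid, []))
        f = set(footprinted.get(rsid, []))
        rows.append(
            {
                "rsid": rsid,
                "disrupted_motifs": ",".join(sorted(d)),
                "footprint_motifs": ",".join(sorted(f)),
                "agree": bool(d & f),
            }
        )
    return pd.DataFrame(
        rows, columns=["rsid", "disrupted_motifs", "footprint_motifs", "agree"]
    )


def concordance_fisher(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2 x 2 contingency table.

    Returns (odds ratio, p).  The odds ratio uses the Haldane +0.5 correction
    when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    (a, b), (c, d) = t
    if min(a, b, c, d) == 0:
        oddsratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return float(oddsratio), float(p)
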