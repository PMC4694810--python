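"""Co-localized and co-regulated lncRNA-gene pairs (confounder exclusion).

A protein-coding gene within 5 kb of a lncRNA (interval gap, overlap = 0, the
BEDTools-window reading) is co-localized with it. Co-regulation is scored from
active TF regulations: for gene A and lncRNA B, r_AB is the fraction of A's
TFs that also regulate B, r_BA the converse, and r = sqrt(r_AB * r_BA); pairs
with r strictly greater than 0.8 are co-regulated. Active regulations are the
candidate TF->target edges whose univariate regression survives
Benjamini-Hochberg control at FDR < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GenomicInterval
from .lcg_correlation import regress

logger = logging.getLogger("lfsn")

DEFAULT_MAX_GAP = 5_000
DEFAULT_COREG_THRESHOLD = 0.8
DEFAULT_ACTIVE_FDR = 0.01


@dataclass(frozen=True)
class CoregulationScore:
    gene_id: str
    lnc_id: str
    r_ab: float
    r_ba: float
    r: float

    def __post_init__(self) -> None:
        for v in (self.r_ab, self.r_ba, self.r):
            if not 0.0 <= v <= 1.0:
                raise ValueError("coregulation ratios must lie in [0, 1]")


def colocalized_pairs(
    lnc_coords: Sequence[GenomicInterval],
    gene_coords: Sequence[GenomicInterval],
    max_gap: int = DEFAULT_MAX_GAP,
) -> set[tuple[str, str]]:
    """(lnc, gene) pairs whose intervals lie within max_gap bp on the same
    chromosome (gap <= max_gap, inclusive; overlapping intervals count as
    gap 0; strand-agnostic)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in gene_coords:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    out: set[tuple[str, str]] = set()
    for l in lnc_coords:
        for g in by_chrom.get(l.chromosome, []):
            if g.start > l.end + max_gap:
                break
            if l.start < g.end and g.start < l.end:
                gap = 0
            else:
                gap = max(l.start, g.start) - min(l.end, g.end)
            if gap <= max_gap:
                out.add((l.entity_id, g.entity_id))
    return out


def active_regulations(
    candidates: Mapping[str, frozenset[str]],
    tf_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    fdr: float = DEFAULT_ACTIVE_FDR,
) -> dict[str, frozenset[str]]:
    """Retain TF->target edges whose target-on-TF regression is significant
    after Benjamini-Hochberg adjustment over all candidate edges jointly.
    TFs (or targets) without expression are dropped with a logged count."""
    edges: list[tuple[str, str]] = []
    n_dropped = 0
    tf_rows = {e: i for i, e in enumerate(tf_expr.entity_ids)}
    target_rows = {e: i for i, e in enumerate(target_expr.entity_ids)}
    for tf, targets in candidates.items():
        if tf not in tf_rows:
            n_dropped += len(targets)
            continue
        for t in targets:
            if t in target_rows:
                edges.append((tf, t))
            else:
                n_dropped += 1
    if n_dropped:
        logger.info("active_regulations: dropped %d edges lacking expression", n_dropped)
    if not edges:
        return {}
    pvals = np.array([
        regress(tf_expr.values[tf_rows[tf]], target_expr.values[target_rows[t]]).p_value
        for tf, t in edges
    ])
    keep, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    out: dict[str, set[str]] = {}
    for (tf, t), k in zip(edges, keep):
        if k:
            out.setdefault(tf, set()).add(t)
    return {tf: frozenset(t) for tf, t in out.items()}


def regulators_of(regulations: Mapping[str, frozenset[str]]) -> dict[str, frozenset[str]]:
    """Invert tf -> targets into target -> set of TFs."""
    out: dict[str, set[str]] = {}
    for tf, targets in regulations.items():
        for t in targets:
            out.setdefault(t, set()).add(tf)
    return {t: frozenset(tfs) for t, tfs in out.items()}


def coregulation_score(tfs_of_a: frozenset[str], tfs_of_b: frozenset[str],
                       gene_id: str = "A", lnc_id: str = "B") -> CoregulationScore:
    """r = sqrt(r_AB * r_BA); defined as 0 when either TF set is empty."""
    if not tfs_of_a or not tfs_of_b:
        return CoregulationScore(gene_id, lnc_id, 0.0, 0.0, 0.0)
    inter = len(tfs_of_a & tfs_of_b)
    r_ab = inter / len(tfs_of_a)
    r_ba = inter / len(tfs_of_b)
    return CoregulationScore(gene_id, lnc_id, r_ab, r_ba, float(np.sqrt(r_ab * r_ba)))


def coregulated_pairs(
    regulations: Mapping[str, frozenset[str]],
    lnc_ids: Sequence[str],
    gene_ids: Sequence[str],
    threshold: float = DEFAULT_COREG_THRESHOLD,
) -> set[tuple[str, str]]:
    """(lnc, gene) pairs with coregulation score r strictly above threshold,
    computed from (active) TF regulations."""
    tf_of = regulators_of(regulations)
    lnc_with_tfs = [l for l in lnc_ids if tf_of.get(l)]
    gene_with_tfs = [g for g in gene_ids if tf_of.get(g)]
    out: set[tuple[str, str]] = set()
    for l in lnc_with_tfs:
        for g in gene_with_tfs:
            score = coregulation_score(tf_of[g], tf_of[l], gene_id=g, lnc_id=l)
            if score.r > threshold:
                out.add((l, g))
    return out
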