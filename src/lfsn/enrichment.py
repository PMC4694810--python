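"""Hypergeometric GO BP enrichment of the common LCGs of a lncRNA pair.

For lncRNAs A and B the shared LCG set (required to contain at least three
genes) is tested against every retained GO BP term with the upper-tail
hypergeometric probability

    p_i = P(X >= x) = 1 - sum_{t=0}^{x-1} C(K_i, t) C(N-K_i, M-t) / C(N, M)

where N is the annotated background size, K_i the term size, M the size of
the shared LCG set inside the background, and x the overlap with the term.
The tail sum is evaluated in log space for stability. Each enriched term
yields a candidate functional module G_AB = common LCGs annotated to that
term, later vetted against the protein-interaction network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection
from .lcg_correlation import LCGSet

DEFAULT_ALPHA_ENRICH = 0.01
DEFAULT_MIN_COMMON = 3


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    x: int
    K_i: int
    M: int
    N: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.K_i, self.M) <= self.N):
            raise ValueError("inconsistent hypergeometric counts")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class CandidateModule:
    """A lncRNA pair, an enriched term, and the shared-LCG subset G_AB.

    topology_pass is None until the PPI filter has run.
    """

    pair: frozenset[str]
    term_id: str
    genes: frozenset[str]
    enrichment: EnrichmentResult
    p_adjusted: float
    topology_pass: Optional[bool] = None

    def with_verdict(self, passed: bool) -> "CandidateModule":
        return replace(self, topology_pass=passed)


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(x: int, K_i: int, M: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K_i, M), summed in log space so
    extreme overlaps at transcriptome-scale N do not underflow.

    x = 0 gives 1 exactly (the tail is the whole distribution).
    """
    for name, v in (("x", x), ("K_i", K_i), ("M", M), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    x, K_i, M, N = int(x), int(K_i), int(M), int(N)
    if K_i > N or M > N:
        raise ValueError("K_i and M must not exceed N")
    if x > min(K_i, M):
        raise ValueError("x cannot exceed min(K_i, M)")
    if x == 0:
        return 1.0
    lc_nm = _lchoose(N, M)
    log_terms = []
    for t in range(x, min(K_i, M) + 1):
        if M - t > N - K_i:
            continue  # outside the hypergeometric support
        log_terms.append(_lchoose(K_i, t) + _lchoose(N - K_i, M - t) - lc_nm)
    if not log_terms:
        raise ValueError("impossible configuration: no attainable overlap >= x")
    top = max(log_terms)
    if top == float("-inf"):
        raise ValueError("impossible configuration: no attainable overlap >= x")
    return min(1.0, math.exp(top + math.log(math.fsum(math.exp(l - top) for l in log_terms))))


def common_lcgs(lcgs_a: LCGSet, lcgs_b: LCGSet,
                min_size: int = DEFAULT_MIN_COMMON) -> Optional[frozenset[str]]:
    """Shared LCGs of a pair; None when fewer than min_size genes overlap
    (the pair produces no candidate modules)."""
    if lcgs_a.alpha != lcgs_b.alpha:
        raise ValueError("LCG sets computed at different alpha levels")
    common = lcgs_a.genes & lcgs_b.genes
    if len(common) < min_size:
        return None
    return frozenset(common)


def enrich_pair(
    pair: tuple[str, str] | frozenset[str],
    common: frozenset[str],
    go: GeneSetCollection,
    alpha_enrich: float = DEFAULT_ALPHA_ENRICH,
    correction: str = "BH",
) -> list[CandidateModule]:
    """Candidate modules for one lncRNA pair: every retained GO term whose
    overlap with the shared LCGs is significant at alpha_enrich (after the
    chosen multiplicity correction across all I retained terms).

    x and M are counted inside the annotated background (genes outside it
    cannot contribute to any term's overlap).
    """
    if len(go) == 0:
        raise ValueError("empty gene-set collection")
    if correction not in {"none", "BH", "bonferroni"}:
        raise ValueError(f"unknown correction {correction!r}")
    pair = frozenset(pair)
    if len(pair) != 2:
        raise ValueError("pair must contain two distinct lncRNAs")
    N = go.background_size
    annotated_common = common & go.universe
    M = len(annotated_common)
    term_ids = go.term_ids
    pvals = np.ones(len(term_ids))
    overlaps: list[frozenset[str]] = []
    for i, term in enumerate(term_ids):
        genes = go.genes(term)
        hit = annotated_common & genes
        overlaps.append(frozenset(hit))
        pvals[i] = hypergeom_upper_tail(len(hit), len(genes), M, N)
    if correction == "none":
        adjusted = pvals
        significant = pvals < alpha_enrich
    elif correction == "bonferroni":
        adjusted = np.minimum(pvals * len(term_ids), 1.0)
        significant = adjusted < alpha_enrich
    else:
        significant, adjusted, _, _ = multipletests(pvals, alpha=alpha_enrich, method="fdr_bh")
        significant = adjusted < alpha_enrich
    out: list[CandidateModule] = []
    for i, term in enumerate(term_ids):
        if significant[i] and len(overlaps[i]) >= 1:
            res = EnrichmentResult(term, len(overlaps[i]), len(go.genes(term)), M, N,
                                   max(pvals[i], np.nextafter(0, 1)))
            out.append(CandidateModule(pair, term, overlaps[i], res, float(adjusted[i])))
    return out
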