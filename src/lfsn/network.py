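"""Assembly and topological analysis of the lncRNA functional synergistic
network (LFSN).

Nodes are lncRNAs; an edge joins two lncRNAs that co-regulate at least one
functional module that survived enrichment and PPI-topology filtering. Edge
weight is the number of shared modules (the unweighted analyses treat every
edge as weight 1). Topological analyses: discrete power-law fit of the degree
distribution, top-decile hubs, k-clique percolation communities, chromosome
co-localization of synergistic pairs, and enrichment/degree tests for special
node sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from networkx.algorithms.community import k_clique_communities
from scipy import optimize, stats
from scipy.special import zeta

from .enrichment import CandidateModule
from .io_formats import GenomicInterval


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble(passing: Iterable[CandidateModule]) -> nx.Graph:
    """Build the LFSN from candidates with topology_pass = True: one edge per
    lncRNA pair with >= 1 passing module; weight = number of passing modules,
    and the module list (term id, gene set) is stored on the edge."""
    g = nx.Graph()
    for cand in passing:
        if cand.topology_pass is not True:
            continue
        a, b = sorted(cand.pair)
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
            g[a][b]["modules"].append((cand.term_id, cand.genes))
        else:
            g.add_edge(a, b, weight=1, modules=[(cand.term_id, cand.genes)])
    # deterministic module ordering regardless of candidate order
    for _, _, data in g.edges(data=True):
        data["modules"].sort(key=lambda m: (m[0], tuple(sorted(m[1]))))
    return g


# ---------------------------------------------------------------------------
# Power-law degree distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    xmin: int
    ks_stat: float

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("power-law exponent must exceed 1")
        if self.xmin < 1:
            raise ValueError("xmin must be >= 1")


def _discrete_mle(xs: np.ndarray, xmin: int) -> float:
    """Maximum-likelihood scaling exponent for a discrete power law with
    lower cutoff xmin (zeta-normalized likelihood)."""
    n = xs.size
    slog = float(np.log(xs).sum())

    def negll(alpha: float) -> float:
        return n * math.log(zeta(alpha, xmin)) + alpha * slog

    res = optimize.minimize_scalar(negll, bounds=(1.0001, 12.0), method="bounded")
    return float(res.x)


def _ks_discrete(xs: np.ndarray, alpha: float, xmin: int) -> float:
    values = np.arange(xmin, xs.max() + 1)
    pmf = values.astype(float) ** (-alpha) / zeta(alpha, xmin)
    cdf_model = np.cumsum(pmf)
    counts = np.bincount(xs, minlength=xs.max() + 1)[xmin:]
    cdf_emp = np.cumsum(counts) / xs.size
    return float(np.max(np.abs(cdf_emp - cdf_model)))


def fit_power_law(degrees: Sequence[int]) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit with xmin chosen by KS
    minimization over candidate cutoffs."""
    xs = np.asarray([d for d in degrees if d >= 1], dtype=int)
    if xs.size < 10:
        raise ValueError("need at least 10 nodes with degree >= 1")
    if np.all(xs == xs[0]):
        raise ValueError("degenerate distribution: all degrees equal")
    best: Optional[PowerLawFit] = None
    for xmin in sorted(set(xs)):
        tail = xs[xs >= xmin]
        if tail.size < 10 or np.all(tail == tail[0]):
            continue
        alpha = _discrete_mle(tail, xmin)
        ks = _ks_discrete(tail, alpha, xmin)
        if best is None or ks < best.ks_stat:
            best = PowerLawFit(alpha, xmin, ks)
    if best is None:
        raise ValueError("no admissible xmin (too few distinct degrees)")
    return best


def sample_discrete_power_law(alpha: float, n: int, xmin: int = 1,
                              rng: int | np.random.Generator = 0,
                              xmax: int = 10_000) -> np.ndarray:
    """Draw from a truncated discrete power law by inverse-CDF lookup
    (test/benchmark helper)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    values = np.arange(xmin, xmax + 1)
    pmf = values.astype(float) ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(values, size=n, p=pmf)


# ---------------------------------------------------------------------------
# Hubs and communities
# ---------------------------------------------------------------------------


def hubs(graph: nx.Graph, fraction: float = 0.10, weighted: bool = False) -> frozenset[str]:
    """The ceil(fraction * n) highest-connectivity nodes. With weighted=True,
    connectivity is node strength (sum of incident edge weights, the weighted
    network's summary score). Ties at the cutoff break lexicographically."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if weighted:
        conn = dict(graph.degree(weight="weight"))
    else:
        conn = dict(graph.degree())
    k = math.ceil(fraction * graph.number_of_nodes())
    ranked = sorted(conn, key=lambda v: (-conn[v], v))
    return frozenset(ranked[:k])


@dataclass(frozen=True)
class CliqueModule:
    k: int
    members: frozenset[str]
    community_id: int

    def __post_init__(self) -> None:
        if len(self.members) < self.k:
            raise ValueError("community smaller than k")


def clique_communities(graph: nx.Graph, k: int) -> list[CliqueModule]:
    """k-clique percolation communities: connected components of the k-clique
    adjacency graph (two k-cliques adjacent iff they share k-1 nodes). Nodes
    may belong to several communities."""
    if k < 3:
        raise ValueError("k must be >= 3")
    comms = [frozenset(c) for c in k_clique_communities(graph, k)]
    comms.sort(key=lambda c: tuple(sorted(c)))
    return [CliqueModule(k, c, i) for i, c in enumerate(comms)]


def module_participation(graph: nx.Graph, k: int) -> float:
    """Fraction of network lncRNAs belonging to >= 1 k-clique community."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    members: set[str] = set()
    for mod in clique_communities(graph, k):
        members |= mod.members
    return len(members) / graph.number_of_nodes()


def k_sweep(graph: nx.Graph, k_min: int = 3, k_max: int = 8) -> dict[int, dict[str, float]]:
    """Community counts and cumulative lncRNA ratios across a k range."""
    out: dict[int, dict[str, float]] = {}
    n = max(graph.number_of_nodes(), 1)
    seen: set[str] = set()
    for k in range(k_min, k_max + 1):
        mods = clique_communities(graph, k)
        for m in mods:
            seen |= m.members
        out[k] = {"n_modules": len(mods), "cumulative_lnc_ratio": len(seen) / n}
    return out


def threshold_network(graph: nx.Graph, min_weight: int) -> nx.Graph:
    """Weighted-LFSN variant: keep edges with weight >= min_weight."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes())
    for a, b, data in graph.edges(data=True):
        if data.get("weight", 1) >= min_weight:
            g.add_edge(a, b, **data)
    return g


def weighted_modules(graph: nx.Graph, k: int,
                     weight_thresholds: Sequence[int]) -> dict[int, list[CliqueModule]]:
    """Clique-percolation modules at a gradient of edge-weight thresholds."""
    return {w: clique_communities(threshold_network(graph, w), k)
            for w in weight_thresholds}


# ---------------------------------------------------------------------------
# Chromosome co-localization of synergistic pairs
# ---------------------------------------------------------------------------


@dataclass
class ColocalizationReport:
    n_pairs: int
    n_excluded: int
    n_same_chr: int
    frac_same_chr: float
    n_within_window: int
    frac_within_window: float
    p_same_chr: float
    p_within_window: float


def _interval_gap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chromosome != b.chromosome:
        return np.inf
    if a.start < b.end and b.start < a.end:
        return 0.0
    return float(max(a.start, b.start) - min(a.end, b.end))


def chromosome_colocalization(
    graph: nx.Graph,
    coords: Sequence[GenomicInterval],
    window: float = 10_000_000,
    n_perm: int = 1000,
    seed: int = 0,
) -> ColocalizationReport:
    """Same-chromosome and within-window (gap strictly < window) fractions of
    synergistic pairs, with permutation p-values obtained by shuffling the
    lncRNA-to-coordinate assignment."""
    loc = {iv.entity_id: iv for iv in coords}
    pairs = [(a, b) for a, b in graph.edges() if a in loc and b in loc]
    n_excluded = graph.number_of_edges() - len(pairs)
    if not pairs:
        raise ValueError("no edge has coordinates for both endpoints")

    def fractions(assignment: Mapping[str, GenomicInterval]) -> tuple[float, float]:
        same = within = 0
        for a, b in pairs:
            gap = _interval_gap(assignment[a], assignment[b])
            if np.isfinite(gap):
                same += 1
                if gap < window:
                    within += 1
        return same / len(pairs), within / len(pairs)

    obs_same, obs_within = fractions(loc)
    rng = np.random.default_rng(seed)
    located = sorted({n for pair in pairs for n in pair})
    ivs = [loc[n] for n in located]
    ge_same = ge_within = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(located))
        shuffled = {located[i]: ivs[perm[i]] for i in range(len(located))}
        s, w = fractions(shuffled)
        ge_same += s >= obs_same
        ge_within += w >= obs_within
    return ColocalizationReport(
        n_pairs=len(pairs),
        n_excluded=n_excluded,
        n_same_chr=int(round(obs_same * len(pairs))),
        frac_same_chr=obs_same,
        n_within_window=int(round(obs_within * len(pairs))),
        frac_within_window=obs_within,
        p_same_chr=(1 + ge_same) / (1 + n_perm),
        p_within_window=(1 + ge_within) / (1 + n_perm),
    )


# ---------------------------------------------------------------------------
# Degree and set enrichment tests for special lncRNA sets
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test: exact null enumeration on small
    tie-free samples, otherwise the normal approximation with tie correction.
    Returns (Mann-Whitney U statistic, p)."""
    dx = np.asarray(x, dtype=float)
    dy = np.asarray(y, dtype=float)
    if dx.size == 0 or dy.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([dx, dy])
    if np.ptp(pooled) == 0:  # every observation tied: no evidence either way
        return float(dx.size * dy.size / 2), 1.0
    ties = len(np.unique(pooled)) < dx.size + dy.size
    if not ties and dx.size <= 25 and dy.size <= 25:
        res = stats.mannwhitneyu(dx, dy, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(dx, dy, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def degree_difference_test(graph: nx.Graph, special: Iterable[str]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on degrees of the special lncRNAs vs
    all other network lncRNAs. Returns (statistic, p)."""
    special = set(special) & set(graph.nodes())
    others = set(graph.nodes()) - special
    if not special or not others:
        raise ValueError("both groups must be nonempty")
    return wilcoxon_rank_sum([graph.degree(v) for v in sorted(special)],
                             [graph.degree(v) for v in sorted(others)])


@dataclass
class FisherRecord:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    degenerate: bool = False


def set_enrichment_test(universe: Iterable[str], special: Iterable[str],
                        target: Iterable[str]) -> FisherRecord:
    """Fisher's exact test (two-sided, conditional) for enrichment of the
    special set within the target set over the universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    special = set(special) & universe
    target = set(target) & universe
    a = len(special & target)
    b = len(special - target)
    c = len(target - special)
    d = len(universe - special - target)
    table = ((a, b), (c, d))
    if b == 0 and c == 0 and d == 0:
        return FisherRecord(table, float("nan"), 1.0, degenerate=True)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return FisherRecord(table, float(odds), float(p))
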