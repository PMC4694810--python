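"""Topological vetting of candidate functional modules in the PPI network.

A candidate module passes when (i) every member gene lies within shortest-path
distance 2 of its nearest other member, and (ii) the module's characteristic
path length (CPL, the mean over all unordered member pairs of their
shortest-path distance in the full network) is significantly shorter than in
degree-preserving randomizations of the network.

Randomization uses edge switching: repeatedly pick two edges (a-b, c-d) and
rewire to (a-d, c-b), rejecting swaps that would create self-loops or
parallel edges, so the degree sequence is preserved exactly. One pool of
randomized networks is generated per input PPI graph and reused across all
modules; the empirical p-value uses the (r+1)/(n+1) pseudocount form with a
strict "shorter than" comparison, so ties count against significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .enrichment import CandidateModule

logger = logging.getLogger("lfsn")

DEFAULT_N_RANDOM = 1000
DEFAULT_CPL_THRESHOLD = 0.05
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class TopologyVerdict:
    genes: frozenset[str]
    n_mapped: int
    min_dist_ok: bool
    cpl_real: float
    cpl_p: Optional[float]
    n_random: int
    passed: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# Distances and criteria
# ---------------------------------------------------------------------------


def _adjacency(graph: nx.Graph) -> tuple[csr_matrix, dict[str, int]]:
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for a, b in graph.edges():
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
    data = np.ones(len(rows), dtype=np.int8)
    return csr_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes))), index


def subset_distances(genes, graph: nx.Graph) -> tuple[list[str], np.ndarray]:
    """Pairwise shortest-path distances among the module genes, computed in
    the FULL network (small induced subgraphs are almost always disconnected,
    which would make the criteria vacuous). Genes absent from the network are
    dropped with a logged count; unreachable pairs get +inf.

    Returns (mapped gene list, len x len distance matrix).
    """
    genes = sorted(set(genes))
    mapped = [g for g in genes if g in graph]
    if len(mapped) < len(genes):
        logger.info("subset_distances: dropped %d unmapped genes", len(genes) - len(mapped))
    if len(mapped) < 2:
        raise ValueError("unmappable: fewer than 2 module genes are in the network")
    adj, index = _adjacency(graph)
    idx = [index[g] for g in mapped]
    full = shortest_path(adj, method="D", unweighted=True, indices=idx)
    return mapped, full[:, idx]


def _subset_distance_matrix(adj: csr_matrix, idx: Sequence[int]) -> np.ndarray:
    full = shortest_path(adj, method="D", unweighted=True, indices=list(idx))
    return full[:, list(idx)]


def min_distance_ok(distances: np.ndarray, rule: str = "nearest") -> bool:
    """Criterion (i): with the default 'nearest' rule, every gene's distance
    to its nearest other member is <= 2; 'all_pairs' demands every pairwise
    distance <= 2."""
    d = np.asarray(distances, dtype=float).copy()
    np.fill_diagonal(d, np.inf)
    if rule == "nearest":
        return bool(np.all(d.min(axis=1) <= 2))
    if rule == "all_pairs":
        return bool(np.all(d <= 2))
    raise ValueError(f"unknown min_dist rule {rule!r}")


def cpl(distances: np.ndarray) -> float:
    """Characteristic path length: mean over unordered pairs; +inf when any
    pair is unreachable."""
    d = np.asarray(distances, dtype=float)
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    if np.any(np.isinf(vals)):
        return np.inf
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------


def edge_switch(graph: nx.Graph, n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
                seed: int | np.random.Generator = 0) -> nx.Graph:
    """Degree-preserving randomization by repeated edge swaps.

    Attempts n_swaps_per_edge * |E| swaps; each picks two distinct edges and a
    random orientation, and is rejected if it would create a self-loop or a
    parallel edge. The degree sequence is invariant under the accepted move.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [tuple(e) for e in graph.edges()]
    edge_set = {frozenset(e) for e in edges}
    m = len(edges)
    if m < 2:
        return graph.copy()
    n_attempts = n_swaps_per_edge * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.integers(0, 2, size=n_attempts)
    for k in range(n_attempts):
        i, j = pick[k]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip[k]:
            c, d = d, c
        # proposed: a-d, c-b
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
    out = nx.Graph()
    out.add_nodes_from(graph.nodes())
    out.add_edges_from(edges)
    return out


class RandomNetworkPool:
    """A reusable pool of degree-preserving randomizations of one PPI graph,
    stored as sparse adjacency matrices over a fixed node indexing."""

    def __init__(self, graph: nx.Graph, n_random: int = DEFAULT_N_RANDOM,
                 n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE, seed: int = 0):
        if n_random <= 0:
            raise ValueError("n_random must be positive (degenerate null otherwise)")
        self.n_random = n_random
        self.nodes = sorted(graph.nodes())
        self.index = {v: i for i, v in enumerate(self.nodes)}
        rng = np.random.default_rng(seed)
        self.matrices: list[csr_matrix] = []
        for _ in range(n_random):
            randomized = edge_switch(graph, n_swaps_per_edge, rng)
            adj, _ = _adjacency_with_index(randomized, self.index)
            self.matrices.append(adj)

    def subset_cpls(self, genes: Sequence[str]) -> np.ndarray:
        idx = [self.index[g] for g in genes if g in self.index]
        out = np.empty(self.n_random)
        for k, adj in enumerate(self.matrices):
            out[k] = cpl(_subset_distance_matrix(adj, idx))
        return out


def _adjacency_with_index(graph: nx.Graph, index: dict[str, int]) -> tuple[csr_matrix, dict[str, int]]:
    rows, cols = [], []
    for a, b in graph.edges():
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
    data = np.ones(len(rows), dtype=np.int8)
    n = len(index)
    return csr_matrix((data, (rows, cols)), shape=(n, n)), index


def cpl_pvalue(genes, graph: nx.Graph, pool: RandomNetworkPool) -> TopologyVerdict:
    """Empirical probability that the same gene subset has a strictly shorter
    CPL in a randomized network: p = (1 + #shorter) / (1 + n_random)."""
    mapped, dist = subset_distances(genes, graph)
    ok = min_distance_ok(dist)
    real = cpl(dist)
    random_cpls = pool.subset_cpls(mapped)
    r = int(np.sum(random_cpls < real))
    p = (1 + r) / (1 + pool.n_random)
    return TopologyVerdict(frozenset(genes), len(mapped), ok, real, p, pool.n_random,
                           passed=False)


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------


def filter_candidates(
    candidates: list[CandidateModule],
    graph: nx.Graph,
    cpl_threshold: float = DEFAULT_CPL_THRESHOLD,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
    min_dist_rule: str = "nearest",
    pool: Optional[RandomNetworkPool] = None,
) -> tuple[list[CandidateModule], dict[frozenset[str], TopologyVerdict]]:
    """Set topology_pass on every candidate: pass iff criterion (i) holds and
    the CPL p-value is below cpl_threshold. The randomized-network pool is
    built once (or supplied) and shared across modules; identical gene sets
    are evaluated once. Criterion (ii) is skipped when (i) already fails."""
    if not candidates:
        return [], {}
    if pool is None:
        pool = RandomNetworkPool(graph, n_random=n_random, seed=seed)
    verdicts: dict[frozenset[str], TopologyVerdict] = {}
    out: list[CandidateModule] = []
    for cand in candidates:
        key = cand.genes
        if key not in verdicts:
            verdicts[key] = _evaluate(key, graph, pool, cpl_threshold, min_dist_rule)
        out.append(cand.with_verdict(verdicts[key].passed))
    return out, verdicts


def _evaluate(genes: frozenset[str], graph: nx.Graph, pool: RandomNetworkPool,
              cpl_threshold: float, min_dist_rule: str) -> TopologyVerdict:
    try:
        mapped, dist = subset_distances(genes, graph)
    except ValueError:
        return TopologyVerdict(genes, 0, False, np.inf, None, pool.n_random,
                               passed=False, reason="unmappable")
    ok = min_distance_ok(dist, rule=min_dist_rule)
    real = cpl(dist)
    if not ok:
        return TopologyVerdict(genes, len(mapped), False, real, None, pool.n_random,
                               passed=False, reason="min_distance")
    random_cpls = pool.subset_cpls(mapped)
    r = int(np.sum(random_cpls < real))
    p = (1 + r) / (1 + pool.n_random)
    passed = p < cpl_threshold
    return TopologyVerdict(genes, len(mapped), True, real, p, pool.n_random,
                           passed=passed, reason="" if passed else "cpl_p")
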