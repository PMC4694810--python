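"""Cancer-associated lncRNAs, Markov clustering of hallmark subnetworks, and
prognostic-module testing.

Cancer-associated lncRNAs are collected either from per-lncRNA univariate Cox
proportional-hazards fits (raw Wald p < 0.05) or from tumor/normal
differential expression (Student's t-test, Bonferroni-adjusted p < 0.01).
Known disease lncRNAs are mapped onto measured ones by >= 80% reciprocal
genomic overlap. Modules are found in each hallmark subnetwork with the
Markov Clustering Algorithm (expansion 2, inflation 2.0, self-loops added);
for each module of >= 3 lncRNAs, tumor samples are split into two groups by
K-means (K = 2) on the module lncRNAs' expression, the split is tested by the
two-group log-rank test, and modules with log-rank p < 0.05 are re-tested in
a multivariate Cox model adjusting for clinical covariates. Survival ties use
the Breslow approximation (lifelines' default).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans

from .io_formats import ClinicalTable, ExpressionMatrix, GenomicInterval

logger = logging.getLogger("lfsn")

DEFAULT_COX_ALPHA = 0.05
DEFAULT_DE_FDR = 0.01
DEFAULT_LOGRANK_ALPHA = 0.05
DEFAULT_MIN_MODULE_SIZE = 3


# ---------------------------------------------------------------------------
# Cancer-associated lncRNA sets
# ---------------------------------------------------------------------------


@dataclass
class CancerAssocSet:
    mode: str
    lncs: frozenset[str]
    stats: dict[str, float]  # per-lncRNA raw Wald p (cox) or adjusted p (de)
    skipped: frozenset[str] = frozenset()  # constant-expression lncRNAs


def _align_samples(expr: ExpressionMatrix, clinical: ClinicalTable) -> np.ndarray:
    if set(expr.sample_ids) != set(clinical.sample_ids):
        raise ValueError("expression and clinical tables cover different samples")
    order = [expr.sample_ids.index(s) for s in clinical.sample_ids]
    return expr.values[:, order]


def cancer_associated(
    lnc_expr: ExpressionMatrix,
    clinical: Optional[ClinicalTable] = None,
    labels: Optional[Mapping[str, int]] = None,
    mode: str = "cox",
    cox_alpha: float = DEFAULT_COX_ALPHA,
    de_fdr: float = DEFAULT_DE_FDR,
) -> CancerAssocSet:
    """Extend the cancer-associated lncRNA set by prognosis (mode='cox':
    univariate proportional-hazards Wald p < 0.05, raw) or by differential
    expression (mode='de': two-sample t-test, Bonferroni-adjusted p < 0.01).

    Constant-expression lncRNAs admit no test and are skipped with a flag.
    """
    if mode == "cox":
        if clinical is None:
            raise ValueError("cox mode requires a clinical table")
        if clinical.event.sum() == 0:
            raise ValueError("no events in clinical table")
        values = _align_samples(lnc_expr, clinical)
        base = pd.DataFrame({"time": clinical.time, "event": clinical.event})
        kept: dict[str, float] = {}
        skipped: set[str] = set()
        stats_out: dict[str, float] = {}
        for i, lnc in enumerate(lnc_expr.entity_ids):
            x = values[i]
            if np.ptp(x) == 0:
                skipped.add(lnc)
                continue
            df = base.copy()
            df["x"] = (x - x.mean()) / x.std(ddof=0)
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="time", event_col="event")
            except ConvergenceError:
                skipped.add(lnc)
                continue
            p = float(cph.summary.loc["x", "p"])
            stats_out[lnc] = p
            if p < cox_alpha:
                kept[lnc] = p
        return CancerAssocSet("cox", frozenset(kept), stats_out, frozenset(skipped))

    if mode == "de":
        if labels is None:
            raise ValueError("de mode requires tumor/normal labels")
        group = np.array([labels[s] for s in lnc_expr.sample_ids])
        if min((group == 0).sum(), (group == 1).sum()) < 2:
            raise ValueError("each group needs >= 2 samples")
        skipped = set()
        raw: dict[str, float] = {}
        for i, lnc in enumerate(lnc_expr.entity_ids):
            x = lnc_expr.values[i]
            if np.ptp(x) == 0:
                skipped.add(lnc)
                continue
            _, p = stats.ttest_ind(x[group == 1], x[group == 0])
            raw[lnc] = float(p)
        m = len(raw)
        adjusted = {l: min(p * m, 1.0) for l, p in raw.items()}
        kept = frozenset(l for l, p in adjusted.items() if p < de_fdr)
        return CancerAssocSet("de", kept, adjusted, frozenset(skipped))

    raise ValueError(f"unknown mode {mode!r}")


def map_known_lncRNAs(
    known: Sequence[GenomicInterval],
    measured: Sequence[GenomicInterval],
    min_overlap: float = 0.8,
) -> dict[str, str]:
    """Match known disease lncRNAs to measured ones by reciprocal overlap:
    the shared length must cover >= min_overlap of BOTH intervals. Returns
    known id -> measured id (best overlap when several qualify)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in measured:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    out: dict[str, str] = {}
    for kv in known:
        best: tuple[float, str] | None = None
        for mv in by_chrom.get(kv.chromosome, []):
            ov = min(kv.end, mv.end) - max(kv.start, mv.start)
            if ov <= 0:
                continue
            if ov >= min_overlap * len(kv) and ov >= min_overlap * len(mv):
                frac = ov / max(len(kv), len(mv))
                if best is None or frac > best[0] or (frac == best[0] and mv.entity_id < best[1]):
                    best = (frac, mv.entity_id)
        if best is not None:
            out[kv.entity_id] = best[1]
    return out


# ---------------------------------------------------------------------------
# Markov clustering (MCL)
# ---------------------------------------------------------------------------


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[frozenset[str]]:
    """Markov Clustering: alternate expansion (matrix power) and inflation
    (elementwise power + column renormalization) of the column-stochastic
    flow matrix with self-loops added, until the matrix change falls below
    tol. Clusters are read off the limit matrix's attractor rows; every node
    is assigned to at least one cluster. Deterministic."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes())
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("edge weights must be non-negative")
        m[index[a], index[b]] = m[index[b], index[a]] = w
    np.fill_diagonal(m, 1.0)  # self-loops damp oscillation
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        m[m < 1e-12] = 0.0
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("mcl: no convergence after %d iterations; using current state", max_iter)
    # attractors: rows with nonzero diagonal; cluster = attractor row support,
    # overlapping attractor rows merged
    thresh = 1e-8
    clusters: list[set[str]] = []
    assigned: set[str] = set()
    for i in range(n):
        if m[i, i] > thresh:
            members = {nodes[j] for j in np.nonzero(m[i] > thresh)[0]}
            merged = False
            for c in clusters:
                if c & members:
                    c |= members
                    merged = True
                    break
            if not merged:
                clusters.append(set(members))
            assigned |= members
    for v in nodes:  # orphans (numerically dead columns) become singletons
        if v not in assigned:
            clusters.append({v})
    return [frozenset(c) for c in sorted(clusters, key=lambda c: tuple(sorted(c)))]


# ---------------------------------------------------------------------------
# Sample clustering and survival tests
# ---------------------------------------------------------------------------


def cluster_samples(
    module_expr: ExpressionMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    method: str = "kmeans",
) -> np.ndarray:
    """Two-group sample partition from module lncRNA expression: K-means with
    multiple seeded restarts (default) or Ward agglomerative clustering cut at
    k. Group 1 is the higher mean-module-expression group, so hazard ratios
    orient consistently across modules. Returns 0/1 labels per sample."""
    if module_expr.n_entities < 2:
        raise ValueError("need >= 2 lncRNAs in the module")
    if module_expr.n_samples < 4:
        raise ValueError("need >= 4 samples")
    X = module_expr.values.T  # samples x lncRNAs
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("degenerate clustering: all samples identical")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
    elif method == "ward":
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    if k == 2:
        means = [X[labels == g].mean() for g in (0, 1)]
        if means[0] > means[1]:
            labels = 1 - labels
    return labels.astype(int)


def logrank(labels: np.ndarray, clinical: ClinicalTable) -> tuple[float, float]:
    """Two-group log-rank test (1 df). Returns (chi-square statistic, p)."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("log-rank test requires exactly two nonempty groups")
    if clinical.event.sum() == 0:
        raise ValueError("no events")
    a = labels == groups[0]
    res = logrank_test(
        clinical.time[a], clinical.time[~a],
        event_observed_A=clinical.event[a], event_observed_B=clinical.event[~a],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class PrognosticModuleResult:
    members: frozenset[str]
    labels: np.ndarray
    logrank_stat: float
    logrank_p: float
    hazard_ratio: float
    hr_p: float
    covariates: tuple[str, ...]
    converged: bool = True
    flagged_reason: str = ""

    @property
    def significant(self) -> bool:
        return (self.converged and self.logrank_p < DEFAULT_LOGRANK_ALPHA
                and self.hr_p < DEFAULT_COX_ALPHA)


def cox_multivariate(
    clinical: ClinicalTable,
    module_group: np.ndarray,
    covariates: Sequence[str] = (),
    members: Iterable[str] = (),
    logrank_stat: float = float("nan"),
    logrank_p: float = float("nan"),
) -> PrognosticModuleResult:
    """Proportional-hazards fit of survival on the module group indicator plus
    clinical covariates; reports the group hazard ratio and Wald p. Separation
    or non-convergence yields a flagged (non-significant) result, not a crash."""
    group = np.asarray(module_group, dtype=float)
    if np.ptp(group) == 0:
        raise ValueError("collinear/degenerate: group indicator is constant")
    df = pd.DataFrame({"time": clinical.time, "event": clinical.event, "group": group})
    for c in covariates:
        if c not in clinical.covariates.columns:
            raise ValueError(f"unknown covariate {c!r}")
        col = clinical.covariates[c].to_numpy(float)
        if np.ptp(col) == 0:
            logger.info("cox_multivariate: dropping constant covariate %r", c)
            continue
        if np.allclose(col, group) or np.allclose(col, 1 - group):
            raise ValueError(f"covariate {c!r} is collinear with the group indicator")
        df[c] = col
    used = tuple(c for c in df.columns if c not in {"time", "event", "group"})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        return PrognosticModuleResult(frozenset(members), group.astype(int),
                                      logrank_stat, logrank_p, float("nan"), 1.0,
                                      used, converged=False, flagged_reason=str(exc))
    hr = float(np.exp(cph.params_["group"]))
    p = float(cph.summary.loc["group", "p"])
    return PrognosticModuleResult(frozenset(members), group.astype(int),
                                  logrank_stat, logrank_p, hr, p, used)


def kaplan_meier_curves(labels: np.ndarray, clinical: ClinicalTable) -> pd.DataFrame:
    """Kaplan-Meier survival estimates per group as a tidy (time, survival,
    group) table for external plotting."""
    labels = np.asarray(labels)
    frames = []
    for g in np.unique(labels):
        mask = labels == g
        km = KaplanMeierFitter()
        km.fit(clinical.time[mask], clinical.event[mask])
        df = km.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        df["group"] = int(g)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Full prognostic procedure over hallmark subnetworks
# ---------------------------------------------------------------------------


def prognostic_modules(
    subnetworks: Mapping[str, nx.Graph],
    lnc_expr: ExpressionMatrix,
    clinical: ClinicalTable,
    covariates: Sequence[str] = ("age", "sex"),
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    logrank_alpha: float = DEFAULT_LOGRANK_ALPHA,
    seed: int = 0,
    inflation: float = 2.0,
    cluster_method: str = "kmeans",
) -> list[PrognosticModuleResult]:
    """MCL modules in each hallmark subnetwork -> K=2 sample clustering ->
    log-rank screen (p < logrank_alpha) -> multivariate Cox. Modules smaller
    than min_module_size are discarded (too few lncRNAs to cluster samples
    on). Returns results for every module that reached the Cox stage."""
    order = [lnc_expr.sample_ids.index(s) for s in clinical.sample_ids]
    seen: set[frozenset[str]] = set()
    results: list[PrognosticModuleResult] = []
    for h in sorted(subnetworks):
        g = subnetworks[h]
        if g.number_of_edges() == 0:
            continue
        for module in mcl(g, inflation=inflation):
            members = frozenset(m for m in module if m in lnc_expr.entity_ids)
            if len(members) < min_module_size or members in seen:
                continue
            seen.add(members)
            sub = lnc_expr.subset(sorted(members))
            sub = ExpressionMatrix(sub.entity_ids, clinical.sample_ids, sub.values[:, order])
            try:
                labels = cluster_samples(sub, k=2, seed=seed, method=cluster_method)
            except ValueError:
                continue
            if len(np.unique(labels)) != 2:
                continue
            stat, p = logrank(labels, clinical)
            if p >= logrank_alpha:
                continue
            results.append(cox_multivariate(
                clinical, labels, covariates, members=members,
                logrank_stat=stat, logrank_p=p,
            ))
    return results
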