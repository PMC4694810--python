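"""Seeded synthetic input bundles with planted ground-truth synergistic
lncRNA pairs.

The generator emulates the data conditions the pipeline is designed for:
paired log2 lncRNA/mRNA expression in which each planted lncRNA pair jointly
drives a small gene module, GO BP terms that contain each planted module as a
coherent subset, a scale-free protein-interaction backbone in which each
planted module is densified into a clique (so planted modules satisfy both
proximity criteria while decoy gene sets usually do not), survival times whose
log-hazard tracks the mean expression of one planted lncRNA module, and
positional/TF confounders for exercising the co-localization/co-regulation
exclusion filter.

When three or more pairs are planted, the first three pairs form a triangle
over three lncRNAs; that triangle is the survival "risk module" (a prognostic
module needs at least three member lncRNAs to survive downstream module-size
filtering). The triangle's three GO terms map to a single hallmark in the toy
hallmark map shipped with the bundle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    GenomicInterval,
    write_bed,
    write_clinical,
    write_expression,
    write_gmt,
    write_hallmark_map,
    write_ppi,
    write_tf_regulations,
)

__all__ = ["ScenarioConfig", "ScenarioBundle", "generate", "truth_eval", "write_bundle"]


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults are the package's reference desk-scale scenario: 60 lncRNAs,
    600 genes, 120 samples, 6 planted pairs of joint effect 0.9 against
    residual noise sd 0.5, an exponential survival model with ~70% events and
    a log-hazard shift of 1.5 per unit of (standardized) risk-module
    expression.
    """

    n_lnc: int = 60
    n_genes: int = 600
    n_samples: int = 120
    n_planted_pairs: int = 6
    module_size: int = 8
    effect: float = 0.9
    noise_sd: float = 0.5
    ppi_model: tuple[str, int] = ("barabasi_albert", 2)
    frac_events: float = 0.7
    risk_effect: float = 1.5
    n_decoy_terms: int = 30
    confounded_fraction: float = 0.05
    n_tfs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lnc", "n_genes", "n_samples", "n_planted_pairs", "module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.module_size < 3:
            raise ValueError("module_size must be >= 3 (a functional module needs >= 3 genes)")
        if not 0 < self.frac_events <= 1:
            raise ValueError("frac_events must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.module_size * self.n_planted_pairs > self.n_genes:
            raise ValueError(
                f"module_size*n_planted_pairs = {self.module_size * self.n_planted_pairs} "
                f"exceeds n_genes = {self.n_genes}"
            )


@dataclass
class ScenarioBundle:
    """All pipeline inputs plus the planted ground truth."""

    config: ScenarioConfig
    lnc_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    ppi: nx.Graph
    go: GeneSetCollection
    hallmark_map: dict[str, frozenset[str]]
    lnc_coords: list[GenomicInterval]
    gene_coords: list[GenomicInterval]
    clinical: ClinicalTable
    tf_regulations: dict[str, frozenset[str]]
    truth_pairs: frozenset[frozenset[str]]
    truth_modules: dict[frozenset[str], frozenset[str]]
    risk_module_lncs: frozenset[str]
    confounded_pairs: frozenset[tuple[str, str]]


# canonical tumor capability names for the toy hallmark map
_HALLMARKS = [
    "self_sufficiency_in_growth", "insensitivity_to_antigrowth", "evading_apoptosis",
    "limitless_replicative_potential", "sustained_angiogenesis",
    "tissue_invasion_and_metastasis", "genome_instability_and_mutation",
    "tumor_promoting_inflammation", "evading_immune_detection", "deregulated_metabolism",
]

_LNC_SD = 1.5
_BASELINE = 8.0


def _planted_pairs(lnc_ids: list[str], n_pairs: int) -> list[tuple[str, str]]:
    """First three pairs form a triangle over 3 lncRNAs; remaining pairs are
    vertex-disjoint from everything planted so far."""
    pairs: list[tuple[str, str]] = []
    if n_pairs >= 3:
        tri = lnc_ids[:3]
        pairs = [(tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])]
        next_free = 3
    else:
        next_free = 0
    while len(pairs) < n_pairs:
        a, b = lnc_ids[next_free], lnc_ids[next_free + 1]
        pairs.append((a, b))
        next_free += 2
    return pairs


def generate(config: ScenarioConfig) -> ScenarioBundle:
    """Generate a complete, seeded input bundle with planted ground truth."""
    ss = np.random.SeedSequence(config.seed)
    (ss_lnc, ss_gene, ss_ppi, ss_go, ss_coord, ss_surv, ss_tf) = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]

    lnc_ids = [f"lnc{i:04d}" for i in range(config.n_lnc)]
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    sample_ids = [f"s{i:03d}" for i in range(config.n_samples)]

    n_lnc_needed = 3 + 2 * max(0, config.n_planted_pairs - 3) if config.n_planted_pairs >= 3 \
        else 2 * config.n_planted_pairs
    if n_lnc_needed > config.n_lnc:
        raise ValueError("n_lnc too small for the requested planted pairs")

    pairs = _planted_pairs(lnc_ids, config.n_planted_pairs)

    # --- expression -------------------------------------------------------
    lnc_values = _BASELINE + _LNC_SD * ss_lnc.standard_normal((config.n_lnc, config.n_samples))
    lnc_expr = ExpressionMatrix(lnc_ids, sample_ids, lnc_values)

    gene_values = _BASELINE + _LNC_SD * ss_gene.standard_normal((config.n_genes, config.n_samples))
    truth_modules: dict[frozenset[str], frozenset[str]] = {}
    gene_cursor = 0
    lnc_index = {l: i for i, l in enumerate(lnc_ids)}
    for a, b in pairs:
        module = gene_ids[gene_cursor:gene_cursor + config.module_size]
        gene_cursor += config.module_size
        driver = (lnc_values[lnc_index[a]] + lnc_values[lnc_index[b]]) / 2.0
        for g in module:
            gi = gene_ids.index(g)
            noise = ss_gene.standard_normal(config.n_samples) * config.noise_sd
            gene_values[gi] = _BASELINE * (1 - config.effect) + config.effect * driver + noise
        truth_modules[frozenset((a, b))] = frozenset(module)
    gene_expr = ExpressionMatrix(gene_ids, sample_ids, gene_values)

    # --- PPI: scale-free backbone + planted cliques ------------------------
    model, m = config.ppi_model
    if model != "barabasi_albert":
        raise ValueError(f"unknown ppi_model {model!r}")
    backbone = nx.barabasi_albert_graph(
        config.n_genes, m, seed=int(ss_ppi.integers(2**31)))
    ppi = nx.relabel_nodes(backbone, {i: gene_ids[i] for i in range(config.n_genes)})
    for module in truth_modules.values():
        for u, v in itertools.combinations(sorted(module), 2):
            ppi.add_edge(u, v)

    # --- GO terms: one superset term per planted module + decoys -----------
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_term_of_pair: dict[frozenset[str], str] = {}
    non_planted = gene_ids[gene_cursor:]
    for i, (pair, module) in enumerate(truth_modules.items()):
        extra = ss_go.choice(non_planted, size=4, replace=False)
        term_id = f"GO:P{i:04d}"
        terms[term_id] = (f"planted process {i}", module | frozenset(extra))
        planted_term_of_pair[pair] = term_id
    for j in range(config.n_decoy_terms):
        size = int(ss_go.integers(10, 41))
        members = ss_go.choice(non_planted, size=size, replace=False)
        terms[f"GO:D{j:04d}"] = (f"decoy process {j}", frozenset(members))
    background: set[str] = set()
    for _, genes in terms.values():
        background |= genes
    go = GeneSetCollection(terms, background_size=len(background))

    # --- toy hallmark map: triangle terms share one hallmark ----------------
    hallmark_map: dict[str, set[str]] = {h: set() for h in _HALLMARKS}
    pair_list = list(truth_modules)
    for i, pair in enumerate(pair_list):
        term = planted_term_of_pair[pair]
        if config.n_planted_pairs >= 3 and i < 3:
            hallmark_map[_HALLMARKS[0]].add(term)
        else:
            hallmark_map[_HALLMARKS[1 + (i % (len(_HALLMARKS) - 1))]].add(term)
    decoy_terms = [t for t in terms if t.startswith("GO:D")]
    for j, t in enumerate(decoy_terms[: len(decoy_terms) // 2]):
        hallmark_map[_HALLMARKS[j % len(_HALLMARKS)]].add(t)
    hallmark_final = {h: frozenset(ts) for h, ts in hallmark_map.items() if ts}

    # --- genomic coordinates + positional confounders ----------------------
    chroms = [f"chr{i}" for i in range(1, 6)]
    lnc_coords: list[GenomicInterval] = []
    gene_coords: list[GenomicInterval] = []
    gene_pos: dict[str, tuple[str, int, int]] = {}
    for g in gene_ids:
        chrom = chroms[int(ss_coord.integers(len(chroms)))]
        start = int(ss_coord.integers(1_000, 200_000_000))
        end = start + int(ss_coord.integers(500, 50_000))
        gene_coords.append(GenomicInterval(g, chrom, start, end))
        gene_pos[g] = (chrom, start, end)
    n_conf = int(round(config.confounded_fraction * config.n_lnc))
    confounded: set[tuple[str, str]] = set()
    # co-localized confounders: lncRNA placed within 5 kb of a non-planted gene
    conf_lncs = lnc_ids[-max(n_conf, 0):] if n_conf else []
    conf_genes = list(non_planted[-len(conf_lncs):]) if conf_lncs else []
    conf_pairs = dict(zip(conf_lncs, conf_genes))
    for l in lnc_ids:
        if l in conf_pairs:
            chrom, gstart, gend = gene_pos[conf_pairs[l]]
            start = gend + int(ss_coord.integers(0, 4_000))
            end = start + int(ss_coord.integers(500, 900))
            confounded.add((l, conf_pairs[l]))
        else:
            chrom = chroms[int(ss_coord.integers(len(chroms)))]
            start = int(ss_coord.integers(1_000, 200_000_000))
            end = start + int(ss_coord.integers(500, 20_000))
        lnc_coords.append(GenomicInterval(l, chrom, start, end))

    # --- TF regulations + co-regulation confounders -------------------------
    tf_ids = [f"tf{i:02d}" for i in range(config.n_tfs)]
    regulations: dict[str, set[str]] = {tf: set() for tf in tf_ids}
    all_targets = lnc_ids + gene_ids
    for tf in tf_ids:
        k = int(ss_tf.integers(10, 40))
        for t in ss_tf.choice(all_targets, size=k, replace=False):
            regulations[tf].add(str(t))
    # plant pairs sharing an identical (hence >80% overlapping) TF complement
    for l, g in list(conf_pairs.items()):
        shared = ss_tf.choice(tf_ids, size=5, replace=False)
        for tf in tf_ids:
            regulations[tf].discard(l)
            regulations[tf].discard(g)
        for tf in shared:
            regulations[str(tf)] |= {l, g}
        confounded.add((l, g))
    tf_regulations = {tf: frozenset(t) for tf, t in regulations.items() if t}

    # --- survival: exponential PH on the risk module ------------------------
    risk_lncs = frozenset(lnc_ids[:3]) if config.n_planted_pairs >= 3 else frozenset(
        lnc_ids[: 2 * min(config.n_planted_pairs, 1)])
    risk_rows = [lnc_index[l] for l in sorted(risk_lncs)]
    score = lnc_values[risk_rows].mean(axis=0)
    z = (score - score.mean()) / score.std(ddof=0)
    lam0 = np.log(2) / 1000.0  # baseline median survival ~1000 days
    hazard = lam0 * np.exp(config.risk_effect * z)
    t_event = ss_surv.exponential(1.0 / hazard)
    # independent exponential censoring tuned to the target event fraction
    f = config.frac_events
    if f >= 1.0:
        time, event = t_event, np.ones(config.n_samples, dtype=int)
    else:
        lam_c = lam0 * (1 - f) / f
        t_cens = ss_surv.exponential(1.0 / lam_c, size=config.n_samples)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)
    covariates = pd.DataFrame({
        "age": np.round(60 + 10 * ss_surv.standard_normal(config.n_samples), 1),
        "sex": ss_surv.integers(0, 2, size=config.n_samples),
    })
    clinical = ClinicalTable(sample_ids, time, event, covariates)

    return ScenarioBundle(
        config=config,
        lnc_expr=lnc_expr,
        gene_expr=gene_expr,
        ppi=ppi,
        go=go,
        hallmark_map=hallmark_final,
        lnc_coords=lnc_coords,
        gene_coords=gene_coords,
        clinical=clinical,
        tf_regulations=tf_regulations,
        truth_pairs=frozenset(frozenset(p) for p in pairs),
        truth_modules=truth_modules,
        risk_module_lncs=risk_lncs,
        confounded_pairs=frozenset(confounded),
    )


def truth_eval(predicted_pairs, truth_pairs) -> dict[str, float]:
    """Precision/recall of predicted unordered lncRNA pairs against the
    planted truth. Empty prediction with empty truth counts as precision 1."""
    pred = {frozenset(p) for p in predicted_pairs}
    truth = {frozenset(p) for p in truth_pairs}
    if any(len(p) != 2 for p in pred | truth):
        raise ValueError("pairs must have two distinct members")
    tp = len(pred & truth)
    precision = tp / len(pred) if pred else 1.0
    recall = tp / len(truth) if truth else 1.0
    return {
        "n_predicted": len(pred),
        "n_truth": len(truth),
        "n_true_positive": tp,
        "precision": precision,
        "recall": recall,
    }


def write_bundle(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component in its pipeline input format, plus the
    planted truth pairs as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lnc_expr": outdir / "lnc_expression.tsv",
        "gene_expr": outdir / "gene_expression.tsv",
        "ppi": outdir / "ppi_edges.tsv",
        "go": outdir / "go_bp.gmt",
        "hallmark_map": outdir / "hallmark_map.tsv",
        "lnc_coords": outdir / "lnc_coords.bed",
        "gene_coords": outdir / "gene_coords.bed",
        "clinical": outdir / "clinical.tsv",
        "tf_regulations": outdir / "tf_regulations.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
    }
    write_expression(bundle.lnc_expr, paths["lnc_expr"])
    write_expression(bundle.gene_expr, paths["gene_expr"])
    write_ppi(bundle.ppi, paths["ppi"])
    write_gmt(bundle.go, paths["go"])
    write_hallmark_map(bundle.hallmark_map, paths["hallmark_map"])
    write_bed(bundle.lnc_coords, paths["lnc_coords"])
    write_bed(bundle.gene_coords, paths["gene_coords"])
    write_clinical(bundle.clinical, paths["clinical"])
    write_tf_regulations(bundle.tf_regulations, paths["tf_regulations"])
    with open(paths["truth_pairs"], "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in bundle.truth_pairs):
            fh.write(f"{pair[0]}\t{pair[1]}\n")
    return paths
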