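"""End-to-end orchestration: LCG screen -> shared-LCG pair enumeration ->
GO enrichment -> PPI topology filter -> LFSN assembly -> hallmark subnetworks
-> prognostic modules -> report.

Pair enumeration never scans all lncRNA pairs: an inverted gene -> lncRNA
index yields exactly the pairs sharing >= min_common LCGs. All stochastic
stages (edge switching, permutations, K-means restarts) draw from named
substreams of the single run seed, so reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import networkx as nx
import numpy as np
import yaml

from . import clinical as clinical_mod
from . import coregulation as coreg_mod
from . import hallmark as hallmark_mod
from . import network as network_mod
from . import ppi_filter
from .enrichment import CandidateModule, common_lcgs, enrich_pair
from .io_formats import (
    check_disjoint_universes,
    load_bed,
    load_clinical,
    load_expression,
    load_gmt,
    load_hallmark_map,
    load_ppi,
    load_tf_regulations,
    write_lfsn,
)
from .lcg_correlation import all_lcgs, apply_confounder_filter
from .synthetic_data import ScenarioBundle

logger = logging.getLogger("lfsn")


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    # input paths (unused when a ScenarioBundle is supplied directly)
    lnc_expression: str = ""
    gene_expression: str = ""
    ppi: str = ""
    go_gmt: str = ""
    hallmark_map: str = ""
    clinical: str = ""
    lnc_coords: str = ""
    gene_coords: str = ""
    tf_regulations: str = ""
    # thresholds
    alpha_lcg: float = 1e-10
    min_common_lcgs: int = 3
    alpha_enrich: float = 0.01
    enrich_correction: str = "BH"
    n_random: int = 1000
    cpl_threshold: float = 0.05
    min_dist_rule: str = "nearest"
    hub_fraction: float = 0.10
    k_min: int = 3
    k_max: int = 6
    mcl_inflation: float = 2.0
    cluster_method: str = "kmeans"
    survival_covariates: tuple[str, ...] = ("age", "sex")
    confounder_filter: bool = False
    coloc_max_gap: int = 5_000
    coreg_threshold: float = 0.8
    colocalization_window: float = 10_000_000
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_lcg <= 1 or not 0 < self.alpha_enrich <= 1:
            raise ValueError("significance levels must lie in [0, 1]")
        if not 0 < self.cpl_threshold <= 1:
            raise ValueError("cpl_threshold must lie in (0, 1]")
        if self.min_common_lcgs < 1 or self.n_random < 1:
            raise ValueError("min_common_lcgs and n_random must be positive")
        if not 0 < self.hub_fraction <= 1:
            raise ValueError("hub_fraction must lie in (0, 1]")
        if self.k_min < 3 or self.k_max < self.k_min:
            raise ValueError("need 3 <= k_min <= k_max")
        self.survival_covariates = tuple(self.survival_covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    lcgs: dict
    candidate_pairs: list[frozenset[str]]
    candidates: list[CandidateModule]
    lfsn: nx.Graph
    hallmark_subnetworks: dict[str, nx.Graph]
    hallmark_presence: dict[str, bool]
    prognostic: list
    counts: dict[str, Any] = field(default_factory=dict)
    colocalized: set[tuple[str, str]] = field(default_factory=set)
    coregulated: set[tuple[str, str]] = field(default_factory=set)


def _substream(seed: int, label: str) -> int:
    """A deterministic per-stage 31-bit seed derived from the run seed."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def shared_lcg_pairs(lcgs: dict, min_common: int) -> list[frozenset[str]]:
    """All lncRNA pairs sharing >= min_common LCGs, via an inverted
    gene -> lncRNA index (no all-pairs scan)."""
    gene_to_lnc: dict[str, list[str]] = {}
    for lnc, s in lcgs.items():
        for g in s.genes:
            gene_to_lnc.setdefault(g, []).append(lnc)
    counts: dict[frozenset[str], int] = {}
    for lncs in gene_to_lnc.values():
        for a, b in itertools.combinations(sorted(lncs), 2):
            key = frozenset((a, b))
            counts[key] = counts.get(key, 0) + 1
    pairs = [p for p, c in counts.items() if c >= min_common]
    pairs.sort(key=lambda p: tuple(sorted(p)))
    return pairs


def run_bundle(bundle: ScenarioBundle, config: Optional[RunConfig] = None) -> PipelineResult:
    """Run the full pipeline on an in-memory input bundle."""
    import time

    cfg = config or RunConfig()
    counts: dict[str, Any] = {}
    coloc: set[tuple[str, str]] = set()
    coreg: set[tuple[str, str]] = set()
    t_start = time.perf_counter()

    def _tick(stage: str) -> None:
        logger.info("stage %s done at %.2fs", stage, time.perf_counter() - t_start)

    check_disjoint_universes(bundle.lnc_expr, bundle.gene_expr)

    # 1. LCG screen
    lcgs = all_lcgs(bundle.lnc_expr, bundle.gene_expr, alpha=cfg.alpha_lcg)
    if cfg.confounder_filter:
        coloc |= coreg_mod.colocalized_pairs(
            bundle.lnc_coords, bundle.gene_coords, max_gap=cfg.coloc_max_gap)
        active = coreg_mod.active_regulations(
            bundle.tf_regulations,
            tf_expr=bundle.gene_expr, target_expr=_stack(bundle))
        coreg |= coreg_mod.coregulated_pairs(
            active or bundle.tf_regulations,
            bundle.lnc_expr.entity_ids, bundle.gene_expr.entity_ids,
            threshold=cfg.coreg_threshold)
        lcgs = {lnc: apply_confounder_filter(s, coloc, coreg) for lnc, s in lcgs.items()}
        counts["n_colocalized_pairs"] = len(coloc)
        counts["n_coregulated_pairs"] = len(coreg)
    counts["n_lnc_with_lcgs"] = sum(1 for s in lcgs.values() if s.genes)
    _tick("lcg")

    # 2. shared-LCG pairs + enrichment
    pairs = shared_lcg_pairs(lcgs, cfg.min_common_lcgs)
    counts["n_pairs_tested"] = len(pairs)
    candidates: list[CandidateModule] = []
    for pair in pairs:
        a, b = sorted(pair)
        common = common_lcgs(lcgs[a], lcgs[b], min_size=cfg.min_common_lcgs)
        if common is None:
            continue
        candidates.extend(enrich_pair(pair, common, bundle.go,
                                      alpha_enrich=cfg.alpha_enrich,
                                      correction=cfg.enrich_correction))
    counts["n_candidate_modules"] = len(candidates)
    counts["n_pairs_enriched"] = len({c.pair for c in candidates})
    _tick("enrichment")

    # 3. PPI topology filter
    filtered, verdicts = ppi_filter.filter_candidates(
        candidates, bundle.ppi,
        cpl_threshold=cfg.cpl_threshold, n_random=cfg.n_random,
        seed=_substream(cfg.seed, "edge_switch"), min_dist_rule=cfg.min_dist_rule)
    passing = [c for c in filtered if c.topology_pass]
    counts["n_modules_passing_topology"] = len(passing)
    _tick("topology_filter")

    # 4. LFSN
    lfsn = network_mod.assemble(passing)
    counts["n_edges"] = lfsn.number_of_edges()
    counts["n_network_lncs"] = lfsn.number_of_nodes()
    if lfsn.number_of_nodes():
        counts["hubs"] = sorted(network_mod.hubs(lfsn, cfg.hub_fraction))
        counts["modules_per_k"] = network_mod.k_sweep(lfsn, cfg.k_min, cfg.k_max)

    # 5. hallmark subnetworks
    subnets = hallmark_mod.hallmark_subnetworks(lfsn, bundle.hallmark_map)
    presence = hallmark_mod.hallmark_presence(subnets)
    counts["n_hallmarks_present"] = sum(presence.values())
    _tick("hallmark")

    # 6. prognostic modules
    prognostic = clinical_mod.prognostic_modules(
        subnets, bundle.lnc_expr, bundle.clinical,
        covariates=[c for c in cfg.survival_covariates
                    if c in bundle.clinical.covariates.columns],
        seed=_substream(cfg.seed, "kmeans"),
        inflation=cfg.mcl_inflation, cluster_method=cfg.cluster_method)
    counts["n_modules_logrank_significant"] = len(prognostic)
    counts["n_prognostic_modules"] = sum(1 for r in prognostic if r.significant)
    _tick("clinical")

    return PipelineResult(cfg, lcgs, pairs, filtered, lfsn, subnets, presence,
                          prognostic, counts, colocalized=coloc, coregulated=coreg)


def _stack(bundle: ScenarioBundle):
    """lncRNA and gene expression as one matrix (TF targets span both)."""
    from .io_formats import ExpressionMatrix

    return ExpressionMatrix(
        bundle.lnc_expr.entity_ids + bundle.gene_expr.entity_ids,
        bundle.lnc_expr.sample_ids,
        np.vstack([bundle.lnc_expr.values, bundle.gene_expr.values]),
    )


def load_bundle_from_config(cfg: RunConfig) -> ScenarioBundle:
    """Assemble a ScenarioBundle from the files a RunConfig points at."""
    from .synthetic_data import ScenarioConfig

    lnc_expr = load_expression(cfg.lnc_expression)
    gene_expr = load_expression(cfg.gene_expression)
    universe = gene_expr.entity_ids
    go = load_gmt(cfg.go_gmt, universe=universe)
    ppi = load_ppi(cfg.ppi)
    hmap = load_hallmark_map(cfg.hallmark_map) if cfg.hallmark_map else {}
    clin = load_clinical(cfg.clinical) if cfg.clinical else None
    lnc_coords = load_bed(cfg.lnc_coords) if cfg.lnc_coords else []
    gene_coords = load_bed(cfg.gene_coords) if cfg.gene_coords else []
    tf_regs = load_tf_regulations(cfg.tf_regulations) if cfg.tf_regulations else {}
    if clin is None:
        raise ValueError("a clinical table is required for the full pipeline")
    return ScenarioBundle(
        config=ScenarioConfig(seed=cfg.seed),
        lnc_expr=lnc_expr, gene_expr=gene_expr, ppi=ppi, go=go,
        hallmark_map=hmap, lnc_coords=lnc_coords, gene_coords=gene_coords,
        clinical=clin, tf_regulations=tf_regs,
        truth_pairs=frozenset(), truth_modules={},
        risk_module_lncs=frozenset(), confounded_pairs=frozenset(),
    )


def run(config: RunConfig, outdir: str | Path,
        bundle: Optional[ScenarioBundle] = None) -> PipelineResult:
    """Run the pipeline from files (or a supplied bundle) and write all
    artifacts plus a reproducibility manifest into outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = load_bundle_from_config(config)
    result = run_bundle(bundle, config)

    write_lfsn(result.lfsn, outdir / "lfsn_edges.tsv", outdir / "lfsn.graphml")
    with open(outdir / "candidate_modules.tsv", "w") as fh:
        fh.write("lnc_a\tlnc_b\tterm_id\tp\tp_adjusted\ttopology_pass\tgenes\n")
        for c in sorted(result.candidates,
                        key=lambda c: (tuple(sorted(c.pair)), c.term_id)):
            a, b = sorted(c.pair)
            fh.write(f"{a}\t{b}\t{c.term_id}\t{c.enrichment.p:.6g}\t"
                     f"{c.p_adjusted:.6g}\t{c.topology_pass}\t"
                     f"{';'.join(sorted(c.genes))}\n")
    for i, r in enumerate(result.prognostic):
        km = clinical_mod.kaplan_meier_curves(r.labels, bundle.clinical)
        km.to_csv(outdir / f"km_module_{i:02d}.tsv", sep="\t", index=False)
    with open(outdir / "prognostic_modules.tsv", "w") as fh:
        fh.write("members\tlogrank_stat\tlogrank_p\thazard_ratio\thr_p\tcovariates\tsignificant\n")
        for r in result.prognostic:
            fh.write(f"{';'.join(sorted(r.members))}\t{r.logrank_stat:.6g}\t"
                     f"{r.logrank_p:.6g}\t{r.hazard_ratio:.6g}\t{r.hr_p:.6g}\t"
                     f"{','.join(r.covariates)}\t{r.significant}\n")
    if config.confounder_filter:
        for name, pairs in (("colocalized_pairs.tsv", result.colocalized),
                            ("coregulated_pairs.tsv", result.coregulated)):
            with open(outdir / name, "w") as fh:
                fh.write("lnc_id\tgene_id\n")
                for l, g in sorted(pairs):
                    fh.write(f"{l}\t{g}\n")
    manifest = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "python": sys.version.split()[0],
        "counts": result.counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_dict(result), fh, indent=2, sort_keys=True, default=str)
    return result


def report_dict(result: PipelineResult) -> dict[str, Any]:
    """Stage-count summary mirroring the construction steps."""
    return {
        "counts": result.counts,
        "hallmark_presence": result.hallmark_presence,
        "prognostic_modules": [
            {
                "members": sorted(r.members),
                "logrank_p": r.logrank_p,
                "hazard_ratio": r.hazard_ratio,
                "hr_p": r.hr_p,
                "significant": r.significant,
            }
            for r in result.prognostic
        ],
    }


def report(run_dir: str | Path) -> dict[str, Any]:
    """Pure function of a completed run directory: re-read its report JSON,
    flagging partial runs."""
    run_dir = Path(run_dir)
    path = run_dir / "report.json"
    if not path.exists():
        partial = {p.name: p.exists() for p in [run_dir / "manifest.json",
                                                run_dir / "lfsn_edges.tsv"]}
        return {"partial": True, "artifacts": partial}
    with open(path) as fh:
        out = json.load(fh)
    out["partial"] = False
    return out
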