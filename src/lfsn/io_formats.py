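"""Readers/writers for the standard formats the pipeline touches, plus the
shared core data types.

All tabular formats are plain TSV; gene sets are GMT; genomic intervals are
BED (0-based half-open); the protein-interaction network is a two-column edge
list. Expression matrices are assumed already normalized and log2-transformed
— no normalization is performed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("lfsn")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Core data types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 expression values, entities (lncRNAs or genes) x samples."""

    entity_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.entity_ids)) != len(self.entity_ids):
            dup = _first_duplicate(self.entity_ids)
            raise FormatError(f"duplicate entity id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at entity {self.entity_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.entity_ids.index(entity_id)]

    def subset(self, entity_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.entity_ids.index(e) for e in entity_ids]
        return ExpressionMatrix(list(entity_ids), list(self.sample_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """GO BP term -> gene set, with the annotatable background size N."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background_size: int

    def __post_init__(self) -> None:
        if self.background_size < 0:
            raise ValueError("background_size must be non-negative")

    @property
    def term_ids(self) -> list[str]:
        return list(self.terms)

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    entity_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise FormatError(f"{self.entity_id}: empty chromosome")
        if self.start >= self.end:
            raise FormatError(
                f"{self.entity_id}: start {self.start} >= end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ClinicalTable:
    """Per-sample survival time (days), event indicator and covariates."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"duplicate sample id: {_first_duplicate(self.sample_ids)!r}")
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise FormatError("time/event length does not match sample_ids")
        if np.any(self.time <= 0):
            bad = self.sample_ids[int(np.argmax(self.time <= 0))]
            raise FormatError(f"non-positive survival time for sample {bad!r}")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise FormatError("event indicator must be 0/1")
        if len(self.covariates) != n:
            raise FormatError("covariate table length does not match sample_ids")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event}, index=self.sample_ids)
        return pd.concat([df, self.covariates.set_axis(self.sample_ids)], axis=1)


def _first_duplicate(ids: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate present")


# ---------------------------------------------------------------------------
# Expression matrices (TSV)
# ---------------------------------------------------------------------------


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Load a genes-x-samples TSV (first column = entity ids, header = samples).

    Raises :class:`FormatError` naming the offending id for duplicated rows and
    the coordinates of any non-numeric cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    ids = [str(x) for x in df.index]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate entity id: {_first_duplicate(ids)!r}")
    samples = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at "
                f"entity {ids[i]!r}, sample {samples[j]!r}"
            )
        # exact (round-trip) conversion; pandas' C parser can be off by 1 ulp
        values[:, j] = [float(x) for x in df[col]]
    return ExpressionMatrix(ids, samples, values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    # default float formatting is the shortest round-trip repr (exact reload)
    matrix.to_frame().to_csv(path, sep="\t", index_label="id")


def check_disjoint_universes(lnc: ExpressionMatrix, genes: ExpressionMatrix) -> None:
    """lncRNA and mRNA identifier universes must not overlap."""
    common = set(lnc.entity_ids) & set(genes.entity_ids)
    if common:
        raise FormatError(
            f"lncRNA and gene universes overlap: {sorted(common)[:5]} ..."
        )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def load_gmt(
    path: str | Path,
    min_size: int = 5,
    max_size: int = 500,
    universe: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Load GO BP gene sets from GMT, keeping terms with min_size..max_size
    genes after intersection with the measured-gene universe (if given).

    Term sizes count unique genes. The background size N is the number of
    genes annotated to at least one retained term.
    """
    universe_set = frozenset(universe) if universe is not None else None
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    n_dropped = 0
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line with fewer than 3 fields: {line[:60]!r}")
            term_id, description = parts[0], parts[1]
            if term_id in terms:
                raise FormatError(f"{path}: duplicate term id {term_id!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if universe_set is not None:
                genes = genes & universe_set
            if min_size <= len(genes) <= max_size:
                terms[term_id] = (description, genes)
            else:
                n_dropped += 1
    if n_lines == 0:
        raise FormatError(f"{path}: empty GMT file")
    logger.info("load_gmt: retained %d terms, dropped %d by size filter", len(terms), n_dropped)
    background: set[str] = set()
    for _, genes in terms.values():
        background |= genes
    return GeneSetCollection(terms, background_size=len(background))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, genes) in collection.terms.items():
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Protein-interaction network (edge-list TSV / SIF)
# ---------------------------------------------------------------------------


def load_ppi(path: str | Path) -> nx.Graph:
    """Load an undirected PPI edge list: self-loops removed, duplicate and
    reversed edges merged, and only the maximum connected component kept.

    Ties between equal-size components are broken by the lexicographically
    smallest sorted node list, so loads are deterministic.
    """
    g = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 3 and parts[1] and not parts[0] == parts[1]:
                # SIF: source <relation> target
                a, b = parts[0], parts[2]
            elif len(parts) >= 2:
                a, b = parts[0], parts[1]
            else:
                raise FormatError(f"{path}:{ln}: expected at least two columns")
            if a == b:
                continue  # self-loop
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise FormatError(f"{path}: no edges found")
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda nodes: (-len(nodes), nodes))
    keep = components[0]
    if len(components) > 1:
        logger.info(
            "load_ppi: kept maximum component with %d of %d nodes",
            len(keep), g.number_of_nodes(),
        )
    return g.subgraph(keep).copy()


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def load_bed(path: str | Path) -> list[GenomicInterval]:
    """Load BED3+ intervals; the name column (4) is required, strand (6) is
    optional. Coordinates are kept 0-based half-open as written."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED line lacks a name column")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{ln}: start {start} >= end {end}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in {"+", "-"} else "."
            out.append(GenomicInterval(name, chrom, start, end, strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.entity_id}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Clinical table, TF regulations, hallmark map (TSV)
# ---------------------------------------------------------------------------


def load_clinical(path: str | Path) -> ClinicalTable:
    """Load a clinical TSV with columns sample_id, time, event, then covariates."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"sample_id", "time", "event"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    covariate_cols = [c for c in df.columns if c not in required]
    return ClinicalTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        covariates=df[covariate_cols].reset_index(drop=True),
    )


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def load_tf_regulations(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a two-column TSV (tf_id, target_id) into tf -> target set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "target"], dtype=str,
                     comment="#")
    out: dict[str, set[str]] = {}
    for tf, target in zip(df["tf"], df["target"]):
        out.setdefault(tf, set()).add(target)
    return {tf: frozenset(t) for tf, t in out.items() if t}


def write_tf_regulations(regs: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(regs):
            for target in sorted(regs[tf]):
                fh.write(f"{tf}\t{target}\n")


def load_hallmark_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a two-column TSV (hallmark_id, term_id) into hallmark -> term set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["hallmark", "term"], dtype=str,
                     comment="#")
    out: dict[str, set[str]] = {}
    for h, t in zip(df["hallmark"], df["term"]):
        out.setdefault(h, set()).add(t)
    return {h: frozenset(t) for h, t in out.items()}


def write_hallmark_map(hmap: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in sorted(hmap):
            for t in sorted(hmap[h]):
                fh.write(f"{h}\t{t}\n")


# ---------------------------------------------------------------------------
# LFSN output (weighted edge list + GraphML)
# ---------------------------------------------------------------------------


def write_lfsn(graph: nx.Graph, edge_path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Write the synergistic network as weighted edge-list TSV (lncA, lncB,
    weight, semicolon-joined term ids) and optionally GraphML."""
    with open(edge_path, "w") as fh:
        fh.write("lnc_a\tlnc_b\tweight\tterms\n")
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((a, b))
            terms = ";".join(t for t, _ in data.get("modules", []))
            fh.write(f"{a}\t{b}\t{data.get('weight', 1)}\t{terms}\n")
    if graphml_path is not None:
        g2 = nx.Graph()
        g2.add_nodes_from(graph.nodes())
        for a, b, data in graph.edges(data=True):
            g2.add_edge(a, b, weight=int(data.get("weight", 1)),
                        terms=";".join(t for t, _ in data.get("modules", [])))
        nx.write_graphml(g2, graphml_path)


def load_lfsn(edge_path: str | Path) -> nx.Graph:
    df = pd.read_csv(edge_path, sep="\t", dtype={"lnc_a": str, "lnc_b": str})
    g = nx.Graph()
    for _, row in df.iterrows():
        terms = [] if pd.isna(row.get("terms")) or row.get("terms") == "" else str(row["terms"]).split(";")
        g.add_edge(row["lnc_a"], row["lnc_b"], weight=int(row["weight"]),
                   modules=[(t, frozenset()) for t in terms])
    return g
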