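"""Cancer-hallmark subnetworks of the LFSN.

Each hallmark of cancer is operationalized as a set of GO BP terms. An LFSN
edge belongs to a hallmark's subnetwork when at least one of its passing
functional modules is annotated to a term mapped to that hallmark; an edge may
appear in several subnetworks. A hallmark is "present" in an LFSN when its
subnetwork has at least one edge.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx


def hallmark_subnetworks(lfsn: nx.Graph,
                         hallmark_map: Mapping[str, frozenset[str]]) -> dict[str, nx.Graph]:
    """Split the LFSN into per-hallmark subgraphs by module term membership."""
    if not hallmark_map:
        raise ValueError("empty hallmark map")
    out: dict[str, nx.Graph] = {h: nx.Graph() for h in hallmark_map}
    for a, b, data in lfsn.edges(data=True):
        edge_terms = {t for t, _ in data.get("modules", [])}
        for h, terms in hallmark_map.items():
            if edge_terms & terms:
                out[h].add_edge(a, b, **data)
    return out


def hallmark_presence(subnetworks: Mapping[str, nx.Graph]) -> dict[str, bool]:
    """A hallmark is present iff its subnetwork carries >= 1 edge."""
    return {h: g.number_of_edges() > 0 for h, g in subnetworks.items()}
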