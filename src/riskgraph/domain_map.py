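"""Directed domain-interaction network inferred from cross-domain drivers.

An edge source-domain -> target-domain counts the retained driver-term
pairs whose hub sits in the source domain's graph and whose term belongs to
the target domain.  Terms mapped to several domains contribute one count
per mapped domain, so column totals are interpretable as contributions,
not unique pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class DomainInteractionGraph:
    graph: nx.DiGraph

    @property
    def domains(self) -> list:
        return sorted(self.graph.nodes)

    def weight(self, src: str, tgt: str) -> int:
        return self.graph.edges[src, tgt]["weight"] if self.graph.has_edge(src, tgt) else 0

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges(data="weight"))

    def to_matrix(self) -> pd.DataFrame:
        """Dense source x target count matrix (lossless counterpart)."""
        doms = self.domains
        mat = pd.DataFrame(0, index=doms, columns=doms, dtype=int)
        for s, t, w in self.graph.edges(data="weight"):
            mat.loc[s, t] = int(w)
        mat.index.name = "source_domain"
        return mat

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame, graph_sizes: Optional[Mapping] = None) -> "DomainInteractionGraph":
        g = nx.DiGraph()
        for dom in matrix.index:
            g.add_node(dom, graph_size=int(graph_sizes.get(dom, 0)) if graph_sizes else 0)
        for s in matrix.index:
            for t in matrix.columns:
                w = int(matrix.loc[s, t])
                if w > 0:
                    g.add_edge(s, t, weight=w)
        return cls(graph=g)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source_domain": s, "target_domain": t, "weight": int(w)}
            for s, t, w in sorted(self.graph.edges(data="weight"))
        ]
        return pd.DataFrame(rows, columns=["source_domain", "target_domain", "weight"])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def infer_domain_interactions(
    records: pd.DataFrame,
    term_domains: Mapping,
    graph_sizes: Optional[Mapping] = None,
    unique_drivers: bool = False,
) -> DomainInteractionGraph:
    """Count cross-domain driving relationships.

    ``records`` needs columns hub, term, domain (the graph the hub was
    found in) and should already be filtered to retained drivers.  With
    ``unique_drivers`` each (source, target) cell counts distinct hubs
    instead of driver-term pairs.  Terms with no domain mapping are
    excluded with a warning.
    """
    g = nx.DiGraph()
    sizes = graph_sizes or {}
    for dom in set(records["domain"]) | set(sizes):
        g.add_node(dom, graph_size=int(sizes.get(dom, 0)))
    tallies: Dict = {}
    for row in records.itertuples(index=False):
        targets = term_domains.get(row.term, frozenset())
        if not targets:
            log.warning("term %s has no domain mapping; excluded", row.term)
            continue
        for tgt in targets:
            key = (row.domain, tgt)
            if unique_drivers:
                tallies.setdefault(key, set()).add(row.hub)
            else:
                tallies[key] = tallies.get(key, 0) + 1
    for (src, tgt), val in sorted(tallies.items()):
        w = len(val) if unique_drivers else val
        if tgt not in g:
            g.add_node(tgt, graph_size=int(sizes.get(tgt, 0)))
        g.add_edge(src, tgt, weight=int(w))
    return DomainInteractionGraph(graph=g)


def domain_degree_fractions(dg: DomainInteractionGraph) -> pd.DataFrame:
    """Per-domain weighted in/out degree and out fraction.

    Self-edges contribute to both in- and out-degree.  The out fraction is
    NaN when a domain has neither incoming nor outgoing weight.
    """
    if dg.graph.number_of_nodes() == 0:
        raise ValueError("empty domain-interaction graph")
    rows = []
    for dom in dg.domains:
        out_w = sum(w for _, _, w in dg.graph.out_edges(dom, data="weight"))
        in_w = sum(w for _, _, w in dg.graph.in_edges(dom, data="weight"))
        total = out_w + in_w
        rows.append(
            {
                "domain": dom,
                "out_weight": int(out_w),
                "in_weight": int(in_w),
                "out_fraction": out_w / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["domain", "out_weight", "in_weight", "out_fraction"])
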