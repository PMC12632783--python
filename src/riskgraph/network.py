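"""Annotated interaction network: data model, I/O, evidence flags and filters.

Nodes carry a risk score on [0, 5], three binary expression-evidence flags
and a set of biodomain labels.  Edges carry PubMed support and the
(type, class) pairs of the source records they were merged from.  Networks
are undirected and simple: duplicate edges between a node pair are merged
into one edge holding the union of the PubMed IDs, and self-loops are
dropped on ingestion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx
import numpy as np
import pandas as pd

from riskgraph.errors import SchemaError, VocabularyError

log = logging.getLogger(__name__)

TRS_MAX = 5.0

#: Brain tissues sampled in immunohistochemistry evidence tables.
BRAIN_TISSUES = frozenset(
    {
        "caudate",
        "cerebellum",
        "cerebral cortex",
        "hippocampus",
        "hypothalamus",
        "pituitary gland",
        "dorsal raphe",
        "choroid plexus",
        "substantia nigra",
    }
)

#: Reliability labels accepted as evidence of expression.
RELIABLE_LABELS = frozenset({"Enhanced", "Supported", "Approved"})
RELIABILITY_VOCAB = RELIABLE_LABELS | {"Uncertain"}

#: Level labels counting as any level of expression.
EXPRESSED_LEVELS = frozenset({"Low", "Medium", "High", "Ascending", "Descending"})
LEVEL_VOCAB = EXPRESSED_LEVELS | {"Not Detected"}

EDGE_COLUMNS = ["node_a", "node_b", "itype", "iclass", "pubmed_ids"]
NODE_COLUMNS = ["symbol", "risk_score", "expr_hpa", "expr_de", "expr_sc", "biodomains"]


@dataclass(frozen=True)
class GeneNode:
    """One gene/protein node with its annotations."""

    symbol: str
    risk_score: float = 0.0
    expr_hpa: bool = False
    expr_de: bool = False
    expr_sc: bool = False
    biodomains: frozenset = frozenset()

    def __post_init__(self):
        if not (0.0 <= self.risk_score <= TRS_MAX):
            raise ValueError(f"risk_score {self.risk_score} outside [0, {TRS_MAX}] for {self.symbol}")

    @property
    def any_expression(self) -> bool:
        return self.expr_hpa or self.expr_de or self.expr_sc


@dataclass(frozen=True)
class Interaction:
    """One (merged) undirected edge with its literature support."""

    node_a: str
    node_b: str
    itype: str = "interacts-with"
    iclass: str = "ppi"
    pubmed_ids: frozenset = frozenset()
    sources: tuple = ()

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise ValueError(f"self-loop {self.node_a}")


@dataclass(frozen=True)
class GraphStats:
    n_nodes: int
    n_edges: int
    n_components: int
    mean_degree: float
    assortativity: float  # nan marks "undefined" (zero degree variance)


@dataclass(frozen=True)
class ExpressionEvidence:
    """Raw evidence rows for one gene, before reduction to binary flags.

    ``hpa_rows`` are (tissue, reliability, level) tuples; ``de_fdr`` is the
    differential-expression FDR (None when the gene was not measured);
    ``sc_p90``/``sc_frac_expressing`` summarise single-cell expression.
    """

    hpa_rows: tuple = ()
    de_fdr: Optional[float] = None
    sc_p90: float = 0.0
    sc_frac_expressing: float = 0.0


class AnnotatedNetwork:
    """Undirected simple graph over :class:`GeneNode` with merged edges."""

    def __init__(self):
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, node: GeneNode) -> None:
        self.graph.add_node(
            node.symbol,
            risk_score=float(node.risk_score),
            expr_hpa=bool(node.expr_hpa),
            expr_de=bool(node.expr_de),
            expr_sc=bool(node.expr_sc),
            biodomains=frozenset(node.biodomains),
        )

    def add_interaction(
        self,
        node_a: str,
        node_b: str,
        itype: str = "interacts-with",
        iclass: str = "ppi",
        pubmed_ids: Iterable = (),
    ) -> bool:
        """Add one interaction record, merging into an existing edge.

        Self-loops are silently dropped (returns False).  Nodes referenced
        only by edges get default annotations and a logged warning.
        """
        if node_a == node_b:
            return False
        for sym in (node_a, node_b):
            if sym not in self.graph:
                log.warning("node %s referenced only in edge table; default annotations assigned", sym)
                self.add_node(GeneNode(sym))
        pm = frozenset(str(p) for p in pubmed_ids if str(p))
        if self.graph.has_edge(node_a, node_b):
            data = self.graph.edges[node_a, node_b]
            data["pubmed_ids"] = data["pubmed_ids"] | pm
            data["sources"] = data["sources"] + ((itype, iclass),)
        else:
            self.graph.add_edge(node_a, node_b, pubmed_ids=pm, sources=((itype, iclass),))
        return True

    # -- accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def symbols(self) -> list:
        return sorted(self.graph.nodes)

    def node(self, symbol: str) -> GeneNode:
        d = self.graph.nodes[symbol]
        return GeneNode(symbol, d["risk_score"], d["expr_hpa"], d["expr_de"], d["expr_sc"], d["biodomains"])

    def nodes(self) -> Iterator[GeneNode]:
        for sym in self.symbols():
            yield self.node(sym)

    def interactions(self) -> Iterator[Interaction]:
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
            d = self.graph.edges[u, v]
            itype, iclass = d["sources"][0]
            yield Interaction(u, v, itype, iclass, d["pubmed_ids"], d["sources"])

    def risk(self, symbol: str) -> float:
        return self.graph.nodes[symbol]["risk_score"]

    def biodomains(self, symbol: str) -> frozenset:
        return self.graph.nodes[symbol]["biodomains"]

    def copy(self) -> "AnnotatedNetwork":
        out = AnnotatedNetwork()
        out.graph = self.graph.copy()
        return out

    def to_graphml(self, path) -> None:
        """Write GraphML with set-valued attributes flattened to ';' strings."""
        g = nx.Graph()
        for sym, d in self.graph.nodes(data=True):
            g.add_node(
                sym,
                risk_score=d["risk_score"],
                expr_hpa=d["expr_hpa"],
                expr_de=d["expr_de"],
                expr_sc=d["expr_sc"],
                biodomains=";".join(sorted(d["biodomains"])),
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, pubmed_ids=";".join(sorted(d["pubmed_ids"])), n_pubmed=len(d["pubmed_ids"]))
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------


def _split_semicolon(value) -> frozenset:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return frozenset()
    return frozenset(s for s in str(value).split(";") if s)


def _require_columns(df: pd.DataFrame, required: list, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}' in {path}")


def read_network(edge_table_path, node_table_path=None) -> AnnotatedNetwork:
    """Read an annotated network from TSV edge and node tables.

    The edge table needs columns ``node_a, node_b, itype, iclass,
    pubmed_ids`` (semicolon-separated IDs); the node table ``symbol,
    risk_score, expr_hpa, expr_de, expr_sc, biodomains``.  Duplicate edge
    records are merged, self-loops dropped, and edge-only nodes receive
    default annotations with a warning.
    """
    net = AnnotatedNetwork()
    if node_table_path is not None:
        nodes = pd.read_csv(node_table_path, sep="\t", dtype=str, keep_default_na=False)
        _require_columns(nodes, NODE_COLUMNS, node_table_path)
        for i, row in enumerate(nodes.itertuples(index=False)):
            try:
                risk = float(row.risk_score)
            except ValueError as exc:
                raise SchemaError(
                    f"non-numeric risk_score '{row.risk_score}' at row {i + 2} of {node_table_path}"
                ) from exc
            net.add_node(
                GeneNode(
                    symbol=str(row.symbol),
                    risk_score=risk,
                    expr_hpa=_parse_bool(row.expr_hpa),
                    expr_de=_parse_bool(row.expr_de),
                    expr_sc=_parse_bool(row.expr_sc),
                    biodomains=_split_semicolon(row.biodomains),
                )
            )
    edges = pd.read_csv(edge_table_path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(edges, EDGE_COLUMNS, edge_table_path)
    for row in edges.itertuples(index=False):
        net.add_interaction(
            str(row.node_a), str(row.node_b), str(row.itype), str(row.iclass), _split_semicolon(row.pubmed_ids)
        )
    return net


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no", ""}:
        return False
    raise SchemaError(f"cannot parse boolean value '{value}'")


def write_network(net: AnnotatedNetwork, edge_table_path, node_table_path) -> None:
    """Write the network back to the TSV formats accepted by read_network."""
    node_rows = [
        {
            "symbol": n.symbol,
            "risk_score": repr(n.risk_score),
            "expr_hpa": n.expr_hpa,
            "expr_de": n.expr_de,
            "expr_sc": n.expr_sc,
            "biodomains": ";".join(sorted(n.biodomains)),
        }
        for n in net.nodes()
    ]
    pd.DataFrame(node_rows, columns=NODE_COLUMNS).to_csv(node_table_path, sep="\t", index=False)
    edge_rows = [
        {
            "node_a": e.node_a,
            "node_b": e.node_b,
            "itype": e.itype,
            "iclass": e.iclass,
            "pubmed_ids": ";".join(sorted(e.pubmed_ids)),
        }
        for e in net.interactions()
    ]
    pd.DataFrame(edge_rows, columns=EDGE_COLUMNS).to_csv(edge_table_path, sep="\t", index=False)


# ---------------------------------------------------------------------
# Evidence reduction
# ---------------------------------------------------------------------


def expression_flags(
    evidence: ExpressionEvidence,
    sc_p90_threshold: float = 1.0,
    sc_frac_threshold: float = 0.1,
    de_fdr_max: float = 0.05,
):
    """Reduce raw evidence to the three binary flags plus the benchmark flag.

    Returns ``(expr_hpa, expr_de, expr_sc, not_expressed_benchmark)``.

    ``expr_hpa`` is true iff some brain-tissue row pairs a reliable
    reliability label with an expression-level label; the benchmark flag is
    true iff every sampled row has level "Not Detected".  ``expr_de`` is
    true iff the differential-expression FDR is at most ``de_fdr_max``.
    ``expr_sc`` requires both single-cell thresholds to be met; the
    single-cell thresholds are configuration (the upstream cut separating
    expressed from non-expressed genes is data-derived, so the defaults
    here are placeholders).
    """
    expr_hpa = False
    all_not_detected = bool(evidence.hpa_rows)
    for tissue, reliability, level in evidence.hpa_rows:
        if reliability not in RELIABILITY_VOCAB:
            raise VocabularyError(f"unknown reliability label '{reliability}'")
        if level not in LEVEL_VOCAB:
            raise VocabularyError(f"unknown level label '{level}'")
        if tissue not in BRAIN_TISSUES:
            continue
        if level != "Not Detected":
            all_not_detected = False
        if reliability in RELIABLE_LABELS and level in EXPRESSED_LEVELS:
            expr_hpa = True
    expr_de = evidence.de_fdr is not None and evidence.de_fdr <= de_fdr_max
    expr_sc = evidence.sc_p90 >= sc_p90_threshold and evidence.sc_frac_expressing >= sc_frac_threshold
    return expr_hpa, expr_de, expr_sc, all_not_detected


# ---------------------------------------------------------------------
# Filtering and statistics
# ---------------------------------------------------------------------


def filter_network(net: AnnotatedNetwork, min_pubmed: int = 2, require_expression: bool = True) -> AnnotatedNetwork:
    """Apply the node-expression and edge-literature filters.

    Nodes survive when any of the three expression flags is set (if
    ``require_expression``); edges survive when they carry at least
    ``min_pubmed`` distinct PubMed IDs and both endpoints survive.  Nodes
    isolated by edge removal are retained — they can still act as seeds.
    """
    out = AnnotatedNetwork()
    kept = set()
    for node in net.nodes():
        if require_expression and not node.any_expression:
            continue
        kept.add(node.symbol)
        out.add_node(node)
    for e in net.interactions():
        if e.node_a in kept and e.node_b in kept and len(e.pubmed_ids) >= min_pubmed:
            out.graph.add_edge(e.node_a, e.node_b, pubmed_ids=e.pubmed_ids, sources=e.sources)
    return out


def network_stats(net) -> GraphStats:
    """Basic composition statistics of a network or bare graph.

    Assortativity is Newman's r: the Pearson correlation of endpoint
    degrees over edges (both orientations); NaN when degree variance is
    zero or the graph has no edges.
    """
    g = net.graph if isinstance(net, AnnotatedNetwork) else net
    n, m = g.number_of_nodes(), g.number_of_edges()
    ncomp = nx.number_connected_components(g) if n else 0
    mean_deg = 2.0 * m / n if n else 0.0
    assort = float("nan")
    if m:
        deg = dict(g.degree())
        xs = np.empty(2 * m)
        ys = np.empty(2 * m)
        for i, (u, v) in enumerate(g.edges()):
            xs[2 * i], ys[2 * i] = deg[u], deg[v]
            xs[2 * i + 1], ys[2 * i + 1] = deg[v], deg[u]
        if np.var(xs) > 0:
            assort = float(np.corrcoef(xs, ys)[0, 1])
    return GraphStats(n, m, ncomp, mean_deg, assort)
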