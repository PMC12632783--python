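"""Domain-specific subgraph reconstruction by risk-weighted shortest paths.

For a target domain, every edge of the filtered base network is weighted by
(trs_max - trs_u) + (trs_max - trs_v) plus an annotation penalty (0 when
both endpoints belong to the domain, 3 when one does, 5 when neither
does), so the cheapest routes run through high-risk, in-domain nodes.  The
domain graph is the union over all unordered seed pairs of one minimum-cost
path; ties between co-optimal paths are broken deterministically by the
lexicographically smallest node sequence.
"""

from __future__ import annotations

import heapq
import logging
from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import networkx as nx
import pandas as pd

from riskgraph.network import AnnotatedNetwork, GraphStats, network_stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeWeightParams:
    """Parameters of the composite reconstruction edge cost."""

    trs_max: float = 5.0
    penalty_both: float = 0.0
    penalty_one: float = 3.0
    penalty_neither: float = 5.0

    def __post_init__(self):
        if not (0 <= self.penalty_both <= self.penalty_one <= self.penalty_neither):
            raise ValueError("penalties must be non-negative and ordered both <= one <= neither")

    @property
    def weight_max(self) -> float:
        return 2.0 * self.trs_max + self.penalty_neither


@dataclass
class BiodomainGraph:
    """Reconstructed domain graph with node provenance.

    Node attributes on ``graph``: provenance in {"input", "added_in_domain",
    "added_out_domain"}, risk_score, biodomains, hop_distance (hops to the
    nearest input node within this graph).  Edge attribute: recon_weight.
    """

    domain: str
    graph: nx.Graph
    seeds: Tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def provenance_counts(self) -> Dict[str, int]:
        counts = {"input": 0, "added_in_domain": 0, "added_out_domain": 0}
        for _, p in self.graph.nodes(data="provenance"):
            counts[p] += 1
        return counts

    def stats(self) -> GraphStats:
        return network_stats(self.graph)

    def stats_row(self) -> dict:
        s = self.stats()
        c = self.provenance_counts()
        return {
            "domain": self.domain,
            "n_nodes": s.n_nodes,
            "n_edges": s.n_edges,
            "n_input": c["input"],
            "n_added_in": c["added_in_domain"],
            "n_added_out": c["added_out_domain"],
            "components": s.n_components,
            "mean_degree": s.mean_degree,
            "assortativity": s.assortativity,
        }

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for sym, d in self.graph.nodes(data=True):
            g.add_node(
                sym,
                provenance=d["provenance"],
                risk_score=d["risk_score"],
                biodomains=";".join(sorted(d["biodomains"])),
                hop_distance=d["hop_distance"],
            )
        for u, v, w in self.graph.edges(data="recon_weight"):
            g.add_edge(u, v, recon_weight=w)
        nx.write_graphml(g, path)


def reconstruction_edge_weight(
    trs_u: float,
    trs_v: float,
    u_in_domain: bool,
    v_in_domain: bool,
    params: EdgeWeightParams = EdgeWeightParams(),
) -> float:
    """Composite edge cost: risk deficits of both endpoints plus penalty."""
    for t in (trs_u, trs_v):
        if not (0.0 <= t <= params.trs_max):
            raise ValueError(f"risk score {t} outside [0, {params.trs_max}]")
    n_in = int(u_in_domain) + int(v_in_domain)
    penalty = (params.penalty_neither, params.penalty_one, params.penalty_both)[n_in]
    return (params.trs_max - trs_u) + (params.trs_max - trs_v) + penalty


# ---------------------------------------------------------------------
# Deterministic shortest paths
# ---------------------------------------------------------------------


def _dijkstra_single_paths(adj: Mapping, source, targets: set):
    """Single-source Dijkstra returning one path per reached target.

    ``adj`` maps node -> sorted list of (neighbor, weight); weights must be
    non-negative (zero is legal).  Among co-optimal paths the
    lexicographically smallest node sequence is selected, by keeping full
    paths in the heap so entries pop in (cost, path) order.
    """
    heap = [(0.0, (source,))]
    done: dict = {}
    remaining = set(targets)
    remaining.discard(source)
    while heap and remaining:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done[node] = (cost, path)
        remaining.discard(node)
        for nbr, w in adj[node]:
            if nbr not in done:
                heapq.heappush(heap, (cost + w, path + (nbr,)))
    return {t: done[t] for t in targets if t in done}


def shortest_path_union(graph: nx.Graph, seeds: Iterable, weights: Mapping) -> Tuple[nx.Graph, dict]:
    """Union of one shortest path per unordered seed pair.

    ``weights`` maps unordered node pairs (as sorted tuples) to
    non-negative costs.  Returns (union graph, {pair: (cost, path)}).
    Unreachable pairs are omitted from the path map but every seed is
    present in the union graph (possibly isolated).
    """
    seeds = sorted(set(seeds))
    adj: Dict = {n: [] for n in graph.nodes}
    for u, v in graph.edges():
        w = weights[(u, v) if u <= v else (v, u)]
        if w < 0:
            raise ValueError("negative edge weight")
        adj[u].append((v, w))
        adj[v].append((u, w))
    for n in adj:
        adj[n].sort()

    union = nx.Graph()
    union.add_nodes_from(seeds)
    paths = {}
    for i, s in enumerate(seeds):
        targets = set(seeds[i + 1 :])
        if not targets:
            continue
        for t, (cost, path) in sorted(_dijkstra_single_paths(adj, s, targets).items()):
            paths[(s, t)] = (cost, path)
            nx.add_path(union, path)
    for u, v in union.edges():
        key = (u, v) if u <= v else (v, u)
        union.edges[u, v]["recon_weight"] = weights[key]
    return union, paths


# ---------------------------------------------------------------------
# Domain graph construction
# ---------------------------------------------------------------------


def domain_edge_weights(base: AnnotatedNetwork, domain: str, params: EdgeWeightParams = EdgeWeightParams()) -> dict:
    """Reconstruction cost of every base edge for one target domain."""
    weights = {}
    g = base.graph
    for u, v in g.edges():
        key = (u, v) if u <= v else (v, u)
        weights[key] = reconstruction_edge_weight(
            g.nodes[u]["risk_score"],
            g.nodes[v]["risk_score"],
            domain in g.nodes[u]["biodomains"],
            domain in g.nodes[v]["biodomains"],
            params,
        )
    return weights


def build_domain_graph(
    base: AnnotatedNetwork,
    seeds: Iterable,
    domain: str,
    params: EdgeWeightParams = EdgeWeightParams(),
) -> BiodomainGraph:
    """Build the domain graph from seed genes over the filtered base network.

    Seeds absent from the base graph are excluded with a warning (a handful
    of leading-edge genes routinely fall outside the base graph).  Seeds
    unreachable from every other seed stay in the graph as isolated nodes.
    The base network is never mutated; weights are recomputed per domain.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    present = seeds & set(base.graph.nodes)
    missing = seeds - present
    if missing:
        log.warning("%d seed genes absent from the base graph: %s", len(missing), sorted(missing)[:10])
    if not present:
        raise ValueError("no seed genes present in the base graph")

    weights = domain_edge_weights(base, domain, params)
    union, _ = shortest_path_union(base.graph, present, weights)

    g = nx.Graph()
    for node in union.nodes:
        data = base.graph.nodes[node]
        if node in present:
            prov = "input"
        elif domain in data["biodomains"]:
            prov = "added_in_domain"
        else:
            prov = "added_out_domain"
        g.add_node(
            node,
            provenance=prov,
            risk_score=data["risk_score"],
            biodomains=data["biodomains"],
            hop_distance=-1,
        )
    for u, v, w in union.edges(data="recon_weight"):
        g.add_edge(u, v, recon_weight=w)

    # hop distance to the nearest input node, within the domain graph
    queue = deque()
    for s in sorted(present):
        g.nodes[s]["hop_distance"] = 0
        queue.append(s)
    while queue:
        node = queue.popleft()
        d = g.nodes[node]["hop_distance"]
        for nbr in g.neighbors(node):
            if g.nodes[nbr]["hop_distance"] < 0:
                g.nodes[nbr]["hop_distance"] = d + 1
                queue.append(nbr)

    return BiodomainGraph(domain=domain, graph=g, seeds=tuple(sorted(present)))


def term_coverage(term_genes: Iterable, graph) -> float:
    """Fraction of the term's genes present in the graph.

    Accepts a BiodomainGraph, AnnotatedNetwork, bare networkx graph, or any
    iterable of node names.
    """
    term_genes = set(term_genes)
    if not term_genes:
        raise ValueError("empty term")
    if isinstance(graph, (BiodomainGraph, AnnotatedNetwork)):
        nodes = set(graph.graph.nodes)
    elif isinstance(graph, nx.Graph):
        nodes = set(graph.nodes)
    else:
        nodes = set(graph)
    return len(term_genes & nodes) / len(term_genes)
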