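"""End-to-end orchestration: filter -> seed -> reconstruct -> kda -> join ->
integrate -> domain map, with a JSON run manifest.

A single global seed deterministically derives per-stage substreams, so a
rerun with the same configuration reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from riskgraph import __version__
from riskgraph.catalog import ModuleCatalog, read_catalog
from riskgraph.domain_map import domain_degree_fractions, infer_domain_interactions
from riskgraph.enrichment import SeedParams, preranked_gsea, results_to_frame, select_seed_genes
from riskgraph.errors import PipelineError
from riskgraph.integration import IntegrationParams, integrate_drivers
from riskgraph.kda import KdaParams, delta_fdr_join, filter_drivers, wkda_run
from riskgraph.network import filter_network, network_stats, read_network, write_network
from riskgraph.reconstruction import EdgeWeightParams, build_domain_graph

log = logging.getLogger(__name__)

# fixed offsets deriving per-stage substreams from the global seed
_SEED_GSEA = 11
_SEED_KDA = 23


@dataclass
class PipelineConfig:
    edge_table: str
    node_table: str
    gmt: str
    term_domain_table: str
    out_dir: str
    seed: int = 0
    min_pubmed: int = 2
    require_expression: bool = True
    domains: Optional[List[str]] = None
    seed_params: SeedParams = field(default_factory=SeedParams)
    edge_weight: EdgeWeightParams = field(default_factory=EdgeWeightParams)
    kda: KdaParams = field(default_factory=KdaParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (
            ("seed_params", SeedParams),
            ("edge_weight", EdgeWeightParams),
            ("kda", KdaParams),
            ("integration", IntegrationParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def params_dict(self) -> dict:
        d = asdict(self)
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    Any stage failure aborts the run: the manifest, including the failing
    stage's name and input, is written before the error propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "params": config.params_dict(), "stages": []}
    stage = "init"

    def _record(name: str, **counts):
        manifest["stages"].append({"name": name, "counts": counts})
        log.info("stage %s: %s", name, counts)

    def _fail(exc: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise PipelineError(stage, str(exc)) from exc

    try:
        stage = "filter"
        net = read_network(config.edge_table, config.node_table)
        catalog = read_catalog(config.gmt, config.term_domain_table)
        filtered = filter_network(net, min_pubmed=config.min_pubmed, require_expression=config.require_expression)
        write_network(filtered, out / "filtered_edges.tsv", out / "filtered_nodes.tsv")
        fstats = network_stats(filtered)
        _record(stage, nodes_in=net.n_nodes, edges_in=net.n_edges, nodes_kept=fstats.n_nodes, edges_kept=fstats.n_edges)

        stage = "seed"
        ranked = {node.symbol: node.risk_score for node in net.nodes()}
        sp = SeedParams(
            padj_max=config.seed_params.padj_max,
            nes_min=config.seed_params.nes_min,
            gsea_nperm=config.seed_params.gsea_nperm,
            gsea_weight_exponent=config.seed_params.gsea_weight_exponent,
            seed=config.seed + _SEED_GSEA,
        )
        gsea_results = preranked_gsea(ranked, catalog, sp)
        results_to_frame(gsea_results).to_csv(out / "gsea_results.tsv", sep="\t", index=False)
        domains = config.domains or sorted(catalog.domains())
        seeds_dir = out / "seeds"
        seeds_dir.mkdir(exist_ok=True)
        seeds_by_domain = {}
        for dom in domains:
            seeds = select_seed_genes(gsea_results, dom, sp)
            seeds_by_domain[dom] = seeds
            (seeds_dir / f"{dom}.txt").write_text("".join(f"{g}\n" for g in sorted(seeds)))
        _record(stage, terms_scored=len(gsea_results), domains=len(domains),
                domains_with_seeds=sum(1 for s in seeds_by_domain.values() if s))

        stage = "reconstruct"
        graphs_dir = out / "graphs"
        graphs_dir.mkdir(exist_ok=True)
        domain_graphs = {}
        stat_rows = []
        for dom, seeds in seeds_by_domain.items():
            if not seeds:
                log.warning("domain %s has no seed genes; skipped", dom)
                continue
            present = seeds & set(filtered.graph.nodes)
            if not present:
                log.warning("domain %s seeds all absent from the filtered graph; skipped", dom)
                continue
            bg = build_domain_graph(filtered, seeds, dom, config.edge_weight)
            bg.to_graphml(graphs_dir / f"{dom}.graphml")
            stat_rows.append(bg.stats_row())
            domain_graphs[dom] = bg
        pd.DataFrame(stat_rows).to_csv(out / "graph_stats.tsv", sep="\t", index=False)
        _record(stage, graphs=len(domain_graphs), total_nodes=sum(g.n_nodes for g in domain_graphs.values()))

        stage = "kda"
        kda_raw: Dict[str, Dict[int, pd.DataFrame]] = {}
        for dom, bg in domain_graphs.items():
            kda_raw[dom] = {}
            for ef in (1, 0):
                kp = KdaParams(
                    depth=config.kda.depth,
                    nperm=config.kda.nperm,
                    min_module_size=config.kda.min_module_size,
                    edge_factor=ef,
                    coverage_min=config.kda.coverage_min,
                    fdr_max=config.kda.fdr_max,
                    seed=config.seed + _SEED_KDA,
                )
                kda_raw[dom][ef] = wkda_run(bg, catalog, kp)
        _record(stage, pairs_tested=sum(len(d[1]) for d in kda_raw.values()))

        stage = "join"
        drivers_dir = out / "drivers"
        drivers_dir.mkdir(exist_ok=True)
        retained = {}
        n_joined = 0
        for dom, runs in kda_raw.items():
            joined = delta_fdr_join(runs[1], runs[0], nperm=config.kda.nperm)
            n_joined += len(joined)
            kept = filter_drivers(joined, config.kda, domain=dom)
            kept.to_csv(drivers_dir / f"{dom}.tsv", sep="\t", index=False)
            retained[dom] = kept
        combined = (
            pd.concat([df for df in retained.values() if len(df)], ignore_index=True)
            if any(len(df) for df in retained.values())
            else pd.DataFrame()
        )
        combined.to_csv(out / "drivers_all.tsv", sep="\t", index=False)
        _record(stage, pairs_joined=n_joined, pairs_retained=len(combined))

        stage = "integrate"
        consensus = integrate_drivers(retained, config.integration, term_domains=catalog.term_domains)
        consensus.to_csv(out / "consensus.tsv", sep="\t", index=False)
        _record(stage, consensus_pairs=len(consensus))

        stage = "domains"
        sizes = {dom: g.n_nodes for dom, g in domain_graphs.items()}
        if len(combined):
            dg = infer_domain_interactions(combined, catalog.term_domains, graph_sizes=sizes)
            dg.edge_frame().to_csv(out / "domain_interactions.tsv", sep="\t", index=False)
            dg.to_matrix().to_csv(out / "domain_matrix.tsv", sep="\t")
            domain_degree_fractions(dg).to_csv(out / "domain_degree.tsv", sep="\t", index=False)
            n_dom_edges = dg.graph.number_of_edges()
        else:
            pd.DataFrame(columns=["source_domain", "target_domain", "weight"]).to_csv(
                out / "domain_interactions.tsv", sep="\t", index=False
            )
            n_dom_edges = 0
        _record(stage, domain_edges=n_dom_edges)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - manifest must record the stage
        _fail(exc)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
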