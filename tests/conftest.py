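import numpy as np
import pytest

import riskgraph as rg


@pytest.fixture(scope="session")
def default_config():
    return rg.GeneratorConfig()


@pytest.fixture(scope="session")
def bundle(default_config):
    """Default synthetic benchmark (500 genes, 40 terms, 3 planted drivers, seed 7)."""
    return rg.generate_benchmark(default_config)


@pytest.fixture(scope="session")
def filtered(bundle):
    net, _, _ = bundle
    return rg.filter_network(net)


@pytest.fixture(scope="session")
def kda_joined(bundle, filtered):
    """Both edge-factor runs on the filtered base graph, joined and filtered."""
    _, catalog, truth = bundle
    params = rg.KdaParams(edge_factor=1, seed=11)
    weighted = rg.wkda_run(filtered, catalog, params)
    unweighted = rg.wkda_run(filtered, catalog, rg.KdaParams(edge_factor=0, seed=11))
    joined = rg.delta_fdr_join(weighted, unweighted, nperm=params.nperm)
    kept = rg.filter_drivers(joined, params, domain="base")
    return {
        "weighted": weighted,
        "unweighted": unweighted,
        "joined": joined,
        "kept": kept,
        "truth": truth,
        "catalog": catalog,
        "params": params,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_annotated(nodes, edges):
    """Helper: build an AnnotatedNetwork from terse specs.

    nodes: {symbol: (risk, domains)} ; edges: [(a, b, n_pubmed)].
    """
    net = rg.AnnotatedNetwork()
    pm = 0
    for sym, (risk, domains) in nodes.items():
        net.add_node(rg.GeneNode(sym, risk_score=risk, expr_hpa=True, biodomains=frozenset(domains)))
    for a, b, k in edges:
        ids = [str(10_000 + pm + i) for i in range(k)]
        pm += k
        net.add_interaction(a, b, pubmed_ids=ids)
    return net
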