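import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskgraph as rg
from riskgraph.catalog import ModuleCatalog
from riskgraph.enrichment import EnrichmentResult, enrichment_score


def brute_force_es(scores_desc, hit_mask, exponent=1.0):
    """Independent oracle: full running-sum loop over every position.

    The extreme of larger magnitude wins; on an exact magnitude tie the
    negative extreme is reported.
    """
    nh = sum(hit_mask)
    n = len(scores_desc)
    nr = sum(abs(s) ** exponent for s, h in zip(scores_desc, hit_mask) if h)
    miss = 1.0 / (n - nh)
    run = 0.0
    lo, hi = 0.0, 0.0
    for s, h in zip(scores_desc, hit_mask):
        run += (abs(s) ** exponent) / nr if h else -miss
        lo, hi = min(lo, run), max(hi, run)
    return hi if hi > -lo + 1e-12 else lo


class TestEnrichmentScore:
    def test_worked_example_top_pair(self):
        ranked = {f"g{i}": s for i, s in enumerate([5, 4, 3, 2, 1], start=1)}
        es, lead = enrichment_score(ranked, {"g1", "g2"})
        assert es == pytest.approx(1.0)
        assert lead == frozenset({"g1", "g2"})

    def test_bottom_ranked_set_negative(self):
        ranked = {f"g{i}": 10 - i for i in range(10)}
        es, _ = enrichment_score(ranked, {"g8", "g9"})
        assert es < 0

    def test_oracle_equivalence_exhaustive(self):
        """ES matches the brute-force running sum on all small lists/subsets."""
        rng = np.random.default_rng(42)
        for n in range(3, 11):
            scores = np.sort(rng.uniform(0.1, 5.0, size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            ranked = dict(zip(genes, scores))
            for k in range(1, 5):
                if k >= n:
                    continue
                for subset in itertools.combinations(range(n), k):
                    mask = [i in subset for i in range(n)]
                    expected = brute_force_es(scores, mask)
                    es, _ = enrichment_score(ranked, {genes[i] for i in subset})
                    assert es == pytest.approx(expected, abs=1e-12), (n, subset)

    def test_leading_edge_positive_es(self):
        ranked = {f"g{i}": 20 - i for i in range(20)}
        es, lead = enrichment_score(ranked, {"g0", "g3", "g15"})
        assert es > 0
        # the trailing hit far down the list is not in the leading edge
        assert lead == frozenset({"g0", "g3"})


@pytest.fixture(scope="module")
def toy_results():
    rng = np.random.default_rng(3)
    genes = [f"g{i:02d}" for i in range(60)]
    scores = np.concatenate([rng.uniform(3, 5, 10), rng.uniform(0, 2, 50)])
    terms = {
        "TOP": frozenset(genes[:8]),
        "RANDOM": frozenset(str(g) for g in rng.choice(genes, 10, replace=False)),
        "TINY": frozenset(genes[:1]),
        "ALL": frozenset(genes),
    }
    catalog = ModuleCatalog(terms=terms, term_domains={t: frozenset({"D"}) for t in terms})
    results = rg.preranked_gsea(dict(zip(genes, scores)), catalog, rg.SeedParams(seed=1, gsea_nperm=500))
    return {r.term: r for r in results}


class TestPrerankedGsea:

    def test_degenerate_terms_skipped(self, toy_results):
        assert "TINY" not in toy_results
        assert "ALL" not in toy_results

    def test_signal_term_significant(self, toy_results):
        assert toy_results["TOP"].pval <= 0.01
        assert toy_results["TOP"].nes > 1.0

    def test_pvalues_within_permutation_bounds(self, toy_results):
        for r in toy_results.values():
            assert 1.0 / 501 <= r.pval <= 1.0

    def test_padj_at_least_pval(self, toy_results):
        for r in toy_results.values():
            assert r.padj >= r.pval - 1e-15

    def test_leading_edge_subset_of_term(self, toy_results, ):
        assert toy_results["TOP"].leading_edge <= frozenset(f"g{i:02d}" for i in range(8))

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rg.preranked_gsea((["a", "a"], [1.0, 2.0]), ModuleCatalog(terms={"T": frozenset("a")}))


class TestSelectSeedGenes:
    def _result(self, term, padj, nes, lead, domain="Synapse"):
        return EnrichmentResult(term, 0.5, nes, padj / 2, padj, frozenset(lead), frozenset({domain}))

    def test_padj_boundary_excluded(self):
        res = [self._result("t1", 0.02, 2.0, {"a"})]
        assert rg.select_seed_genes(res, "Synapse") == frozenset()

    def test_nes_boundary_excluded(self):
        res = [self._result("t1", 0.005, 1.5, {"a"})]
        assert rg.select_seed_genes(res, "Synapse") == frozenset()
        # nes must be strictly above the threshold
        res = [self._result("t1", 0.005, 1.66, {"a"})]
        assert rg.select_seed_genes(res, "Synapse") == frozenset()

    def test_union_of_leading_edges(self):
        res = [
            self._result("t1", 0.005, 2.0, {"a", "b"}),
            self._result("t2", 0.005, 2.0, {"b", "c"}),
            self._result("t3", 0.005, 2.0, {"z"}, domain="Other"),
        ]
        assert rg.select_seed_genes(res, "Synapse") == frozenset({"a", "b", "c"})

    def test_unknown_domain_raises(self):
        res = [self._result("t1", 0.005, 2.0, {"a"})]
        with pytest.raises(KeyError):
            rg.select_seed_genes(res, "Nonexistent")

    def test_enriched_term_recovery_on_benchmark(self, bundle):
        """Planted risk-enriched terms are recovered at default thresholds."""
        net, catalog, truth = bundle
        ranked = {n.symbol: n.risk_score for n in net.nodes()}
        params = rg.SeedParams(seed=1)
        results = rg.preranked_gsea(ranked, catalog, params)
        qualifying = {r.term for r in results if r.padj <= params.padj_max and r.nes > params.nes_min}
        recovered = qualifying & set(truth.risk_enriched_terms)
        assert len(recovered) / len(truth.risk_enriched_terms) >= 0.9


class TestOra:
    def test_worked_example_exact_tail(self):
        # universe 20, query 5, term 4, overlap 3: p = P[X >= 3] for
        # X ~ Hypergeom(20, 4, 5) = (C(4,3)C(16,2) + C(4,4)C(16,1)) / C(20,5)
        expected = Fraction(math.comb(4, 3) * math.comb(16, 2) + math.comb(4, 4) * math.comb(16, 1),
                            math.comb(20, 5))
        universe = [f"u{i}" for i in range(20)]
        term = universe[:4]
        query = universe[:3] + universe[10:12]
        df = rg.ora_hypergeometric(query, universe, ModuleCatalog(terms={"T": frozenset(term)}))
        assert df.loc[0, "overlap"] == 3
        assert df.loc[0, "pval"] == pytest.approx(float(expected), rel=1e-12)

    def test_zero_overlap_not_enriched(self):
        universe = [f"u{i}" for i in range(50)]
        df = rg.ora_hypergeometric(universe[40:45], universe, ModuleCatalog(terms={"T": frozenset(universe[:3])}))
        assert df.loc[0, "pval"] >= 0.5

    def test_term_equals_universe_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        df = rg.ora_hypergeometric(universe[:4], universe, ModuleCatalog(terms={"T": frozenset(universe)}))
        assert df.loc[0, "pval"] == pytest.approx(1.0)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            rg.ora_hypergeometric([], [], ModuleCatalog(terms={"T": frozenset("a")}))


class TestFisherOverlap:
    def test_worked_odds_ratio(self):
        universe = [f"u{i}" for i in range(100)]
        a = universe[:10]
        b = universe[5:15]
        result = rg.fisher_overlap(a, b, universe)
        assert result.counts == (5, 5, 5, 85)
        assert result.odds_ratio == pytest.approx(17.0)

    def test_disjoint_odds_zero(self):
        universe = [f"u{i}" for i in range(100)]
        result = rg.fisher_overlap(universe[:30], universe[30:60], universe)
        assert result.odds_ratio == 0.0

    def test_degenerate_full_overlap(self):
        universe = [f"u{i}" for i in range(10)]
        result = rg.fisher_overlap(universe, universe, universe)
        assert result.pval == pytest.approx(1.0)
        assert math.isnan(result.odds_ratio)

    def test_infinity_marker(self):
        universe = [f"u{i}" for i in range(20)]
        result = rg.fisher_overlap(universe[:5], universe[:5], universe)
        assert result.odds_ratio == math.inf


def naive_bh(pvalues):
    """O(m^2) step-up oracle."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for later_pos, j in enumerate(order, start=1):
            if later_pos >= rank_pos:
                candidates.append(min(1.0, pvalues[j] * m / later_pos))
        adjusted[i] = min(candidates)
    return adjusted


class TestBhAdjust:
    def test_worked_example_all_004(self):
        out = rg.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert rg.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_worked_example_two(self):
        assert np.allclose(rg.bh_adjust([0.005, 0.5]), [0.01, 0.5])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            rg.bh_adjust([0.5, 1.2])

    def test_matches_naive_oracle_random(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = int(rng.integers(1, 30))
            p = rng.uniform(0, 1, size=m)
            assert np.allclose(rg.bh_adjust(p), naive_bh(list(p)))

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_property_bounded_and_monotone(self, pvals):
        adj = rg.bh_adjust(pvals)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.allclose(adj, naive_bh(pvals))
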