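"""Rank-based enrichment: preranked GSEA seeding, ORA, Fisher overlap, BH.

The preranked GSEA here is the standard weighted Kolmogorov-Smirnov running
sum with a gene-permutation null: the enrichment score is the running-sum
value at its maximal deviation from zero, hit increments are proportional
to |statistic|^exponent, the normalized score divides by the mean permuted
score of the same sign, and p-values are two one-sided permutation
probabilities with the +1 correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from riskgraph.catalog import ModuleCatalog

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedParams:
    """Thresholds and settings for seed-gene selection."""

    padj_max: float = 0.01
    nes_min: float = 1.66
    gsea_nperm: int = 1000
    gsea_weight_exponent: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    es: float
    nes: float
    pval: float
    padj: float
    leading_edge: frozenset
    term_domain: frozenset


@dataclass(frozen=True)
class OverlapResult:
    odds_ratio: float  # math.inf when a denominator cell is 0 with positive numerator
    pval: float
    counts: Tuple[int, int, int, int]  # n11, n12, n21, n22


# ---------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment, restored to input order.

    adjusted_i = min over j >= i (in sorted order) of min(1, p_(j) * m / j).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------


def _as_ranked(ranked) -> Tuple[List[str], np.ndarray]:
    """Normalize input to (genes, scores) sorted by descending score.

    Accepts a mapping gene->score, a pandas Series, or a pair of parallel
    sequences.  Ties are broken by input order with a warning; duplicate
    genes are an error.
    """
    if isinstance(ranked, pd.Series):
        genes, scores = list(ranked.index), ranked.to_numpy(dtype=float)
    elif isinstance(ranked, Mapping):
        genes, scores = list(ranked.keys()), np.array(list(ranked.values()), dtype=float)
    else:
        genes, scores = list(ranked[0]), np.asarray(ranked[1], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in ranked list")
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking statistic must be finite")
    order = np.argsort(-scores, kind="stable")
    scores_sorted = scores[order]
    if np.unique(scores_sorted).size != scores_sorted.size:
        log.warning("ties in the ranking statistic; broken by input order")
    return [genes[i] for i in order], scores_sorted


def _es_from_hits(hit_pos: np.ndarray, hit_w: np.ndarray, n: int) -> Tuple[float, int]:
    """Enrichment score from sorted 0-based hit positions and their weights.

    The running sum rises by w_i / sum(w) at each hit and falls by
    1 / (n - n_hits) at each miss; between hits it is linear, so only the
    values immediately before and after each hit need checking.  Returns
    (es, index_of_extreme_position).
    """
    nh = hit_pos.size
    nr = hit_w.sum()
    miss = 1.0 / (n - nh)
    cum_w = np.cumsum(hit_w) / nr
    k = np.arange(nh)
    after = cum_w - (hit_pos - k) * miss  # value just after hit k
    before = np.concatenate(([0.0], cum_w[:-1])) - (hit_pos - k) * miss  # just before hit k
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = after[i_max]
    es_neg = before[i_min]
    # on a magnitude tie (up to float tolerance) the negative extreme wins
    if es_pos > -es_neg + 1e-12:
        return float(es_pos), i_max
    return float(es_neg), i_min


def enrichment_score(ranked, gene_set: Iterable, weight_exponent: float = 1.0) -> Tuple[float, frozenset]:
    """Enrichment score and leading edge of one gene set, no permutations.

    Returns ``(es, leading_edge)``.  The set must hit at least one but not
    all positions of the ranked list.
    """
    genes, scores = _as_ranked(ranked)
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    hit_idx = np.array(sorted(index[g] for g in gene_set if g in index), dtype=int)
    if hit_idx.size == 0 or hit_idx.size >= n:
        raise ValueError("gene set must hit at least one and fewer than all ranked positions")
    w = np.abs(scores[hit_idx]) ** weight_exponent
    es, i_ext = _es_from_hits(hit_idx, w, n)
    if es >= 0:
        lead = frozenset(genes[i] for i in hit_idx[hit_idx <= hit_idx[i_ext]])
    else:
        lead = frozenset(genes[i] for i in hit_idx[hit_idx >= hit_idx[i_ext]])
    return es, lead


def preranked_gsea(ranked, sets: ModuleCatalog, params: SeedParams = SeedParams()) -> List[EnrichmentResult]:
    """Run preranked GSEA for every term of the catalog.

    Terms with fewer than two genes in the ranked list, or spanning the
    entire list (no misses), are skipped with a warning.  The null
    permutes gene labels, i.e. draws random same-size subsets of the
    ranked list.  BH adjustment runs across all scored terms.
    """
    genes, scores = _as_ranked(ranked)
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    w_all = np.abs(scores) ** params.gsea_weight_exponent
    rng = np.random.default_rng(params.seed)

    rows = []
    for term in sorted(sets.terms):
        hit_idx = np.array(sorted(index[g] for g in sets.terms[term] if g in index), dtype=int)
        nh = hit_idx.size
        if nh < 2:
            log.warning("term %s has < 2 genes in the ranked list; skipped", term)
            continue
        if nh >= n:
            log.warning("term %s spans the entire ranked list; skipped", term)
            continue
        es, i_ext = _es_from_hits(hit_idx, w_all[hit_idx], n)
        if es >= 0:
            lead = frozenset(genes[i] for i in hit_idx[hit_idx <= hit_idx[i_ext]])
        else:
            lead = frozenset(genes[i] for i in hit_idx[hit_idx >= hit_idx[i_ext]])

        perm_es = np.empty(params.gsea_nperm)
        for b in range(params.gsea_nperm):
            idx = np.sort(rng.choice(n, size=nh, replace=False))
            perm_es[b] = _es_from_hits(idx, w_all[idx], n)[0]
        if es >= 0:
            same = perm_es[perm_es >= 0]
            pval = (1 + int((same >= es).sum())) / (1 + same.size)
        else:
            same = perm_es[perm_es < 0]
            pval = (1 + int((same <= es).sum())) / (1 + same.size)
        denom = np.abs(same).mean() if same.size else float("nan")
        nes = es / denom if denom and not math.isnan(denom) else float("nan")
        rows.append((term, es, nes, pval, lead))

    if not rows:
        return []
    padj = bh_adjust([r[3] for r in rows])
    return [
        EnrichmentResult(
            term=term,
            es=es,
            nes=nes,
            pval=pval,
            padj=float(adj),
            leading_edge=lead,
            term_domain=sets.term_domains.get(term, frozenset()),
        )
        for (term, es, nes, pval, lead), adj in zip(rows, padj)
    ]


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "es": r.es,
                "nes": r.nes,
                "pval": r.pval,
                "padj": r.padj,
                "leading_edge": ";".join(sorted(r.leading_edge)),
                "term_domain": ";".join(sorted(r.term_domain)),
            }
            for r in results
        ],
        columns=["term", "es", "nes", "pval", "padj", "leading_edge", "term_domain"],
    )


def select_seed_genes(results: Iterable[EnrichmentResult], domain: str, params: SeedParams = SeedParams()) -> frozenset:
    """Union of leading edges over the domain's qualifying terms.

    A term qualifies with padj <= padj_max and nes > nes_min.  Returns the
    empty set when no term qualifies.  A domain absent from every result's
    labels raises KeyError.
    """
    results = list(results)
    known = set()
    for r in results:
        known |= r.term_domain
    if domain not in known:
        raise KeyError(f"unknown domain label '{domain}'")
    seeds: set = set()
    for r in results:
        if domain in r.term_domain and r.padj <= params.padj_max and r.nes > params.nes_min:
            seeds |= r.leading_edge
    return frozenset(seeds)


# ---------------------------------------------------------------------
# Over-representation and overlap tests
# ---------------------------------------------------------------------


def ora_hypergeometric(query: Iterable, universe: Iterable, sets: ModuleCatalog) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each term in `query`.

    p = P[X >= overlap] with X ~ Hypergeom(|universe|, |term ∩ universe|,
    |query|); BH adjustment across tested terms.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for term in sorted(sets.terms):
        term_genes = sets.terms[term] & universe
        k = len(term_genes & query)
        p = float(sps.hypergeom.sf(k - 1, len(universe), len(term_genes), len(query)))
        rows.append({"term": term, "overlap": k, "term_size": len(term_genes), "pval": min(1.0, p)})
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "pval"])
    if len(df):
        df["padj"] = bh_adjust(df["pval"].to_numpy())
    else:
        df["padj"] = []
    return df


def fisher_overlap(set_a: Iterable, set_b: Iterable, universe: Iterable) -> OverlapResult:
    """Two-sided Fisher exact test on the 2x2 overlap table.

    The odds ratio is the sample odds ratio (n11*n22)/(n12*n21), reported
    as +inf when a denominator cell is zero while the numerator cells are
    positive, and NaN for fully degenerate tables.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    _, pval = sps.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    num, den = n11 * n22, n12 * n21
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = math.nan
    return OverlapResult(odds_ratio=odds, pval=float(pval), counts=(n11, n12, n21, n22))
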