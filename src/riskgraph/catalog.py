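"""Gene-set catalog: GMT gene sets plus a term-to-domain mapping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping

import pandas as pd

from riskgraph.errors import SchemaError


@dataclass
class ModuleCatalog:
    """GO-term-style gene sets with their biodomain assignments.

    ``terms`` maps term id -> member genes; ``term_domains`` maps term id ->
    set of domain labels (terms may belong to several domains).
    """

    terms: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    term_domains: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def domains(self) -> frozenset:
        out = set()
        for doms in self.term_domains.values():
            out |= doms
        return frozenset(out)

    def terms_for_domain(self, domain: str) -> list:
        return sorted(t for t, doms in self.term_domains.items() if domain in doms)

    def coverage(self, term: str, nodes: Iterable) -> float:
        genes = self.terms[term]
        if not genes:
            raise ValueError(f"term {term} is empty")
        nodes = set(nodes)
        return len(genes & nodes) / len(genes)

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path) -> Dict[str, FrozenSet[str]]:
    """Read a GMT file: name <tab> description <tab> gene...

    Empty files yield an empty catalog.
    """
    terms = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SchemaError(f"malformed GMT record at line {i + 1} of {path}")
            terms[parts[0]] = frozenset(g for g in parts[2:] if g)
    return terms


def write_gmt(terms: Mapping[str, Iterable], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(terms):
            genes = "\t".join(sorted(terms[name]))
            fh.write(f"{name}\t{description}\t{genes}\n" if genes else f"{name}\t{description}\n")


def read_term_domains(path) -> Dict[str, FrozenSet[str]]:
    """Read the term->domain TSV (columns term_id, domain; one row per pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("term_id", "domain"):
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}' in {path}")
    out: Dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.term_id), set()).add(str(row.domain))
    return {t: frozenset(d) for t, d in out.items()}


def write_term_domains(term_domains: Mapping[str, Iterable], path) -> None:
    rows = [
        {"term_id": term, "domain": dom}
        for term in sorted(term_domains)
        for dom in sorted(term_domains[term])
    ]
    pd.DataFrame(rows, columns=["term_id", "domain"]).to_csv(path, sep="\t", index=False)


def read_catalog(gmt_path, term_domain_path=None) -> ModuleCatalog:
    terms = read_gmt(gmt_path)
    domains = read_term_domains(term_domain_path) if term_domain_path is not None else {}
    return ModuleCatalog(terms=terms, term_domains=domains)
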