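"""Binomial over/under-representation test for annotation terms.

For a query gene set of size ``n`` drawn from a universe of ``N`` annotated
genes, a term annotated to ``K`` universe genes has expected query count
``n*K/N``.  The observed count ``k`` is tested against Binomial(n, K/N):
upper tail P(X >= k) when k exceeds the expectation (over-representation,
direction "+"), lower tail P(X <= k) otherwise (direction "-").  Raw
p-values are Bonferroni-corrected over the number of terms with at least one
annotated universe gene.

The universe defaults to all genes carrying at least one annotation in the
reference set, not all genome genes, and the query is intersected with it
before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from scipy.stats import binom

__all__ = ["AnnotationTable", "EnrichmentRow", "binomial_enrichment"]


@dataclass(frozen=True)
class AnnotationTable:
    """Term -> annotated-gene mapping with optional display metadata."""

    term_to_genes: Mapping[str, frozenset[str]]
    term_names: Mapping[str, str] = field(default_factory=dict)
    term_aspects: Mapping[str, str] = field(default_factory=dict)

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    aspect: str
    K: int  # universe genes annotated to the term
    n: int  # query genes within the universe
    N: int  # universe size
    k: int  # query genes annotated to the term
    expected: float  # n * K / N
    direction: str  # "+" over, "-" under
    p_raw: float
    p_bonferroni: float


def expected_count(K: int, n: int, N: int) -> float:
    """Expected number of annotated query genes, ``n * K / N``."""
    if N <= 0:
        raise ValueError("universe size must be positive")
    if K > N or n > N:
        raise ValueError(f"K ({K}) and n ({n}) must not exceed N ({N})")
    return n * K / N


def binomial_enrichment(
    query: set[str],
    annotation: AnnotationTable,
    universe: set[str] | None = None,
) -> list[EnrichmentRow]:
    """Test every annotation term for over/under-representation in a gene set.

    Parameters
    ----------
    query
        Gene identifiers of interest (e.g. protein-coding CNV genes);
        intersected with the universe before testing.
    annotation
        Term -> gene annotation table, taken as given (no ontology-graph
        propagation is applied here).
    universe
        Reference gene set; defaults to all genes with at least one
        annotation in ``annotation``.

    Returns rows sorted by raw p-value.  The Bonferroni multiplier is the
    number of terms with K >= 1 in the chosen annotation set.
    """
    if universe is None:
        universe = set(annotation.annotated_genes)
    N = len(universe)
    if N == 0:
        raise ValueError("empty annotation universe")
    q = query & universe
    n = len(q)
    if n == 0:
        raise ValueError("query has no genes in the annotated universe")
    term_K = {
        term: len(genes & universe) for term, genes in annotation.term_to_genes.items()
    }
    m = sum(1 for K in term_K.values() if K >= 1)
    rows: list[EnrichmentRow] = []
    for term, genes in annotation.term_to_genes.items():
        K = term_K[term]
        if K == 0:
            continue
        k = len(genes & q)
        exp = expected_count(K, n, N)
        p = K / N
        if k > exp:
            direction = "+"
            p_raw = float(binom.sf(k - 1, n, p))
        else:
            direction = "-"
            p_raw = float(binom.cdf(k, n, p))
        rows.append(
            EnrichmentRow(
                term_id=term,
                term_name=annotation.term_names.get(term, term),
                aspect=annotation.term_aspects.get(term, "biological_process"),
                K=K,
                n=n,
                N=N,
                k=k,
                expected=exp,
                direction=direction,
                p_raw=p_raw,
                p_bonferroni=min(1.0, m * p_raw),
            )
        )
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows
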