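"""Gene Ontology-style over-representation analysis.

One-sided Fisher's exact (hypergeometric upper tail) per annotation term,
with Bonferroni control across the tested terms, reproducing the statistic
behind a "-log10(Bonferroni-adjusted P)" enrichment bar chart. Semantic
clustering / visualization of the resulting terms is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, log10
from typing import Iterable, Optional, Sequence

from .models import ValidationError
from .stats import hypergeom_tail

__all__ = ["TermAnnotation", "EnrichmentResult", "enrich"]


@dataclass(frozen=True)
class TermAnnotation:
    """A term (e.g. a GO biological process) and its annotated gene set."""

    term_id: str
    genes: frozenset[str]
    name: str = ""


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one term.

    k of n query genes fall in the term's K annotated genes, out of a
    universe of N. ``p_adj`` is Bonferroni over the m tested terms;
    ``significant`` applies a strict ``p_adj < alpha`` cut.
    """

    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    significant: bool

    @property
    def neg_log10_adj(self) -> float:
        return inf if self.p_adj == 0 else -log10(self.p_adj)


def enrich(
    query: Iterable[str],
    annotations: Sequence[TermAnnotation],
    universe: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    correction_scope: str = "annotated",
) -> list[EnrichmentResult]:
    """Test each term for over-representation in ``query``.

    The universe defaults to the union of all annotated genes; a query gene
    outside the universe is an error. ``correction_scope`` selects which
    terms count toward the Bonferroni factor m: every term with a non-empty
    gene set in the universe (``"annotated"``, default) or only terms
    actually overlapping the query (``"overlapping"``). Results are sorted
    by (p_adj, term id); ordering is invariant to input order.
    """
    query_set = frozenset(query)
    if universe is None:
        universe_set = frozenset(g for t in annotations for g in t.genes)
    else:
        universe_set = frozenset(universe)
    if not universe_set:
        raise ValidationError("empty gene universe")
    missing = query_set - universe_set
    if missing:
        raise ValidationError(f"query genes outside universe: {sorted(missing)[:5]}")
    if correction_scope not in ("annotated", "overlapping"):
        raise ValidationError(f"bad correction_scope {correction_scope!r}")

    N = len(universe_set)
    n = len(query_set)
    tested: list[tuple[TermAnnotation, int, int]] = []
    for term in annotations:
        term_genes = term.genes & universe_set
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query_set)
        if correction_scope == "overlapping" and k == 0:
            continue
        tested.append((term, k, K))
    m = len(tested)

    results = []
    for term, k, K in tested:
        p = hypergeom_tail(k, K, n, N)
        p_adj = min(1.0, m * p)
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                name=term.name,
                k=k,
                K=K,
                n=n,
                N=N,
                p=p,
                p_adj=p_adj,
                significant=p_adj < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return results
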