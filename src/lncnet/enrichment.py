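"""Hypergeometric term enrichment over lncRNA target genes.

Counting follows the annotated-only convention: N is the number of
annotated genes in the background, n the number of annotated genes in the
query, M the background genes carrying a term and m the query genes
carrying it. The fold-enrichment score is (m/n) / (M/N) and significance
is the upper-tail hypergeometric probability P(X >= m), computed in log
space via scipy's survival function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .io import GeneSet


@dataclass(frozen=True)
class EnrichmentInput:
    N: int  # annotated background genes
    n: int  # annotated query genes
    M: int  # background genes carrying the term
    m: int  # query genes carrying the term

    def __post_init__(self):
        if not (0 <= self.m <= self.n <= self.N and self.m <= self.M <= self.N):
            raise ValueError(f"inconsistent counts {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    count: int
    fold_enrichment: float
    p: float


def fold_score(inp: EnrichmentInput) -> float:
    """(m/n) / (M/N): the query's term frequency over the background's."""
    if inp.n == 0 or inp.M == 0:
        raise ZeroDivisionError("n and M must be positive")
    return (inp.m / inp.n) / (inp.M / inp.N)


def hypergeom_p(inp: EnrichmentInput) -> float:
    """Upper tail P(X >= m), X ~ Hypergeometric(N, M, n)."""
    if inp.m == 0:
        return 1.0
    return float(stats.hypergeom.sf(inp.m - 1, inp.N, inp.M, inp.n))


def enrich(
    query_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str],
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Per-term enrichment of ``query_genes`` against ``background``.

    Genes absent from every gene set are unannotated and excluded from
    both N and n. Results are sorted by p ascending (ties by term_id);
    ``adjust`` replaces p with Benjamini–Hochberg adjusted values.
    """
    background = set(background)
    query = set(query_genes)
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    annotated = set().union(*(gs.member_gene_ids for gs in gene_sets)) if gene_sets else set()
    bg_ann = background & annotated
    q_ann = query & annotated
    N, n = len(bg_ann), len(q_ann)
    results = []
    for gs in gene_sets:
        M = len(gs.member_gene_ids & bg_ann)
        m = len(gs.member_gene_ids & q_ann)
        if M == 0 or n == 0:
            continue
        inp = EnrichmentInput(N=N, n=n, M=M, m=m)
        results.append(
            EnrichmentResult(gs.term_id, gs.term_name, m, fold_score(inp), hypergeom_p(inp))
        )
    if adjust and results:
        ps = stats.false_discovery_control([r.p for r in results], method="bh")
        results = [
            EnrichmentResult(r.term_id, r.term_name, r.count, r.fold_enrichment, float(q))
            for r, q in zip(results, ps)
        ]
    return sorted(results, key=lambda r: (r.p, r.term_id))


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.term_name, r.count, r.p, r.fold_enrichment) for r in results],
        columns=["term_id", "term_name", "count", "p_value", "fold_enrichment"],
    )


__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "enrich",
    "fold_score",
    "hypergeom_p",
    "results_to_frame",
]
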