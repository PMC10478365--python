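"""GO biological-process over-representation and per-gene participation counts.

Over-representation uses the one-sided hypergeometric upper tail
P(X >= k) with the annotation universe as background, followed by
Benjamini-Hochberg FDR across all tested processes.  A process is
"enriched" when its adjusted p-value falls below the significance level
(default 0.01).  The participation statistic counts, per gene, how many
enriched processes of the complete and of the regulatory network contain
it (N_i = N1_i + N2_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import GOAnnotations, ValidationError, canon

logger = logging.getLogger("comorbid_rank")

__all__ = [
    "EnrichmentResult",
    "Criterion4Counts",
    "hypergeom_tail",
    "bh_fdr",
    "enrich_processes",
    "criterion4_counts",
    "write_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one process in a query set.

    k of the n query genes are annotated to the process; K of the N universe
    genes are.  q_value is the BH-adjusted p across all tested processes.
    """

    process_id: str
    name: str
    p_value: float
    q_value: float
    k: int
    K: int
    n: int
    N: int
    members: frozenset[str]
    enriched: bool


@dataclass
class Criterion4Counts:
    """Per-gene counts of enriched processes containing the gene: n1 for the
    complete network, n2 for the regulatory network, total n1 + n2."""

    n1: dict[str, int] = field(default_factory=dict)
    n2: dict[str, int] = field(default_factory=dict)

    def n_total(self, gene: str) -> int:
        g = canon(gene)
        return self.n1.get(g, 0) + self.n2.get(g, 0)

    def genes(self) -> set[str]:
        return set(self.n1) | set(self.n2)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1,
    order-preserving with the input)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich_processes(
    query: Iterable[str],
    annotations: GOAnnotations,
    alpha: float = 0.01,
    ease_offset: int = 0,
) -> list[EnrichmentResult]:
    """Test every process with at least one query member for over-representation.

    Query genes outside the annotation universe are dropped with a warning.
    `ease_offset` subtracts that many query successes before taking the tail
    (the conservative EASE variant uses 1); the default is the plain test.
    """
    universe = annotations.universe
    q = {canon(g) for g in query}
    dropped = q - universe
    if dropped:
        logger.warning(
            "%d query gene(s) outside the annotation universe dropped (e.g. %s)",
            len(dropped), sorted(dropped)[:3],
        )
    q &= universe
    if not q:
        raise ValidationError("empty query after restricting to the annotation universe")
    n, N = len(q), len(universe)
    tested: list[tuple[str, int, int, frozenset[str], float]] = []
    for pid in sorted(annotations.genes_by_process):
        members = annotations.genes_by_process[pid]
        k = len(members & q)
        if k == 0:
            continue
        p = hypergeom_tail(k - ease_offset, len(members), n, N)
        tested.append((pid, k, len(members), members, p))
    qvals = bh_fdr([t[4] for t in tested])
    return [
        EnrichmentResult(
            process_id=pid,
            name=annotations.names.get(pid, pid),
            p_value=p,
            q_value=qv,
            k=k,
            K=K,
            n=n,
            N=N,
            members=members,
            enriched=qv < alpha,
        )
        for (pid, k, K, members, p), qv in zip(tested, qvals)
    ]


def criterion4_counts(
    enriched_complete: Iterable[EnrichmentResult],
    enriched_regulatory: Iterable[EnrichmentResult],
    genes: Iterable[str],
) -> Criterion4Counts:
    """Count, per gene, the enriched processes containing it in each network.

    Genes never seen in any enriched process keep count 0 but stay in the
    output, so every candidate receives a criterion value.
    """
    counts = Criterion4Counts()
    gene_set = {canon(g) for g in genes}
    counts.n1 = {g: 0 for g in gene_set}
    counts.n2 = {g: 0 for g in gene_set}
    for res in enriched_complete:
        if not res.enriched:
            continue
        for g in res.members & gene_set:
            counts.n1[g] += 1
    for res in enriched_regulatory:
        if not res.enriched:
            continue
        for g in res.members & gene_set:
            counts.n2[g] += 1
    return counts


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("process_id\tname\tk\tK\tn\tN\tp\tq\tenriched\tmembers\n")
        for r in sorted(results, key=lambda r: (r.p_value, r.process_id)):
            fh.write(
                f"{r.process_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{int(r.enriched)}\t"
                f"{';'.join(sorted(r.members))}\n"
            )
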