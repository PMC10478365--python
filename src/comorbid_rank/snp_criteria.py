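"""Qualifying-SNP filtering and the binary SNP criteria (criteria 8-10).

A SNP *qualifies* when it is an eQTL for the gene in the target tissue
(default brain) and its minor-allele frequency is at least the cutoff
(default 5%, boundary inclusive).  The binary criteria give a gene rank 1
when it carries a qualifying SNP (criterion 8), a qualifying SNP associated
with one of the two studied diseases (criterion 9), or with a comorbid
disease (criterion 10); otherwise the gene falls to the worst rank N, the
size of the candidate list, which deliberately gives these criteria extra
weight in the final average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_model import SNPRecord, ValidationError, canon

logger = logging.getLogger("comorbid_rank")

__all__ = [
    "QualifyingSnpIndex",
    "BinaryCriterionRanks",
    "filter_qualifying_snps",
    "binary_snp_criterion",
    "snp_density",
    "write_binary_ranks",
]


@dataclass
class QualifyingSnpIndex:
    """Per-gene lists of SNPs passing the tissue and MAF filters."""

    by_gene: dict[str, tuple[SNPRecord, ...]] = field(default_factory=dict)
    tissue: str = "brain"
    maf_min: float = 0.05

    def records_for(self, gene: str) -> tuple[SNPRecord, ...]:
        return self.by_gene.get(canon(gene), ())


def filter_qualifying_snps(
    catalog: Iterable[SNPRecord], tissue: str = "brain", maf_min: float = 0.05
) -> QualifyingSnpIndex:
    """Keep exactly the SNPs that are eQTLs in `tissue` (case-insensitive
    match) with maf >= maf_min."""
    if not 0.0 < maf_min < 1.0:
        raise ValidationError(f"maf_min must lie in (0, 1), got {maf_min}")
    tissue_key = tissue.strip().lower()
    by_gene: dict[str, list[SNPRecord]] = {}
    for rec in catalog:
        if rec.maf < maf_min:
            continue
        if tissue_key not in {t.strip().lower() for t in rec.eqtl_tissues}:
            continue
        by_gene.setdefault(canon(rec.gene), []).append(rec)
    return QualifyingSnpIndex(
        by_gene={
            g: tuple(sorted(records, key=lambda r: r.snp_id))
            for g, records in by_gene.items()
        },
        tissue=tissue,
        maf_min=maf_min,
    )


@dataclass
class BinaryCriterionRanks:
    """Rank 1 (has evidence) or N = candidate-list size (no evidence)."""

    criterion_id: int
    ranks: dict[str, int]  # canonical symbol -> 1 or n_candidates
    n_candidates: int
    evidence: dict[str, tuple[str, ...]] = field(default_factory=dict)


def binary_snp_criterion(
    candidates: Sequence[str],
    index: QualifyingSnpIndex,
    criterion_id: int,
    disease_whitelist: Iterable[str] | None = None,
) -> BinaryCriterionRanks:
    """Assign rank 1 or the fallback rank N per gene.

    criterion 8: any qualifying SNP counts.  criteria 9 and 10: the
    qualifying SNP must additionally be associated with a whitelisted disease
    (the two studied diseases for 9, the comorbid-disease list for 10);
    matching is case-insensitive.
    """
    if criterion_id not in (8, 9, 10):
        raise ValidationError(f"binary SNP criteria are 8, 9 and 10, got {criterion_id}")
    if not candidates:
        raise ValidationError("empty candidate list")
    whitelist = {
        d.strip().lower() for d in (disease_whitelist or ()) if d.strip()
    }
    if criterion_id in (9, 10) and not whitelist:
        raise ValidationError(
            f"criterion {criterion_id} requires a non-empty disease whitelist"
        )
    seen: set[str] = set()
    order: list[str] = []
    for g in candidates:
        key = canon(g)
        if key not in seen:
            seen.add(key)
            order.append(key)
    n = len(order)
    ranks: dict[str, int] = {}
    evidence: dict[str, tuple[str, ...]] = {}
    for key in order:
        hits: list[str] = []
        for rec in index.records_for(key):
            if criterion_id == 8:
                hits.append(rec.snp_id)
            else:
                diseases = {d.strip().lower() for d in rec.associated_diseases}
                if diseases & whitelist:
                    hits.append(rec.snp_id)
        ranks[key] = 1 if hits else n
        evidence[key] = tuple(hits)
    return BinaryCriterionRanks(
        criterion_id=criterion_id, ranks=ranks, n_candidates=n, evidence=evidence
    )


def snp_density(gene: str, index: QualifyingSnpIndex, gene_length_nt: int) -> float:
    """Qualifying SNPs per 1000 nucleotides of the gene."""
    if gene_length_nt <= 0:
        raise ValidationError("gene_length_nt must be positive")
    return len(index.records_for(gene)) * 1000.0 / gene_length_nt


def write_binary_ranks(ranks: BinaryCriterionRanks, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\trank\tevidence_snp_ids\n")
        for gene in sorted(ranks.ranks):
            snps = ";".join(ranks.evidence.get(gene, ()))
            fh.write(f"{gene}\t{ranks.ranks[gene]}\t{snps}\n")
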