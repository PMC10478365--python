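"""Rank assembly and average-rank aggregation over the ten criteria.

Criteria 1-3 rank external prioritizer scores along their fixed directions;
criterion 4 ranks genes by their enriched-process participation count;
criteria 5 and 6 rank the unweighted mean of the normalized degree,
clustering and betweenness centralities in the complete and regulatory
networks; criterion 7 orders genes by adjusted specificity p-value among
positively shifted genes; criteria 8-10 are the binary SNP ranks.  The
final priority is the arithmetic mean of the ten ranks, ascending.

Ties within a score-based criterion share the average (fractional) rank, so
each criterion's ranks sum to N(N+1)/2 whenever no gene is missing a score;
a missing score falls to the worst rank N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enrichment import Criterion4Counts
from .io_model import (
    ExternalScoreTable,
    PriorityReport,
    PriorityRow,
    ValidationError,
    canon,
)
from .network_analysis import CentralityRecord
from .process_specificity import SpecificityScore
from .snp_criteria import BinaryCriterionRanks

logger = logging.getLogger("comorbid_rank")

__all__ = [
    "CriterionRankMatrix",
    "rank_by_score",
    "assemble_rank_matrix",
    "aggregate_average_rank",
    "write_rank_matrix",
]

_DIRECTIONS = ("higher_is_better", "lower_is_better")


@dataclass
class CriterionRankMatrix:
    """Candidate genes x criteria 1..10 rank matrix.

    `table` is indexed by canonical symbol with columns rank1..rank10;
    `provenance` records, per criterion, whether the ranks came from an
    external file, were computed, or fell back to N for a missing input.
    """

    candidates: list[str]  # display symbols, defines N
    table: pd.DataFrame
    provenance: dict[int, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.candidates)

    def rank(self, gene: str, criterion_id: int) -> float:
        return float(self.table.at[canon(gene), f"rank{criterion_id}"])


def _dedupe_candidates(candidates: Sequence[str]) -> tuple[list[str], list[str]]:
    """(display list, canonical list) with case-insensitive de-duplication."""
    display: list[str] = []
    keys: list[str] = []
    seen: set[str] = set()
    for g in candidates:
        key = canon(g)
        if key not in seen:
            seen.add(key)
            display.append(g)
            keys.append(key)
    return display, keys


def rank_by_score(
    scores: Mapping[str, float], direction: str, candidates: Sequence[str]
) -> dict[str, float]:
    """Rank candidates by score: best score -> rank 1, ties averaged, genes
    without a score -> worst rank N."""
    if direction not in _DIRECTIONS:
        raise ValidationError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    display, keys = _dedupe_candidates(candidates)
    if not keys:
        raise ValidationError("empty candidate list")
    n = len(keys)
    score_map = {canon(g): float(s) for g, s in scores.items()}
    present = [k for k in keys if k in score_map]
    out: dict[str, float] = {k: float(n) for k in keys}
    if present:
        vals = np.array([score_map[k] for k in present], dtype=float)
        if direction == "higher_is_better":
            vals = -vals
        ranks = rankdata(vals, method="average")
        for k, r in zip(present, ranks):
            out[k] = float(r)
    return out


def _criterion7_ranks(
    scores: Iterable[SpecificityScore], keys: Sequence[str]
) -> dict[str, float]:
    """Specificity ordering: ascending q among positively shifted genes, ties
    averaged; non-positive or degenerate genes follow, in symbol order."""
    by_key = {canon(s.gene): s for s in scores}
    positive = [
        k for k in keys
        if k in by_key and not by_key[k].degenerate and by_key[k].t_stat > 0
    ]
    rest = sorted(k for k in keys if k not in set(positive))
    out: dict[str, float] = {}
    if positive:
        qvals = np.array([by_key[k].q_value for k in positive], dtype=float)
        for k, r in zip(positive, rankdata(qvals, method="average")):
            out[k] = float(r)
    for offset, k in enumerate(rest, start=len(positive) + 1):
        out[k] = float(offset)
    return out


def _centrality_scores(
    records: Iterable[CentralityRecord], keys: Sequence[str]
) -> dict[str, float]:
    """Mean of (dc, bc, cc) per entity; candidates absent from the network
    score 0 (worst), they are not excluded."""
    by_key = {canon(r.entity): (r.dc + r.bc + r.cc) / 3.0 for r in records}
    return {k: by_key.get(k, 0.0) for k in keys}


def assemble_rank_matrix(
    external: Iterable[ExternalScoreTable | None],
    c4: Criterion4Counts,
    centralities_complete: Iterable[CentralityRecord],
    centralities_regulatory: Iterable[CentralityRecord],
    c7: Iterable[SpecificityScore],
    c8: BinaryCriterionRanks,
    c9: BinaryCriterionRanks,
    c10: BinaryCriterionRanks,
    candidates: Sequence[str],
) -> CriterionRankMatrix:
    """Build the full genes x 10 rank matrix.

    `external` holds up to three score tables (criteria 1-3); a missing table
    fills its column with the worst rank N and is flagged in the provenance.
    """
    display, keys = _dedupe_candidates(candidates)
    if not keys:
        raise ValidationError("empty candidate list")
    n = len(keys)
    columns: dict[str, dict[str, float]] = {}
    provenance: dict[int, str] = {}

    tables: dict[int, ExternalScoreTable] = {}
    for t in external:
        if t is None:
            continue
        if t.criterion_id in tables:
            raise ValidationError(f"duplicate external table for criterion {t.criterion_id}")
        tables[t.criterion_id] = t
    for cid in (1, 2, 3):
        if cid in tables:
            t = tables[cid]
            columns[f"rank{cid}"] = rank_by_score(t.scores, t.direction, display)
            provenance[cid] = "external"
        else:
            columns[f"rank{cid}"] = {k: float(n) for k in keys}
            provenance[cid] = "missing:worst_rank"

    columns["rank4"] = rank_by_score(
        {k: float(c4.n_total(k)) for k in keys}, "higher_is_better", display
    )
    provenance[4] = "computed:enriched_process_participation"
    columns["rank5"] = rank_by_score(
        _centrality_scores(centralities_complete, keys), "higher_is_better", display
    )
    provenance[5] = "computed:complete_network_centrality"
    columns["rank6"] = rank_by_score(
        _centrality_scores(centralities_regulatory, keys), "higher_is_better", display
    )
    provenance[6] = "computed:regulatory_network_centrality"
    columns["rank7"] = _criterion7_ranks(c7, keys)
    provenance[7] = "computed:process_specificity"

    for cid, binary in ((8, c8), (9, c9), (10, c10)):
        if binary.criterion_id != cid:
            raise ValidationError(
                f"criterion id mismatch: expected {cid}, got {binary.criterion_id}"
            )
        if set(binary.ranks) != set(keys) or binary.n_candidates != n:
            raise ValidationError(
                f"criterion {cid} candidate list does not match the matrix candidates"
            )
        columns[f"rank{cid}"] = {k: float(binary.ranks[k]) for k in keys}
        provenance[cid] = "computed:binary_snp"

    table = pd.DataFrame(
        {col: [columns[col][k] for k in keys] for col in (f"rank{i}" for i in range(1, 11))},
        index=pd.Index(keys, name="gene"),
    )
    bad = (table < 1) | (table > n)
    if bool(bad.to_numpy().any()):
        raise ValidationError("rank outside [1, N] in assembled matrix")
    return CriterionRankMatrix(candidates=display, table=table, provenance=provenance)


def aggregate_average_rank(matrix: CriterionRankMatrix) -> PriorityReport:
    """Average the ten ranks per gene; sort ascending, ties alphabetical."""
    if matrix.table.isna().to_numpy().any():
        raise ValidationError("rank matrix is incomplete (NaN entries)")
    if list(matrix.table.columns) != [f"rank{i}" for i in range(1, 11)]:
        raise ValidationError("rank matrix must carry columns rank1..rank10")
    display_by_key = {canon(g): g for g in matrix.candidates}
    if set(display_by_key) != set(matrix.table.index):
        raise ValidationError("matrix index does not match candidate list")
    rows = [
        PriorityRow(
            gene=display_by_key[key],
            ranks=tuple(float(v) for v in matrix.table.loc[key]),
            average_rank=float(matrix.table.loc[key].mean()),
        )
        for key in matrix.table.index
    ]
    report = PriorityReport(rows=rows)
    report.rows = report.sorted_rows()
    return report


def write_rank_matrix(matrix: CriterionRankMatrix, path: str | Path) -> None:
    out = matrix.table.copy()
    display_by_key = {canon(g): g for g in matrix.candidates}
    out.index = [display_by_key[k] for k in out.index]
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6f")
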