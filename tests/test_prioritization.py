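"""Ranking rules, matrix assembly and average-rank aggregation."""

import numpy as np
import pandas as pd
import pytest

from comorbid_rank.enrichment import Criterion4Counts
from comorbid_rank.io_model import ExternalScoreTable, ValidationError
from comorbid_rank.network_analysis import CentralityRecord
from comorbid_rank.prioritization import (
    CriterionRankMatrix,
    aggregate_average_rank,
    assemble_rank_matrix,
    rank_by_score,
)
from comorbid_rank.process_specificity import SpecificityScore
from comorbid_rank.snp_criteria import BinaryCriterionRanks


class TestRankByScore:
    def test_ties_get_average_rank(self):
        ranks = rank_by_score(
            {"A": 0.9, "B": 0.5, "C": 0.5, "D": 0.1},
            "higher_is_better",
            ["A", "B", "C", "D"],
        )
        assert ranks == {"A": 1.0, "B": 2.5, "C": 2.5, "D": 4.0}

    def test_lower_is_better(self):
        ranks = rank_by_score({"A": 1e-5, "B": 0.3}, "lower_is_better", ["A", "B"])
        assert ranks == {"A": 1.0, "B": 2.0}

    def test_missing_gene_gets_worst_rank(self):
        ranks = rank_by_score(
            {"A": 1.0, "B": 0.5, "C": 0.2}, "higher_is_better", ["A", "B", "C", "E"]
        )
        assert ranks["E"] == 4.0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValidationError):
            rank_by_score({"A": 1.0}, "higher_is_better", [])

    def test_bad_direction_rejected(self):
        with pytest.raises(ValidationError):
            rank_by_score({"A": 1.0}, "best_first", ["A"])

    def test_rank_sum_conserved_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            scores = {
                f"G{i}": float(rng.integers(0, 5)) for i in range(n)  # many ties
            }
            ranks = rank_by_score(scores, "higher_is_better", list(scores))
            assert sum(ranks.values()) == pytest.approx(n * (n + 1) / 2)

    def test_case_insensitive_score_lookup(self):
        ranks = rank_by_score({"drd2": 2.0, "COMT": 1.0}, "higher_is_better", ["DRD2", "comt"])
        assert ranks["DRD2"] == 1.0


def _binary(cid, ranks, n):
    return BinaryCriterionRanks(criterion_id=cid, ranks=dict(ranks), n_candidates=n)


def _spec(gene, t, q, degenerate=False):
    return SpecificityScore(
        gene=gene, t_stat=t, df=10.0, p_value=q, q_value=q,
        mean_test=0.5 + (0.1 if t > 0 else -0.1), mean_control=0.5,
        degenerate=degenerate, specific=t > 0 and q < 0.05,
    )


def _assemble(candidates, **overrides):
    """Full matrix from simple per-criterion inputs with sensible defaults."""
    n = len(candidates)
    keys = [c.upper() for c in candidates]
    defaults = dict(
        external=[
            ExternalScoreTable(1, {k: float(i) for i, k in enumerate(keys)}),
            ExternalScoreTable(2, {k: float(i + 1) for i, k in enumerate(keys)}),
            ExternalScoreTable(3, {k: float(i) for i, k in enumerate(keys)}),
        ],
        c4=Criterion4Counts(n1={k: i for i, k in enumerate(keys)}, n2={}),
        centralities_complete=[
            CentralityRecord(entity=c, dc=0.1 * i, bc=0.1 * i, cc=0.1 * i, degree_raw=i)
            for i, c in enumerate(candidates)
        ],
        centralities_regulatory=[],
        c7=[_spec(c, t=1.0, q=0.01 * (i + 1)) for i, c in enumerate(candidates)],
        c8=_binary(8, {k: 1 for k in keys}, n),
        c9=_binary(9, {k: n for k in keys}, n),
        c10=_binary(10, {k: n for k in keys}, n),
    )
    defaults.update(overrides)
    return assemble_rank_matrix(candidates=candidates, **defaults)


class TestAssemble:
    CANDS = ["GA", "GB", "GC", "GD"]

    def test_highest_participation_gets_rank_one(self):
        m = _assemble(self.CANDS)
        assert m.rank("GD", 4) == 1.0  # largest n_total

    def test_best_centrality_gets_rank_one(self):
        m = _assemble(self.CANDS)
        assert m.rank("GD", 5) == 1.0

    def test_binary_ranks_passed_through(self):
        m = _assemble(self.CANDS)
        assert m.rank("GA", 8) == 1.0
        assert m.rank("GA", 9) == 4.0

    def test_missing_external_table_fills_worst_rank(self):
        m = _assemble(self.CANDS, external=[None, None, None])
        assert all(m.rank(c, 1) == 4.0 for c in self.CANDS)
        assert m.provenance[1].startswith("missing")

    def test_absent_from_regulatory_network_scores_worst_tie(self):
        m = _assemble(self.CANDS)  # empty regulatory centralities: all score 0
        assert all(m.rank(c, 6) == 2.5 for c in self.CANDS)

    def test_criterion7_positive_genes_precede_degenerate(self):
        c7 = [
            _spec("GA", t=2.0, q=0.04),
            _spec("GB", t=-1.0, q=0.01),
            _spec("GC", t=1.0, q=0.02),
            _spec("GD", t=0.0, q=1.0, degenerate=True),
        ]
        m = _assemble(self.CANDS, c7=c7)
        assert m.rank("GC", 7) == 1.0  # smallest q among positive
        assert m.rank("GA", 7) == 2.0
        # non-positive and degenerate follow, in symbol order
        assert m.rank("GB", 7) == 3.0
        assert m.rank("GD", 7) == 4.0

    def test_candidate_mismatch_rejected(self):
        bad = _binary(8, {"GA": 1}, 1)
        with pytest.raises(ValidationError):
            _assemble(self.CANDS, c8=bad)


class TestAggregate:
    @staticmethod
    def _matrix(rank_rows):
        genes = list(rank_rows)
        table = pd.DataFrame(
            {f"rank{i + 1}": [rank_rows[g][i] for g in genes] for i in range(10)},
            index=[g.upper() for g in genes],
        )
        return CriterionRankMatrix(candidates=genes, table=table)

    def test_all_ones_first(self):
        report = aggregate_average_rank(
            self._matrix({"GA": [2.0] * 10, "GB": [1.0] * 10})
        )
        assert report.rows[0].gene == "GB"
        assert report.rows[0].average_rank == 1.0

    def test_arithmetic_mean(self):
        report = aggregate_average_rank(
            self._matrix({"GA": list(range(1, 11)), "GB": [1.0] * 10})
        )
        (row,) = [r for r in report.rows if r.gene == "GA"]
        assert row.average_rank == pytest.approx(5.5)

    def test_order_invariant_under_criterion_permutation(self):
        rng = np.random.default_rng(1)
        base = {"GA": [1.0] * 10, "GB": [2.0] * 10}
        perm = rng.permutation(10)
        shuffled = {g: [ranks[i] for i in perm] for g, ranks in base.items()}
        r1 = aggregate_average_rank(self._matrix(base))
        r2 = aggregate_average_rank(self._matrix(shuffled))
        assert [r.gene for r in r1.rows] == [r.gene for r in r2.rows]

    def test_incomplete_matrix_rejected(self):
        m = self._matrix({"GA": [1.0] * 10})
        m.table.iloc[0, 3] = np.nan
        with pytest.raises(ValidationError):
            aggregate_average_rank(m)

    def test_ties_broken_alphabetically(self):
        report = aggregate_average_rank(
            self._matrix({"GB": [1.0] * 10, "GA": [1.0] * 10})
        )
        assert [r.gene for r in report.rows] == ["GA", "GB"]


class TestProperties:
    def test_bounds_and_rank_sum_conservation(self):
        rng = np.random.default_rng(9)
        candidates = [f"G{i}" for i in range(12)]
        n = len(candidates)
        external = [
            ExternalScoreTable(cid, {c: float(rng.integers(0, 6)) for c in candidates})
            for cid in (1, 2, 3)
        ]
        m = _assemble(candidates, external=external)
        assert ((m.table >= 1) & (m.table <= n)).all().all()
        for cid in range(1, 8):
            assert m.table[f"rank{cid}"].sum() == pytest.approx(n * (n + 1) / 2)
        report = aggregate_average_rank(m)
        assert all(1 <= r.average_rank <= n for r in report.rows)

    def test_permutation_invariance_of_candidate_order(self):
        candidates = ["GA", "GB", "GC", "GD"]
        n = len(candidates)
        # inputs keyed by gene, independent of the candidate ordering
        kwargs = dict(
            external=[
                ExternalScoreTable(1, {"GA": 3.0, "GB": 1.0, "GC": 2.0, "GD": 0.5}),
                None,
                None,
            ],
            c4=Criterion4Counts(n1={"GA": 2, "GB": 0, "GC": 5, "GD": 1}, n2={}),
            centralities_complete=[
                CentralityRecord("GA", 0.2, 0.1, 0.0, 2),
                CentralityRecord("GC", 0.5, 0.2, 0.1, 3),
            ],
            centralities_regulatory=[],
            c7=[
                _spec("GA", t=1.0, q=0.02),
                _spec("GB", t=-1.0, q=0.5),
                _spec("GC", t=1.0, q=0.01),
                _spec("GD", t=0.0, q=1.0, degenerate=True),
            ],
            c8=_binary(8, {"GA": 1, "GB": n, "GC": 1, "GD": n}, n),
            c9=_binary(9, {k: n for k in ("GA", "GB", "GC", "GD")}, n),
            c10=_binary(10, {"GA": n, "GB": n, "GC": n, "GD": 1}, n),
        )
        m1 = assemble_rank_matrix(candidates=candidates, **kwargs)
        m2 = assemble_rank_matrix(candidates=list(reversed(candidates)), **kwargs)
        for c in candidates:
            for cid in range(1, 11):
                assert m1.rank(c, cid) == m2.rank(c, cid)

    def test_dominance_ordering(self):
        rows = {
            "GDOM": [1.0] * 10,
            "GMID": [1.0] * 5 + [2.0] * 5,
            "GLOW": [3.0] * 10,
        }
        report = aggregate_average_rank(TestAggregate._matrix(rows))
        assert [r.gene for r in report.rows] == ["GDOM", "GMID", "GLOW"]

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            genes = [f"G{i}" for i in range(n)]
            score_sets = [
                {g: float(rng.integers(0, 4)) for g in genes} for _ in range(10)
            ]
            # implementation route
            cols = {}
            for cid, scores in enumerate(score_sets, start=1):
                cols[cid] = rank_by_score(scores, "higher_is_better", genes)
            table = pd.DataFrame(
                {f"rank{cid}": [cols[cid][g] for g in genes] for cid in range(1, 11)},
                index=genes,
            )
            report = aggregate_average_rank(
                CriterionRankMatrix(candidates=genes, table=table)
            )
            # oracle: rank(g) = #better + (#tied + 1) / 2, averaged by hand
            expected = {}
            for g in genes:
                total = 0.0
                for scores in score_sets:
                    better = sum(1 for h in genes if scores[h] > scores[g])
                    tied = sum(1 for h in genes if scores[h] == scores[g])
                    total += better + (tied + 1) / 2
                expected[g] = total / 10
            for row in report.rows:
                assert row.average_rank == pytest.approx(expected[row.gene], abs=1e-12)
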