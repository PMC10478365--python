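"""Per-gene specificity for disease-shared GO processes (criterion 7).

Processes linked to both diseases form the *test* set; every other annotated
process is *control*.  For each gene we build 0/1 annotation indicator
vectors over the two sets and compare them with Welch's unequal-variance
t-test; a positive statistic means the gene is preferentially annotated to
the shared processes.  P-values are BH-adjusted across genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_model import DiseaseProcessLinks, GOAnnotations, ValidationError, canon
from .enrichment import bh_fdr

logger = logging.getLogger("comorbid_rank")

__all__ = [
    "TestControlSets",
    "SpecificityScore",
    "build_test_control_sets",
    "welch_t",
    "criterion7_scores",
    "write_specificity",
]


@dataclass(frozen=True)
class TestControlSets:
    """Partition of all annotated processes into disease-shared (test) and
    remaining (control) sets."""

    test: frozenset[str]
    control: frozenset[str]

    def __post_init__(self) -> None:
        if self.test & self.control:
            raise ValidationError("test and control process sets must be disjoint")


@dataclass(frozen=True)
class SpecificityScore:
    gene: str
    t_stat: float
    df: float
    p_value: float
    q_value: float
    mean_test: float
    mean_control: float
    degenerate: bool
    specific: bool


def build_test_control_sets(
    links: DiseaseProcessLinks,
    disease_a: str,
    disease_b: str,
    annotations: GOAnnotations,
) -> TestControlSets:
    """test = processes linked to both diseases (restricted to annotated
    processes); control = all remaining annotated processes."""
    annotated = annotations.processes()
    linked_a = links.processes_for(disease_a)
    linked_b = links.processes_for(disease_b)
    shared = linked_a & linked_b
    outside = shared - annotated
    if outside:
        logger.warning(
            "%d disease-shared process(es) absent from the annotations dropped (e.g. %s)",
            len(outside), sorted(outside)[:3],
        )
    test = shared & annotated
    if not test:
        raise ValidationError(
            f"no annotated process is linked to both {disease_a!r} and {disease_b!r}; "
            "the process-specificity criterion is undefined"
        )
    return TestControlSets(test=frozenset(test), control=frozenset(annotated - test))


def welch_t(
    sample_x: Sequence[float], sample_y: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p).

    t = (x̄ − ȳ) / sqrt(s²x/nx + s²y/ny) with Welch–Satterthwaite degrees of
    freedom.  Raises when either sample has fewer than 2 values or both
    variances vanish.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("welch_t requires at least 2 values per sample")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise ValidationError("welch_t degenerate: both sample variances are zero")
    with warnings.catch_warnings():
        # sparse 0/1 indicator vectors routinely trigger scipy's
        # catastrophic-cancellation precision warning; the statistic is fine
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def criterion7_scores(
    genes: Iterable[str],
    annotations: GOAnnotations,
    sets: TestControlSets,
    alpha: float = 0.05,
) -> list[SpecificityScore]:
    """Welch test per gene on its 0/1 annotation indicators over test vs.
    control processes; q = BH over all genes.

    Genes whose indicators are constant on both sets with equal means (e.g.
    entirely unannotated) are degenerate: they get t = 0, p = 1 and a flag.
    Constant indicators with *different* means are perfect separation and get
    the limiting statistic (t = ±inf, p = 0).  A gene is "specific" when
    non-degenerate, positively shifted and q < alpha.
    """
    if len(sets.test) < 2 or len(sets.control) < 2:
        raise ValidationError(
            "criterion 7 needs at least 2 test and 2 control processes, got "
            f"{len(sets.test)} / {len(sets.control)}"
        )
    test_procs = sorted(sets.test)
    control_procs = sorted(sets.control)
    display: dict[str, str] = {}
    for g in genes:
        key = canon(g)
        if key not in display or g < display[key]:
            display[key] = g

    partial: list[tuple[str, float, float, float, float, float, bool]] = []
    for key in sorted(display):
        procs = annotations.processes_of(key)
        x = [1.0 if p in procs else 0.0 for p in test_procs]
        y = [1.0 if p in procs else 0.0 for p in control_procs]
        mean_x = math.fsum(x) / len(x)
        mean_y = math.fsum(y) / len(y)
        try:
            t, df, p = welch_t(x, y)
            degenerate = False
        except ValidationError:
            if mean_x != mean_y:
                # both indicators constant but different: perfect separation,
                # the limiting Welch statistic
                t = math.copysign(math.inf, mean_x - mean_y)
                df, p = float("nan"), 0.0
                degenerate = False
            else:
                t, df, p = 0.0, float("nan"), 1.0
                degenerate = True
        partial.append((key, t, df, p, mean_x, mean_y, degenerate))

    qvals = bh_fdr([row[3] for row in partial])
    return [
        SpecificityScore(
            gene=display[key],
            t_stat=t,
            df=df,
            p_value=p,
            q_value=q,
            mean_test=mean_x,
            mean_control=mean_y,
            degenerate=degenerate,
            specific=(not degenerate) and t > 0 and q < alpha,
        )
        for (key, t, df, p, mean_x, mean_y, degenerate), q in zip(partial, qvals)
    ]


def write_specificity(scores: Iterable[SpecificityScore], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tt\tdf\tp\tq\tmean_test\tmean_control\tspecific_flag\n")
        for s in sorted(scores, key=lambda s: s.gene.upper()):
            fh.write(
                f"{s.gene}\t{s.t_stat:.10g}\t{s.df:.10g}\t{s.p_value:.6g}\t"
                f"{s.q_value:.6g}\t{s.mean_test:.10g}\t{s.mean_control:.10g}\t"
                f"{int(s.specific)}\n"
            )
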