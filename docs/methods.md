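# Methods

## Problem and model

The package ranks candidate genes for the comorbidity of two diseases.  Its
input universe is an *associative gene network*: a graph whose nodes are
genes and proteins (a symbol may appear as both) and whose edges carry one
of seven relation types — activity, degradation, expression and transport
regulation, downregulation, generic association, and protein–protein
binding.  The *complete* comorbidity network is the subgraph induced on the
entities associated with both diseases (association tables are unioned over
their two provenances, a curated network database and a GeneCards-style
relevance list).  The *regulatory* network keeps only the regulation-type
edges; degradation regulation is included in that set by default because it
is a regulation category, and the set is configurable.

Gene and protein nodes sharing a symbol are distinct in the stored network
but are merged into one *entity* for every statistic that feeds the
ranking, because the final table ranks symbols, not node classes.  Symbols
are matched case-insensitively across files; the lexicographically smallest
spelling is kept for display.

## The ten criteria

1. **Criteria 1–3** ingest external prioritizer score tables with fixed
   directions: criterion 1 a relevance score (higher better), criterion 2 a
   p-value (lower better), criterion 3 an average score (higher better).
   A missing table fills its column with the worst rank `N` rather than
   dropping genes, keeping the ten columns commensurate; the manifest flags
   the substitution.
2. **Criterion 4** counts, per gene, the enriched GO biological processes
   containing it — `N_i = N1_i + N2_i` over the complete and regulatory
   networks — and ranks descending.
3. **Criteria 5–6** rank the unweighted mean of three normalized
   centralities on the entity-level simple graph (multi-edges collapsed,
   direction and type ignored): degree centrality `k/(N−1)`; betweenness
   `Σ σ_st(n)/σ_st` normalized by `(N−1)(N−2)/2`, with disconnected pairs
   contributing zero; and the neighbour-pair form `CC = 2e_n/(k_n(k_n−1))`,
   which is the local clustering coefficient — the formula is implemented
   exactly as written, and `CC = 0` when the degree is below 2 (the
   denominator would vanish).  Candidates absent from the regulatory
   network score 0 there (worst), not exclusion.
4. **Criterion 7** splits all annotated GO processes into a *test* set
   (linked to both diseases) and a *control* set (everything else), builds
   each gene's 0/1 annotation indicator vectors over the two sets, and
   compares them with Welch's unequal-variance t-test; p-values are
   BH-adjusted across genes.  The per-gene sample construction is the most
   direct reading of "interactions between genes and biological processes";
   weighted alternatives are out of scope.  Ranking: ascending q among
   genes with a positive statistic, then all non-positive or degenerate
   genes in symbol order.  Two edge cases: indicators constant on both sets
   with equal means (e.g. an unannotated gene) are *degenerate* (t = 0,
   p = 1, flagged); constant with different means is perfect separation and
   receives the limiting statistic (t = ±inf, p = 0).
5. **Criteria 8–10** are binary.  A SNP *qualifies* if it is an eQTL for
   the gene in the target tissue (default brain) and its minor-allele
   frequency is at least 0.05 — the boundary is inclusive ("at least 5%"),
   a conventional genotyping-array detectability cutoff.  Criterion 8 gives
   rank 1 for any qualifying SNP; criterion 9 additionally requires
   association with one of the two studied diseases; criterion 10 with a
   disease from a user-supplied comorbid-disease whitelist.  Criteria 9 and
   10 draw from the criterion-8-filtered SNP set, reading "present in list
   Y" literally.  Everything else falls to rank `N`, the candidate-list
   size — deliberately heavy, which up-weights polymorphism evidence in the
   final average.  `N` generalizes the published fallback constant, which
   was simply that study's list length.  Disease-name matching is
   case-insensitive exact string match; synonym resolution is out of scope.

**Aggregation.**  Score-based criteria use fractional (average) ranks for
ties, so each complete column sums to `N(N+1)/2`; this conservation law is
exercised by the tests.  Genes missing a score get rank `N`.  The final
priority is the arithmetic mean of the ten ranks, sorted ascending with
alphabetical tie-break.

## Statistical components

* **Over-representation**: one-sided hypergeometric upper tail
  `P(X ≥ k)` with the annotation file's gene universe as background
  (self-contained and overridable; no whole-genome background is assumed),
  BH-FDR across tested processes, enriched at `q < 0.01`.  An optional
  EASE-style offset (subtracting successes before taking the tail) is
  available but defaults to 0, the plain test.  Processes with zero query
  overlap are not tested.
* **BH-FDR** is the standard step-up adjustment (monotone, clipped at 1,
  order-preserving); implemented over `statsmodels.stats.multitest` and
  cross-checked in the tests against a longhand step-up computation.
* **Welch test**: `scipy.stats.ttest_ind(equal_var=False)` with the
  Welch–Satterthwaite degrees of freedom; cross-checked against the
  longhand formulas to 1e-9.
* **Centralities** are delegated to networkx and cross-checked against an
  independent BFS path-counting oracle on random graphs (N ≤ 30, 1e-9).
* **Cross-talk specificity** `CTS = K_i/M_i` (links in the analyzed network
  over links in the global network) and hub detection (`BC ≥ 0.005`,
  `CC ≥ 0.2` inclusive, degree `> 40` strict, mirroring the printed
  cutoffs) are exposed as standalone utilities.

## Tunable parameters

| key | default | meaning |
|-----|---------|---------|
| `enrichment.alpha` | 0.01 | FDR threshold for "enriched" |
| `enrichment.ease_offset` | 0 | conservative EASE offset on the tail |
| `specificity.alpha` | 0.05 | FDR threshold for the "specific" flag |
| `snp.tissue` | `brain` | eQTL tissue required to qualify |
| `snp.maf_min` | 0.05 | minor-allele-frequency cutoff (inclusive) |
| `hub.bc_min`, `hub.cc_min`, `hub.degree_gt` | 0.005, 0.2, 40 | hub cutoffs |
| regulatory type set | all but associative, protein–protein | regulatory-subnetwork filter |

## Synthetic studies

`synthetic_data.generate_study` emulates the database extracts the pipeline
normally ingests, with one pseudo-random stream per artifact (split by
artifact name from a single seed, so adding an artifact never perturbs the
others; identical config ⇒ byte-identical bundle).  Defaults: 200 genes,
25% disease overlap (so ~50 candidates), 5 planted drivers, 100 GO
processes of which 8 are linked to both diseases, background annotation
rate 0.05, edge density 0.08, ~2 SNPs per gene.  Per-type edge proportions
follow a literature-extracted disease network's breakdown (associative
edges dominate) — cosmetic realism only.

Drivers are planted with every signature the criteria reward, each scaled
by a single `driver_signal` in [0, 1]: extra edges into the shared gene set
(drawn from a regulation-tilted type mix so the signal reaches the
regulatory network), annotation probability on disease-shared processes
raised from 0.05 toward 0.95 (other shared genes get a smaller boost so
those processes come out enriched), a guaranteed brain-eQTL,
common-minor-allele, disease-associated SNP with probability
`driver_signal`, and additively/multiplicatively better external scores.
At `driver_signal = 0` every planted effect vanishes and drivers are
exchangeable with the other shared genes, which is what makes the null
calibration check meaningful.

What passing synthetic tests does **not** show: real extracts have
scale-free degree structure, ontology DAG redundancy, LD between SNPs and
correlated external scores, none of which are modelled; recovery numbers
on this generator therefore bound sanity, not field performance.

## Numerical and design choices

* Duplicate identical edges collapse at parse time; parallel edges of
  different types are kept.  Self-loops are dropped from the entity graph.
* Centralities require ≥ 2 entities; the pipeline degrades the regulatory
  criterion to an all-zero (all-tie) column when the regulatory network is
  smaller, rather than aborting a run whose other nine criteria are fine.
* An empty disease intersection aborts with an explicit "no shared genes"
  failure; an empty test set for criterion 7 aborts because the criterion
  is undefined.
* Problem sizes in the test suite and acceptance script (random graphs
  N ≤ 30 for the centrality oracle, exhaustive hypergeometric enumeration
  N ≤ 12, 20 seeds per signal level and 50 null seeds at 200 genes) were
  chosen to make the checks exact or tightly concentrated while keeping a
  full run in the tens of seconds.
* The two published node-accounting figures (213 combined genes/proteins
  vs. 231 genes + 353 proteins for the complete network) describe different
  countables — merged entities vs. class-distinct nodes; the package
  exposes both views (`entities()` vs. node-class counts) and does not
  reconcile them.

## Known limitations

No GO graph propagation (annotations are taken as given), no directed or
weighted centralities, no LD pruning or eQTL effect sizes, no synonym
resolution for disease names, and no attempt to reproduce any published
per-gene rank table — those depend on proprietary 2021 database snapshots.
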