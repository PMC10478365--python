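# comorbid-rank

Multi-criteria prioritization of candidate genes for disease **comorbidity**
— the co-occurrence of two disorders (the motivating case is ADHD and
developmental dyslexia) in the same patients above chance.

Given a global typed gene/protein association network and per-disease
gene-association tables, the package builds the **complete comorbidity
network** — the subgraph induced on genes associated with *both* diseases —
and its **regulatory subnetwork** (regulation-type edges only), scores every
shared gene under ten criteria, and aggregates the per-criterion ranks by
arithmetic mean into a final priority table: the lower the average rank, the
stronger the candidate.

The ten criteria, for gene *i* over a candidate list of size *N*:

| # | Evidence | Rank rule |
|---|----------|-----------|
| 1–3 | external prioritizer scores (relevance score ↑, p-value ↓, average score ↑) | `Rank(X_i)` over the sorted score list |
| 4 | participation in enriched GO biological processes | descending `N_i = N1_i + N2_i` (counts over the complete and regulatory networks) |
| 5–6 | network centrality in the complete / regulatory network | descending mean of DC, BC, CC |
| 7 | specificity for disease-shared GO processes | ascending FDR-adjusted Welch-test p among positively shifted genes |
| 8–10 | qualifying SNPs (brain eQTL, MAF ≥ 5%); disease-associated; comorbid-disease-associated | 1 if evidence present, else `N` |

Centralities are computed on the entity-level simple graph: degree centrality
`DC = k_n/(N−1)`, betweenness `BC = Σ_{s≠n≠t} σ_st(n)/σ_st` normalized by
`(N−1)(N−2)/2`, and the neighbour-pair clustering form
`CC = 2e_n/(k_n(k_n−1))`.  All three lie in `[0, 1]`.  Hub detection
(`BC ≥ 0.005`, `CC ≥ 0.2`, degree `> 40`), cross-talk specificity
(`CTS = K_i/M_i`), hypergeometric GO over-representation with
Benjamini–Hochberg FDR, and a self-contained synthetic-study generator with
planted driver genes are included.

## Worked example

Generate a synthetic study (200 genes, 25% disease overlap, 5 planted
drivers at signal 0.9) and run the full pipeline:

```bash
comorbid-rank synth --out study --seed 7 --n-genes 200 --overlap 0.25 \
    --drivers 5 --signal 0.9
```

then point a config at the bundle and run it (or call
`comorbid_rank.run_pipeline` directly, as in `tests/test_pipeline.py`).  The
top of `priority_report.tsv` for seed 7:

```
gene      rank1 rank2 rank3 rank4 rank5 rank6 rank7 rank8 rank9 rank10  average_rank
GENE0145  1.0   6.0   2.0   2.0   2.0   6.0   1.5   1.0   1.0   1.0     2.35
GENE0074  4.0   1.0   3.0   4.0   5.0   2.0   4.0   1.0   1.0   1.0     2.60
GENE0102  2.0   9.0   5.0   1.0   7.0   3.0   1.5   1.0   1.0   1.0     3.15
GENE0050  5.0   8.0   1.0   4.0   3.0   4.0   4.0   1.0   1.0   1.0     3.20
GENE0154  3.0   10.0  4.0   4.0   1.0   5.0   4.0   1.0   1.0   1.0     3.40
```

The candidate list holds the 50 genes shared by both synthetic diseases;
each row shows the ten per-criterion ranks and their mean.  The five planted
drivers (`GENE0050`, `GENE0074`, `GENE0102`, `GENE0145`, `GENE0154`) occupy
exactly the top five rows — rank 1 on the binary SNP criteria 8–10 and
near-top ranks elsewhere — giving a top-20 driver recovery of 1.0.

Every stage also writes its intermediate table (network summaries,
enrichment results, centralities, specificity scores, per-criterion SNP
ranks, the full rank matrix) plus a `manifest.json` with thresholds and
input digests.

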