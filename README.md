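# mirgrn

Integrative network analysis of microRNA–target data with gene regulatory
networks (GRNs).

MicroRNAs (miRNAs) are small non-coding RNAs that regulate gene expression
post-transcriptionally, and their role is best understood in the context of
the networks their target genes live in — co-expression, physical
protein–protein interaction, genetic interaction, co-localization, pathway
and shared-protein-domain associations. `mirgrn` builds **heterogeneous
miRNA–gene–gene networks** by overlaying directed miRNA→gene targeting
edges onto an undirected gene–gene association graph, and then analyzes
them: biomarker-driven subnetwork selection, community detection by
modularity maximization, and degree-centrality hub analysis. Everything
runs offline from local tab-separated tables; a synthetic-data module
generates realistic inputs (scale-free and planted-partition networks,
multi-source target tables with controlled overlap) for testing and
benchmarking.

Intended users: computational biologists who have gene/protein interaction
dumps, miRNA–target tables from validated and predicted databases, and
differentially-expressed-gene (DEG) lists, and who want reproducible,
scriptable integration of the three.

## The core rules and statistics

- **Consensus aggregation.** Validated miRNA–target databases are
  *unioned*; predicted databases require *consensus*: a (miRNA, gene) pair
  is kept only if reported by ≥ 2 distinct predicted sources. With sources
  reporting each true pair independently with probability *p*, the expected
  retention is the binomial tail `P(Bin(n, p) ≥ 2)` — a closed form the test
  suite checks empirically.
- **Heterogeneous degree.** Each node gets one degree: a miRNA's degree is
  its number of distinct target genes; a gene's degree counts gene–gene
  neighbours plus regulating miRNAs.
- **Community detection.** Newman–Girvan modularity
  `Q = Σ_c [L_c/m − (d_c/2m)²]` is maximized by Clauset–Newman–Moore greedy
  agglomeration (`fast_greedy`, default) or Louvain; every partition reports
  its recomputed modularity.
- **Hub coupling.** Proteins are ranked by degree and cut into consecutive
  clusters of 50; the Pearson correlation between cluster mean protein
  degree and the mean degree of the regulating miRNAs quantifies whether
  hub miRNAs preferentially regulate hub proteins.

## Worked example

A curated fixture ships with the package: twelve validated interactions
between seven miRNAs and eight hub proteins of the human physical-
interaction network. Running `python examples/03_hub_centrality.py` prints:

```
fixture: 7 miRNAs target 8 hub proteins; MYC is regulated by 4 miRNAs
     mirna  mirna_degree hub_targets hub_target_degrees
 miR-17-5p             3     MYC;APP                4;1
  miR-146a             2       BRCA1                  1
miR-30a-3p             2       EP300                  2

hub-coupled simulation (alpha=1): Pearson r = 0.672 across 10 clusters of 50 proteins
```

The first block is the fixture itself: MYC is the most-regulated hub (four
distinct miRNAs, among them miR-17-5p, let-7a and miR-145), and miR-17-5p
is the top miRNA with three hub targets. The second block is parameter
recovery on synthetic data: with hub-coupling strength α = 1 the
cluster-level correlation between protein centrality and regulator-miRNA
centrality is strongly positive, while α = 0 (uniform targeting) gives
r ≈ 0. The other scripts in `examples/` walk through enrichment and
consensus (`01`), DEG subnetworks and communities (`02`), and biomarker
selections (`04`).

There is also a CLI mirroring the library
(`mirgrn simulate | convert | harmonize | enrich | select | communities |
centrality | summarize | run`); `mirgrn run --config pipeline.yaml` chains
the stages and writes a JSON run report with all seeds.

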