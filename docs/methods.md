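# Methods

## Data model

A `GeneNetwork` is an undirected simple graph over gene/protein symbols
with an optional non-negative weight per edge and a `network_type` tag
(one of coexpression, physical, genetic, colocalization, pathway,
shared_protein_domain, predicted). A `MirnaGRN` overlays directed
miRNA→gene targeting edges onto such a graph. Three invariants are
enforced on every construction: the miRNA and gene namespaces are
disjoint (a symbol used as both is rejected), every miRNA keeps at least
one target edge (operations that strand a miRNA drop it with a log line),
and gene–gene edges form a simple graph (no self-loops, parallel edges
collapsed keeping the maximum weight). Genes appearing only as targets
are auto-registered as gene nodes. Internally both containers wrap a
`networkx.Graph` with `node_class`/`edge_class` attributes; miRNA→gene
direction is implied by the node classes, which is enough because every
analysis here treats the overlay as undirected.

**Degree.** Each node has one degree: a miRNA's degree is its number of
distinct target genes; a gene's degree counts gene–gene neighbours plus
regulating miRNAs. Counting regulators toward a gene's degree was a
genuinely open choice; we include them so that the heterogeneous degree
is exactly the simple-graph degree of the overlay, and document it here
rather than offering a switch.

## Identifier harmonization

Interaction dumps mix Ensembl gene IDs (`ENSG` + digits) with symbols.
`map_ensembl_to_symbol` substitutes symbols through a many-to-one ID map
and drops (with a report, never an exception) any edge with an unmapped
Ensembl node; many-to-one maps can create parallel edges, which the
subsequent graph construction collapses. miRNA ids are normalized by
stripping a three-letter species prefix and canonicalizing the family
token to `miR`/`let`, keeping member/arm tokens (`-3p`, `-5p`, letter
variants) verbatim; the function is idempotent. Arm variants are *not*
merged (miR-29a and miR-29a-3p stay distinct): inferring database-version
equivalences is out of scope. Gene symbols are compared case-sensitively.

## Consensus aggregation of target tables

Validated databases are unioned: any experimentally supported
(miRNA, gene) pair is kept. Predicted databases require consensus: a pair
survives only if reported by at least two *distinct* source tags (record
multiplicity within one source does not count), applied across whatever
tables are passed. The union reading for validated sources is deliberate —
it is the natural contrast to the explicit "at least two" rule for
predictions, where false positives are the concern. Both operations retain
full provenance (one record per (mirna, gene, source) triple), so the
supporting databases of any pair remain queryable. Consequences asserted
as properties: consensus ⊆ union, and adding a source never removes a
retained pair.

## Enrichment, DEG subnetworks, selections

`enrich_network` adds miRNA→gene edges only for genes present in the
network. Two modes mirror the two integration styles: the complete
network keeps the full gene layer; the miRNA-only network keeps just
targeted genes and the gene–gene edges among them. `deg_subnetwork` keeps
genes that are DEGs *and* have at least one gene–gene edge to another DEG
— a DEG connected only to non-DEGs is dropped — then re-attaches miRNA
edges to the survivors; the operation is idempotent.

Selections around a biomarker-of-interest (BI) set: `only` keeps edges
with both endpoints BIs, `any` keeps edges touching a BI (node sets are
the retained endpoints), and `indirect` takes the induced subgraph on all
nodes within undirected distance ≤ 2 of a BI. "Indirect" has no standard
definition; two hops is the default and is exposed as `max_dist`.
Induced-subgraph (rather than BFS-tree) semantics were chosen so the
result is a well-formed network. The degree filter uses a strict `>`
against the cut-off. These yield the containment chain
only ⊆ any ⊆ indirect, asserted on random instances.

## Community detection

The overlay is clustered as one undirected, unweighted graph (weights are
ignored by default; no weighting scheme is imposed on mixed edge
classes). Default method is Clauset–Newman–Moore greedy modularity
agglomeration (`fast_greedy`), with Louvain as the alternative; both come
from networkx, and seeds are explicit parameters, never global state.
Partitions are repackaged with community ids 1..k ordered by decreasing
size (ties by smallest member id), so "the largest community" is id 1 and
extraction is deterministic. The reported modularity is the Newman–Girvan
score recomputed in-package from the assignment; tests compare it to
networkx's and igraph's independent implementations at 1e-9. An edgeless
graph gets singleton communities and modularity 0 by convention. On the
eight-node two-clique benchmark the greedy result attains the exhaustive
optimum over all 4140 partitions (Q = 0.4231).

## Centrality clusters and the hub-coupling correlation

Proteins are sorted by decreasing degree (ties broken lexicographically
by id for determinism) and cut into consecutive blocks of `cluster_size`
(default 50, the convention for this analysis; the last block may be
smaller). For the correlation, protein degrees come from the *gene-gene*
network (pass the full association network as `gene_net` when the
enriched network is a restriction of it) and miRNA degrees are
distinct-target counts in the enriched network. Per cluster, each
regulated protein contributes the mean degree of its regulators; the
cluster averages those contributions; Pearson's r is computed across
clusters containing at least one regulated protein, and is refused
(rather than returned as NaN) with fewer than two usable clusters or zero
variance. The exact quantity summarized per cluster is a design choice —
the per-cluster table is exposed so alternative summaries (e.g. counts of
proteins regulated by top-degree miRNAs) can be derived from it. The
top-miRNA table ranks miRNAs by degree and lists each one's targets
inside cluster 1; when no external gene network is given it ranks
proteins on their combined overlay degree, which is what makes the
miRNA-only fixture analyzable.

## Synthetic data

Generators are pure functions of a frozen `GeneratorConfig` (seed
included); identical configs give bit-identical output.

- **Gene networks:** Barabási–Albert preferential attachment (default,
  m = 2 — centrality analyses need degree heterogeneity and protein
  networks are heavy-tailed), planted-partition (4 blocks × 25 nodes,
  p_in = 0.3, p_out = 0.01 as the community-recovery benchmark), and
  Erdős–Rényi. Planted block labels travel as node attributes.
- **Multi-source target tables:** a ground-truth set of 200 (miRNA, gene)
  pairs is drawn; each of 4 sources reports each true pair independently
  with probability 0.6. This design gives the ≥2-consensus rule the
  closed-form expected retention `P(Bin(4, 0.6) ≥ 2) = 0.8208`, checked
  within 3 standard errors over 50 seeds. Sources are pure subsets of the
  truth: source-specific false positives are *not* modelled, so these
  tests quantify the rule's recall, not its precision on real databases.
- **Hub-coupled targeting:** each of 50 miRNAs draws a target count k
  log-uniformly in [1, 30] and samples k distinct genes from a 500-node
  scale-free network with probability ∝ degree^(α·k/k_max). Scaling the
  exponent by the miRNA's own relative connectivity is what couples
  *miRNA* hubness to *gene* hubness: at α = 0 every miRNA targets
  uniformly (mean r ≈ 0.08 over 20 seeds), while at α = 1 the
  high-degree miRNAs concentrate on network hubs (mean r ≈ 0.64), and
  the mean correlation is monotone in α over {0, 0.5, 1, 2}. A fixed
  per-event exponent would *not* produce this coupling — the probability
  that a given miRNA regulates a given gene would factorize — so the
  coupling strength is deliberately a property of each miRNA.
- **Curated fixture:** twelve validated miRNA→protein pairs among
  high-centrality hubs of the human physical-interaction network (seven
  miRNAs, eight proteins; MYC regulated by four miRNAs), used as the
  worked example throughout.

What the generators do not emulate: real GeneMANIA weight distributions,
miRBase naming in full, database-specific false-positive structure, and
correlated errors between predicted sources. Passing tests therefore
demonstrate the correctness of the rules and estimators under the stated
models, not performance on any particular database release.

## Numerical and degenerate-input choices

Weights are carried through I/O (round-trips preserve them exactly via
shortest-repr formatting) but no analysis consumes them by default.
Empty inputs warn and return empty results where a scientist would expect
a degenerate answer (empty DEG list, empty enrichment intersection) and
raise where the quantity is undefined (community detection on an empty
graph, correlation with < 2 usable clusters). Pearson's r uses
scipy.stats and is tested against the two-pass textbook formula at 1e-12.
Malformed table rows (missing node fields) are skipped and counted, with
a `strict` flag upgrading them to errors; non-numeric weights are always
errors naming the line.

## Scope and limitations

Live database/web queries, TCGA downloads and the differential-expression
test itself are out of scope: interaction tables, target tables,
annotation tables and DEG lists are file inputs (a pluggable fetcher
could be layered on the same readers). Visualization is limited to
GraphML/TSV exports that any graph viewer loads. Organisms are a string
tag; no cross-species mapping. No overlapping communities, no consensus
clustering, no weighted or betweenness/eigenvector centrality. Problem
sizes in the test and acceptance runs (500-gene networks, 20–50 seeds)
were chosen as the smallest scales at which the distributional checks are
stable.
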