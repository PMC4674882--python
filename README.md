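# pathfun

Functional annotation of experimentally defined pathways, and analysis of
the functional network they form.

## The problem

Molecular function is usually mapped with protein–protein interaction
networks, where a multifunctional protein collapses into a single highly
connected node and topological clustering can glue together functions
that never co-occur in the cell. `pathfun` takes the opposite starting
point: *pathways* — curated gene sets validated under specific
experimental conditions — are the units of function, so a gene acting in
several contexts appears in each of its pathways independently. The
package is for systems biologists who want pathway-level functional
annotation, a pathway–pathway functional network, and quantitative reads
on gene pleiotropy and multifunctionality, from five standard inputs:

- a pathway collection (GMT or ConsensusPathDB-style tab file),
- an ontology (OBO 1.2),
- gene annotations (GAF 2.x),
- a symmetric term–term semantic distance table (TSV),
- genetic interactions (2-column TSV or BioGRID-style tab).

## The method

After consolidating the pathway collection (merging duplicate names,
dropping undersized records, collapsing identical gene sets, resolving
subset pairs toward the median size) and building evidence-filtered,
ancestor-closed gene annotations, the core computation per pathway *P*
is:

1. **Enrichment profile** — every term *t* with one-sided Fisher
   p < 0.01 over the instance table
   (genes of *P* carrying *t*; other instances in *P*; instances of *t*
   outside; other instances outside). The uncorrected p-value is the
   term's *enrichment score*.
2. **Functional profile** — discard single-gene terms, then scan by
   ascending score and keep each term that represents at least one
   unrepresented gene (a minimal-cover heuristic).
3. **Pleiotropy** — append any enriched term with score < 5·10⁻⁴ whose
   semantic distance to *every* profile term exceeds 11.2: evidence of
   an independent second function.

Pathways then become nodes of an undirected network with edge weight

    w(A,B) = J(A,B) + W(A,B),
    J(A,B) = |A∩B| / |A∪B|,
    W(A,B) = [ Σ_{a∈A,b∈B, a≠b, d(a,b)<T} (T − d(a,b))/T ] / (|A|·|B| − |A∩B|),

with T = 0.8, where A, B are the profiles' term sets and d is the
semantic distance. The network is clustered by greedy cohesiveness
growth (weighted density ≥ 0.25, ≥ 3 nodes, overlapping clusters
merged), and analysed for betweenness centrality, the power-law degree
exponent γ, genetic-interaction enrichment against seeded randomised
pair redraws, gene multifunctionality, and a UPGMA functional tree with
a gene-overlap matrix.

## Worked example

No external database snapshots are required: the package generates a
complete synthetic input universe with planted structure.

```
pfn simulate --seed 1 --out demo/inputs
pfn init-config --out demo/config.yaml   # then point the five paths at demo/inputs
pfn run --config demo/config.yaml --out demo/run
```

or equivalently in Python:

```python
from pathfun import FixtureSpec, RunConfig, generate, run_pipeline

bundle = generate(FixtureSpec(seed=1), "demo/inputs")
cfg = RunConfig(
    pathways=str(bundle.gmt), obo=str(bundle.obo), gaf=str(bundle.gaf),
    distances=str(bundle.distances), interactions=str(bundle.gis), seed=1,
)
result = run_pipeline(cfg, "demo/run")
```

The run directory contains every intermediate (consolidation stage log,
consolidated GMT, enrichment and functional profile TSVs, edge list,
GraphML, clusters, newick tree, overlap matrix) plus `summary.json`.
With seed 1 the summary reads, in part:

```
n_pathways = 23            # of 24 planted, after consolidation
n_genes = 98
n_profiles = 15            # pathways with a non-empty functional profile
median_terms_per_profile = 1.0
pct_single_term_profiles = 66.7
n_pleiotropic_terms_added = 2     # both planted pleiotropic terms recovered
n_edges = 13
shared_term_edge_fraction = 0.62  # rest are semantic-similarity links
n_clusters = 1
distribution_classes = {overlapping: 3, pleiotropic: 2, single: 10}
gi_enrichment_factors = {within_pathway: 1.98, within_cluster: 2.62}
```

and the first stage-log rows mirror the consolidation table:

```
stage                     pathways  unique_genes  median_size  mean_size  sd_size
original                  34        107           4.0          6.03       4.92
duplicate_names_merged    33        107           4.0          6.18       4.95
small_pathways_removed    31        107           5.0          6.48       4.96
```

Reading the numbers: 34 raw records consolidate to 23 pathways; most
profiles need a single term (the planted modules are functionally
tight); the two pathways carrying a planted remote function gain exactly
their planted pleiotropic annotation; and genetic interactions planted
within modules come out enriched within the recovered cluster
(factor 2.62) relative to 100 seeded random redraws.

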