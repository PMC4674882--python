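# Methods

## Overview

`pathfun` annotates experimentally defined pathways — curated gene sets,
not topological modules of an interaction graph — with compact functional
profiles drawn from an ontology, and links the annotated pathways into a
weighted functional network. The chain is:

1. **Consolidation.** Raw pathway collections aggregated from several
   source databases are redundant. Same-named records are merged (union
   of gene sets), records with fewer than `min_pathway_size` (default 3)
   genes are dropped, identical gene sets are collapsed to one
   representative, and proper-subset pairs are resolved by keeping the
   member whose size is closer to the median pathway size. Genes with no
   accepted functional annotation are then removed and the size floor
   re-applied. Every stage logs (pathway count, unique genes,
   median/mean/sd of size).
2. **Annotation.** Ontology terms reach genes through association rows
   filtered by evidence code (default: experimental codes EXP, IDA, IPI,
   IMP, IGI, IEP plus sequence-orthology codes ISS, ISA, ISO, ISM),
   aspect (biological process) and NOT-qualifiers. Each gene's term set
   is closed upward over `is_a`/`part_of`; terms annotating more than
   `max_term_frequency` (default 50%) of the analysed genes are removed
   as uninformative.
3. **Enrichment.** Per pathway, every term carried by at least one
   member gene is scored with a one-sided Fisher's exact test over
   annotation *instances* ((gene, term) pairs after closure): cells are
   the genes in the pathway carrying the term, the other instances
   inside the pathway, the term's instances outside, and all other
   instances outside. Scores below `alpha` (default 0.01) form the
   enrichment profile. No multiple-testing correction is applied — the
   subsequent cover step is the false-positive filter.
4. **Functional profiles.** Terms supported by a single gene are
   discarded; remaining terms are scanned in ascending score order and
   greedily selected whenever they represent at least one unrepresented
   gene (a score-first set cover). A second pass appends *pleiotropic*
   terms: enriched terms with score below `pleiotropy_alpha` (default
   5e-4) whose semantic distance to every term already in the profile
   exceeds `pleiotropy_threshold` (default 11.2).
5. **Network.** Pathway pairs are weighted by the Jaccard similarity J
   of their profile term sets plus a semantic component W: over ordered
   cross-profile term pairs excluding identical terms, pairs with
   distance d < T (default 0.8) contribute (T−d)/T, summed and divided
   by |A|·|B|−|A∩B|. Edges exist where J+W > 0. Overlapping clusters
   are grown greedily by cohesiveness w_in/(w_in+w_boundary)
   (ClusterONE-style), kept at weighted density ≥ 0.25 and size ≥ 3,
   and merged above an overlap score of 0.8.
6. **Downstream.** Genetic interactions are classified over all pathway
   combinations of their two genes (within-pathway / within-cluster /
   uncharacterised) and compared against seeded uniform redraws of the
   same number of gene pairs; genes in several pathways are summarised
   by membership histograms and cross-profile semantic divergence; a
   UPGMA tree over mean cross-profile distances accompanies a gene
   overlap-coefficient matrix.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_pathway_size` | 3 | genes required for a statistically usable pathway |
| `alpha` | 0.01 | enrichment-score ceiling for profile entry (uncorrected, strict `<`) |
| `pleiotropy_alpha` | 5e-4 | score ceiling for pleiotropic candidates |
| `pleiotropy_threshold` | 11.2 | semantic distance a candidate must exceed to every profile term; `auto` recomputes the 95th percentile of pooled within-profile distances |
| `similarity_threshold` T | 0.8 | distance below which two distinct terms count as near-identical |
| `max_term_frequency` | 0.5 | gene fraction above which a term is uninformative |
| `density_threshold` | 0.25 | weighted density floor for clusters |
| `gi_replicates` | 100 | randomised GI redraws |

All distances are consumed from a precomputed symmetric term–term table;
the package never derives semantic distances from a real ontology.

## Numerical and design choices

- **Instance-based contingency tables.** The enrichment table mixes a
  gene count (n11) with instance counts in the other cells, implemented
  verbatim; `table="genes"` offers the conventional gene-count 2×2 as a
  sanity alternative. With one instance per (gene, term) pair the
  outside-term cell coincides under both readings.
- **Strictness.** "Enriched at 0.01" is strict `<`; "over 50%" is
  strict `>`; "distance greater than the threshold" is strict `>`.
- **Subset resolution.** The median is computed once at stage entry and
  held fixed during the removal fixpoint; pairs are examined in
  id-sorted order; equidistant ties remove the larger pathway.
  Retention among identical gene sets is by lexicographic (name, id).
  These tie rules make consolidation deterministic and order-invariant.
- **Percentile convention.** The pleiotropy threshold quoted as "95% of
  pairs above" alongside a median of 6 is internally inconsistent; the
  package computes the 95th percentile of the pooled within-profile
  distance distribution (95% *below*, linear interpolation). Callers
  preferring the fixed published value pass 11.2 explicitly (the
  default).
- **Missing distances** disqualify a pleiotropic candidate (skipped and
  counted) and contribute zero to semantic edge weights — conservative
  on both sides, never a silent zero or infinity.
- **Edge-weight combination.** J and W are added: the semantic sum
  explicitly excludes identical shared terms, so the two are disjoint
  evidence. `combine="max"` is available.
- **Degree exponent** γ is the negated least-squares slope of
  log(count) on log(degree) over the empirical histogram (empty bins and
  degree-0 nodes dropped) — the period-typical estimate; a
  maximum-likelihood fit would differ and is deliberately not the
  default.
- **Betweenness** defaults to unweighted; the weighted mode uses edge
  length 1/weight.
- **Clustering determinism.** Seeds are taken in descending
  weighted-degree order with id tie-breaks; growth moves are evaluated
  in sorted node order; merging uses the match coefficient
  |A∩B|²/(|A||B|). The density/size filter is re-applied after merging
  so every returned cluster honours its bound.
- **UPGMA** is scipy average linkage; node heights are half the merge
  distance (two leaves at distance 4 join at height 2), giving an
  ultrametric tree serialised as newick.
- **GI classification denominator** is the total number of pathway-pair
  classifications (every combination classified separately, shared
  pathways once each); a per-GI best-classification mode is not the
  default because multi-pathway genes are the object of study.
- **Gene divergence denominator.** The normalized cross-profile
  distance divides the summed term-pair distances by the size of the
  union of the profiles' terms (`terms-union`, default) or by the
  number of summed pairs (`per-pair`). A third reading — dividing by
  the union of the pathways' *genes* — is arguable from the method's
  prose but not implemented as a mode.
- Floating-point summary statistics (median/mean/sd of pathway sizes,
  sample sd with ddof=1) are computed over *sorted* size arrays so they
  are bitwise-reproducible regardless of record order.

## The synthetic data generator

Real inputs (a pathway compendium, an ontology release, an annotation
release, a distance table, an interaction database) are external
snapshots; the package instead validates every stage on generated
universes with planted truths (`pathfun.fixtures`):

- **Term DAG.** A root with `n_planted_modules` subtrees ("modules") of
  depth `dag_depth` and branching `dag_branching`, with one diamond
  (multi-parent) node per module and an obsolete decoy term. The toy
  semantic metric is the weighted undirected shortest-path length with
  depth-dependent edge lengths (3.2 below the root, ≈2.5 at internal
  levels, 0.35 at the leaf level). Consequences, by construction:
  sibling leaves are ~0.7 apart (below T=0.8, so semantic edges occur);
  within-module pairs top out near 10.7 (the 95th within-profile
  percentile lands near 11, keeping the 11.2 default meaningful);
  cross-module leaf pairs exceed 17 (always pleiotropy-eligible). The
  metric satisfies symmetry, zero self-distance and the triangle
  inequality exactly.
- **Genes and annotations** split evenly across modules; each gene is
  annotated to 1–3 module leaves under experimental evidence codes.
  Decoy rows (IEA-only genes — the planted unannotated set — plus NOT
  and wrong-aspect rows) exercise the filters.
- **Pathways** draw from module gene pools with log-normal sizes
  (median 5, σ=1.3: right-skewed, mean ≈ 2× median, as in curated
  compendia). Each base pathway carries one private gene, which makes
  accidental subset relations impossible and planted ones attributable.
  Name-duplicates (overlapping splits), gene-set duplicates and subset
  fragments are injected at per-class rates, with the consolidation
  outcome of every injection — including the per-stage summary
  statistics and the subset-resolution survivor under the median rule —
  precomputed into the manifest.
- **Planted pleiotropy.** Selected moderate-size pathways (6–14 genes)
  receive an exclusive within-module leaf on every gene (the expected
  cover) and an exclusive cross-module leaf on five genes (the expected
  pleiotropic addition). Host size is capped because a pathway's share
  of all annotation instances inflates the remote term's tail
  probability past the 5e-4 gate.
- **Genetic interactions** are sampled within modules at
  `gi_within_cluster_rate` (default 0.05) and across modules at a 10×
  lower background, with duplicate/reversed rows for the reader to
  collapse.

What the generator does *not* emulate: realistic term/gene nomenclature,
annotation depth heterogeneity across genes, evidence-code error
structure, and the long-range correlation structure of a real ontology.
Passing tests therefore demonstrate algorithmic correctness and planted-
signal recovery, not that real-compendium headline numbers are
reproduced — those depend on specific database snapshots.

## Test design notes

- The Fisher implementation is checked against exact integer-binomial
  pmf summation on every 2×2 table with grand total ≤ 60.
- Cover tests draw random *enrichment-profile* instances: supports are
  random gene subsets and scores are genuine hypergeometric tail
  probabilities thresholded at 0.01, matching the contract the cover
  step consumes (scores anti-correlated with support size). Against an
  exhaustive subset-search optimum, the greedy cover is held to the
  (1 + ln n) factor. Because selection is score-first rather than
  coverage-first, that factor is a strong empirical expectation on
  realistic instances, not a theorem; score-independent artificial
  instances can exceed it.
- UPGMA is verified against a brute-force agglomeration oracle on
  4-leaf matrices and for ultrametricity on 8-leaf matrices; GI
  enrichment recovery uses two planted clusters of ten pathways with
  within-cluster interactions at 10× background, where the
  within-cluster factor must exceed 2 while a uniform null stays in
  [0.5, 2].
- Problem sizes throughout (24-pathway bundles, 120 genes, ≤60-total
  exhaustive sweeps, 100–200 seeded instances) are chosen so the whole
  suite runs in well under a minute while every oracle remains
  exhaustive at its scale.

## Known limitations

- Gene symbols are matched as exact strings; no alias resolution or
  cross-database identifier mapping.
- Pathway topology (reactions, internal edges) is out of scope; a
  pathway is a set.
- Semantic distances are an input; coverage gaps in the table propagate
  as skipped comparisons, logged but not imputed.
- The degree-exponent estimate is a log–log least-squares slope and
  inherits that estimator's small-sample bias.
- GI types (positive/negative/synthetic-lethal) are pooled.
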