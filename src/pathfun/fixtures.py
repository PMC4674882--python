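"""Synthetic input universes with planted structure.

Real runs of this package consume five external resources: an ontology
(OBO), gene annotations (GAF), a term-term semantic distance table,
a pathway collection (GMT/CPDB) and genetic interactions.  This module
generates all five from a seed, with *planted truths* recorded in a
manifest so every pipeline stage can be validated without downloads:

* a DAG of terms organised into functional modules (subtrees), with a toy
  semantic metric = weighted undirected shortest-path length.  Edge
  lengths are depth-dependent (3.2 at the root, ~2.5 at internal levels,
  0.35 at the leaf level) so that sibling leaves sit below the semantic
  similarity threshold of 0.8, within-module pairs stay below the
  pleiotropy threshold of 11.2 (the 95th within-profile percentile lands
  near 11), and cross-module pairs exceed it;
* genes assigned to modules and annotated to module leaf terms under
  experimental evidence codes (decoy IEA / NOT / wrong-aspect rows
  included — genes given only decoy rows are the planted unannotated
  genes);
* pathways drawn from module gene pools with a log-normal size
  distribution (median ~5, heavy right tail, mimicking curated pathway
  databases), plus injected name-duplicates, gene-set duplicates, subset
  pathways and undersized pathways whose consolidation outcome the
  manifest pre-computes;
* planted pleiotropic pathways: one exclusive within-module term covering
  every pathway gene (the expected cover) and one semantically remote
  cross-module term on four of the genes (the expected pleiotropic
  addition);
* genetic interactions sampled within modules at one rate and across
  modules at a lower background rate.

Each base pathway carries one private gene found in no other pathway, so
no two planted base pathways can stand in a subset relation by accident.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = ["FixtureSpec", "FixtureBundle", "generate", "gi_enrichment_scenario"]

ROOT = "GO:0000001"
ROOT_EDGE = 3.2
LEAF_EDGE = 0.35


@dataclass
class FixtureSpec:
    """Parameters of a synthetic input universe.

    The defaults emulate the statistical shape of a curated yeast pathway
    compendium at desk scale: log-normal pathway sizes (median ~5, mean
    ~2x the median), a handful of functional modules, ~15% of raw records
    redundant per duplication class, and within-module genetic
    interactions an order of magnitude above background.
    """

    seed: int = 0
    n_genes: int = 120
    n_planted_modules: int = 3
    dag_depth: int = 3
    dag_branching: int = 2
    n_pathways: int = 24
    size_log_median: float = 5.0
    size_log_sigma: float = 1.3
    min_pathway_size: int = 3
    n_small_pathways: int = 2
    name_duplicate_rate: float = 0.15
    geneset_duplicate_rate: float = 0.15
    subset_duplicate_rate: float = 0.15
    unannotated_rate: float = 0.05
    pleiotropy_rate: float = 0.1
    gi_within_cluster_rate: float = 0.05
    gi_background_rate: float = 0.005

    def __post_init__(self) -> None:
        rates = (
            self.name_duplicate_rate,
            self.geneset_duplicate_rate,
            self.subset_duplicate_rate,
            self.unannotated_rate,
            self.pleiotropy_rate,
            self.gi_within_cluster_rate,
            self.gi_background_rate,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.min_pathway_size < 3:
            raise ValueError("planted pathways must have at least 3 genes")
        if self.dag_depth < 2 or self.dag_branching < 2:
            raise ValueError("DAG needs depth >= 2 and branching >= 2")
        if self.n_genes < self.n_planted_modules * 10:
            raise ValueError("need at least 10 genes per planted module")


@dataclass
class FixtureBundle:
    """Paths of a generated bundle plus its planted-truth manifest."""

    directory: Path
    obo: Path
    gaf: Path
    distances: Path
    gmt: Path
    gis: Path
    manifest: dict


def _stats_row(stage: str, gene_sets: list[frozenset]) -> dict:
    if not gene_sets:
        return {
            "stage": stage,
            "pathways": 0,
            "unique_genes": 0,
            "median_size": float("nan"),
            "mean_size": float("nan"),
            "sd_size": float("nan"),
        }
    sizes = np.sort(np.array([len(g) for g in gene_sets], dtype=float))
    return {
        "stage": stage,
        "pathways": len(gene_sets),
        "unique_genes": len(set().union(*gene_sets)),
        "median_size": float(np.median(sizes)),
        "mean_size": float(np.mean(sizes)),
        "sd_size": float(np.std(sizes, ddof=1)) if len(sizes) > 1 else float("nan"),
    }


def _build_dag(spec: FixtureSpec):
    """Module-structured term DAG with weighted edges (toy metric graph).

    Returns (metric graph, term->namespace-ordered dict of terms,
    module -> leaves, module -> all terms, extra diamond edges).
    """
    inner = 5.0 / (spec.dag_depth - 1)  # keeps within-module max ~10.7
    g = nx.Graph()
    g.add_node(ROOT)
    terms: dict[str, dict] = {ROOT: {"name": "biological_process", "parents": []}}
    module_leaves: dict[str, list[str]] = {}
    module_terms: dict[str, list[str]] = {}
    counter = 1

    def new_term(name: str) -> str:
        nonlocal counter
        counter += 1
        tid = f"GO:{counter:07d}"
        terms[tid] = {"name": name, "parents": []}
        return tid

    for m in range(spec.n_planted_modules):
        mod = new_term(f"module {m} process")
        terms[mod]["parents"].append((ROOT, "is_a"))
        g.add_edge(mod, ROOT, weight=ROOT_EDGE)
        module_terms[f"M{m}"] = [mod]
        level = [mod]
        for depth in range(1, spec.dag_depth + 1):
            weight = LEAF_EDGE if depth == spec.dag_depth else inner
            nxt = []
            for parent in level:
                for k in range(spec.dag_branching):
                    t = new_term(f"module {m} d{depth} {terms[parent]['name']}/{k}")
                    rel = "part_of" if (depth == 2 and k == 0) else "is_a"
                    terms[t]["parents"].append((parent, rel))
                    g.add_edge(t, parent, weight=weight)
                    nxt.append(t)
                    module_terms[f"M{m}"].append(t)
            level = nxt
        module_leaves[f"M{m}"] = level
        # one diamond: first leaf also descends from the second branch
        if len(level) > 1:
            first_leaf = level[0]
            branches = [
                t
                for t in module_terms[f"M{m}"]
                if any(p == mod for p, _ in terms[t]["parents"])
            ]
            if len(branches) > 1:
                alt = branches[1]
                terms[first_leaf]["parents"].append((alt, "is_a"))
                g.add_edge(first_leaf, alt, weight=inner + LEAF_EDGE)
    return g, terms, module_leaves, module_terms


def _write_obo(path: Path, terms: dict[str, dict]) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n\n")
        for tid in sorted(terms):
            info = terms[tid]
            fh.write("[Term]\n")
            fh.write(f"id: {tid}\nname: {info['name']}\n")
            fh.write("namespace: biological_process\n")
            for parent, rel in info["parents"]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {terms[parent]['name']}\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! {terms[parent]['name']}\n")
            fh.write("\n")
        # an obsolete term: must be excluded by the reader
        fh.write("[Term]\nid: GO:9999999\nname: defunct process\n")
        fh.write("namespace: biological_process\nis_obsolete: true\n\n")


def _write_distances(path: Path, g: nx.Graph) -> dict[tuple[str, str], float]:
    dists: dict[tuple[str, str], float] = {}
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    nodes = sorted(g.nodes)
    with open(path, "w") as fh:
        fh.write("#term_a\tterm_b\tdistance\n")
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                v = lengths[a][b]
                dists[(a, b)] = v
                fh.write(f"{a}\t{b}\t{v:.10g}\n")
    return dists


def generate(spec: FixtureSpec, out_dir) -> FixtureBundle:
    """Write a complete synthetic bundle into ``out_dir``.

    The same spec and seed always produce byte-identical files.  The
    returned manifest records module membership, planted duplicates and
    their expected consolidation outcomes (including per-stage summary
    statistics), planted pleiotropic terms and genetic-interaction counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    modules = [f"M{m}" for m in range(spec.n_planted_modules)]

    metric_graph, terms, module_leaves, module_terms = _build_dag(spec)

    # --- genes ------------------------------------------------------------
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    gene_module: dict[str, str] = {}
    pools: dict[str, list[str]] = {m: [] for m in modules}
    for i, g in enumerate(genes):
        m = modules[i % len(modules)]
        gene_module[g] = m
        pools[m].append(g)

    # --- base pathways ----------------------------------------------------
    per_mod = {m: [] for m in modules}
    private: dict[str, str] = {}
    shared = {m: list(pools[m]) for m in modules}
    names: list[str] = []
    base: dict[str, frozenset] = {}
    base_module: dict[str, str] = {}
    for i in range(spec.n_pathways):
        m = modules[i % len(modules)]
        name = f"{m} pathway {i:02d}"
        priv = shared[m].pop(0)
        private[name] = priv
        names.append(name)
        base_module[name] = m
    for i, name in enumerate(names):
        m = base_module[name]
        mu, sigma = np.log(spec.size_log_median), spec.size_log_sigma
        s = int(round(float(rng.lognormal(mu, sigma))))
        s = max(spec.min_pathway_size, min(s, len(shared[m]) + 1))
        extra = rng.choice(len(shared[m]), size=s - 1, replace=False)
        base[name] = frozenset([private[name]] + [shared[m][k] for k in sorted(extra)])
        per_mod[m].append(name)

    # --- planted pleiotropy -----------------------------------------------
    n_pleio = int(round(spec.pleiotropy_rate * spec.n_pathways))
    pleio_records = []
    pleio_names: list[str] = []
    # moderate-size hosts: large pathways dilute the planted remote term's
    # enrichment (its tail probability grows with the pathway's share of
    # all annotation instances)
    eligible = [n for n in names if 6 <= len(base[n]) <= 14]
    for k in range(min(n_pleio, len(eligible))):
        name = eligible[k]
        m = base_module[name]
        other = modules[(modules.index(m) + 1) % len(modules)]
        # exclusive cover term: a fresh leaf annotated to every pathway gene
        cover = f"GO:{8000001 + k:07d}"
        host = module_leaves[m][0]
        host_parent = terms[host]["parents"][0][0]
        terms[cover] = {"name": f"planted cover {k}", "parents": [(host_parent, "is_a")]}
        metric_graph.add_edge(cover, host_parent, weight=LEAF_EDGE)
        module_terms[m].append(cover)
        # remote term: fresh leaf in a different module on 4 of the genes
        remote = f"GO:{8100001 + k:07d}"
        rhost_parent = terms[module_leaves[other][0]]["parents"][0][0]
        terms[remote] = {
            "name": f"planted remote {k}",
            "parents": [(rhost_parent, "is_a")],
        }
        metric_graph.add_edge(remote, rhost_parent, weight=LEAF_EDGE)
        module_terms[other].append(remote)
        carriers = sorted(base[name])[:5]
        pleio_records.append(
            {
                "pathway": name,
                "cover_term": cover,
                "pleiotropic_term": remote,
                "carrier_genes": carriers,
            }
        )
        pleio_names.append(name)

    # --- annotations -------------------------------------------------------
    pleio_genes = {g for r in pleio_records for g in base[r["pathway"]]}
    candidates = [
        g for g in genes if g not in private.values() and g not in pleio_genes
    ]
    n_unann = int(round(spec.unannotated_rate * spec.n_genes))
    unannotated = set(
        rng.choice(candidates, size=min(n_unann, len(candidates)), replace=False)
    )
    assignments: dict[str, list[str]] = {}
    for g in genes:
        if g in unannotated:
            continue
        leaves = module_leaves[gene_module[g]]
        k = int(rng.integers(1, 4))
        pick = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False)
        assignments[g] = [leaves[i] for i in sorted(pick)]
    for rec in pleio_records:
        for g in base[rec["pathway"]]:
            assignments.setdefault(g, []).append(rec["cover_term"])
        for g in rec["carrier_genes"]:
            assignments[g].append(rec["pleiotropic_term"])

    gaf_rows: list[str] = []
    for g in sorted(assignments):
        for t in assignments[g]:
            ev = ["IDA", "IMP", "IGI", "ISS"][int(rng.integers(0, 4))]
            gaf_rows.append(
                f"SYN\t{g}\t{g}\t\t{t}\tPMID:1\t{ev}\t\tP\t{g}\t\tgene\ttaxon:4932\t20140101\tSYN"
            )
    for g in sorted(unannotated):  # decoy rows only: IEA evidence
        t = module_leaves[gene_module[g]][0]
        gaf_rows.append(
            f"SYN\t{g}\t{g}\t\t{t}\tPMID:1\tIEA\t\tP\t{g}\t\tgene\ttaxon:4932\t20140101\tSYN"
        )
    # decoys on annotated genes: NOT qualifier and wrong aspect
    g0 = sorted(assignments)[0]
    t0 = module_leaves[gene_module[g0]][-1]
    gaf_rows.append(
        f"SYN\t{g0}\t{g0}\tNOT|involved_in\t{t0}\tPMID:1\tIDA\t\tP\t{g0}\t\tgene\ttaxon:4932\t20140101\tSYN"
    )
    gaf_rows.append(
        f"SYN\t{g0}\t{g0}\t\t{t0}\tPMID:1\tIDA\t\tF\t{g0}\t\tgene\ttaxon:4932\t20140101\tSYN"
    )

    # --- duplications ------------------------------------------------------
    records: list[tuple[str, str, frozenset]] = []  # (name, source, genes)

    def bern(rate: float) -> bool:
        return bool(rng.random() < rate)

    name_dups, gs_dups, subsets = [], [], {}
    for name in names:
        gset = base[name]
        if len(gset) >= 6 and name not in pleio_names and bern(spec.name_duplicate_rate):
            ordered = sorted(gset)
            half = len(ordered) // 2 + 1
            a = frozenset(ordered[:half])
            b = frozenset(ordered[half - 1 :])  # overlap keeps the union exact
            records.append((name, "dbA", a))
            records.append((name, "dbB", b))
            name_dups.append(name)
        else:
            records.append((name, "dbA", gset))
        if bern(spec.geneset_duplicate_rate):
            records.append((f"{name} (alt)", "dbB", gset))
            gs_dups.append(name)
        if (
            len(gset) >= 5
            and name not in pleio_names
            and bern(spec.subset_duplicate_rate)
        ):
            k = int(rng.integers(3, len(gset)))
            others = [g for g in sorted(gset) if g != private[name]]
            pick = rng.choice(len(others), size=k - 1, replace=False)
            sub = frozenset([private[name]] + [others[i] for i in sorted(pick)])
            records.append((f"{name} fragment", "dbC", sub))
            subsets[name] = sub
    small_pool = sorted(set(genes) - set(private.values()))
    for i in range(spec.n_small_pathways):
        size = 1 + i % 2
        picked = small_pool[i * 2 : i * 2 + size]
        if picked:
            records.append((f"tiny pathway {i}", "dbA", frozenset(picked)))

    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    # --- expected consolidation outcomes -----------------------------------
    stage_sets = {}
    stage_sets["original"] = [g for _, _, g in records]
    after_merge = {name: base[name] for name in names}
    for name in gs_dups:
        after_merge[f"{name} (alt)"] = base[name]
    for name, sub in subsets.items():
        after_merge[f"{name} fragment"] = sub
    for n, s, g in records:
        if n.startswith("tiny pathway"):
            after_merge[n] = g
    stage_sets["duplicate_names_merged"] = list(after_merge.values())
    after_small = {
        n: g for n, g in after_merge.items() if len(g) >= spec.min_pathway_size
    }
    stage_sets["small_pathways_removed"] = list(after_small.values())
    after_dedupe = {n: g for n, g in after_small.items() if not n.endswith(" (alt)")}
    stage_sets["identical_gene_sets_removed"] = list(after_dedupe.values())
    entry_sizes = [len(g) for g in after_dedupe.values()]
    median = float(np.median(entry_sizes))
    after_subsets = dict(after_dedupe)
    subset_survivors = {}
    for name, sub in subsets.items():
        s_sup, s_sub = len(base[name]), len(sub)
        d_sup, d_sub = abs(s_sup - median), abs(s_sub - median)
        if d_sub > d_sup:
            loser = f"{name} fragment"
        elif d_sup > d_sub:
            loser = name
        else:  # equidistant: the larger pathway goes
            loser = name if s_sup > s_sub else f"{name} fragment"
        survivor = name if loser != name else f"{name} fragment"
        subset_survivors[name] = survivor
        del after_subsets[loser]
    stage_sets["pathway_subsets_removed"] = list(after_subsets.values())
    final = {}
    for n, g in after_subsets.items():
        g2 = frozenset(x for x in g if x not in unannotated)
        if len(g2) >= spec.min_pathway_size:
            final[n] = g2
    stage_sets["unannotated_genes_removed"] = list(final.values())
    expected_stats = [
        _stats_row(stage, stage_sets[stage])
        for stage in (
            "original",
            "duplicate_names_merged",
            "small_pathways_removed",
            "identical_gene_sets_removed",
            "pathway_subsets_removed",
            "unannotated_genes_removed",
        )
    ]

    # --- genetic interactions ----------------------------------------------
    within, background = [], []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if gene_module[a] == gene_module[b]:
                if bern(spec.gi_within_cluster_rate):
                    within.append((a, b))
            elif bern(spec.gi_background_rate):
                background.append((a, b))
    gi_rows = [f"{a}\t{b}" for a, b in within + background]
    if gi_rows:  # redundancy the reader must collapse
        a, b = (within + background)[0]
        gi_rows.append(f"{b}\t{a}")
    gi_order = rng.permutation(len(gi_rows))
    gi_rows = [gi_rows[i] for i in gi_order]

    # --- write files --------------------------------------------------------
    obo = out_dir / "ontology.obo"
    gaf = out_dir / "annotations.gaf"
    dist = out_dir / "distances.tsv"
    gmt = out_dir / "pathways.gmt"
    gis = out_dir / "interactions.tsv"
    _write_obo(obo, terms)
    with open(gaf, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        fh.write("\n".join(gaf_rows) + "\n")
    _write_distances(dist, metric_graph)
    with open(gmt, "w") as fh:
        for name, source, gset in records:
            fh.write(f"{name}\t{source}\t" + "\t".join(sorted(gset)) + "\n")
    with open(gis, "w") as fh:
        fh.write("#gene_a\tgene_b\n")
        fh.write("\n".join(gi_rows) + "\n")

    manifest = {
        "spec": asdict(spec),
        "modules": {
            m: {
                "genes": pools[m],
                "terms": sorted(module_terms[m]),
                "leaves": module_leaves[m],
                "pathways": per_mod[m],
            }
            for m in modules
        },
        "base_pathways": {n: sorted(base[n]) for n in names},
        "private_genes": private,
        "unannotated_genes": sorted(unannotated),
        "planted": {
            "name_duplicates": name_dups,
            "geneset_duplicates": gs_dups,
            "subsets": {n: sorted(s) for n, s in subsets.items()},
            "subset_survivors": subset_survivors,
            "subset_stage_median": median,
            "pleiotropy": pleio_records,
        },
        "expected": {
            "stage_stats": expected_stats,
            "final_pathways": {n: sorted(g) for n, g in final.items()},
        },
        "gis": {
            "n_within_module": len(within),
            "n_background": len(background),
            "n_rows_written": len(gi_rows),
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return FixtureBundle(out_dir, obo, gaf, dist, gmt, gis, manifest)


def gi_enrichment_scenario(
    seed: int,
    n_clusters: int = 2,
    pathways_per_cluster: int = 10,
    n_unclustered: int = 10,
    genes_per_pathway: int = 10,
    n_gis: int = 250,
    within_factor: float = 10.0,
):
    """Scaled genetic-interaction enrichment scenario with planted clusters.

    Builds a collection of disjoint pathways — ``n_clusters`` planted
    clusters of ``pathways_per_cluster`` pathways plus unclustered
    singletons — and draws ``n_gis`` gene pairs with same-cluster
    cross-pathway pairs weighted ``within_factor`` times the background.
    Returns (collection, clusters, planted GIs, uniform GIs).
    """
    from .pathways import Pathway, PathwayCollection
    from .network import ClusterSet
    from .downstream import GeneticInteraction

    rng = np.random.default_rng(seed)
    pathways = []
    cluster_sets: list[set[str]] = [set() for _ in range(n_clusters)]
    gene_of_pathway: dict[str, list[str]] = {}
    gidx = 0
    total_paths = n_clusters * pathways_per_cluster + n_unclustered
    for p in range(total_paths):
        pid = f"P{p:03d}"
        gs = [f"G{gidx + i:04d}" for i in range(genes_per_pathway)]
        gidx += genes_per_pathway
        pathways.append(Pathway(pid, f"pathway {p}", frozenset(gs)))
        gene_of_pathway[pid] = gs
        if p < n_clusters * pathways_per_cluster:
            cluster_sets[p // pathways_per_cluster].add(pid)
    collection = PathwayCollection(pathways)
    clusters = ClusterSet(cluster_sets, density_threshold=0.25)
    clusters.unclustered = {
        p.id for p in pathways if not any(p.id in c for c in cluster_sets)
    }

    genes = sorted(collection.genes)
    cluster_of: dict[str, int] = {}
    path_of: dict[str, str] = {}
    for ci, cset in enumerate(cluster_sets):
        for pid in cset:
            for g in gene_of_pathway[pid]:
                cluster_of[g] = ci
                path_of[g] = pid
    for pid, gs in gene_of_pathway.items():
        for g in gs:
            path_of.setdefault(g, pid)

    m = len(genes)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    weights = np.ones(len(pairs))
    for k, (i, j) in enumerate(pairs):
        a, b = genes[i], genes[j]
        same_cluster = (
            a in cluster_of and b in cluster_of and cluster_of[a] == cluster_of[b]
        )
        if same_cluster and path_of[a] != path_of[b]:
            weights[k] = within_factor
    probs = weights / weights.sum()
    planted_idx = rng.choice(len(pairs), size=n_gis, replace=False, p=probs)
    uniform_idx = rng.choice(len(pairs), size=n_gis, replace=False)

    def to_gis(idx):
        out = []
        for k in idx:
            i, j = pairs[int(k)]
            out.append(GeneticInteraction(genes[i], genes[j]))
        return out

    return collection, clusters, to_gis(planted_idx), to_gis(uniform_idx)
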