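"""Genetic-interaction enrichment, gene multifunctionality and the
functional tree / gene-overlap matrix.

Genetic interactions (GIs) tend to fall between genes that share function.
Each GI is classified over *all* pathway combinations of its two genes:
a combination where both genes sit in the same pathway is within-pathway,
one where the two pathways co-occur in a network cluster is
within-cluster, anything else is uncharacterised.  Enrichment is measured
against seeded randomizations that redraw the same number of gene pairs
uniformly from the analysed gene universe.

Multifunctionality summaries count pathway membership per gene and compare
the functional profiles of a multi-pathway gene's pathways by semantic
distance.  The functional tree arranges pathways by mean cross-profile
term distance using UPGMA (average-linkage agglomeration); the companion
matrix reports the percentage gene overlap between pathway pairs using the
overlap coefficient, so a pathway nested in another scores 100.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .pathways import PathwayCollection
from .profiles import FunctionalProfile, SemanticDistanceMatrix
from .network import ClusterSet

__all__ = [
    "GeneticInteraction",
    "GIClassification",
    "read_gis",
    "classify_gis",
    "randomize_gis",
    "enrichment_factor",
    "multipathway_summary",
    "gene_profile_divergence",
    "functional_tree_and_overlap",
]

CATEGORIES = ("within_pathway", "within_cluster", "uncharacterised")


@dataclass(frozen=True)
class GeneticInteraction:
    """Unordered gene pair; stored canonically (gene_a < gene_b)."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self interaction {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


def _make_gi(a: str, b: str) -> GeneticInteraction:
    a, b = sorted((a, b))
    return GeneticInteraction(a, b)


@dataclass
class GIClassification:
    """Counts of pathway-pair classifications aggregated over GIs."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: 100.0 * self.counts.get(c, 0) / total for c in CATEGORIES}


def read_gis(
    path,
    known_genes: set[str],
    col_a: int = 0,
    col_b: int = 1,
    sep: str = "\t",
) -> list[GeneticInteraction]:
    """Read gene pairs from a 2-column TSV or a BioGRID-style tab file.

    ``col_a``/``col_b`` select the interactor columns (0-based; BioGRID
    tab2 official symbols live in columns 7 and 8).  Pairs touching a gene
    outside ``known_genes`` are dropped, self-pairs are dropped, and the
    remainder deduplicated under canonical (sorted) order.
    """
    seen: set[tuple[str, str]] = set()
    out: list[GeneticInteraction] = []
    need = max(col_a, col_b) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split(sep)
            if len(cols) < need:
                raise ValueError(f"{path}: malformed interaction line {lineno}")
            a, b = cols[col_a].strip(), cols[col_b].strip()
            if not a or not b:
                raise ValueError(f"{path}: empty gene field at line {lineno}")
            if a == b or a not in known_genes or b not in known_genes:
                continue
            key = tuple(sorted((a, b)))
            if key in seen:
                continue
            seen.add(key)
            out.append(_make_gi(a, b))
    return out


def classify_gis(
    gis: list[GeneticInteraction],
    collection: PathwayCollection,
    clusters: ClusterSet,
) -> GIClassification:
    """Classify every pathway combination of every GI.

    For a GI between genes with pathway sets Pa and Pb, all |Pa|*|Pb|
    ordered combinations are examined: a shared pathway (counted once per
    shared pathway) is within-pathway; two distinct pathways co-occurring
    in at least one cluster are within-cluster; anything else (different
    clusters, or an unclustered pathway) is uncharacterised.
    """
    gene_idx = collection.gene_index()
    member = clusters.membership()
    counts = {c: 0 for c in CATEGORIES}
    for gi in gis:
        pa = gene_idx.get(gi.gene_a)
        pb = gene_idx.get(gi.gene_b)
        if not pa or not pb:
            raise ValueError(
                f"gene {gi.gene_a if not pa else gi.gene_b} is in no pathway; "
                "filter interactions against the collection first"
            )
        for p in pa:
            for q in pb:
                if p == q:
                    counts["within_pathway"] += 1
                elif member.get(p, set()) & member.get(q, set()):
                    counts["within_cluster"] += 1
                else:
                    counts["uncharacterised"] += 1
    return GIClassification(counts)


def randomize_gis(
    known_genes: set[str],
    n: int,
    seed: int,
    replicates: int = 100,
) -> list[list[GeneticInteraction]]:
    """Seeded uniform redraws of ``n`` distinct unordered gene pairs.

    Pairs are indexed lexicographically ((i, j), i < j) and drawn without
    replacement, so each replicate is a uniform sample of distinct pairs.
    """
    genes = sorted(known_genes)
    m = len(genes)
    total = m * (m - 1) // 2
    if m < 2:
        raise ValueError("need at least two genes")
    if n > total:
        raise ValueError(f"cannot draw {n} distinct pairs from {total}")
    rng = np.random.default_rng(seed)
    rows = np.arange(m - 1)
    row_start = rows * m - rows * (rows + 1) // 2  # first index of row i
    out: list[list[GeneticInteraction]] = []
    for _ in range(replicates):
        ks = rng.choice(total, size=n, replace=False)
        reps = []
        for k in ks:
            i = int(np.searchsorted(row_start, k, side="right")) - 1
            j = i + 1 + int(k - row_start[i])
            reps.append(_make_gi(genes[i], genes[j]))
        out.append(reps)
    return out


def enrichment_factor(
    observed,
    randomized,
    category: str,
) -> float:
    """Observed percentage over the mean randomized percentage.

    ``observed`` may be a :class:`GIClassification` or a bare percentage;
    ``randomized`` a list of classifications or percentages.
    """
    obs = (
        observed.percentages[category]
        if isinstance(observed, GIClassification)
        else float(observed)
    )
    if not randomized:
        raise ValueError("no randomized replicates")
    vals = [
        r.percentages[category] if isinstance(r, GIClassification) else float(r)
        for r in randomized
    ]
    mean = float(np.mean(vals))
    if mean == 0:
        raise ValueError(f"mean randomized percentage for {category} is zero")
    return obs / mean


def multipathway_summary(collection: PathwayCollection) -> dict:
    """Histogram of pathway membership per gene plus {1, 2, >=3} shares."""
    idx = collection.gene_index()
    hist: dict[int, int] = {}
    for g, ps in idx.items():
        hist[len(ps)] = hist.get(len(ps), 0) + 1
    n = sum(hist.values())
    bins = {
        "1": hist.get(1, 0),
        "2": hist.get(2, 0),
        "3+": sum(v for k, v in hist.items() if k >= 3),
    }
    pct = {k: (100.0 * v / n if n else 0.0) for k, v in bins.items()}
    return {"histogram": dict(sorted(hist.items())), "bins": bins, "percentages": pct, "n_genes": n}


def gene_profile_divergence(
    gene: str,
    collection: PathwayCollection,
    profiles: dict[str, FunctionalProfile],
    d: SemanticDistanceMatrix,
    mode: str = "terms-union",
) -> tuple[int, int, float]:
    """Diversity of the functional profiles a multi-pathway gene spans.

    Returns (number of distinct profiles, number of disjoint profile
    groups, normalized cross-profile distance).  Profiles are distinct
    when their term sets differ; groups are connected components of the
    "share >= 1 term" relation.  The distance sums all cross-profile term
    pair distances (identical terms contribute 0; unknown pairs skipped)
    and divides by the size of the union of the profiles' terms
    (``terms-union``) or by the number of summed pairs (``per-pair``).
    """
    if mode not in ("terms-union", "per-pair"):
        raise ValueError(f"unknown divergence mode {mode!r}")
    pids = sorted(collection.gene_index().get(gene, set()))
    if len(pids) < 2:
        raise ValueError(f"gene {gene} participates in fewer than two pathways")
    term_sets = [frozenset(profiles[p].term_set) for p in pids]
    distinct = len(set(term_sets))

    parent = list(range(len(pids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pids)):
        for j in range(i + 1, len(pids)):
            if term_sets[i] & term_sets[j]:
                parent[find(i)] = find(j)
    groups = len({find(i) for i in range(len(pids))})

    total = 0.0
    n_pairs = 0
    for i in range(len(pids)):
        for j in range(i + 1, len(pids)):
            for a in term_sets[i]:
                for b in term_sets[j]:
                    v = d.get(a, b)
                    if v is not None:
                        total += v
                        n_pairs += 1
    if mode == "terms-union":
        union = frozenset().union(*term_sets)
        denom = len(union)
    else:
        denom = n_pairs
    norm = total / denom if denom else 0.0
    return distinct, groups, norm


def _profile_distance_matrix(
    profiles: dict[str, FunctionalProfile],
    d: SemanticDistanceMatrix,
) -> tuple[list[str], np.ndarray, int]:
    """Mean cross-profile term distance per pathway pair.

    Pairs with no known term distance fall back to the maximum observed
    mean distance; the count of such fallbacks is returned.
    """
    ids = sorted(profiles)
    n = len(ids)
    mat = np.zeros((n, n))
    missing_pairs: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            A = sorted(profiles[ids[i]].term_set)
            B = sorted(profiles[ids[j]].term_set)
            vals = [
                d.get(a, b) for a in A for b in B if d.get(a, b) is not None
            ]
            if vals:
                mat[i, j] = mat[j, i] = float(np.mean(vals))
            else:
                missing_pairs.append((i, j))
    if missing_pairs:
        fallback = float(mat.max())
        for i, j in missing_pairs:
            mat[i, j] = mat[j, i] = fallback
    return ids, mat, len(missing_pairs)


def upgma(ids: list[str], mat: np.ndarray) -> TreeNode:
    """UPGMA tree from a symmetric distance matrix.

    Average-linkage agglomeration (scipy); node heights are half the
    linkage merge distance, so two leaves at distance 4 join at height 2
    and the tree is ultrametric.  Returns a rooted skbio TreeNode with
    branch lengths.
    """
    if len(ids) < 2:
        raise ValueError("need at least two leaves")
    Z = linkage(squareform(mat, checks=False), method="average")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    heights = [0.0] * len(ids)
    for a, b, dist, _ in Z:
        left, right = nodes[int(a)], nodes[int(b)]
        h = dist / 2.0
        left.length = h - heights[int(a)]
        right.length = h - heights[int(b)]
        nodes.append(TreeNode(children=[left, right]))
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


def functional_tree_and_overlap(
    profiles: dict[str, FunctionalProfile],
    collection: PathwayCollection,
    d: SemanticDistanceMatrix,
) -> tuple[TreeNode, pd.DataFrame]:
    """Arrange pathways by functional similarity; report gene overlap.

    The tree is UPGMA over mean cross-profile term distances.  The overlap
    matrix holds 100 * |genes_i ∩ genes_j| / min(|genes_i|, |genes_j|)
    with the self-comparison diagonal masked (NaN).
    """
    ids, mat, _ = _profile_distance_matrix(profiles, d)
    if len(ids) < 2:
        raise ValueError("need at least two pathways")
    tree = upgma(ids, mat)
    genes = {p.id: p.genes for p in collection if p.id in profiles}
    ov = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i == j:
                continue
            ga, gb = genes[a], genes[b]
            ov.iloc[i, j] = 100.0 * len(ga & gb) / min(len(ga), len(gb))
    return tree, ov
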