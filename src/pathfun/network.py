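"""Pathway network assembly, clustering and topology statistics.

Annotated pathways become nodes; two pathways are linked when their
functional profiles share terms (Jaccard similarity of the term sets) or
carry distinct terms that are semantically near-identical (pairwise
distances below a similarity threshold ``T``, distances normalised to
(T - d)/T, summed and divided by the number of comparable term pairs).
The two components are disjoint evidence — the semantic weight explicitly
excludes identical shared terms — so the default edge weight is their sum.

Clustering follows the greedy cohesiveness-growth scheme of overlapping
protein-complex detection (ClusterONE-style): grow a cluster from a seed
to maximise w_in / (w_in + w_boundary), keep clusters above a weighted
density floor, and merge heavily overlapping clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .profiles import FunctionalProfile, SemanticDistanceMatrix

__all__ = [
    "ClusterSet",
    "jaccard_weight",
    "semantic_weight",
    "build_network",
    "betweenness",
    "degree_exponent",
    "cluster",
    "assign_functional_groups",
]


def jaccard_weight(A: set[str], B: set[str]) -> float:
    """|A ∩ B| / |A ∪ B| over two term sets."""
    if not A and not B:
        raise ValueError("Jaccard weight undefined for two empty sets")
    union = A | B
    return len(A & B) / len(union)


def semantic_weight(
    A: set[str],
    B: set[str],
    d: SemanticDistanceMatrix,
    T: float = 0.8,
) -> float:
    """Edge weight from semantically near-identical distinct terms.

    Over ordered pairs (a, b), a in A, b in B, excluding identical terms,
    pairs with known distance below ``T`` contribute (T - d)/T; the sum is
    divided by |A|*|B| - |A ∩ B| (the number of comparable pairs).  A zero
    denominator (e.g. A == B == one term) gives 0.  Missing distances
    contribute 0.
    """
    if not A or not B:
        raise ValueError("semantic weight undefined for empty term sets")
    denom = len(A) * len(B) - len(A & B)
    if denom == 0:
        return 0.0
    V = 0.0
    for a in A:
        for b in B:
            if a == b:
                continue
            dist = d.get(a, b)
            if dist is not None and dist < T:
                V += (T - dist) / T
    return V / denom


def build_network(
    profiles: list[FunctionalProfile],
    d: SemanticDistanceMatrix,
    T: float = 0.8,
    combine: str = "sum",
    classes: dict[str, str] | None = None,
) -> nx.Graph:
    """Weighted undirected pathway graph from functional profiles.

    Each node is a pathway id with its profile size (and distribution
    class when given); an edge appears between two pathways iff their
    combined weight J + W (or max(J, W)) is positive, with per-edge
    provenance flags ``shared_term`` (J > 0) and ``semantic`` (W > 0).
    """
    if combine not in ("sum", "max"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    g = nx.Graph()
    term_sets: dict[str, set[str]] = {}
    for fp in sorted(profiles, key=lambda p: p.pathway_id):
        if not fp.terms:
            raise ValueError(f"profile {fp.pathway_id} is empty")
        term_sets[fp.pathway_id] = fp.term_set
        attrs = {"profile_size": len(fp)}
        if classes:
            attrs["distribution_class"] = classes.get(fp.pathway_id, "")
        g.add_node(fp.pathway_id, **attrs)
    for a, b in combinations(sorted(term_sets), 2):
        J = jaccard_weight(term_sets[a], term_sets[b])
        W = semantic_weight(term_sets[a], term_sets[b], d, T)
        total = J + W if combine == "sum" else max(J, W)
        if total > 0:
            g.add_edge(
                a,
                b,
                jaccard=J,
                semantic=W,
                weight=total,
                shared_term=J > 0,
                semantic_link=W > 0,
            )
    return g


def shared_edge_fraction(net: nx.Graph) -> float:
    """Fraction of edges carrying at least one identical shared term."""
    m = net.number_of_edges()
    if m == 0:
        return float("nan")
    return sum(1 for *_, e in net.edges(data=True) if e["shared_term"]) / m


def betweenness(net: nx.Graph, weighted: bool = False) -> dict[str, float]:
    """Normalized betweenness centrality; weighted mode treats edge length
    as 1/weight (strong functional links are short)."""
    if weighted:
        lengths = {(u, v): 1.0 / e["weight"] for u, v, e in net.edges(data=True)}
        nx.set_edge_attributes(net, lengths, "length")
        return nx.betweenness_centrality(net, weight="length", normalized=True)
    return nx.betweenness_centrality(net, normalized=True)


def degree_exponent(net: nx.Graph) -> float:
    """Power-law exponent gamma of the degree distribution.

    Least-squares slope of log(count) against log(degree) over the
    empirical degree histogram (zero-degree nodes and empty bins dropped);
    gamma is the negated slope.  Requires >= 3 distinct positive degrees.
    """
    degs = [deg for _, deg in net.degree() if deg > 0]
    ks, counts = np.unique(degs, return_counts=True)
    if len(ks) < 3:
        raise ValueError("need at least 3 distinct positive degrees for a fit")
    slope = np.polyfit(np.log(ks), np.log(counts), 1)[0]
    return float(-slope)


@dataclass
class ClusterSet:
    """Overlapping clusters of pathway nodes above a density floor."""

    clusters: list[set[str]]
    density_threshold: float
    unclustered: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def membership(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for i, c in enumerate(self.clusters):
            for node in c:
                out.setdefault(node, set()).add(i)
        return out


def weighted_density(net: nx.Graph, nodes: set[str]) -> float:
    """Sum of internal edge weights over the number of possible pairs."""
    n = len(nodes)
    if n < 2:
        return 0.0
    w = sum(
        e["weight"] for u, v, e in net.subgraph(nodes).edges(data=True)
    )
    return 2.0 * w / (n * (n - 1))


def _cohesiveness(net: nx.Graph, nodes: set[str]) -> float:
    w_in = 0.0
    w_bound = 0.0
    for u in nodes:
        for v, e in net[u].items():
            if v in nodes:
                w_in += e["weight"] / 2.0
            else:
                w_bound += e["weight"]
    total = w_in + w_bound
    return w_in / total if total > 0 else 0.0


def cluster(
    net: nx.Graph,
    density_threshold: float = 0.25,
    min_size: int = 3,
    merge_overlap: float = 0.8,
) -> ClusterSet:
    """Greedy cohesiveness-growth clustering with overlap merging.

    Seeds are taken from unassigned nodes in descending weighted-degree
    order (ties by node id).  From each seed the cluster is grown/shrunk
    by the single add-or-remove move that most improves cohesiveness
    w_in/(w_in + w_boundary) until no move helps.  Candidate clusters of
    fewer than ``min_size`` nodes are discarded; clusters whose overlap
    score |A∩B|^2/(|A||B|) exceeds ``merge_overlap`` are merged; the final
    set keeps clusters meeting the weighted density floor.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    strength = {
        u: sum(e["weight"] for e in net[u].values()) for u in net.nodes
    }
    order = sorted(net.nodes, key=lambda u: (-strength[u], u))
    assigned: set[str] = set()
    candidates: list[set[str]] = []
    for seed in order:
        if seed in assigned:
            continue
        c = {seed}
        f = _cohesiveness(net, c)
        while True:
            best_f, best_move = f, None
            frontier = {v for u in c for v in net[u] if v not in c}
            for v in sorted(frontier):
                f2 = _cohesiveness(net, c | {v})
                if f2 > best_f:
                    best_f, best_move = f2, ("add", v)
            for v in sorted(c):
                if v == seed or len(c) == 1:
                    continue
                f2 = _cohesiveness(net, c - {v})
                if f2 > best_f:
                    best_f, best_move = f2, ("remove", v)
            if best_move is None:
                break
            op, v = best_move
            c = c | {v} if op == "add" else c - {v}
            f = best_f
        if len(c) >= min_size:
            candidates.append(c)
            assigned |= c

    # merge heavily overlapping candidates (match coefficient)
    merged = True
    while merged:
        merged = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                a, b = candidates[i], candidates[j]
                ov = len(a & b) ** 2 / (len(a) * len(b))
                if ov > merge_overlap:
                    candidates[i] = a | b
                    del candidates[j]
                    merged = True
                    break
            if merged:
                break

    kept = [
        c
        for c in candidates
        if len(c) >= min_size and weighted_density(net, c) >= density_threshold
    ]
    kept.sort(key=lambda c: sorted(c))
    clustered = set().union(*kept) if kept else set()
    return ClusterSet(kept, density_threshold, set(net.nodes) - clustered)


def assign_functional_groups(
    net: nx.Graph,
    profiles: list[FunctionalProfile],
    d: SemanticDistanceMatrix,
    T: float = 0.8,
) -> dict[str, str]:
    """Label each pathway by its dominant semantic term group.

    Terms across all profiles are merged into groups (connected
    components of the "distance < T" relation, group id = smallest member
    term); each pathway gets the group most frequent among its profile
    terms, ties resolved by lexicographic group id.
    """
    by_id = {fp.pathway_id: fp for fp in profiles}
    terms = sorted({t.term for fp in profiles for t in fp.terms})
    parent = {t: t for t in terms}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for a, b in combinations(terms, 2):
        v = d.get(a, b)
        if v is not None and v < T:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    group = {t: find(t) for t in terms}
    labels: dict[str, str] = {}
    for node in net.nodes:
        fp = by_id.get(node)
        if fp is None or not fp.terms:
            continue
        counts: dict[str, int] = {}
        for t in fp.terms:
            g = group[t.term]
            counts[g] = counts.get(g, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        labels[node] = best
    return labels
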