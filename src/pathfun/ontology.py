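"""Gene Ontology structure and gene-annotation handling.

Reads an OBO 1.2 ontology (via :mod:`obonet`) and GAF 2.x gene-association
files, filters annotation rows by evidence code, aspect and NOT-qualifiers,
propagates annotations up the hierarchy (every gene inherits the ancestors
of its directly assigned terms), and removes terms so frequent across the
analysed gene set that they carry no discriminating information.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import obonet

__all__ = [
    "Ontology",
    "GeneAnnotationMap",
    "EXPERIMENTAL_EVIDENCE",
    "ORTHOLOG_EVIDENCE",
    "DEFAULT_EVIDENCE",
    "read_obo",
    "read_gaf",
    "propagate_ancestors",
    "remove_frequent_terms",
]

# Evidence-code policy: experimentally derived annotations plus annotations
# inferred from sequence orthology.  Configurable at the read_gaf call site.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
ORTHOLOG_EVIDENCE = frozenset({"ISS", "ISA", "ISO", "ISM"})
DEFAULT_EVIDENCE = EXPERIMENTAL_EVIDENCE | ORTHOLOG_EVIDENCE

ASPECT_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}

DEFAULT_RELATIONS = ("is_a", "part_of")


@dataclass
class Ontology:
    """Directed acyclic term hierarchy.

    ``parents`` maps a term to its direct parents along the configured
    relations; ``relations`` records the relation type of each child→parent
    edge.  Obsolete terms and edges to unknown terms are excluded.
    """

    terms: dict[str, dict]  # term id -> {"name": str, "namespace": str}
    parents: dict[str, set[str]]
    relations: dict[tuple[str, str], str]
    loaded_relations: tuple[str, ...] = DEFAULT_RELATIONS

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def namespace(self, term: str) -> str | None:
        info = self.terms.get(term)
        return info.get("namespace") if info else None

    def name(self, term: str) -> str:
        return self.terms[term].get("name", term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` along parent edges (excluding
        the term itself)."""
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out


def read_obo(path, relations: tuple[str, ...] = DEFAULT_RELATIONS) -> Ontology:
    """Parse an OBO 1.2 file into an :class:`Ontology`.

    Obsolete terms are excluded; ``is_a`` edges are always loaded and other
    relations (``part_of`` by default) when listed in ``relations``.  A
    cyclic hierarchy is an error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms: dict[str, dict] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = {
            "name": data.get("name", node),
            "namespace": data.get("namespace", ""),
        }
    parents: dict[str, set[str]] = {}
    rel_of: dict[tuple[str, str], str] = {}
    wanted = set(relations) | {"is_a"}
    check = nx.DiGraph()
    check.add_nodes_from(terms)
    for child, parent, key in graph.edges(keys=True):
        if key not in wanted:
            continue
        if parent not in terms or child not in terms:
            continue  # dangling reference (e.g. to an obsolete term)
        parents.setdefault(child, set()).add(parent)
        rel_of[(child, parent)] = key
        check.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(check):
        cycle = nx.find_cycle(check)
        raise ValueError(f"ontology relation graph contains a cycle: {cycle}")
    return Ontology(terms, parents, rel_of, tuple(sorted(wanted)))


@dataclass
class GeneAnnotationMap:
    """gene symbol -> set of ontology term ids, with provenance of the
    filtering policy used to build it."""

    assignments: dict[str, set[str]]
    evidence_filter: frozenset[str] = DEFAULT_EVIDENCE
    aspect: str = "P"
    skipped_unknown_terms: int = 0
    propagated: bool = False
    removed_frequent: frozenset[str] = frozenset()

    def __contains__(self, gene: str) -> bool:
        return gene in self.assignments

    def get(self, gene: str) -> set[str]:
        return self.assignments.get(gene, set())

    @property
    def genes(self) -> set[str]:
        return set(self.assignments)

    def term_index(self) -> dict[str, set[str]]:
        """term -> set of genes carrying it."""
        idx: dict[str, set[str]] = {}
        for g, ts in self.assignments.items():
            for t in ts:
                idx.setdefault(t, set()).add(g)
        return idx

    def n_instances(self) -> int:
        """Total number of (gene, term) annotation instances."""
        return sum(len(ts) for ts in self.assignments.values())


def read_gaf(
    path,
    ontology: Ontology,
    evidence_codes: frozenset[str] = DEFAULT_EVIDENCE,
    aspect: str = "P",
) -> GeneAnnotationMap:
    """Read a GAF 2.1/2.2 file, keeping rows that pass the filters.

    A row is kept when its evidence code is accepted, its aspect matches,
    its qualifier carries no NOT negation and its term exists in the
    ontology (unknown terms are skipped and counted).  Gene symbols are
    taken from column 3 (DB Object Symbol).
    """
    if not evidence_codes:
        raise ValueError("evidence_codes must be non-empty")
    assignments: dict[str, set[str]] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: malformed GAF line {lineno}")
            symbol, qualifier, term = cols[2].strip(), cols[3], cols[4].strip()
            evidence, row_aspect = cols[6].strip(), cols[8].strip()
            if evidence not in evidence_codes or row_aspect != aspect:
                continue
            if "NOT" in qualifier.split("|"):
                continue
            if term not in ontology:
                skipped += 1
                continue
            assignments.setdefault(symbol, set()).add(term)
    return GeneAnnotationMap(
        assignments,
        evidence_filter=frozenset(evidence_codes),
        aspect=aspect,
        skipped_unknown_terms=skipped,
    )


def propagate_ancestors(ann: GeneAnnotationMap, ont: Ontology) -> GeneAnnotationMap:
    """Add every ancestor of each assigned term to the gene.

    Ancestors are followed along the relations the ontology was loaded
    with; terms outside the annotation aspect's namespace (e.g. a
    cross-namespace parent) are excluded, so the closed map stays within
    one aspect.
    """
    want_ns = ASPECT_NAMESPACE.get(ann.aspect, "")
    cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in cache:
            cache[term] = {a for a in ont.ancestors(term) if ont.namespace(a) == want_ns}
        return cache[term]

    closed = {
        g: set().union(ts, *(closure(t) for t in ts)) for g, ts in ann.assignments.items()
    }
    return GeneAnnotationMap(
        closed,
        evidence_filter=ann.evidence_filter,
        aspect=ann.aspect,
        skipped_unknown_terms=ann.skipped_unknown_terms,
        propagated=True,
        removed_frequent=ann.removed_frequent,
    )


def remove_frequent_terms(
    ann: GeneAnnotationMap,
    universe: set[str],
    max_fraction: float = 0.5,
) -> tuple[GeneAnnotationMap, dict[str, int]]:
    """Drop terms annotating more than ``max_fraction`` of the gene universe.

    ``universe`` should be the annotated genes appearing in the analysed
    pathway collection.  A term is removed (from every gene) when its
    frequency among universe genes *strictly* exceeds the threshold;
    returns the pruned map and the removed terms with their gene counts.
    """
    if not universe:
        raise ValueError("empty gene universe")
    counts: dict[str, int] = {}
    for g in universe:
        for t in ann.assignments.get(g, ()):
            counts[t] = counts.get(t, 0) + 1
    cutoff = max_fraction * len(universe)
    removed = {t: n for t, n in counts.items() if n > cutoff}
    pruned = {g: ts - removed.keys() for g, ts in ann.assignments.items()}
    pruned = {g: ts for g, ts in pruned.items() if ts}
    return (
        GeneAnnotationMap(
            pruned,
            evidence_filter=ann.evidence_filter,
            aspect=ann.aspect,
            skipped_unknown_terms=ann.skipped_unknown_terms,
            propagated=ann.propagated,
            removed_frequent=ann.removed_frequent | frozenset(removed),
        ),
        removed,
    )
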