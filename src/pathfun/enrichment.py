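"""Per-pathway term enrichment via one-sided Fisher's exact tests.

For each term carried by at least one gene of a pathway, a 2x2 table is
built over annotation *instances* — (gene, term) pairs after ancestor
closure and frequent-term removal — and the over-representation tail
probability of the hypergeometric null is computed.  These uncorrected
p-values are used directly as enrichment scores: no multiple-testing
correction is applied, because downstream profile construction is designed
to discard spurious terms itself.

An alternative conventional gene-count table (``table="genes"``) is
available: there the margins count genes rather than annotation instances.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

__all__ = [
    "ContingencyTable",
    "EnrichmentEntry",
    "EnrichmentProfile",
    "build_table",
    "fisher_one_sided",
    "build_enrichment_profile",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for one (pathway, term) pair.

    n11: genes in the pathway carrying the term;
    n12: instances of other terms inside the pathway;
    n21: instances of the term outside the pathway;
    n22: instances of other terms outside the pathway.
    """

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


@dataclass(frozen=True)
class EnrichmentEntry:
    term: str
    score: float
    supporting_genes: frozenset[str]


@dataclass
class EnrichmentProfile:
    """All terms over-represented in one pathway at the score threshold,
    sorted ascending by enrichment score."""

    pathway_id: str
    entries: list[EnrichmentEntry]
    alpha: float

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def terms(self) -> set[str]:
        return {e.term for e in self.entries}


def build_table(pathway, term: str, ann, universe: set[str], table: str = "instances") -> ContingencyTable:
    """Build the 2x2 table for ``term`` against ``pathway``.

    ``universe`` is the full consolidated gene set; genes of the pathway
    must be contained in it.  In the default instance mode the off-cells
    count (gene, term) annotation instances; in gene mode they count genes.
    """
    inside = pathway.genes if hasattr(pathway, "genes") else set(pathway)
    n11 = sum(1 for g in inside if term in ann.get(g))
    outside = universe - set(inside)
    n21 = sum(1 for g in outside if term in ann.get(g))
    if table == "instances":
        in_inst = sum(len(ann.get(g)) for g in inside)
        out_inst = sum(len(ann.get(g)) for g in outside)
        return ContingencyTable(n11, in_inst - n11, n21, out_inst - n21)
    elif table == "genes":
        return ContingencyTable(n11, len(inside) - n11, n21, len(outside) - n21)
    raise ValueError(f"unknown table mode {table!r}")


def fisher_one_sided(t: ContingencyTable) -> float:
    """Over-representation tail probability P(X >= n11).

    X is hypergeometric with population ``total``, ``n11 + n21`` marked
    items and a draw of ``n11 + n12``.  Always in (0, 1]; n11 = 0 gives 1.
    """
    if t.total < 1:
        raise ValueError("contingency table is empty")
    p = float(hypergeom.sf(t.n11 - 1, t.total, t.n11 + t.n21, t.n11 + t.n12))
    return min(max(p, 5e-324), 1.0)


def build_enrichment_profile(
    pathway,
    ann,
    universe: set[str],
    alpha: float = 0.01,
    table: str = "instances",
) -> EnrichmentProfile:
    """Score every term annotating >= 1 pathway gene; keep score < alpha.

    Entries are sorted ascending by score, ties broken by more supporting
    genes then lexicographic term id.  Raises if no pathway gene carries
    any annotation (an upstream-contract violation: unannotated genes are
    removed during ingest).
    """
    if not set(pathway.genes) <= universe:
        raise ValueError(f"pathway {pathway.id} has genes outside the universe")
    support: dict[str, set[str]] = {}
    for g in pathway.genes:
        for t in ann.get(g):
            support.setdefault(t, set()).add(g)
    if not support:
        raise ValueError(f"pathway {pathway.id} has no annotated genes")

    # instance totals shared by every term's table
    outside = universe - set(pathway.genes)
    in_inst = sum(len(ann.get(g)) for g in pathway.genes)
    out_inst = sum(len(ann.get(g)) for g in outside)
    term_gene_counts: dict[str, int] | None = None
    if table == "instances":
        # count term instances outside the pathway in one pass
        term_gene_counts = {}
        for g in outside:
            for t in ann.get(g):
                if t in support:
                    term_gene_counts[t] = term_gene_counts.get(t, 0) + 1

    entries = []
    for t, genes in support.items():
        n11 = len(genes)
        if table == "instances":
            n21 = term_gene_counts.get(t, 0)
            tab = ContingencyTable(n11, in_inst - n11, n21, out_inst - n21)
        else:
            tab = build_table(pathway, t, ann, universe, table=table)
        score = fisher_one_sided(tab)
        if score < alpha:
            entries.append(EnrichmentEntry(t, score, frozenset(genes)))
    entries.sort(key=lambda e: (e.score, -len(e.supporting_genes), e.term))
    return EnrichmentProfile(pathway.id, entries, alpha)
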