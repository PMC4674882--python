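"""Functional profiles: minimal covering term sets plus pleiotropy.

A pathway's *functional profile* is the smallest-practical ordered subset
of its enriched terms that together annotate ("represent") the maximum
number of its genes.  Terms are considered in ascending enrichment-score
order and greedily selected whenever they cover at least one so-far
uncovered gene; terms supported by a single gene are excluded as likely
spurious.

A second pass captures gene pleiotropy: a strongly enriched term (score
below ``max_score``) that is semantically remote (distance above a
threshold) from *every* term already in the profile indicates an
independent second function and is appended with origin ``pleiotropic``.
Semantic distances between terms are consumed as a precomputed symmetric
matrix; missing pairs disqualify a candidate rather than defaulting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .enrichment import EnrichmentProfile

__all__ = [
    "SemanticDistanceMatrix",
    "ProfileTerm",
    "FunctionalProfile",
    "greedy_cover",
    "derive_pleiotropy_threshold",
    "augment_pleiotropic",
    "classify_distribution",
    "profile_distance_stats",
]


class SemanticDistanceMatrix:
    """Symmetric term-term semantic distance lookup.

    Missing pairs are explicit: :meth:`get` returns ``None`` for an unknown
    pair (never a silent zero).  Identical terms are at distance 0.
    """

    def __init__(self, distances: dict[tuple[str, str], float] | None = None):
        self._d: dict[frozenset[str], float] = {}
        if distances:
            for (a, b), v in distances.items():
                self.set(a, b, v)

    def set(self, a: str, b: str, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative distance d({a},{b})={value}")
        if a == b:
            if value != 0:
                raise ValueError(f"self-distance d({a},{a}) must be 0")
            return
        self._d[frozenset((a, b))] = float(value)

    def get(self, a: str, b: str) -> float | None:
        if a == b:
            return 0.0
        return self._d.get(frozenset((a, b)))

    def __len__(self) -> int:
        return len(self._d)

    def values(self) -> list[float]:
        return list(self._d.values())

    def coverage(self, pairs: Iterable[tuple[str, str]]) -> float:
        """Fraction of the given pairs with a known distance."""
        pairs = list(pairs)
        if not pairs:
            return 1.0
        known = sum(1 for a, b in pairs if self.get(a, b) is not None)
        return known / len(pairs)

    @classmethod
    def from_tsv(cls, path) -> "SemanticDistanceMatrix":
        """Load ``term_a<TAB>term_b<TAB>distance`` rows (symmetric
        completion applied; conflicting asymmetric duplicates are an
        error)."""
        m = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}: malformed distance line {lineno}")
                a, b, v = parts[0].strip(), parts[1].strip(), float(parts[2])
                prev = m.get(a, b)
                if prev is not None and prev != v and a != b:
                    raise ValueError(
                        f"{path}: conflicting distances for ({a},{b}): {prev} vs {v}"
                    )
                m.set(a, b, v)
        return m

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for pair in sorted(self._d, key=sorted):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{self._d[pair]:g}\n")


@dataclass(frozen=True)
class ProfileTerm:
    term: str
    score: float
    supporting_genes: frozenset[str]
    origin: str  # "cover" | "pleiotropic"


@dataclass
class FunctionalProfile:
    """Ordered minimal term set covering a pathway's genes."""

    pathway_id: str
    terms: list[ProfileTerm]
    covered_genes: set[str]
    uncovered_genes: set[str]
    skipped_missing_distance: int = 0

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def term_set(self) -> set[str]:
        return {t.term for t in self.terms}

    @property
    def cover_terms(self) -> list[ProfileTerm]:
        return [t for t in self.terms if t.origin == "cover"]

    @property
    def pleiotropic_terms(self) -> list[ProfileTerm]:
        return [t for t in self.terms if t.origin == "pleiotropic"]


def greedy_cover(ep: EnrichmentProfile, pathway) -> FunctionalProfile:
    """Select enriched terms covering the pathway's genes, best score first.

    Terms supported by fewer than two pathway genes are excluded.  The
    remaining candidates are scanned in the profile's ascending-score
    order; a term is selected whenever it represents at least one not-yet
    represented gene, until all genes are covered or candidates run out.
    """
    chosen: list[ProfileTerm] = []
    covered: set[str] = set()
    genes = set(pathway.genes)
    for e in ep:
        if len(e.supporting_genes) < 2:
            continue
        new = e.supporting_genes - covered
        if new:
            chosen.append(ProfileTerm(e.term, e.score, e.supporting_genes, "cover"))
            covered |= e.supporting_genes
        if covered >= genes:
            break
    return FunctionalProfile(ep.pathway_id, chosen, covered & genes, genes - covered)


def derive_pleiotropy_threshold(
    profiles: list[FunctionalProfile],
    d: SemanticDistanceMatrix,
    percentile: float = 95,
) -> float:
    """Percentile of the pooled within-profile pairwise distance
    distribution (linear interpolation between order statistics)."""
    pooled: list[float] = []
    for fp in profiles:
        ts = [t.term for t in fp.terms]
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                v = d.get(ts[i], ts[j])
                if v is not None:
                    pooled.append(v)
    if not pooled:
        raise ValueError("no within-profile term pair has a known distance")
    return float(np.percentile(pooled, percentile))


def augment_pleiotropic(
    fp: FunctionalProfile,
    ep: EnrichmentProfile,
    d: SemanticDistanceMatrix,
    threshold: float = 11.2,
    max_score: float = 0.0005,
) -> FunctionalProfile:
    """Append strongly enriched, semantically remote terms as pleiotropic.

    Candidates are enriched terms absent from the profile with score below
    ``max_score`` and >= 2 supporting genes, evaluated in ascending score
    order.  A candidate is added iff its distance to every term currently
    in the profile is known and strictly greater than ``threshold``; newly
    added terms immediately join the comparison set.  Candidates with any
    missing distance are skipped and counted.
    """
    terms = list(fp.terms)
    present = {t.term for t in terms}
    skipped = fp.skipped_missing_distance
    for e in ep:
        if e.term in present or e.score >= max_score or len(e.supporting_genes) < 2:
            continue
        dists = [d.get(e.term, t.term) for t in terms]
        if any(v is None for v in dists):
            skipped += 1
            continue
        if all(v > threshold for v in dists):
            terms.append(
                ProfileTerm(e.term, e.score, e.supporting_genes, "pleiotropic")
            )
            present.add(e.term)
    return FunctionalProfile(
        fp.pathway_id, terms, set(fp.covered_genes), set(fp.uncovered_genes), skipped
    )


def classify_distribution(fp: FunctionalProfile) -> str:
    """Label how a profile's functions are spread over the pathway's genes.

    Cover terms form a graph with edges between terms whose supporting
    gene sets intersect.  ``discrete`` marks >1 connected component
    (disjoint gene sets carrying different functions), ``pleiotropic``
    marks the presence of appended pleiotropic terms,
    ``discrete_and_pleiotropic`` both, ``single`` a lone cover term with
    no pleiotropy, otherwise ``overlapping``.
    """
    if not fp.terms:
        raise ValueError(f"profile {fp.pathway_id} is empty")
    cover = fp.cover_terms
    has_pleio = bool(fp.pleiotropic_terms)
    n_comp = 0
    if cover:
        # connected components among cover terms via shared supporting genes
        parent = list(range(len(cover)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(cover)):
            for j in range(i + 1, len(cover)):
                if cover[i].supporting_genes & cover[j].supporting_genes:
                    parent[find(i)] = find(j)
        n_comp = len({find(i) for i in range(len(cover))})
    if n_comp > 1 and has_pleio:
        return "discrete_and_pleiotropic"
    if n_comp > 1:
        return "discrete"
    if has_pleio:
        return "pleiotropic"
    if len(cover) == 1:
        return "single"
    return "overlapping"


def profile_distance_stats(
    profiles: list[FunctionalProfile],
    ep_profiles: list[EnrichmentProfile],
    d: SemanticDistanceMatrix,
) -> dict[str, list[float]]:
    """Distance samples behind the within/merged profile histograms.

    ``within_functional`` / ``within_enriched``: distances between distinct
    term pairs inside each profile.  ``merged_functional`` /
    ``merged_enriched``: the null obtained by pooling all annotations (with
    multiplicity) across profiles and pairing terms across different
    pathways, excluding identical-term self comparisons.  Pairs with
    unknown distance are omitted.
    """

    def within(term_lists: list[list[str]]) -> list[float]:
        out: list[float] = []
        for ts in term_lists:
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    if ts[i] == ts[j]:
                        continue
                    v = d.get(ts[i], ts[j])
                    if v is not None:
                        out.append(v)
        return out

    def merged(term_lists: list[list[str]]) -> list[float]:
        out: list[float] = []
        for i in range(len(term_lists)):
            for j in range(i + 1, len(term_lists)):
                for a in term_lists[i]:
                    for b in term_lists[j]:
                        if a == b:
                            continue
                        v = d.get(a, b)
                        if v is not None:
                            out.append(v)
        return out

    fp_terms = [[t.term for t in fp.terms] for fp in profiles]
    ep_terms = [[e.term for e in ep.entries] for ep in ep_profiles]
    return {
        "within_functional": within(fp_terms),
        "within_enriched": within(ep_terms),
        "merged_functional": merged(fp_terms),
        "merged_enriched": merged(ep_terms),
    }
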