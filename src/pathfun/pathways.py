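"""Pathway gene-set ingest and consolidation.

Pathway collections aggregated from multiple source databases (e.g.
ConsensusPathDB exports) carry heavy redundancy: the same pathway name
contributed by several databases with slightly different gene boundaries,
verbatim duplicate gene sets, and small pathways that are strict subsets of
larger ones.  This module reads raw collections (GMT or CPDB-style tab
files) and applies a deterministic consolidation pipeline:

1. merge pathways sharing an identical name (union of gene sets),
2. drop pathways with fewer than ``min_size`` genes,
3. keep a single representative among identical gene sets,
4. resolve proper-subset pairs by retaining the pathway whose size is
   closest to the median pathway size,
5. drop genes without functional annotation, then re-apply the size floor.

Every stage appends a row of summary statistics (pathway count, unique
genes, median/mean/sd of pathway size) to the collection's ``stage_log`` so
the transformation of the data can be reported as a table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "Pathway",
    "PathwayCollection",
    "StageRecord",
    "read_pathways",
    "merge_duplicate_names",
    "drop_small",
    "dedupe_identical_gene_sets",
    "resolve_subsets",
    "drop_unannotated_genes",
    "write_gmt",
]


@dataclass(frozen=True)
class Pathway:
    """A named set of genes acting together under specific conditions."""

    id: str
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has an empty gene set")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class StageRecord:
    """Summary statistics for a collection at one consolidation stage."""

    stage: str
    n_pathways: int
    n_genes: int
    median_size: float
    mean_size: float
    sd_size: float


def _stats(pathways: list[Pathway], stage: str) -> StageRecord:
    if not pathways:
        return StageRecord(stage, 0, 0, float("nan"), float("nan"), float("nan"))
    # sorted so summary statistics are bitwise-reproducible regardless of
    # pathway order
    sizes = np.sort(np.array([p.size for p in pathways], dtype=float))
    genes: set[str] = set().union(*(p.genes for p in pathways))
    # sample sd (ddof=1); nan for a single pathway
    sd = float(np.std(sizes, ddof=1)) if len(sizes) > 1 else float("nan")
    return StageRecord(
        stage,
        len(pathways),
        len(genes),
        float(np.median(sizes)),
        float(np.mean(sizes)),
        sd,
    )


@dataclass
class PathwayCollection:
    pathways: list[Pathway]
    stage_log: list[StageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {dup}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def genes(self) -> set[str]:
        """All genes appearing in at least one pathway."""
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return out

    def gene_index(self) -> dict[str, set[str]]:
        """gene symbol -> ids of the pathways containing it."""
        idx: dict[str, set[str]] = {}
        for p in self.pathways:
            for g in p.genes:
                idx.setdefault(g, set()).add(p.id)
        return idx

    def _advance(self, pathways: list[Pathway], stage: str) -> "PathwayCollection":
        return PathwayCollection(pathways, self.stage_log + [_stats(pathways, stage)])

    def stage_log_frame(self):
        """Stage log as a pandas DataFrame (one row per stage)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "stage": r.stage,
                    "pathways": r.n_pathways,
                    "unique_genes": r.n_genes,
                    "median_size": r.median_size,
                    "mean_size": r.mean_size,
                    "sd_size": r.sd_size,
                }
                for r in self.stage_log
            ]
        )


def _clean_genes(raw: Iterable[str], pathway: str, lineno: int) -> frozenset[str]:
    genes = frozenset(g.strip() for g in raw if g.strip())
    return genes


def read_pathways(path, format: str = "gmt") -> PathwayCollection:
    """Read a pathway collection from a GMT or CPDB-style tab file.

    GMT: ``name<TAB>description<TAB>gene1<TAB>gene2...``.
    cpdb_tab: ``name<TAB>source_db<TAB>gene1,gene2,...`` (comma-separated
    genes in the final column; header lines starting with '#' skipped).
    Pathway ids are ``P0001``-style ordinals in file order; the record name
    is kept verbatim (trimmed) as ``name``.
    """
    if format not in ("gmt", "cpdb_tab"):
        raise ValueError(f"unknown format {format!r}")
    pathways: list[Pathway] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if format == "gmt":
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}: malformed GMT line {lineno}: expected name, "
                        f"description and at least one gene"
                    )
                name, source, raw = parts[0].strip(), parts[1].strip(), parts[2:]
            else:
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}: malformed CPDB line {lineno}: expected name, "
                        f"source and gene column"
                    )
                name, source = parts[0].strip(), parts[1].strip()
                raw = parts[2].split(",")
            genes = _clean_genes(raw, name, lineno)
            if not genes:
                continue
            n += 1
            pid = f"P{n:04d}"
            if pid in seen_ids:
                raise ValueError(f"{path}: duplicate pathway id {pid}")
            seen_ids.add(pid)
            pathways.append(Pathway(pid, name, genes, source))
    return PathwayCollection(pathways, [_stats(pathways, "original")])


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.name}\t{p.source}\t{genes}\n")


def merge_duplicate_names(c: PathwayCollection) -> PathwayCollection:
    """Amalgamate same-named pathways into one entity (union of genes)."""
    by_name: dict[str, list[Pathway]] = {}
    order: list[str] = []
    for p in c:
        key = p.name.strip()
        if key not in by_name:
            order.append(key)
        by_name.setdefault(key, []).append(p)
    merged: list[Pathway] = []
    for key in order:
        group = sorted(by_name[key], key=lambda p: p.id)
        first = group[0]
        if len(group) == 1:
            merged.append(first)
        else:
            genes = frozenset().union(*(p.genes for p in group))
            sources = ";".join(sorted({p.source for p in group if p.source}))
            merged.append(Pathway(first.id, first.name, genes, sources))
    return c._advance(merged, "duplicate_names_merged")


def drop_small(c: PathwayCollection, min_size: int = 3) -> PathwayCollection:
    """Remove pathways with fewer than ``min_size`` genes (too small for
    reliable enrichment statistics)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [p for p in c if p.size >= min_size]
    return c._advance(kept, "small_pathways_removed")


def dedupe_identical_gene_sets(c: PathwayCollection) -> PathwayCollection:
    """Among pathways with equal gene sets keep exactly one.

    The retained representative is the lexicographically smallest (name,
    id) — a deterministic tie rule.
    """
    by_set: dict[frozenset[str], Pathway] = {}
    for p in c:
        cur = by_set.get(p.genes)
        if cur is None or (p.name, p.id) < (cur.name, cur.id):
            by_set[p.genes] = p
    keep_ids = {p.id for p in by_set.values()}
    kept = [p for p in c if p.id in keep_ids]
    return c._advance(kept, "identical_gene_sets_removed")


def resolve_subsets(c: PathwayCollection) -> PathwayCollection:
    """Remove proper-subset redundancy, preferring sizes near the median.

    The median pathway size is computed once over the collection entering
    this stage and held fixed.  While any pathway's gene set is a proper
    subset of another's, the pair member whose size is farther from that
    median is removed; equidistant ties remove the larger pathway.  Pairs
    are examined in id-sorted order and the scan restarts after every
    removal, so the result is deterministic.
    """
    sets = {p.id: p.genes for p in c}
    if len(set(sets.values())) != len(sets):
        raise ValueError("identical gene sets present; run dedupe first")
    if not len(c):
        return c._advance([], "pathway_subsets_removed")
    median = float(np.median([p.size for p in c]))
    alive: dict[str, Pathway] = {p.id: p for p in c}
    changed = True
    while changed:
        changed = False
        ids = sorted(alive)
        for i, a_id in enumerate(ids):
            a = alive[a_id]
            for b_id in ids[i + 1 :]:
                b = alive[b_id]
                if a.genes < b.genes or b.genes < a.genes:
                    da, db = abs(a.size - median), abs(b.size - median)
                    if da > db:
                        loser = a
                    elif db > da:
                        loser = b
                    else:  # equidistant: drop the larger pathway
                        loser = a if a.size > b.size else b
                    del alive[loser.id]
                    changed = True
                    break
            if changed:
                break
    kept = [p for p in c if p.id in alive]
    return c._advance(kept, "pathway_subsets_removed")


def drop_unannotated_genes(
    c: PathwayCollection, ann, min_size: int = 3
) -> PathwayCollection:
    """Remove genes absent from the annotation map, then re-apply the size
    floor.

    ``ann`` is a :class:`~pathfun.ontology.GeneAnnotationMap` (anything with
    an ``assignments`` mapping works).
    """
    annotated = set(ann.assignments)
    kept: list[Pathway] = []
    for p in c:
        genes = frozenset(g for g in p.genes if g in annotated)
        if len(genes) >= min_size:
            kept.append(replace(p, genes=genes))
    return c._advance(kept, "unannotated_genes_removed")
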