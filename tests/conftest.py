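import numpy as np
import pytest
from scipy.stats import hypergeom

from pathfun.enrichment import EnrichmentEntry, EnrichmentProfile
from pathfun.fixtures import FixtureSpec, generate
from pathfun.pathways import Pathway, PathwayCollection


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One deterministic synthetic input bundle shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    return generate(FixtureSpec(seed=7), out)


def make_collection(sets: dict[str, set[str]], names: dict[str, str] | None = None):
    """Build a PathwayCollection from {id: genes} (name defaults to id)."""
    names = names or {}
    pathways = [
        Pathway(pid, names.get(pid, pid), frozenset(genes))
        for pid, genes in sets.items()
    ]
    return PathwayCollection(pathways)


def random_enrichment_instance(seed, alpha=0.01):
    """Random enrichment-profile instance for cover-oracle tests.

    Supports are random gene subsets; scores are genuine hypergeometric
    tail probabilities (term instances inside vs outside a notional
    universe) thresholded at ``alpha`` — the contract greedy_cover
    consumes.  Returns (pathway, enrichment profile).
    """
    rng = np.random.default_rng(seed)
    n_terms = int(rng.integers(2, 13))
    n_genes = int(rng.integers(3, 16))
    genes = [f"g{i}" for i in range(n_genes)]
    entries = []
    M, draw = 400, 40  # notional instance universe / pathway instances
    for t in range(n_terms):
        k = int(rng.integers(1, n_genes + 1))
        supp = frozenset(rng.choice(genes, size=k, replace=False))
        n_outside = int(rng.integers(0, 30))
        score = float(hypergeom.sf(k - 1, M, k + n_outside, draw))
        if score < alpha:
            entries.append(EnrichmentEntry(f"T{t}", score, supp))
    entries.sort(key=lambda e: (e.score, -len(e.supporting_genes), e.term))
    pathway = Pathway("P", "P", frozenset(genes))
    return pathway, EnrichmentProfile("P", entries, alpha)


class DictAnnotation:
    """Minimal stand-in for GeneAnnotationMap in unit tests."""

    def __init__(self, assignments: dict[str, set[str]]):
        self.assignments = {g: set(ts) for g, ts in assignments.items()}

    def get(self, gene):
        return self.assignments.get(gene, set())
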