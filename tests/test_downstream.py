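"""GI classification/enrichment, gene multifunctionality, UPGMA tree."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from pathfun.downstream import (
    GeneticInteraction,
    read_gis,
    classify_gis,
    randomize_gis,
    enrichment_factor,
    multipathway_summary,
    gene_profile_divergence,
    functional_tree_and_overlap,
    upgma,
)
from pathfun.network import ClusterSet
from pathfun.profiles import FunctionalProfile, ProfileTerm, SemanticDistanceMatrix

from conftest import make_collection


def fp(pid, terms):
    pts = [ProfileTerm(t, 1e-4, frozenset(["x", "y"]), "cover") for t in terms]
    return FunctionalProfile(pid, pts, {"x", "y"}, set())


class TestReadGis:
    def write(self, tmp_path, rows):
        f = tmp_path / "gi.tsv"
        f.write_text("#a\tb\n" + "\n".join(rows) + "\n")
        return f

    def test_unknown_gene_dropped(self, tmp_path):
        f = self.write(tmp_path, ["g1\tg2", "g1\tzz"])
        assert len(read_gis(f, {"g1", "g2"})) == 1

    def test_reversed_duplicate_collapses(self, tmp_path):
        f = self.write(tmp_path, ["g1\tg2", "g2\tg1"])
        gis = read_gis(f, {"g1", "g2"})
        assert gis == [GeneticInteraction("g1", "g2")]

    def test_self_pair_dropped(self, tmp_path):
        f = self.write(tmp_path, ["g1\tg1", "g1\tg2"])
        assert len(read_gis(f, {"g1", "g2"})) == 1

    def test_malformed_row_names_line(self, tmp_path):
        f = self.write(tmp_path, ["g1\tg2", "lonely"])
        with pytest.raises(ValueError, match="line 3"):
            read_gis(f, {"g1", "g2"})

    def test_biogrid_style_columns(self, tmp_path):
        f = tmp_path / "bg.tsv"
        f.write_text("id\tx\tx\tx\tx\tx\tx\tGENEA\tGENEB\n")
        gis = read_gis(f, {"GENEA", "GENEB"}, col_a=7, col_b=8)
        assert gis == [GeneticInteraction("GENEA", "GENEB")]


class TestClassifyGis:
    def fig8_setup(self):
        """gene1 in {P1, P2}; gene2 in {P2, P4}; {P1,P2,P3} clustered
        together, P4 in a second cluster."""
        coll = make_collection(
            {
                "P1": {"gene1", "a", "b"},
                "P2": {"gene1", "gene2", "c"},
                "P3": {"d", "e", "f"},
                "P4": {"gene2", "g", "h"},
            }
        )
        clusters = ClusterSet([{"P1", "P2", "P3"}, {"P4"}], 0.25)
        return coll, clusters

    def test_worked_multi_pathway_scenario(self):
        coll, clusters = self.fig8_setup()
        out = classify_gis([GeneticInteraction("gene1", "gene2")], coll, clusters)
        # combinations: (P2,P2) within-pathway; (P1,P2) within-cluster;
        # (P1,P4) and (P2,P4) uncharacterised
        assert out.counts == {
            "within_pathway": 1,
            "within_cluster": 1,
            "uncharacterised": 2,
        }

    def test_single_shared_pathway_is_pure_within(self):
        coll = make_collection({"P1": {"a", "b", "c"}})
        clusters = ClusterSet([], 0.25, unclustered={"P1"})
        out = classify_gis([GeneticInteraction("a", "b")], coll, clusters)
        assert out.percentages["within_pathway"] == 100.0

    def test_unclustered_singletons_uncharacterised(self):
        coll = make_collection({"P1": {"a", "b", "c"}, "P2": {"d", "e", "f"}})
        clusters = ClusterSet([], 0.25, unclustered={"P1", "P2"})
        out = classify_gis([GeneticInteraction("a", "d")], coll, clusters)
        assert out.percentages["uncharacterised"] == 100.0

    def test_percentages_sum_to_100(self):
        coll, clusters = self.fig8_setup()
        out = classify_gis(
            [GeneticInteraction("gene1", "gene2"), GeneticInteraction("a", "c")],
            coll,
            clusters,
        )
        assert sum(out.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_total_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        coll = make_collection(
            {
                f"P{i}": set(
                    rng.choice([f"g{j}" for j in range(12)], size=4, replace=False)
                )
                for i in range(6)
            }
        )
        clusters = ClusterSet([{"P0", "P1"}, {"P2", "P3", "P4"}], 0.25)
        idx = coll.gene_index()
        genes = sorted(coll.genes)
        gis = [
            GeneticInteraction(a, b)
            for a, b in itertools.combinations(genes, 2)
            if rng.random() < 0.3
        ]
        out = classify_gis(gis, coll, clusters)
        expected_total = sum(
            len(idx[g.gene_a]) * len(idx[g.gene_b]) for g in gis
        )
        assert out.total == expected_total


class TestRandomize:
    def test_same_seed_reproduces(self):
        genes = {f"g{i}" for i in range(10)}
        a = randomize_gis(genes, 5, seed=42, replicates=3)
        b = randomize_gis(genes, 5, seed=42, replicates=3)
        assert a == b

    def test_complete_pair_set(self):
        genes = {"a", "b", "c", "d"}
        (rep,) = randomize_gis(genes, 6, seed=0, replicates=1)
        assert {(g.gene_a, g.gene_b) for g in rep} == {
            tuple(sorted(p)) for p in itertools.combinations(sorted(genes), 2)
        }

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError):
            randomize_gis({"a", "b"}, 2, seed=0)

    def test_marginal_gene_frequency_uniform(self):
        genes = {f"g{i}" for i in range(12)}
        reps = randomize_gis(genes, 10, seed=1, replicates=1000)
        counts = {g: 0 for g in sorted(genes)}
        for rep in reps:
            for gi in rep:
                counts[gi.gene_a] += 1
                counts[gi.gene_b] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01


class TestEnrichmentFactor:
    def test_identity_when_equal(self):
        assert enrichment_factor(5.0, [5.0, 5.0], "within_pathway") == 1.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            enrichment_factor(5.0, [0.0], "within_pathway")

    def test_reported_arithmetic(self):
        assert enrichment_factor(5.45, [0.840], "within_pathway") == pytest.approx(
            6.488, abs=1e-3
        )
        assert enrichment_factor(4.37, [0.800], "within_cluster") == pytest.approx(
            5.4625, abs=1e-9
        )


class TestMultipathway:
    def test_small_example(self):
        coll = make_collection(
            {"P1": {"a", "c", "x"}, "P2": {"b", "c", "y"}}
        )
        out = multipathway_summary(coll)
        assert out["histogram"] == {1: 4, 2: 1}
        assert out["percentages"]["1"] == pytest.approx(80.0)
        assert out["percentages"]["2"] == pytest.approx(20.0)
        assert out["percentages"]["3+"] == 0.0

    def test_empty_collection(self):
        coll = make_collection({})
        out = multipathway_summary(coll)
        assert out["histogram"] == {} and out["n_genes"] == 0


class TestGeneDivergence:
    def coll(self):
        return make_collection(
            {"P1": {"g", "a", "b"}, "P2": {"g", "c", "d"}, "P3": {"g", "e", "f"}}
        )

    def test_identical_profiles(self):
        profiles = {"P1": fp("P1", ["t"]), "P2": fp("P2", ["t"]), "P3": fp("P3", ["t"])}
        coll = self.coll()
        d = SemanticDistanceMatrix()
        distinct, groups, dist = gene_profile_divergence("g", coll, profiles, d)
        assert (distinct, groups, dist) == (1, 1, 0.0)

    def test_two_disjoint_profiles_literal_mode(self):
        coll = make_collection({"P1": {"g", "a", "b"}, "P2": {"g", "c", "d"}})
        profiles = {"P1": fp("P1", ["a"]), "P2": fp("P2", ["b"])}
        d = SemanticDistanceMatrix({("a", "b"): 8.0})
        distinct, groups, dist = gene_profile_divergence("g", coll, profiles, d)
        assert (distinct, groups) == (2, 2)
        assert dist == pytest.approx(8.0 / 2)  # sum / |union of terms|

    def test_shared_term_connectivity(self):
        profiles = {
            "P1": fp("P1", ["a"]),
            "P2": fp("P2", ["a", "b"]),
            "P3": fp("P3", ["c"]),
        }
        d = SemanticDistanceMatrix()
        _, groups, _ = gene_profile_divergence("g", self.coll(), profiles, d)
        assert groups == 2

    def test_single_pathway_gene_rejected(self):
        coll = make_collection({"P1": {"g", "a", "b"}})
        with pytest.raises(ValueError):
            gene_profile_divergence("g", coll, {"P1": fp("P1", ["t"])},
                                    SemanticDistanceMatrix())

    def test_modes_proportional_for_fixed_sizes(self):
        coll = make_collection({"P1": {"g", "a", "b"}, "P2": {"g", "c", "d"}})
        profiles = {"P1": fp("P1", ["a"]), "P2": fp("P2", ["b"])}
        d = SemanticDistanceMatrix({("a", "b"): 8.0})
        _, _, lit = gene_profile_divergence("g", coll, profiles, d, "terms-union")
        _, _, per = gene_profile_divergence("g", coll, profiles, d, "per-pair")
        # one pair, union of two terms: literal = sum/2, per-pair = sum/1
        assert per == pytest.approx(lit * 2)


class TestUpgma:
    def test_two_leaves_join_at_half_distance(self):
        tree = upgma(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].length == pytest.approx(2.0)
        assert tips["B"].length == pytest.approx(2.0)

    @staticmethod
    def brute_force_upgma(ids, mat):
        """Exhaustive agglomeration: always merge the closest pair,
        recomputing arithmetic-mean distances over leaf multiplicities."""
        clusters = {i: (frozenset([ids[i]]), 0.0, ids[i]) for i in range(len(ids))}
        dist = {
            frozenset((i, j)): mat[i, j]
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        }
        merges = []
        nxt = len(ids)
        sizes = {i: 1 for i in range(len(ids))}
        while len(clusters) > 1:
            pair = min(dist, key=lambda p: (dist[p], sorted(p)))
            i, j = sorted(pair)
            h = dist[pair] / 2.0
            members = clusters[i][0] | clusters[j][0]
            merges.append((members, h))
            for k in list(clusters):
                if k in (i, j):
                    continue
                dik = dist[frozenset((i, k))]
                djk = dist[frozenset((j, k))]
                dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
                dist[frozenset((nxt, k))] = dnew
            for p in [p for p in dist if i in p or j in p]:
                del dist[p]
            clusters[nxt] = (members, h, None)
            sizes[nxt] = sizes[i] + sizes[j]
            del clusters[i], clusters[j], sizes[i], sizes[j]
            nxt += 1
        return merges

    @pytest.mark.parametrize("seed", range(10))
    def test_four_leaf_trees_match_exhaustive_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        ids = ["A", "B", "C", "D"]
        vals = rng.uniform(1, 10, size=6)
        mat = np.zeros((4, 4))
        mat[np.triu_indices(4, 1)] = vals
        mat += mat.T
        tree = upgma(ids, mat)
        expected = self.brute_force_upgma(ids, mat)
        # compare clades and their heights
        got = {}
        for node in tree.non_tips(include_self=True):
            clade = frozenset(t.name for t in node.tips())
            # height = distance from node to any descendant tip
            tip = next(iter(node.tips()))
            h = 0.0
            cur = tip
            while cur is not node:
                h += cur.length
                cur = cur.parent
            got[clade] = h
        for members, h in expected:
            assert members in got
            assert got[members] == pytest.approx(h)

    @pytest.mark.parametrize("seed", range(20))
    def test_ultrametric_heights_non_decreasing(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 8
        vals = rng.uniform(1, 10, size=n * (n - 1) // 2)
        mat = np.zeros((n, n))
        mat[np.triu_indices(n, 1)] = vals
        mat += mat.T
        tree = upgma([f"L{i}" for i in range(n)], mat)
        # every tip is equidistant from the root, and parent heights
        # dominate child heights
        depths = [tree.distance(t) for t in tree.tips()]
        assert max(depths) - min(depths) < 1e-9
        for node in tree.non_tips(include_self=True):
            for child in node.children:
                assert child.length >= -1e-12


class TestTreeAndOverlap:
    def test_identical_gene_sets_score_100(self):
        coll = make_collection(
            {"P1": {"a", "b", "c"}, "P2": {"a", "b", "c"}, "P3": {"d", "e", "f"}}
        )
        profiles = {
            "P1": fp("P1", ["t1"]),
            "P2": fp("P2", ["t2"]),
            "P3": fp("P3", ["t3"]),
        }
        d = SemanticDistanceMatrix(
            {("t1", "t2"): 2.0, ("t1", "t3"): 9.0, ("t2", "t3"): 9.0}
        )
        tree, ov = functional_tree_and_overlap(profiles, coll, d)
        assert ov.loc["P1", "P2"] == 100.0
        assert np.isnan(ov.loc["P1", "P1"])  # diagonal masked
        assert ov.loc["P1", "P3"] == 0.0
        # functionally closest pair joined first
        clades = [
            frozenset(t.name for t in node.tips()) for node in tree.non_tips()
        ]
        assert frozenset({"P1", "P2"}) in clades

    def test_subset_pathway_scores_100(self):
        coll = make_collection({"P1": {"a", "b", "c", "d"}, "P2": {"a", "b", "c"}})
        profiles = {"P1": fp("P1", ["t1"]), "P2": fp("P2", ["t2"])}
        d = SemanticDistanceMatrix({("t1", "t2"): 3.0})
        _, ov = functional_tree_and_overlap(profiles, coll, d)
        assert ov.loc["P1", "P2"] == 100.0

    def test_single_pathway_rejected(self):
        coll = make_collection({"P1": {"a", "b", "c"}})
        with pytest.raises(ValueError):
            functional_tree_and_overlap(
                {"P1": fp("P1", ["t"])}, coll, SemanticDistanceMatrix()
            )
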