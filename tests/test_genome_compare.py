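"""Genome statistics, hit filtering, clustering, ANI and UPGMA."""

import numpy as np
import pytest

from phagekit.errors import ValidationError
from phagekit.genome_compare import (
    Feature,
    GenomeRecord,
    HitRecord,
    filter_hits,
    genome_stats,
    greedy_cluster,
    locate_modules,
    orthoani,
    pairwise_identity,
    pan_genome,
    upgma,
)
from phagekit.synthetic_data import gen_genome, mutate_genome

SEED = 37


class TestGenomeStats:
    @pytest.mark.parametrize("seq,gc", [("ATGC", 50.0), ("GGCC", 100.0), ("AATT", 0.0)])
    def test_gc_percent(self, seq, gc):
        assert genome_stats(GenomeRecord("g", seq))[1] == pytest.approx(gc)

    def test_coding_density_merges_overlaps(self):
        g = GenomeRecord(
            "g",
            "A" * 100,
            [
                Feature("CDS", 1, 50, "+"),
                Feature("CDS", 41, 60, "-"),
            ],
        )
        assert genome_stats(g)[2] == pytest.approx(60.0)

    def test_non_cds_features_excluded_from_density(self):
        g = GenomeRecord("g", "A" * 100, [Feature("tRNA", 1, 50, "+")])
        assert genome_stats(g)[2] == 0.0

    def test_empty_sequence_invalid(self):
        with pytest.raises(ValidationError):
            genome_stats(GenomeRecord("g", ""))


class TestFilterHits:
    def _hit(self, ident, cov, e):
        return HitRecord("q", "s", ident, cov, e, 100.0)

    @pytest.mark.parametrize(
        "ident,cov,e,kept",
        [
            (60.0, 90.0, 1e-12, True),
            (49.9, 90.0, 1e-12, False),
            (60.0, 84.9, 1e-12, False),
            (60.0, 90.0, 1e-8, False),
            (50.0, 85.0, 1e-9, True),  # boundary values are inclusive
        ],
    )
    def test_thresholds(self, ident, cov, e, kept):
        assert (len(filter_hits([self._hit(ident, cov, e)])) == 1) is kept


def _gene(start, strand, category, gid):
    return Feature("CDS", start, start + 99, strand, functional_category=category, id=gid)


class TestLocateModules:
    def test_gapped_run_of_four(self):
        feats = [_gene(1 + 200 * i, "+", "", f"PEG.{25 + i}") for i in range(10)]
        # lysis genes at positions 28, 29, 32, 33 with two intervening genes
        for f in feats:
            if f.id in ("PEG.28", "PEG.29", "PEG.32", "PEG.33"):
                f.functional_category = "lysis"
        runs = locate_modules(GenomeRecord("g", "A" * 5000, feats), "lysis")
        assert len(runs) == 1
        assert runs[0].member_ids == ["PEG.28", "PEG.29", "PEG.32", "PEG.33"]

    def test_opposite_strand_splits_run(self):
        feats = [
            _gene(1, "+", "lysis", "a"),
            _gene(201, "-", "lysis", "b"),
            _gene(401, "+", "lysis", "c"),
        ]
        runs = locate_modules(GenomeRecord("g", "A" * 5000, feats), "lysis")
        assert [r.member_ids for r in runs] == [["a"], ["b"], ["c"]]

    def test_large_gap_splits_run(self):
        feats = [_gene(1 + 200 * i, "+", "", f"g{i}") for i in range(8)]
        feats[0].functional_category = "lysis"
        feats[4].functional_category = "lysis"  # 3 intervening genes > max_gap 2
        runs = locate_modules(GenomeRecord("g", "A" * 5000, feats), "lysis")
        assert len(runs) == 2

    def test_no_tagged_genes(self):
        feats = [_gene(1, "+", "", "a")]
        assert locate_modules(GenomeRecord("g", "A" * 5000, feats), "lysis") == []


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGTACGT", "ACGTACGTACGT") == 100.0

    def test_disjoint_alphabet_floor(self):
        assert pairwise_identity("A" * 50, "C" * 50) == 0.0

    def test_substituted_copy_recovers_rate(self, rng):
        g = gen_genome(300, seed=SEED)
        m, n_sub = mutate_genome(g, 0.10, seed=SEED + 1)
        assert pairwise_identity(g.sequence, m.sequence) == pytest.approx(90.0, abs=2.0)


class TestGreedyCluster:
    def test_identical_plus_unrelated(self):
        seqs = [("a", "ACGT" * 30), ("b", "ACGT" * 30), ("c", "TTGG" * 25)]
        clusters = greedy_cluster(seqs)
        assert len(clusters) == 2

    def test_impossible_threshold_all_singletons(self):
        seqs = [("a", "ACGT" * 30), ("b", "ACGT" * 30)]
        assert len(greedy_cluster(seqs, id_threshold=1.01)) == 2

    def test_mutated_family_single_cluster(self):
        seed_genome = gen_genome(300, seed=SEED)
        seqs = [("seed", seed_genome.sequence)]
        for i in range(20):
            m, _ = mutate_genome(seed_genome, 0.20, seed=SEED + i)
            seqs.append((f"m{i}", m.sequence))
        clusters = greedy_cluster(seqs, id_threshold=0.5)
        assert len(clusters) == 1
        assert len(clusters[0][1]) == 21


class TestPanGenome:
    P2G = {"p1": "g1", "p2": "g2", "p3": "g3", "p4": "g1", "p5": "g2", "p6": "g1"}

    def test_partition_definitions(self):
        clusters = [
            ("p1", ["p1", "p2", "p3"]),  # all 3 genomes -> core
            ("p4", ["p4", "p5"]),        # 2 of 3 -> accessory
            ("p6", ["p6"]),              # 1 genome -> unique
        ]
        s = pan_genome(clusters, self.P2G, n_genomes=3)
        assert (s.core_count, s.accessory_count, s.unique_count) == (1, 1, 1)

    def test_counts_conserved_and_core_monotone(self, rng):
        # random clusters over 4 genomes
        genomes = [f"g{i}" for i in range(4)]
        p2g, clusters = {}, []
        pid = 0
        for c in range(30):
            size = rng.integers(1, 5)
            chosen = rng.choice(genomes, size=size, replace=False)
            members = []
            for g in chosen:
                p2g[f"p{pid}"] = g
                members.append(f"p{pid}")
                pid += 1
            clusters.append((members[0], members))
        full = pan_genome(clusters, p2g, n_genomes=4)
        assert full.core_count + full.accessory_count + full.unique_count == len(clusters)
        # removing one genome never increases the core count
        for drop in genomes:
            reduced = [
                (cid, [m for m in members if p2g[m] != drop])
                for cid, members in clusters
            ]
            reduced = [(cid, m) for cid, m in reduced if m]
            r = pan_genome(reduced, p2g, n_genomes=3)
            assert r.core_count >= full.core_count


class TestOrthoANI:
    def test_self_is_100(self):
        g = gen_genome(5000, seed=SEED)
        assert orthoani(g, g, fragment_len=1020) == pytest.approx(100.0)

    def test_mutated_pair_recovers_rate(self):
        g = gen_genome(20_400, seed=SEED)
        m, _ = mutate_genome(g, 0.05, seed=SEED + 1)
        ani = orthoani(g, m)
        assert ani == pytest.approx(95.0, abs=1.0)

    def test_unrelated_genomes_undefined(self):
        a = gen_genome(5000, seed=1)
        b = gen_genome(5000, seed=2)
        assert orthoani(a, b) is None

    def test_too_short_signalled(self):
        with pytest.raises(ValidationError, match="too short"):
            orthoani(gen_genome(1500, seed=1), gen_genome(5000, seed=2))

    def test_symmetry(self):
        g = gen_genome(10_200, seed=SEED)
        m, _ = mutate_genome(g, 0.03, seed=SEED + 5)
        assert abs(orthoani(g, m) - orthoani(m, g)) <= 0.5

    def test_monotone_in_substitution_rate(self):
        rates = [0.0, 0.02, 0.05, 0.10]
        means = []
        for rate in rates:
            vals = []
            for s in range(3):
                g = gen_genome(10_200, seed=100 + s)
                m, _ = mutate_genome(g, rate, seed=200 + s)
                vals.append(orthoani(g, m))
            means.append(np.mean(vals))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestUPGMA:
    def test_manual_three_leaf_trace(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        assert upgma(d, ["A", "B", "C"]) == "((A:1,B:1):2,C:3);"

    def test_two_leaves_closed_form(self):
        d = np.array([[0, 5], [5, 0]], dtype=float)
        assert upgma(d, ["A", "B"]) == "(A:2.5,B:2.5);"

    def test_all_zero_distances_height_zero(self):
        from io import StringIO

        from Bio import Phylo

        d = np.zeros((4, 4))
        tree = Phylo.read(StringIO(upgma(d, list("ABCD"))), "newick")
        for leaf in tree.get_terminals():
            assert tree.distance(tree.root, leaf) == 0.0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValidationError):
            upgma(d, ["A", "B"])

    def test_ultrametric_and_matches_scipy_cophenet(self, rng):
        """Re-parsed tree path lengths equal average-linkage merge heights."""
        from io import StringIO

        from Bio import Phylo
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        n = 7
        cond = rng.uniform(1.0, 10.0, size=n * (n - 1) // 2)
        d = squareform(cond)
        labels = [f"L{i}" for i in range(n)]
        tree = Phylo.read(StringIO(upgma(d, labels)), "newick")
        # ultrametric: all leaves equidistant from the root
        depths = [tree.distance(tree.root, leaf) for leaf in tree.get_terminals()]
        assert np.allclose(depths, depths[0])
        # cophenetic path lengths match scipy's average-linkage heights
        expected = squareform(cophenet(linkage(cond, method="average")))
        leaves = {leaf.name: leaf for leaf in tree.get_terminals()}
        for i in range(n):
            for j in range(i + 1, n):
                path = tree.distance(leaves[f"L{i}"], leaves[f"L{j}"])
                assert path == pytest.approx(expected[i, j], rel=1e-9)
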