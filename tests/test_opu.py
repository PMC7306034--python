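"""OPU clustering, Poisson distances, neighbor joining and bootstrap."""

import io as _io
import math

import numpy as np
import pytest

from ndokit.opu import (
    DistanceMatrix, bootstrap_support, cluster_opus, neighbor_joining,
    pairwise_protein_identity, poisson_distance, prepare_phylo_alignment,
    trim_and_translate,
)
from ndokit.seqcore import reverse_complement
from ndokit.synth import gen_cds, gen_clone_set


class TestTrimAndTranslate:
    def test_round_trip_recovers_planted_protein(self, ndo_pair):
        planted = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        insert = "T" + gen_cds(planted, seed=4)  # T completes the split codon
        amplicon = (ndo_pair.forward.expand()[0] + insert
                    + str(reverse_complement(ndo_pair.reverse.expand()[0])))
        assert trim_and_translate(amplicon, ndo_pair) == planted

    def test_partial_terminal_codon_dropped(self, ndo_pair):
        planted = "MKTAYIAK"
        insert = "T" + gen_cds(planted, seed=4) + "GG"  # ragged end
        amplicon = (ndo_pair.forward.expand()[0] + insert
                    + str(reverse_complement(ndo_pair.reverse.expand()[0])))
        assert trim_and_translate(amplicon, ndo_pair) == planted

    def test_missing_forward_footprint(self, ndo_pair):
        amplicon = "ACGT" * 50 + str(
            reverse_complement(ndo_pair.reverse.expand()[0]))
        with pytest.raises(ValueError, match="forward"):
            trim_and_translate(amplicon, ndo_pair)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_protein_identity("MKTAY", "MKTAY") == 1.0

    def test_three_of_four(self):
        assert pairwise_protein_identity("AAAA", "AAAT") == 0.75

    def test_terminal_overhang_free(self):
        # ragged end should not count against identity
        assert pairwise_protein_identity("MKTAYIAK", "MKTAYIAKQRQ") == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=30))
            b = "".join(rng.choice(aas, size=28))
            assert pairwise_protein_identity(a, b) == \
                pairwise_protein_identity(b, a)


class TestClusterOpus:
    def test_identical_sequences_single_opu(self):
        seqs = {f"c{i:02d}": "MKTAYIAKQR" for i in range(48)}
        part = cluster_opus(seqs, 0.98)
        assert part.n_opus == 1
        assert part.proportions == {1: 1.0}

    def test_planted_42_4_2(self):
        clones = gen_clone_set(
            cluster_spec=[(42, 0.01), (4, 0.01), (2, 0.01)],
            between_divergence=0.1, seed=9)
        part = cluster_opus(clones, 0.98)
        assert part.opu_sizes == {1: 42, 2: 4, 3: 2}
        props = [round(100 * v, 1) for v in part.proportions.values()]
        assert props == [87.5, 8.3, 4.2]

    def test_zero_threshold_single_opu(self):
        clones = gen_clone_set(
            cluster_spec=[(3, 0.01), (3, 0.01)], between_divergence=0.2,
            seed=2)
        assert cluster_opus(clones, 0.0).n_opus == 1

    def test_complete_linkage_guarantee(self):
        clones = gen_clone_set(
            cluster_spec=[(6, 0.02), (5, 0.02)], between_divergence=0.15,
            seed=3)
        part = cluster_opus(clones, 0.97)
        by_opu = {}
        for cid, label in part.members.items():
            by_opu.setdefault(label, []).append(clones[cid])
        for members in by_opu.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    assert pairwise_protein_identity(
                        members[i], members[j]) >= 0.97

    def test_proportions_sum_to_one_labels_by_size(self):
        clones = gen_clone_set(
            cluster_spec=[(2, 0.01), (7, 0.01), (4, 0.01)],
            between_divergence=0.1, seed=4)
        part = cluster_opus(clones, 0.98)
        assert math.isclose(sum(part.proportions.values()), 1.0)
        sizes = list(part.opu_sizes.values())
        assert sizes == sorted(sizes, reverse=True) == [7, 4, 2]


class TestPreparePhyloAlignment:
    def test_gapless_unchanged(self):
        rows = [("a", "MKT"), ("b", "MRT")]
        reduced, n = prepare_phylo_alignment(rows)
        assert reduced == rows and n == 3

    def test_complete_deletion_counts(self):
        rows = [("a", "MKTAYIAKQR"), ("b", "M-TAYIA-QR"), ("c", "MKTAY-AKQR")]
        reduced, n = prepare_phylo_alignment(rows)
        assert n == 7
        assert all(len(s) == 7 for _, s in reduced)

    def test_everything_gapped_errors(self):
        with pytest.raises(ValueError):
            prepare_phylo_alignment([("a", "M-"), ("b", "-K")])


class TestPoissonDistance:
    def test_zero(self):
        assert poisson_distance("MKT", "MKT") == 0.0

    def test_closed_form(self):
        a = "A" * 10
        b = "C" + "A" * 9  # p = 0.1
        assert poisson_distance(a, b) == pytest.approx(0.105361, abs=1e-6)

    def test_saturation(self):
        with pytest.raises(ValueError):
            poisson_distance("AAA", "CCC")

    def test_correction_inflates_and_is_monotone(self):
        base = "A" * 20
        last = 0.0
        for k in range(1, 19):
            other = "C" * k + "A" * (20 - k)
            d = poisson_distance(base, other)
            assert d >= k / 20
            assert d > last
            last = d


def _random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree as an edge list; returns (edges, taxa)."""
    edges = {}  # node -> {neighbor: length}

    def add_edge(u, v, w):
        edges.setdefault(u, {})[v] = w
        edges.setdefault(v, {})[u] = w

    def drop_edge(u, v):
        del edges[u][v]
        del edges[v][u]

    add_edge("t0", "t1", float(rng.uniform(0.1, 1.0)))
    internal = 0
    for k in range(2, n_taxa):
        pairs = [(u, v) for u in edges for v in edges[u] if u < v]
        u, v = pairs[int(rng.integers(len(pairs)))]
        w = edges[u][v]
        internal += 1
        mid = f"i{internal}"
        split = float(rng.uniform(0.2, 0.8))
        drop_edge(u, v)
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, f"t{k}", float(rng.uniform(0.1, 1.0)))
    taxa = [f"t{i}" for i in range(n_taxa)]
    return edges, taxa


def _path_distances(edges, taxa):
    import collections

    n = len(taxa)
    m = np.zeros((n, n))
    for i, src in enumerate(taxa):
        dist = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            u = queue.popleft()
            for v, w in edges[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for j, dst in enumerate(taxa):
            m[i, j] = dist[dst]
    return (m + m.T) / 2.0  # exact symmetry despite summation order


def _tip_distances_from_newick(newick, taxa):
    import skbio

    tree = skbio.TreeNode.read(_io.StringIO(newick))
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.find(taxa[i]).distance(tree.find(taxa[j]))
            m[i, j] = m[j, i] = d
    return m


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(("a", "b", "c"),
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        newick = neighbor_joining(dm)
        assert "a:1.0" in newick and "b:2.0" in newick and "c:3.0" in newick

    def test_classic_four_taxon_matrix(self):
        dm = DistanceMatrix(
            ("a", "b", "c", "d"),
            np.array([[0, 5, 9, 9], [5, 0, 10, 10],
                      [9, 10, 0, 8], [9, 10, 8, 0]], float))
        got = _tip_distances_from_newick(neighbor_joining(dm), list(dm.ids))
        assert np.allclose(got, dm.matrix)

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_additive_matrix_exactly_inverted(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        edges, taxa = _random_additive_tree(n_taxa, rng)
        dm = DistanceMatrix(tuple(taxa), _path_distances(edges, taxa))
        newick = neighbor_joining(dm)
        got = _tip_distances_from_newick(newick, taxa)
        assert np.allclose(got, dm.matrix, atol=1e-9)

    def test_topology_matches_reference_nj(self):
        import skbio

        rng = np.random.default_rng(11)
        edges, taxa = _random_additive_tree(7, rng)
        m = _path_distances(edges, taxa)
        mine = skbio.TreeNode.read(_io.StringIO(
            neighbor_joining(DistanceMatrix(tuple(taxa), m))))
        ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids=taxa))
        assert mine.compare_rfd(ref) == 0.0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))

    def test_ultrametric_matches_single_linkage_grouping(self):
        # nested ultrametric distances: ((a,b),c),d
        dm = DistanceMatrix(
            ("a", "b", "c", "d"),
            np.array([[0, 2, 6, 10], [2, 0, 6, 10],
                      [6, 6, 0, 10], [10, 10, 10, 0]], float))
        newick = neighbor_joining(dm)
        import skbio

        tree = skbio.TreeNode.read(_io.StringIO(newick))
        ab = tree.lowest_common_ancestor(["a", "b"])
        assert {t.name for t in ab.tips()} == {"a", "b"}


class TestBootstrap:
    def test_clean_split_full_support(self):
        rows = [("a", "A" * 20), ("b", "A" * 20),
                ("c", "T" * 10 + "A" * 10), ("d", "T" * 10 + "A" * 10)]
        support = bootstrap_support(rows, n_reps=100, seed=1)
        assert len(support) == 1
        assert list(support.values())[0] == 100.0

    def test_reproducible_and_bounded(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base = rng.choice(aas, size=60)
        rows = []
        for i in range(6):
            seq = base.copy()
            k = 3 * (i + 1)
            sites = rng.choice(60, size=k, replace=False)
            for s in sites:
                seq[s] = aas[int(rng.integers(20))]
            rows.append((f"x{i}", "".join(seq)))
        s1 = bootstrap_support(rows, n_reps=50, seed=7)
        s2 = bootstrap_support(rows, n_reps=50, seed=7)
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())
        s3 = bootstrap_support(rows, n_reps=50, seed=8)
        assert set(s3) == set(s1)  # same reference splits
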