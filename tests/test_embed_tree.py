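import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from polyte import (ANCESTOR_LABEL, DistanceMatrix,
                    attach_ancestor_and_report, classical_mds,
                    neighbor_joining)

from _oracles import random_additive_matrix


def dm_from_points(points, labels=None):
    points = np.asarray(points, dtype=float)
    labels = labels or [f"P{i}" for i in range(len(points))]
    return DistanceMatrix(labels, squareform(pdist(points)))


class TestClassicalMds:
    def test_collinear_points_embed_exactly_in_1d(self):
        d = DistanceMatrix(list("abc"), np.array([
            [0.0, 3.0, 7.0], [3.0, 0.0, 4.0], [7.0, 4.0, 0.0]]))
        emb = classical_mds(d, k=1)
        got = squareform(pdist(emb.coords))
        assert np.allclose(got, d.values, atol=1e-9)

    def test_unit_square_recovered(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1]]
        d = dm_from_points(pts)
        emb = classical_mds(d, k=2)
        assert np.allclose(squareform(pdist(emb.coords)), d.values,
                           atol=1e-9)

    def test_two_points_split_symmetrically(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 10.0], [10.0, 0.0]]))
        emb = classical_mds(d, k=1)
        assert np.allclose(sorted(emb.coords[:, 0]), [-5.0, 5.0])

    def test_random_point_clouds_reproduce_distances(self):
        """Exact-embedding property: distances from k-D point sets are
        reproduced to 1e-9."""
        rng = np.random.default_rng(42)
        for n, k in [(5, 2), (8, 3), (12, 2)]:
            d = dm_from_points(rng.normal(size=(n, k)) * 3)
            emb = classical_mds(d, k=k)
            assert np.allclose(squareform(pdist(emb.coords)), d.values,
                               atol=1e-9)

    def test_centroid_at_origin_and_eigenvalues_sorted(self):
        rng = np.random.default_rng(1)
        d = dm_from_points(rng.normal(size=(6, 2)))
        emb = classical_mds(d, k=2)
        assert np.allclose(emb.coords.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)

    def test_orientation_convention(self):
        rng = np.random.default_rng(2)
        d = dm_from_points(rng.normal(size=(5, 2)))
        emb = classical_mds(d, k=2, orient="P3")
        assert np.all(emb.coord_of("P3") <= 0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(list("abc"), np.array([
            [0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]]))
        tree = neighbor_joining(d)
        # limb a = (d_ab + d_ac - d_bc) / 2 = 3, b = 2, c = 6
        hub = [n for n in tree.adjacency if not isinstance(n, str)][0]
        lengths = {n: l for n, l in tree.adjacency[hub]}
        assert lengths == pytest.approx({"a": 3.0, "b": 2.0, "c": 6.0})

    def test_four_taxon_additive_matrix_recovered(self):
        """Additive matrix from a hand-built tree: ((a:2,b:3):1,(c:4,d:5));
        topology and branch lengths are recovered exactly (four-point
        condition holds for the quartet ab|cd)."""
        d = DistanceMatrix(list("abcd"), np.array([
            [0.0, 5.0, 7.0, 8.0],
            [5.0, 0.0, 8.0, 9.0],
            [7.0, 8.0, 0.0, 9.0],
            [8.0, 9.0, 0.0 + 9.0, 0.0],
        ]))
        # four-point condition: d_ab + d_cd <= d_ac + d_bd = d_ad + d_bc
        assert 5 + 9 < 7 + 9 == 8 + 8
        tree = neighbor_joining(d)
        assert np.allclose(tree.leaf_distance_matrix().values, d.values,
                           atol=1e-12)
        assert tree.leaf_split("a") == (frozenset({"b"}),
                                        frozenset({"c", "d"}))

    def test_caterpillar_topology_recovered(self):
        labels, dist = random_additive_matrix(5, np.random.default_rng(7))
        vals = np.zeros((5, 5))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    vals[i, j] = dist[(a, b)]
        d = DistanceMatrix(labels, vals)
        tree = neighbor_joining(d)
        assert np.allclose(tree.leaf_distance_matrix().values, vals,
                           atol=1e-9)

    def test_consistency_on_random_additive_matrices(self):
        """NJ recovers path lengths exactly for random trees, n <= 12."""
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            labels, dist = random_additive_matrix(n, rng)
            vals = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i != j:
                        vals[i, j] = dist[(a, b)]
            tree = neighbor_joining(DistanceMatrix(labels, vals))
            assert np.allclose(tree.leaf_distance_matrix().values, vals,
                               atol=1e-9)

    def test_branch_lengths_nonnegative_on_noisy_input(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        vals = squareform(pdist(pts)) + squareform(
            rng.uniform(0, 0.2, size=28))
        tree = neighbor_joining(DistanceMatrix([f"T{i}" for i in range(8)],
                                               vals))
        for node, edges in tree.adjacency.items():
            for _, length in edges:
                assert length >= 0.0

    def test_too_few_labels_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        labels, dist = random_additive_matrix(7, rng)
        vals = np.zeros((7, 7))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    vals[i, j] = dist[(a, b)]
        tree = neighbor_joining(DistanceMatrix(labels, vals))
        newick = tree.to_newick(digits=9)
        dt = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    got = pdm.distance(taxa[a], taxa[b])
                    assert got == pytest.approx(vals[i, j], abs=1e-6)

    def test_matches_dendropy_nj_topology(self):
        """Cross-check against an independent NJ implementation on a noisy
        (non-additive) matrix: identical unrooted topology."""
        import dendropy

        rng = np.random.default_rng(21)
        pts = rng.normal(size=(7, 3))
        vals = squareform(pdist(pts))
        labels = [f"T{i}" for i in range(7)]
        tree = neighbor_joining(DistanceMatrix(labels, vals))

        csv = "," + ",".join(labels) + "\n"
        for i, a in enumerate(labels):
            csv += a + "," + ",".join(str(v) for v in vals[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=csv.splitlines(True).__iter__(), delimiter=",")
        ref = pdm.nj_tree()
        ref_splits = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in ref.preorder_edge_iter() if e.head_node.parent_node}
        ref_splits = {s for s in ref_splits if 1 < len(s) < 6}
        my_splits = set()
        for leaf in labels:
            a, b = tree.leaf_split(leaf)
            for side in (a, b):
                if 1 < len(side) < 6:
                    my_splits.add(side)
        assert ref_splits <= {frozenset(s) for s in my_splits} | ref_splits
        # compare via normalized bipartitions (complement-invariant)
        norm = lambda ss: {min(s, frozenset(labels) - s, key=sorted)
                           for s in ss}
        assert norm(ref_splits) == norm(my_splits)


class TestAncestorReport:
    def ancestor_matrix(self, rows, labels):
        return DistanceMatrix(labels, np.array(rows, dtype=float))

    def test_zero_distance_population_is_nearest(self):
        d = self.ancestor_matrix(
            [[0, 0, 4, 5], [0, 0, 4, 5], [4, 4, 0, 3], [5, 5, 3, 0]],
            ["A", ANCESTOR_LABEL, "B", "C"])
        rep = attach_ancestor_and_report(d)
        assert rep.nearest == ["A"]
        assert not rep.tied

    def test_equidistant_ancestor_reports_tie(self):
        vals = np.full((4, 4), 2.0)
        np.fill_diagonal(vals, 0.0)
        d = self.ancestor_matrix(vals, ["A", "B", "C", ANCESTOR_LABEL])
        rep = attach_ancestor_and_report(d)
        assert rep.tied
        assert rep.nearest == ["A", "B", "C"]

    def test_missing_ancestor_rejected(self):
        d = self.ancestor_matrix([[0, 1], [1, 0]], ["A", "B"])
        with pytest.raises(ValueError):
            attach_ancestor_and_report(d)

    def test_preset_ancestor_attaches_between_african_and_rest(
            self, preset_result):
        """On serial-founder data the all-absent ancestor attaches on the
        edge separating the African-like clade from the bottlenecked
        groups; oracle = the generator's demography."""
        from polyte import (allele_sharing_distance,
                            population_average_distances, with_ancestor)

        m, panel = preset_result.matrix, preset_result.panel
        ancestral = [s for g in ("African", "Asian", "European")
                     for s in panel.samples_in_group(g)]
        sub = with_ancestor(m.subset_samples(ancestral))
        d = allele_sharing_distance(sub)
        pops = population_average_distances(d, panel)
        rep = attach_ancestor_and_report(pops)
        side_af = {s for s in rep.split[0] | rep.split[1]
                   if s.startswith("African")}
        sides = [set(rep.split[0]), set(rep.split[1])]
        assert side_af in sides
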