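"""Nodal network/statistical features against brute-force oracles."""

import numpy as np
import pytest

from connectogat import (
    ConnectivityMatrix,
    assemble_multimodal_features,
    compute_network_features,
    compute_statistical_features,
    detect_communities,
    minmax_normalize,
    subject_features,
)
from connectogat.features import CommunityPartition, NodeFeatureMatrix

from oracles import (
    brute_betweenness,
    brute_clustering,
    brute_local_efficiency,
    brute_nodal_modularity,
    brute_participation,
    newman_q,
    random_weighted_graph,
)


def cmat(w, modality="SC"):
    return ConnectivityMatrix(w, modality)


class TestCommunities:
    def test_two_disconnected_cliques_split_into_two_modules(self):
        w = np.zeros((8, 8))
        for grp in (range(4), range(4, 8)):
            for i in grp:
                for j in grp:
                    if i != j:
                        w[i, j] = 1.0
        part = detect_communities(cmat(w), seed=0)
        assert part.n_modules == 2
        assert len(set(part.assignment[:4])) == 1
        assert len(set(part.assignment[4:])) == 1
        assert part.assignment[0] != part.assignment[4]

    def test_deterministic_for_fixed_seed(self):
        w = random_weighted_graph(np.random.default_rng(1), 12)
        a = detect_communities(cmat(w), seed=3)
        b = detect_communities(cmat(w), seed=3)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert a.modularity_q == b.modularity_q

    def test_edgeless_graph_degenerates_to_singletons(self):
        part = detect_communities(cmat(np.zeros((5, 5))), seed=0)
        assert part.n_modules == 5
        assert part.modularity_q == 0.0

    def test_q_matches_direct_summation_on_toy_graph(self):
        # two unit-weight triangles joined by a single bridge edge
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
            w[i, j] = w[j, i] = 1.0
        assignment = np.array([0, 0, 0, 1, 1, 1])
        part = detect_communities(cmat(w), seed=0)
        np.testing.assert_array_equal(part.assignment, assignment)
        assert part.modularity_q == pytest.approx(newman_q(w, assignment), abs=1e-12)


class TestNetworkMeasuresOracles:
    @pytest.mark.parametrize("n,seed", [(6, 0), (8, 1), (10, 2), (10, 3)])
    def test_all_seven_measures_match_brute_force(self, n, seed):
        w = random_weighted_graph(np.random.default_rng(seed), n, p=0.4)
        m = cmat(w)
        part = detect_communities(m, seed=0)
        feats = compute_network_features(m, part)
        np.testing.assert_allclose(feats[:, 0], brute_clustering(w), atol=1e-9)
        np.testing.assert_allclose(feats[:, 1], brute_betweenness(w), atol=1e-8)
        np.testing.assert_allclose(feats[:, 2], (w > 0).sum(axis=1), atol=0)
        np.testing.assert_allclose(feats[:, 3], w.sum(axis=1), atol=1e-12)
        np.testing.assert_allclose(
            feats[:, 4], brute_local_efficiency(w), atol=1e-9
        )
        np.testing.assert_allclose(
            feats[:, 5], brute_nodal_modularity(w, part.assignment), atol=1e-12
        )
        np.testing.assert_allclose(
            feats[:, 6], brute_participation(w, part.assignment), atol=1e-12
        )

    def test_unweighted_triangle_has_unit_clustering_zero_betweenness(self):
        w = 1.0 - np.eye(3)
        feats = compute_network_features(cmat(w))
        np.testing.assert_allclose(feats[:, 0], 1.0)
        np.testing.assert_allclose(feats[:, 1], 0.0)

    def test_star_center_betweenness_counts_dependent_pairs(self):
        n = 5  # center 0 with 4 leaves: 6 leaf pairs route through center
        w = np.zeros((n, n))
        w[0, 1:] = w[1:, 0] = 1.0
        feats = compute_network_features(cmat(w))
        assert feats[0, 1] == pytest.approx(6.0)
        np.testing.assert_allclose(feats[1:, 1], 0.0)

    def test_all_edges_in_one_module_gives_zero_participation(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = w[0, 2] = w[2, 0] = 1.0
        part = CommunityPartition(np.array([0, 0, 0, 1, 1]), 0.0, 0)
        feats = compute_network_features(cmat(w), part)
        assert feats[0, 6] == 0.0

    def test_nodal_modularity_sums_to_global_q(self):
        w = random_weighted_graph(np.random.default_rng(5), 12, p=0.5)
        m = cmat(w)
        part = detect_communities(m, seed=1)
        feats = compute_network_features(m, part)
        assert feats[:, 5].sum() == pytest.approx(part.modularity_q, abs=1e-10)

    def test_strength_equals_degree_for_unit_weights(self):
        rng = np.random.default_rng(6)
        w = (random_weighted_graph(rng, 9, p=0.5) > 0).astype(float)
        feats = compute_network_features(cmat(w))
        np.testing.assert_array_equal(feats[:, 2], feats[:, 3])

    def test_measure_ranges(self):
        w = random_weighted_graph(np.random.default_rng(7), 10, p=0.6)
        w = w / w.max()
        feats = compute_network_features(cmat(w))
        assert np.all((feats[:, 0] >= 0) & (feats[:, 0] <= 1))  # CC
        assert np.all((feats[:, 6] >= 0) & (feats[:, 6] < 1))  # PC

    def test_isolated_node_measures_are_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        feats = compute_network_features(cmat(w))
        np.testing.assert_allclose(feats[3], [0, 0, 0, 0, 0, 0, 0], atol=1e-12)

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(8)
        w = random_weighted_graph(rng, 9, p=0.5)
        m = cmat(w)
        part = detect_communities(m, seed=0)
        feats = compute_network_features(m, part)
        perm = rng.permutation(9)
        wp = w[np.ix_(perm, perm)]
        part_p = CommunityPartition(
            np.asarray(part.assignment)[perm], part.modularity_q, 0
        )
        feats_p = compute_network_features(cmat(wp), part_p)
        np.testing.assert_allclose(feats_p, feats[perm], atol=1e-9)

    def test_fc_negative_weights_zeroed_before_network_measures(self):
        a = np.zeros((4, 4))
        a[0, 1], a[2, 3] = 0.5, -0.5
        m = cmat(a + a.T, "FC")
        feats = compute_network_features(m)
        assert feats[2, 2] == 0 and feats[2, 3] == 0  # negative edge ignored


class TestStatisticalFeatures:
    def row_matrix(self, row):
        """Symmetric matrix whose node-0 off-diagonal row equals ``row``."""
        n = len(row) + 1
        a = np.zeros((n, n))
        a[0, 1:] = row
        return cmat(a + a.T, "FC")

    def test_known_moments(self):
        stats = compute_statistical_features(self.row_matrix([1, 2, 3, 4]))
        assert stats[0, 0] == pytest.approx(2.5)
        assert stats[0, 1] == pytest.approx(1.1180, abs=5e-5)  # population std

    def test_constant_row_convention(self):
        stats = compute_statistical_features(self.row_matrix([2.0, 2.0, 2.0]))
        assert stats[0, 1] == 0 and stats[0, 2] == 0 and stats[0, 3] == 0

    def test_symmetric_row_has_zero_skew(self):
        stats = compute_statistical_features(self.row_matrix([-0.4, 0.0, 0.4]))
        assert stats[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_inclusion_flag(self):
        m = self.row_matrix([1.0, 0.0, 0.0, 3.0])
        with_zeros = compute_statistical_features(m)
        without = compute_statistical_features(m, include_zeros=False)
        assert with_zeros[0, 0] == pytest.approx(1.0)
        assert without[0, 0] == pytest.approx(2.0)


class TestAssembly:
    def test_default_multimodal_assembly_is_86x24(self):
        n = 86
        f = assemble_multimodal_features(
            np.zeros((n, 2)), np.zeros((n, 7)), np.zeros((n, 4)),
            np.zeros((n, 7)), np.zeros((n, 4)),
        )
        assert f.values.shape == (86, 24)
        structural = [t in ("morphological", "structural") for t in f.modality_tags]
        assert sum(structural) == 13
        assert f.modality_tags.count("functional") == 11
        assert f.feature_names[:2] == ["VOL", "CT"]
        assert "SC_mean" in f.feature_names and "FC_BC" in f.feature_names

    def test_unimodal_variants_have_eleven_columns(self):
        n = 10
        sc_only = assemble_multimodal_features(
            None, np.zeros((n, 7)), np.zeros((n, 4)), None, None
        )
        fc_only = assemble_multimodal_features(
            None, None, None, np.zeros((n, 7)), np.zeros((n, 4))
        )
        assert sc_only.n_features == 11 and fc_only.n_features == 11

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node count"):
            assemble_multimodal_features(
                np.zeros((5, 2)), np.zeros((6, 7)), np.zeros((5, 4)),
                np.zeros((5, 7)), np.zeros((5, 4)),
            )

    def test_subject_features_row_equivariance(self, micro_cohort):
        cohort, _ = micro_cohort
        s = cohort.subjects[0]
        f = subject_features(s.sc, s.fc, s.morphology, seed=0)
        perm = np.array([3, 1, 5, 0, 2, 4])
        sp = ConnectivityMatrix(s.sc.values[np.ix_(perm, perm)], "SC")
        fp = ConnectivityMatrix(s.fc.values[np.ix_(perm, perm)], "FC")
        f2 = subject_features(sp, fp, s.morphology[perm], seed=0)
        # statistical + morphology columns permute exactly; community-dependent
        # columns (Mod, PC) may differ when Louvain finds a different partition
        cols = [i for i, name in enumerate(f.feature_names)
                if not name.endswith(("Mod", "PC"))]
        np.testing.assert_allclose(
            f2.values[:, cols], f.values[perm][:, cols], atol=1e-9
        )


class TestMinMax:
    def make(self, values):
        values = np.asarray(values, dtype=float)
        f = values.shape[1]
        return NodeFeatureMatrix(values, [f"f{i}" for i in range(f)], ["structural"] * f)

    def test_affine_map_of_single_feature(self):
        train = [self.make([[2.0], [4.0], [6.0]])]
        tr, _, _ = minmax_normalize(train)
        np.testing.assert_allclose(tr[0].values[:, 0], [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        train = [self.make([[5.0, 1.0], [5.0, 2.0]])]
        tr, _, _ = minmax_normalize(train)
        np.testing.assert_allclose(tr[0].values[:, 0], 0.0)

    def test_round_trip_inversion(self):
        rng = np.random.default_rng(0)
        train = [self.make(rng.uniform(-3, 7, size=(6, 4))) for _ in range(3)]
        tr, _, scaler = minmax_normalize(train)
        back = scaler.inverse_transform(tr)
        for orig, rec in zip(train, back):
            np.testing.assert_allclose(rec.values, orig.values, atol=1e-12)

    def test_held_out_can_exceed_unit_interval(self):
        train = [self.make([[0.0], [1.0]])]
        other = [self.make([[2.0]])]
        _, ot, _ = minmax_normalize(train, other)
        assert ot[0].values[0, 0] == pytest.approx(2.0)

    def test_empty_training_list_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([])
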