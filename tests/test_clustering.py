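import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from cuticle_course.clustering import (DistanceMatrix, build_dendrogram,
                                       gene_trajectory_distances, js_distance,
                                       pam, sample_distance_matrix, silhouette,
                                       to_probability_profile)
from cuticle_course.io_model import DEFAULT_GRID, ExpressionMatrix


def euclid_1d(points):
    ids = tuple(str(i) for i in range(len(points)))
    pts = np.asarray(points, float)
    return DistanceMatrix(ids, np.abs(pts[:, None] - pts[None, :]))


class TestProbabilityProfile:
    def test_uniform(self):
        np.testing.assert_allclose(to_probability_profile([1, 1, 1, 1]),
                                   [0.25] * 4)

    def test_zero_entry_preserved(self):
        np.testing.assert_allclose(to_probability_profile([0, 10]), [0, 1])

    def test_random_vectors_sum_to_one(self, rng):
        for _ in range(20):
            v = rng.gamma(1.0, 5.0, size=rng.integers(2, 12))
            assert abs(to_probability_profile(v).sum() - 1) < 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            to_probability_profile([0, 0, 0])


class TestJSDistance:
    def test_identity(self):
        assert js_distance([0.3, 0.7], [0.3, 0.7]) == 0

    def test_disjoint_supports_max_out_at_one(self):
        assert math.isclose(js_distance([1, 0], [0, 1]), 1.0, abs_tol=1e-12)

    def test_half_overlap_value(self):
        # sqrt(0.5*1*log2(2) + 0.5*(0.5*log2(0.5/0.75)+0.5*log2(0.5/0.25)))... direct
        assert math.isclose(js_distance([1, 0], [0.5, 0.5]), 0.557922,
                            abs_tol=1e-5)

    def test_cross_check_against_scipy(self, rng):
        for _ in range(50):
            n = rng.integers(2, 10)
            p = to_probability_profile(rng.gamma(1.0, 1.0, n))
            q = to_probability_profile(rng.gamma(1.0, 1.0, n))
            assert math.isclose(js_distance(p, q),
                                float(jensenshannon(p, q, base=2)),
                                abs_tol=1e-10)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 8))
            p, q, r = (to_probability_profile(rng.gamma(0.5, 1.0, n) + 1e-12)
                       for _ in range(3))
            dpq, dqr, dpr = js_distance(p, q), js_distance(q, r), js_distance(p, r)
            assert dpq >= 0 and dpq <= 1
            assert math.isclose(dpq, js_distance(q, p), abs_tol=1e-12)
            assert dpr <= dpq + dqr + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            js_distance([1, 0], [1, 0, 0])


class TestSampleDistances:
    def test_duplicate_columns_distance_zero(self, grid):
        fpkm = np.ones((4, 7))
        fpkm[:, 0] = fpkm[:, 1] = [1, 2, 3, 4]
        m = ExpressionMatrix(("a", "b", "c", "d"), grid, fpkm)
        d = sample_distance_matrix(m)
        assert d.d[0, 1] == 0

    def test_two_columns_equal_profile_distance(self, rng):
        from cuticle_course.io_model import TimeGrid
        fpkm = rng.gamma(2.0, 5.0, size=(20, 2))
        m = ExpressionMatrix(tuple(f"g{i}" for i in range(20)),
                             TimeGrid((42, 52)), fpkm)
        d = sample_distance_matrix(m)
        expected = js_distance(fpkm[:, 0] / fpkm[:, 0].sum(),
                               fpkm[:, 1] / fpkm[:, 1].sum())
        assert math.isclose(d.d[0, 1], expected, abs_tol=1e-12)

    def test_zero_column_rejected(self, grid):
        fpkm = np.ones((3, 7))
        fpkm[:, 2] = 0
        m = ExpressionMatrix(("a", "b", "c"), grid, fpkm)
        with pytest.raises(ValueError, match="62"):
            sample_distance_matrix(m)


class TestDendrogram:
    def test_two_items_single_merge(self):
        d = euclid_1d([0, 3])
        tree = build_dendrogram(d)
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.linkage_matrix[0, 2] == 3
        assert tree.to_newick().endswith(";")

    def test_tight_pairs_merge_first(self):
        d = euclid_1d([0, 1, 10, 11])
        tree = build_dendrogram(d)
        first_two = {tuple(sorted(row[:2])) for row in tree.linkage_matrix[:2]}
        assert first_two == {(0, 1), (2, 3)}

    def test_ultrametric_input_same_tree_all_linkages(self):
        # two tight pairs at mutual distance 5: ultrametric
        ids = ("a", "b", "c", "d")
        d = np.array([[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]],
                     float)
        dm = DistanceMatrix(ids, d)
        newicks = {build_dendrogram(dm, lk).to_newick()
                   for lk in ("average", "complete", "single")}
        assert len(newicks) == 1

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            build_dendrogram(DistanceMatrix(("a",), np.zeros((1, 1))))


class TestPAM:
    def test_k_equals_n_zero_cost(self):
        d = euclid_1d([0, 1, 10, 11])
        model = pam(d, 4)
        assert model.total_cost == 0
        assert set(model.medoids) == set(d.item_ids)

    def test_two_tight_pairs(self):
        model = pam(euclid_1d([0, 1, 10, 11]), 2)
        assert model.total_cost == 2
        clusters = {model.assignment["0"], model.assignment["1"]}
        assert len(clusters) == 1
        assert model.assignment["2"] == model.assignment["3"]
        assert model.assignment["0"] != model.assignment["2"]

    @pytest.mark.parametrize("n,k", [(5, 2), (7, 3), (9, 2), (9, 4)])
    def test_cost_equals_brute_force_optimum(self, rng, n, k):
        for _ in range(5):
            pts = rng.uniform(0, 100, n)
            d = euclid_1d(pts)
            model = pam(d, k)
            best = min(
                d.d[:, list(meds)].min(axis=1).sum()
                for meds in itertools.combinations(range(n), k))
            assert math.isclose(model.total_cost, best, abs_tol=1e-9)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            pam(euclid_1d([0, 1]), 3)

    def test_deterministic(self, rng):
        pts = rng.uniform(0, 10, 30)
        d = euclid_1d(pts)
        m1, m2 = pam(d, 4), pam(d, 4)
        assert m1.assignment == m2.assignment and m1.medoids == m2.medoids


class TestGeneTrajectoryDistances:
    def test_proportional_genes_distance_zero(self, grid):
        base = np.array([1, 5, 2, 8, 3, 1, 1], float)
        m = ExpressionMatrix(("a", "b"), grid, np.vstack([base, 10 * base]))
        d = gene_trajectory_distances(m)
        assert d.d[0, 1] < 1e-12

    def test_disjoint_spikes_distance_one(self, grid):
        fpkm = np.zeros((2, 7))
        fpkm[0, 0] = fpkm[1, 6] = 5
        m = ExpressionMatrix(("s42", "s96"), grid, fpkm)
        assert math.isclose(gene_trajectory_distances(m).d[0, 1], 1,
                            abs_tol=1e-12)

    def test_matches_composition_of_primitives(self, rng, grid):
        fpkm = rng.gamma(2.0, 5.0, size=(6, 7))
        m = ExpressionMatrix(tuple(f"g{i}" for i in range(6)), grid, fpkm)
        d = gene_trajectory_distances(m)
        for i, j in itertools.combinations(range(6), 2):
            expected = js_distance(to_probability_profile(fpkm[i]),
                                   to_probability_profile(fpkm[j]))
            assert math.isclose(d.d[i, j], expected, abs_tol=1e-12)

    def test_assignment_invariant_under_per_gene_rescaling(self, rng, grid):
        fpkm = rng.gamma(2.0, 10.0, size=(40, 7))
        ids = tuple(f"g{i:02d}" for i in range(40))
        m1 = ExpressionMatrix(ids, grid, fpkm)
        m2 = ExpressionMatrix(ids, grid,
                              fpkm * rng.uniform(0.01, 100, 40)[:, None])
        a1 = pam(gene_trajectory_distances(m1), 4).assignment
        a2 = pam(gene_trajectory_distances(m2), 4).assignment
        assert a1 == a2


class TestSilhouette:
    def test_hand_computed_example(self):
        model = pam(euclid_1d([0, 1, 10, 11]), 2)
        sil, per_cluster = silhouette(model, euclid_1d([0, 1, 10, 11]))
        assert math.isclose(sil["0"], (10.5 - 1) / 10.5, abs_tol=1e-12)
        assert all(0 < s <= 1 for s in sil.values())

    def test_identical_items_score_zero(self):
        d = DistanceMatrix(("a", "b", "c", "d"), np.zeros((4, 4)))
        model = pam(d, 2)
        sil, _ = silhouette(model, d)
        assert all(s == 0 for s in sil.values())

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import silhouette_samples
        pts = np.concatenate([rng.uniform(0, 5, 4), rng.uniform(40, 45, 4),
                              rng.uniform(90, 95, 4)])
        d = euclid_1d(pts)
        model = pam(d, 3)
        assert min(model.cluster_sizes.values()) >= 2
        sil, _ = silhouette(model, d)
        labels = [model.assignment[i] for i in d.item_ids]
        ref = silhouette_samples(d.d, labels, metric="precomputed")
        np.testing.assert_allclose([sil[i] for i in d.item_ids], ref,
                                   atol=1e-10)
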