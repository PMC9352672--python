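"""Behaviour map: embedding, density/watershed regions, post-embedding."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from motifscope import behaviour_map as bm

from conftest import make_cluster_features


class TestTrainEmbedding:
    def test_separated_clusters_stay_separated_in_2d(self, cluster_data,
                                                     small_model):
        _, y = cluster_data
        assert silhouette_score(small_model.training_embedding, y) > 0.5

    def test_too_few_points_raise(self):
        X, _ = make_cluster_features(n_clusters=1, n_per=20)
        with pytest.raises(ValueError):
            bm.train_embedding(X, perplexity=10)

    def test_deterministic_given_seed(self):
        X, _ = make_cluster_features(n_clusters=2, n_per=40, seed=5)
        e1 = bm.train_embedding(X, perplexity=10, seed=3).training_embedding
        e2 = bm.train_embedding(X, perplexity=10, seed=3).training_embedding
        np.testing.assert_array_equal(e1, e2)


class TestBehaviourMap:
    def test_planted_clusters_recovered_as_regions(self, cluster_data,
                                                   small_model, small_map):
        _, y = cluster_data
        assert 3 <= small_map.n_regions <= 5
        pred = [small_map.region_at(xy) for xy in small_model.training_embedding]
        assert adjusted_rand_score(y, pred) >= 0.8

    def test_single_tight_cluster_gives_one_region(self):
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(1, 0.01, (60, 20)))
        emb = rng.normal(0, 1.0, (60, 2))  # one 2D blob
        model = bm.EmbeddingModel(X, emb, 10.0, 0)
        bmap = bm.build_behaviour_map(model, kernel_bandwidth=2.0,
                                      min_peak_distance=2.0)
        assert bmap.n_regions == 1

    def test_uniform_scatter_does_not_crash(self):
        rng = np.random.default_rng(1)
        X = np.abs(rng.normal(1, 0.3, (200, 20)))
        emb = rng.uniform(-50, 50, (200, 2))
        model = bm.EmbeddingModel(X, emb, 10.0, 0)
        bmap = bm.build_behaviour_map(model, kernel_bandwidth="auto",
                                      min_peak_distance="auto")
        assert bmap.n_regions >= 1

    def test_every_grid_cell_is_labelled(self, small_map):
        assert small_map.regions.min() >= 1
        assert len(small_map.peaks) == len(small_map.label_names)

    def test_point_outside_grid_is_unlabelled(self, small_map):
        far = small_map.origin - 10 * small_map.cell_size
        assert small_map.region_at(far) is None


class TestConditionalDistributions:
    def test_p_sums_to_one_and_matches_target_perplexity(self):
        rng = np.random.default_rng(0)
        for perp in (5.0, 15.0, 30.0):
            D = rng.uniform(0.1, 5.0, int(3 * perp))
            p, sigma = bm.conditional_p(D, perp)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            H = -(p[p > 0] * np.log2(p[p > 0])).sum()
            assert 2 ** H == pytest.approx(perp, rel=0.01)
            assert sigma > 0

    def test_q_sums_to_one(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(0, 10, (40, 2))
        q = bm.conditional_q(np.array([1.0, -2.0]), Y)
        assert q.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(q > 0)

    def test_literal_affinity_variant_is_distance_weighted(self):
        D = np.array([1.0, 2.0, 3.0])
        p, _ = bm.conditional_p(D, 2.0, literal_affinity=True)
        np.testing.assert_allclose(p, np.array([1, 4, 9]) / 14.0)

    def test_nan_features_raise(self, small_model):
        z = np.full(small_model.training_features.shape[1], np.nan)
        with pytest.raises(ValueError):
            bm.post_embed(z, small_model)


class TestPostEmbedding:
    def test_training_point_lands_near_its_own_embedding(self, small_model,
                                                         small_map):
        for i in (0, 75, 150):
            y = bm.post_embed(small_model.training_features[i], small_model)
            d = np.linalg.norm(y - small_model.training_embedding[i])
            assert d < small_map.kernel_bandwidth

    def test_nelder_mead_matches_grid_search(self, cluster_data, small_model):
        """The optimizer's minimum must not exceed a dense grid's minimum."""
        X, _ = cluster_data
        rng = np.random.default_rng(7)
        emb = small_model.training_embedding
        lo, hi = emb.min(0) - 5, emb.max(0) + 5
        gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], 200),
                             np.linspace(lo[1], hi[1], 200))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        cell = max((hi - lo) / 199)
        for _ in range(5):
            z = X[rng.integers(len(X))] * np.exp(rng.normal(0, 0.01, X.shape[1]))
            k = int(3 * small_model.perplexity)
            idx = small_model.neighbor_index.kneighbors(
                z[None, :], n_neighbors=k, return_distance=False)[0]
            D = bm.feature_kl_divergence(z, small_model.training_features[idx])
            p, _ = bm.conditional_p(D, small_model.perplexity)
            Y = small_model.training_embedding[idx]
            grid_best = min(bm.kl_objective(g, Y, p) for g in grid)
            y_opt = bm.post_embed(z, small_model)
            assert y_opt is not None
            assert bm.kl_objective(y_opt, Y, p) <= grid_best + 1e-6

    def test_query_unlike_training_data_diverges(self):
        # one-hot mass in a bin no training point uses: every neighbour
        # divergence ties, p is exactly uniform, and KL(uniform || q) is
        # minimized wherever q is uniform — the bisector between the two
        # blobs or infinity. Either way the solution is far from every
        # neighbour and must be reported as diverged.
        rng = np.random.default_rng(0)
        dim, n_per = 746, 15
        c1 = rng.gamma(2.0, 1.0, dim)
        c2 = rng.gamma(2.0, 1.0, dim)
        X = np.array([c * np.exp(rng.normal(0, 0.02, dim))
                      for c in [c1] * n_per + [c2] * n_per])
        unused = 733
        X[:, unused] = 0.0
        X /= X.sum(1, keepdims=True)
        emb = np.concatenate([rng.normal(0, 1, (n_per, 2)),
                              rng.normal(100, 1, (n_per, 2))])
        model = bm.EmbeddingModel(X, emb, 10.0, 0)
        z = np.zeros(dim)
        z[unused] = 1.0
        assert bm.post_embed(z, model) is None


class TestClassification:
    def test_training_points_reclassified_into_own_region(self, small_model,
                                                          small_map):
        for i in (5, 100, 170):
            own = small_map.region_at(small_model.training_embedding[i])
            c = bm.classify(small_model.training_features[i], small_model,
                            small_map)
            assert c.label == own
            assert c.certainty < np.inf

    def test_random_noise_query_does_not_crash(self, small_model, small_map):
        rng = np.random.default_rng(9)
        z = np.abs(rng.normal(0, 1, small_model.training_features.shape[1]))
        c = bm.classify(z, small_model, small_map)
        assert c.label == bm.UNCLASSIFIED or c.label in small_map.peaks

    def test_parallel_batch_equals_serial(self, cluster_data, small_model,
                                          small_map):
        X, _ = cluster_data
        batch = X[::20]
        serial = bm.classify_batch(batch, small_model, small_map, workers=1)
        parallel = bm.classify_batch(batch, small_model, small_map, workers=4)
        assert [c.label for c in serial] == [c.label for c in parallel]


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, small_model, small_map):
        bm.save_model(tmp_path / "m", small_model, small_map)
        model2, map2 = bm.load_model(tmp_path / "m")
        np.testing.assert_array_equal(model2.training_embedding,
                                      small_model.training_embedding)
        assert model2.perplexity == small_model.perplexity
        assert map2 is not None
        assert map2.label_names == small_map.label_names
        np.testing.assert_array_equal(map2.regions, small_map.regions)
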