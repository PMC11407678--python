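import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from orgscape import simgen
from orgscape.io_formats import ParticleTable
from orgscape.landscape import (
    LandscapeError,
    cluster,
    embed,
    fit_landscape,
    map_query,
    merge_clusters,
    size_factor_normalize,
)


class TestSizeFactorNormalize:
    def test_identical_particles_unit_factors(self):
        df = pd.DataFrame({"A": [2.0] * 5, "B": [6.0] * 5, "area": [4] * 5})
        t = ParticleTable(df, ["A", "B"])
        mat, factors, kept = size_factor_normalize(t)
        np.testing.assert_allclose(factors, 1.0)
        np.testing.assert_allclose(mat, np.log1p([[2.0, 6.0]] * 5))

    def test_doubling_one_particle_scales_only_its_factor(self, rng):
        raw = rng.uniform(1, 10, (6, 3))
        t1 = ParticleTable(pd.DataFrame(raw, columns=list("ABC")), list("ABC"))
        raw2 = raw.copy()
        raw2[2] *= 2
        t2 = ParticleTable(pd.DataFrame(raw2, columns=list("ABC")), list("ABC"))
        m1, f1, _ = size_factor_normalize(t1)
        m2, f2, _ = size_factor_normalize(t2)
        # relative to the other particles, only the doubled particle's
        # factor doubles, and every pre-log normalized profile shifts by
        # the same geometric-mean constant (so profiles are unchanged up
        # to one global scale)
        np.testing.assert_allclose(
            (f2[2] / f1[2]) / (f2[0] / f1[0]), 2.0, rtol=1e-9
        )
        ratio = np.expm1(m2) / np.expm1(m1)
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-9)

    def test_formula_oracle_on_random_tables(self, rng):
        raw = rng.uniform(0.5, 20, (40, 4))
        t = ParticleTable(pd.DataFrame(raw, columns=list("ABCD")), list("ABCD"))
        mat, factors, kept = size_factor_normalize(t)
        totals = raw.sum(axis=1)
        expected_f = totals / np.exp(np.log(totals).mean())
        np.testing.assert_allclose(factors, expected_f, rtol=1e-12)
        np.testing.assert_allclose(
            mat, np.log1p(raw / expected_f[:, None]), rtol=1e-12
        )
        # geometric mean of factors is exactly 1
        np.testing.assert_allclose(np.exp(np.log(factors).mean()), 1.0, rtol=1e-12)

    def test_size_factors_invariant_under_global_rescaling(self, rng):
        # factors are relative quantities: a global gain change (e.g. laser
        # power) leaves them untouched
        raw = rng.uniform(1, 30, (20, 3))
        t1 = ParticleTable(pd.DataFrame(raw, columns=list("ABC")), list("ABC"))
        t2 = ParticleTable(pd.DataFrame(raw * 7.5, columns=list("ABC")), list("ABC"))
        _, f1, _ = size_factor_normalize(t1)
        _, f2, _ = size_factor_normalize(t2)
        np.testing.assert_allclose(f1, f2, rtol=1e-12)

    def test_all_zero_particle_dropped_with_warning(self):
        df = pd.DataFrame({"A": [1.0, 0.0, 3.0], "B": [2.0, 0.0, 1.0]})
        t = ParticleTable(df, ["A", "B"])
        with pytest.warns(UserWarning, match="all-zero"):
            mat, factors, kept = size_factor_normalize(t)
        assert list(kept) == [0, 2]
        assert mat.shape == (2, 2)


class TestEmbed:
    def test_pca_step_matches_hand_computed_projection(self):
        # points on the line y = (4/3) x: PC1 direction (3,4)/5, scores
        # -5, 0, 5 for the three distinct points, second component zero
        toy = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]])
        X = np.repeat(toy, 6, axis=0)  # enough rows for the UMAP step
        model = embed(X, seed=0)
        scores = model.pca.transform(toy)
        np.testing.assert_allclose(np.abs(scores[:, 0]), [5.0, 0.0, 5.0], atol=1e-9)
        np.testing.assert_allclose(scores[:, 1], 0.0, atol=1e-9)
        np.testing.assert_allclose(np.abs(model.pca.components_[0]), [0.6, 0.8])

    def test_two_blobs_separate_in_embedding(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.3, (150, 4)), rng.normal(8, 0.3, (150, 4))]
        )
        model = embed(X, seed=0)
        emb = model.embedding
        c1, c2 = emb[:150].mean(axis=0), emb[150:].mean(axis=0)
        within = np.mean(
            [np.linalg.norm(emb[:150] - c1, axis=1).mean(),
             np.linalg.norm(emb[150:] - c2, axis=1).mean()]
        )
        assert np.linalg.norm(c1 - c2) / within > 5

    def test_batch_centering_removes_constant_offsets(self, rng):
        X = rng.normal(0, 1, (200, 5))
        batches = np.repeat([1, 2], 100)
        X[batches == 2] += 3.0  # constant shift in feature space
        model = embed(X, batch_labels=batches, seed=0)
        c1 = model.pcs[batches == 1].mean(axis=0)
        c2 = model.pcs[batches == 2].mean(axis=0)
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_single_particle_rejected(self):
        with pytest.raises(LandscapeError):
            embed(np.ones((1, 3)))

    def test_nan_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(LandscapeError, match="finite"):
            embed(X)


class TestCluster:
    def test_single_blob_yields_one_cluster(self, rng):
        X = rng.normal(0, 0.5, (400, 3))
        model = embed(X, seed=0)
        labels = cluster(model, k=30, seed=0)
        assert set(labels) == {1}

    def test_row_shuffle_gives_same_partition_up_to_relabeling(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.4, (200, 3)), rng.normal(6, 0.4, (200, 3))]
        )
        l1 = cluster(embed(X, seed=1), k=20, seed=1)
        perm = rng.permutation(len(X))
        l2_perm = cluster(embed(X[perm], seed=1), k=20, seed=1)
        l2 = np.empty_like(l2_perm)
        l2[perm] = l2_perm
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_k_must_be_below_n(self, rng):
        model = embed(rng.normal(0, 1, (50, 3)), seed=0)
        with pytest.raises(LandscapeError):
            cluster(model, k=50)

    def test_every_particle_gets_exactly_one_label(self, organelle_table):
        model = fit_landscape(organelle_table, k=30, seed=0)
        assert len(model.cluster_labels) == len(organelle_table)
        assert model.cluster_labels.min() >= 1


class TestMergeClusters:
    def test_nine_clusters_with_one_five_way_group(self):
        labels = np.arange(1, 10)  # 9 singleton clusters
        merged = merge_clusters(labels, {1: [1, 2, 3, 4, 5]})
        assert len(np.unique(merged)) == 5
        assert set(merged[:5]) == {1}

    def test_empty_group_list_is_identity(self, rng):
        labels = rng.integers(1, 5, 30)
        np.testing.assert_array_equal(merge_clusters(labels, {}), labels)

    def test_merging_all_labels_gives_single_cluster(self):
        labels = np.array([1, 2, 3, 1, 2])
        merged = merge_clusters(labels, {9: [1, 2, 3]})
        assert set(merged) == {9}

    def test_unknown_label_rejected(self):
        with pytest.raises(LandscapeError, match="unknown"):
            merge_clusters(np.array([1, 2]), {1: [7]})


class TestMapQuery:
    @pytest.fixture(scope="class")
    def reference(self):
        cfg = simgen.seven_organelle_config(n_particles=1500, seed=2)
        gt = simgen.sample_particles(cfg)
        table = simgen.make_feature_matrix(gt, noise_sd=0.1, n_batches=3, seed=2)
        model = fit_landscape(table, k=30, seed=2)
        return table, model

    def test_marker_count_mismatch_rejected(self, reference):
        _, model = reference
        with pytest.raises(LandscapeError, match="markers"):
            map_query(model, np.ones((5, 3)))

    def test_self_query_label_consistency(self, reference):
        table, model = reference
        mat, _, kept = size_factor_normalize(table)
        proj = map_query(
            model, mat, batch_labels=table.data["replicate"].to_numpy()[kept]
        )
        assert np.mean(proj.labels == model.cluster_labels) >= 0.99

    def test_novel_class_flagged_by_distance(self, reference, rng):
        table, model = reference
        # a marker profile far outside the reference's generative classes
        novel = np.exp(rng.normal(8.0, 0.3, (60, 8)))
        novel_t = ParticleTable(
            pd.DataFrame(novel, columns=table.markers), table.markers
        )
        qmat, _, _ = size_factor_normalize(novel_t)
        proj = map_query(model, qmat)
        # reference self-distance scale: nearest-neighbor distances
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=2).fit(model.embedding)
        self_d = nn.kneighbors(model.embedding)[0][:, 1]
        cutoff = np.percentile(self_d, 99)
        assert np.median(proj.nearest_distance) > cutoff


class TestPipelineRecovery:
    def test_seven_classes_recovered_across_seeds(self):
        """Scaled-down landscape pipeline: 7 clusters, ARI >= 0.9, >=9/10 seeds;
        every cluster mixes all batches (batch gains <= 2x)."""
        ok = 0
        for seed in range(10):
            cfg = simgen.seven_organelle_config(n_particles=2800, seed=seed)
            gt = simgen.sample_particles(cfg)
            table = simgen.make_feature_matrix(
                gt, noise_sd=0.1, n_batches=3,
                batch_gains=np.array([1.0, 1.5, 2.0]), seed=seed,
            )
            model = fit_landscape(table, k=60, seed=seed)
            labels = model.cluster_labels
            truth = table.data["class_label"].to_numpy()[model.kept_index]
            if (
                len(np.unique(labels)) == 7
                and adjusted_rand_score(truth, labels) >= 0.9
            ):
                ok += 1
            if seed == 0:
                reps = table.data["replicate"].to_numpy()[model.kept_index]
                for lab in np.unique(labels):
                    assert len(np.unique(reps[labels == lab])) == 3
        assert ok >= 9
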