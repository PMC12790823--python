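"""Mini-batch training, inference, clustering and the end-to-end pipeline."""

import os

import numpy as np
import pytest

from stgap import (
    FixtureSpec,
    GAAEConfig,
    TrainConfig,
    build_radius_graph,
    adaptive_radius,
    cluster_embeddings,
    embed_and_denoise,
    encode,
    decode,
    evaluate_clustering,
    generate_fixture,
    make_batches,
    normalize_expression,
    partition_graph,
    run_pipeline,
    select_hvg,
    train,
)


@pytest.fixture(scope="module")
def trained_setup(small_fixture):
    """Preprocessed 600-spot fixture with graph, partition and a short training run."""
    spec, ds_raw, truth = small_fixture
    ds = select_hvg(normalize_expression(ds_raw), ds_raw.n_genes)
    r = adaptive_radius(ds.coords)
    g = build_radius_graph(ds.coords, r)
    p = partition_graph(g, spot_batch_size=256, seed=0)
    cfg = TrainConfig(epochs=30, seed=0)
    mcfg = GAAEConfig(layer_dims=[ds.n_genes, 64, 30], seed=0)
    model, history = train(ds, g, p, cfg, mcfg)
    return ds, g, p, cfg, mcfg, model, history, truth


class TestMakeBatches:
    def test_grouping_arithmetic(self):
        # 39 subgraphs at 10 per batch -> 4 batches of 10, 10, 10, 9
        from stgap import PartitionResult

        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, size=(1000, 2))
        g = build_radius_graph(pts, 0.7)
        labels = np.arange(1000) % 39
        p = PartitionResult(
            labels=labels, num_parts=39, cap=25.6, levels=[],
            edge_cut=0, part_weights=np.bincount(labels).astype(float),
        )
        batches = make_batches(g, p, subgraphs_per_batch=10, seed=0, epoch=0)
        assert sorted(len(b.subgraph_ids) for b in batches) == [9, 10, 10, 10]
        assert sum(len(b.node_index) for b in batches) == 1000

    def test_each_spot_exactly_once(self):
        pts = np.random.default_rng(1).uniform(0, 8, size=(500, 2))
        g = build_radius_graph(pts, 0.8)
        p = partition_graph(g, 256, seed=0)
        for epoch in (0, 3):
            batches = make_batches(g, p, 7, seed=0, epoch=epoch)
            all_nodes = np.concatenate([b.node_index for b in batches])
            assert sorted(all_nodes.tolist()) == list(range(500))

    def test_epochs_reshuffle(self):
        pts = np.random.default_rng(2).uniform(0, 8, size=(400, 2))
        g = build_radius_graph(pts, 0.8)
        p = partition_graph(g, 256, seed=0)
        b0 = make_batches(g, p, 5, seed=0, epoch=0)
        b1 = make_batches(g, p, 5, seed=0, epoch=1)
        assert [b.subgraph_ids for b in b0] != [b.subgraph_ids for b in b1]

    def test_block_diagonal_equals_separate_forward(self, trained_setup):
        ds, g, p, cfg, mcfg, model, _, _ = trained_setup[:8]
        X = ds.dense()
        batches = make_batches(g, p, 2, seed=0, epoch=0)
        batch = batches[0]
        Z_joint, cache = encode(X[batch.node_index], batch.graph, model)
        Xh_joint = decode(Z_joint, batch.graph, model, cache)
        offset = 0
        for sid in batch.subgraph_ids:
            nodes = p.part_nodes(sid)
            sub = g.subgraph(nodes)
            Z, c = encode(X[nodes], sub, model)
            Xh = decode(Z, sub, model, c)
            np.testing.assert_allclose(Z_joint[offset: offset + len(nodes)], Z, atol=1e-10)
            np.testing.assert_allclose(Xh_joint[offset: offset + len(nodes)], Xh, atol=1e-10)
            offset += len(nodes)


class TestTrain:
    def test_loss_decreases_on_fixture(self, trained_setup):
        history = trained_setup[6]
        assert np.isfinite(history).all()
        assert history[-1] < history[0]

    def test_zero_learning_rate_freezes(self, trained_setup):
        ds, g, p = trained_setup[:3]
        cfg = TrainConfig(epochs=3, learning_rate=0.0, weight_decay=0.0, seed=0)
        mcfg = GAAEConfig(layer_dims=[ds.n_genes, 16, 8], seed=0)
        model, history = train(ds, g, p, cfg, mcfg)
        from stgap import init_model

        fresh = init_model(mcfg)
        for p1, p2 in zip(model.parameters(), fresh.parameters()):
            np.testing.assert_array_equal(p1, p2)
        assert history[0] == history[1] == history[2]

    def test_seeded_determinism_bitwise(self, trained_setup):
        ds, g, p = trained_setup[:3]
        cfg = TrainConfig(epochs=5, seed=3)
        mcfg = GAAEConfig(layer_dims=[ds.n_genes, 16, 8], seed=3)
        _, h1 = train(ds, g, p, cfg, mcfg)
        _, h2 = train(ds, g, p, cfg, mcfg)
        assert (h1 == h2).all()


class TestInference:
    def test_shapes_and_determinism(self, trained_setup):
        ds, g, p, _, _, model = trained_setup[:6]
        a1 = embed_and_denoise(ds, g, p, model)
        a2 = embed_and_denoise(ds, g, p, model)
        assert a1.embedding.shape == (ds.n_spots, 30)
        assert a1.denoised.shape == (ds.n_spots, ds.n_genes)
        np.testing.assert_array_equal(a1.embedding, a2.embedding)
        np.testing.assert_array_equal(a1.denoised, a2.denoised)

    def test_subgraph_matches_full_graph_when_cut_is_zero(self):
        # two far-apart blobs: the partition severs nothing, so both inference
        # modes see identical neighborhoods
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.5, (60, 2)), rng.normal(50, 0.5, (60, 2))])
        X = rng.poisson(3.0, size=(120, 30)).astype(float)
        from stgap import SpatialDataset

        ds = SpatialDataset(
            X, pts,
            np.array([f"s{i}" for i in range(120)], dtype=object),
            np.array([f"g{j}" for j in range(30)], dtype=object),
        )
        ds = normalize_expression(ds)
        g = build_radius_graph(ds.coords, 2.0)
        p = partition_graph(g, spot_batch_size=600, seed=0)
        assert p.edge_cut == 0
        model, _ = train(ds, g, p, TrainConfig(epochs=3, seed=0), GAAEConfig([30, 8, 4], seed=0))
        a_sub = embed_and_denoise(ds, g, p, model, full_graph=False)
        a_full = embed_and_denoise(ds, g, p, model, full_graph=True)
        np.testing.assert_allclose(a_sub.embedding, a_full.embedding, atol=1e-10)
        np.testing.assert_allclose(a_sub.denoised, a_full.denoised, atol=1e-10)


class TestClustering:
    def test_separable_blobs_recovered(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 0.1, (50, 5)), rng.normal(10, 0.1, (50, 5))])
        truth = np.repeat([0, 1], 50)
        labels = cluster_embeddings(emb, "kmeans", 2, seed=0)
        assert evaluate_clustering(labels, truth)["ARI"] == 1.0

    def test_single_cluster(self):
        emb = np.random.default_rng(0).normal(size=(20, 3))
        labels = cluster_embeddings(emb, "kmeans", 1, seed=0)
        assert len(set(labels.tolist())) == 1

    def test_seeded_determinism(self):
        emb = np.random.default_rng(1).normal(size=(80, 4))
        l1 = cluster_embeddings(emb, "kmeans", 4, seed=5)
        l2 = cluster_embeddings(emb, "kmeans", 4, seed=5)
        np.testing.assert_array_equal(l1, l2)

    def test_k_exceeds_spots(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_embeddings(np.zeros((3, 2)), "kmeans", 5)

    def test_leiden_runs(self):
        rng = np.random.default_rng(2)
        emb = np.vstack([rng.normal(0, 0.2, (40, 4)), rng.normal(5, 0.2, (40, 4))])
        labels = cluster_embeddings(emb, "leiden", 0.5, seed=0)
        assert len(labels) == 80 and len(set(labels.tolist())) >= 2


class TestEvaluate:
    def test_perfect_agreement(self):
        t = np.array([0, 0, 1, 1, 2])
        m = evaluate_clustering(t, t)
        assert m["ARI"] == 1.0 and m["homogeneity"] == 1.0

    def test_random_labels_chance_corrected(self):
        rng = np.random.default_rng(0)
        aris = []
        for s in range(5):
            truth = rng.integers(0, 7, 1000)
            pred = rng.integers(0, 7, 1000)
            aris.append(evaluate_clustering(pred, truth)["ARI"])
        assert abs(np.mean(aris)) < 0.05

    def test_relabeling_invariance(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([0, 0, 1, 1, 2, 2])
        swapped = np.array([1, 1, 0, 0, 2, 2])
        assert evaluate_clustering(pred, truth) == evaluate_clustering(swapped, truth)

    def test_unlabeled_sentinel_excluded(self):
        truth = np.array([0, 0, 1, -1, -1])
        pred = np.array([5, 5, 6, 0, 1])
        m = evaluate_clustering(pred, truth, unlabeled=-1)
        assert m["ARI"] == 1.0

    def test_all_unlabeled(self):
        with pytest.raises(ValueError, match="unlabeled"):
            evaluate_clustering(np.zeros(3), np.full(3, -1), unlabeled=-1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            evaluate_clustering(np.zeros(3), np.zeros(4))


class TestRunPipeline:
    def pipeline_config(self, tmp_path, small_fixture):
        spec, ds_raw, truth = small_fixture
        return {
            "dataset": ds_raw,
            "n_hvg": ds_raw.n_genes,
            "epochs": 10,
            "spot_batch_size": 256,
            "seed": 0,
            "n_clusters": 3,
            "hidden_dims": (32,),
            "latent_dim": 8,
            "out_dir": str(tmp_path / "out"),
        }

    def test_smoke_artifacts_and_coverage(self, tmp_path, small_fixture):
        cfg = self.pipeline_config(tmp_path, small_fixture)
        assign = run_pipeline(cfg)
        out = cfg["out_dir"]
        for f in ("embedding.csv", "denoised.mtx", "labels.csv", "loss.csv", "diagnostics.json"):
            assert os.path.exists(os.path.join(out, f)), f
        assert assign.cluster is not None and len(assign.cluster) == 600
        assert len(assign.loss_history) == 10

    def test_rerun_identical(self, tmp_path, small_fixture):
        cfg = self.pipeline_config(tmp_path, small_fixture)
        run_pipeline({**cfg, "out_dir": str(tmp_path / "a")})
        run_pipeline({**cfg, "out_dir": str(tmp_path / "b")})
        for f in ("labels.csv", "loss.csv"):
            with open(tmp_path / "a" / f, "rb") as fa, open(tmp_path / "b" / f, "rb") as fb:
                assert fa.read() == fb.read()

    def test_missing_coordinates_halts_in_preprocess(self, tmp_path):
        import pandas as pd

        pd.DataFrame([[1]], index=["a"], columns=["g"]).to_csv(tmp_path / "expression.csv")
        with pytest.raises(RuntimeError, match="stage 'preprocess'"):
            run_pipeline(
                {"input": str(tmp_path), "format": "csv_pair", "out_dir": str(tmp_path / "o")}
            )
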