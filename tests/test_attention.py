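"""Self-attention weighting: shapes, masking, equivariance, training."""

import numpy as np
import pytest

import deewana as dw
from deewana.attention import _forward, _loss_and_grads, build_batch


def contexts_from(graph, emb, max_neighbors=10, seed=0):
    return [
        c
        for c in dw.all_neighbor_contexts(graph, emb, max_neighbors, seed=seed)
        if c.neighbors
    ]


@pytest.fixture(scope="module")
def toy():
    """20 contexts from a seeded community-graph embedding (d_model=32)."""
    g, _ = dw.generate_sbm_graph(dw.SyntheticSpec(40, 2, 0.4, 0.05, seed=5))
    corpus = dw.simulate_walks(g, 5, 10, seed=5)
    emb = dw.train_skipgram(corpus, d_model=32, window=3, epochs=2, seed=5)
    ctxs = contexts_from(g, emb)[:20]
    assert len(ctxs) == 20
    return emb, ctxs


class TestBuildModel:
    def test_mlp_sizes_follow_context_size(self):
        m = dw.build_attention_model(d_model=128, heads=1, max_neighbors=10, seed=0)
        n = 11  # center + 10 neighbor slots
        assert m.params["W1"].shape == (n * 128, n * 128 // 2)
        assert m.params["W2"].shape == (n * 128 // 2, 10)
        assert "Wout" not in m.params  # single head projects straight through

    def test_head_subspace_split(self):
        m = dw.build_attention_model(d_model=128, heads=4, max_neighbors=10, seed=0)
        assert m.d_k == m.d_v == 32
        assert m.params["Wq"].shape == (4, 128, 32)
        assert m.params["Wout"].shape == (128, 128)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            dw.build_attention_model(d_model=128, heads=3, max_neighbors=10, seed=0)


class TestForward:
    @pytest.mark.parametrize("heads", [1, 2, 4])
    def test_weights_normalized_with_zero_padding_mass(
        self, toy, heads
    ):
        emb, ctxs = toy
        model = dw.build_attention_model(32, heads, 10, seed=1)
        batch = build_batch(ctxs, emb, 10)
        pred, alpha = dw.attention_forward(model, batch)
        assert pred.shape == alpha.shape == (len(ctxs), 10)
        sums = alpha.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert np.all(alpha[~batch.target_mask] == 0.0)  # padded slots
        assert np.all(alpha[batch.target_mask] > 0.0)
        assert np.all(pred[~batch.target_mask] == 0.0)

    def test_single_neighbor_gets_weight_one(self, random_embedding):
        emb = random_embedding(5, 16, seed=2)
        ctx = dw.NeighborContext("v0", ["v1"], emb.distances_from("v0", ["v1"]), 10, 1)
        model = dw.build_attention_model(16, 4, 10, seed=2)
        w = dw.attention_weights(model, ctx, emb)
        np.testing.assert_allclose(w.weights, [1.0], atol=1e-12)

    def test_single_head_matches_plain_softmax_oracle(self, random_embedding):
        """The packaged path at h=1 must equal a direct softmax(QK^T/sqrt(d_k))
        computed outside the package from the same parameters."""
        emb = random_embedding(8, 16, seed=3)
        nbrs = ["v1", "v2", "v3", "v4"]
        ctx = dw.NeighborContext("v0", nbrs, emb.distances_from("v0", nbrs), 4, 4)
        model = dw.build_attention_model(16, 1, 4, seed=3)

        w = dw.attention_weights(model, ctx, emb)
        assert w.mode == "1H"

        I = np.vstack([emb.row("v0"), emb.rows(nbrs)])
        q = I @ model.params["Wq"][0]
        k = I @ model.params["Wk"][0]
        s = (q @ k.T) / np.sqrt(model.d_k)
        a = np.exp(s - s.max(axis=1, keepdims=True))
        a /= a.sum(axis=1, keepdims=True)
        expected = a[0, 1:] / a[0, 1:].sum()
        np.testing.assert_allclose(w.weights, expected, atol=1e-10)

    @pytest.mark.parametrize("heads", [1, 4])
    def test_permutation_equivariance(self, random_embedding, heads):
        emb = random_embedding(10, 16, seed=4)
        nbrs = ["v1", "v2", "v3", "v4", "v5"]
        ctx = dw.NeighborContext("v0", nbrs, emb.distances_from("v0", nbrs), 10, 5)
        model = dw.build_attention_model(16, heads, 10, seed=4)
        w = dw.attention_weights(model, ctx, emb).weights

        perm = [3, 0, 4, 1, 2]
        nbrs_p = [nbrs[i] for i in perm]
        ctx_p = dw.NeighborContext(
            "v0", nbrs_p, emb.distances_from("v0", nbrs_p), 10, 5
        )
        w_p = dw.attention_weights(model, ctx_p, emb).weights
        np.testing.assert_allclose(w_p, w[perm], atol=1e-12)

    def test_multihead_weights_average_per_head_rows(self, random_embedding):
        """h-head weights equal the mean of per-head center-row softmaxes."""
        emb = random_embedding(8, 16, seed=6)
        nbrs = ["v1", "v2", "v3"]
        ctx = dw.NeighborContext("v0", nbrs, emb.distances_from("v0", nbrs), 3, 3)
        model = dw.build_attention_model(16, 4, 3, seed=6)
        w = dw.attention_weights(model, ctx, emb)
        assert w.mode == "MH"

        I = np.vstack([emb.row("v0"), emb.rows(nbrs)])
        per_head = []
        for h in range(4):
            q = I @ model.params["Wq"][h]
            k = I @ model.params["Wk"][h]
            s = (q @ k.T) / np.sqrt(model.d_k)
            a = np.exp(s - s.max(axis=1, keepdims=True))
            a /= a.sum(axis=1, keepdims=True)
            per_head.append(a[0, 1:])
        mean = np.mean(per_head, axis=0)
        np.testing.assert_allclose(w.weights, mean / mean.sum(), atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("heads", [1, 2])
    def test_analytic_gradients_match_finite_differences(
        self, random_embedding, heads
    ):
        emb = random_embedding(10, 4, seed=7)
        ctxs = [
            dw.NeighborContext(
                f"v{i}",
                [f"v{(i + j) % 10}" for j in range(1, 3)],
                emb.distances_from(f"v{i}", [f"v{(i + j) % 10}" for j in range(1, 3)]),
                3, 2,
            )
            for i in range(4)
        ]
        model = dw.build_attention_model(4, heads, 3, seed=7)
        batch = build_batch(ctxs, emb, 3)
        _, grads = _loss_and_grads(model, batch)

        def loss_at():
            pred, _ = _forward(model, batch)
            resid = (pred - batch.targets) * batch.target_mask
            return (resid ** 2).sum() / batch.target_mask.sum()

        rng = np.random.default_rng(0)
        eps = 1e-6
        for name, g in grads.items():
            flat = model.params[name].ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at()
                flat[idx] = orig - eps
                down = loss_at()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), name


class TestTraining:
    def test_loss_decreases_on_toy_fixture(self, toy):
        emb, ctxs = toy
        model = dw.build_attention_model(32, 1, 10, seed=8)
        model, history = dw.train_attention(
            model, ctxs, emb, epochs=50, learning_rate=1e-3, seed=8
        )
        assert len(history) == 50
        assert np.isfinite(history).all()
        assert history[-1] < history[0]

    def test_zero_epochs_is_a_no_op(self, toy):
        emb, ctxs = toy
        model = dw.build_attention_model(32, 2, 10, seed=9)
        before = {k: v.copy() for k, v in model.params.items()}
        model, history = dw.train_attention(model, ctxs, emb, epochs=0, seed=9)
        assert history == []
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_training_determinism(self, toy):
        emb, ctxs = toy
        histories = []
        for _ in range(2):
            model = dw.build_attention_model(32, 2, 10, seed=10)
            _, h = dw.train_attention(model, ctxs, emb, epochs=5, seed=10)
            histories.append(h)
        assert histories[0] == histories[1]


class TestSerialization:
    def test_round_trip(self, tmp_path, toy):
        emb, ctxs = toy
        model = dw.build_attention_model(32, 4, 10, seed=11)
        dw.train_attention(model, ctxs, emb, epochs=2, seed=11)
        path = tmp_path / "model.npz"
        dw.save_model(model, path)
        back = dw.load_model(path)
        assert back.heads == 4 and back.d_model == 32
        w1 = dw.attention_weights(model, ctxs[0], emb).weights
        w2 = dw.attention_weights(back, ctxs[0], emb).weights
        np.testing.assert_array_equal(w1, w2)
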