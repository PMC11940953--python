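"""Neighborhood aggregation and PCA fusion."""

import numpy as np
import pytest

import deewana as dw
from conftest import make_context


def two_neighbor_setup():
    emb = dw.EmbeddingMatrix(
        ["u", "nb0", "nb1"], np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    )
    ctx = make_context([1.0, 1.0])
    return emb, ctx


class TestMeanAggregate:
    def test_arithmetic_mean(self):
        emb, ctx = two_neighbor_setup()
        np.testing.assert_allclose(dw.mean_aggregate(ctx, emb), [0.5, 0.5])

    def test_single_neighbor_is_identity(self):
        emb = dw.EmbeddingMatrix(["u", "nb0"], np.array([[0.0, 0.0], [2.0, 3.0]]))
        ctx = make_context([1.0])
        np.testing.assert_allclose(dw.mean_aggregate(ctx, emb), [2.0, 3.0])

    def test_isolated_node_falls_back_to_self_vector(self):
        emb = dw.EmbeddingMatrix(["u"], np.array([[4.0, 5.0]]))
        ctx = dw.NeighborContext("u", [], np.empty(0), 10, 0)
        np.testing.assert_allclose(dw.mean_aggregate(ctx, emb), [4.0, 5.0])

    def test_equals_uniform_weighted_aggregate(self, random_embedding):
        emb = random_embedding(12, 6, seed=1)
        nbrs = [f"v{i}" for i in range(1, 8)]
        ctx = dw.NeighborContext(
            "v0", nbrs, emb.distances_from("v0", nbrs), 10, len(nbrs)
        )
        uniform = dw.WeightVector(np.full(len(nbrs), 1 / len(nbrs)), "N")
        np.testing.assert_allclose(
            dw.mean_aggregate(ctx, emb),
            dw.weighted_aggregate(ctx, uniform, emb),
            atol=1e-12,
        )


class TestWeightedAggregate:
    def test_vertex_of_hull(self):
        emb, ctx = two_neighbor_setup()
        w = dw.WeightVector(np.array([1.0 - 1e-12, 1e-12]), "N")
        np.testing.assert_allclose(
            dw.weighted_aggregate(ctx, w, emb), [1.0, 0.0], atol=1e-9
        )

    def test_convex_combination(self):
        emb, ctx = two_neighbor_setup()
        w = dw.WeightVector(np.array([0.6, 0.4]), "N")
        np.testing.assert_allclose(dw.weighted_aggregate(ctx, w, emb), [0.6, 0.4])

    def test_misaligned_lengths_rejected(self):
        emb, ctx = two_neighbor_setup()
        w = dw.WeightVector(np.array([0.5, 0.25, 0.25]), "N")
        with pytest.raises(ValueError):
            dw.weighted_aggregate(ctx, w, emb)

    def test_output_in_convex_hull(self, random_embedding):
        emb = random_embedding(20, 8, seed=2)
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = rng.integers(2, 9)
            nbrs = [f"v{i}" for i in rng.choice(np.arange(1, 20), k, replace=False)]
            ctx = dw.NeighborContext(
                "v0", nbrs, emb.distances_from("v0", nbrs), 10, k
            )
            w = rng.random(k)
            w /= w.sum()
            out = dw.weighted_aggregate(ctx, dw.WeightVector(w, "N"), emb)
            pts = emb.rows(nbrs)
            assert np.all(out >= pts.min(axis=0) - 1e-12)
            assert np.all(out <= pts.max(axis=0) + 1e-12)

    def test_matches_dense_matrix_oracle(self, random_embedding):
        """Stacked per-node aggregation equals the dense W @ R product."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 50))
            g, _ = dw.generate_sbm_graph(
                dw.SyntheticSpec(n, 2, 0.5, 0.2, seed=seed)
            )
            emb = random_embedding(n, 8, seed=seed)
            ctxs = dw.all_neighbor_contexts(g, emb, max_neighbors=n, seed=seed)
            order = g.node_order()
            w_dense = np.zeros((n, n))
            rows = np.zeros((n, 8))
            for i, ctx in enumerate(ctxs):
                if not ctx.neighbors:
                    rows[i] = emb.row(ctx.center)
                    w_dense[i, order[ctx.center]] = 1.0
                    continue
                wv = dw.nonlearning_weights(ctx, "N")
                rows[i] = dw.weighted_aggregate(ctx, wv, emb)
                for nb, wgt in zip(ctx.neighbors, wv.weights):
                    w_dense[i, order[nb]] = wgt
            np.testing.assert_allclose(rows, w_dense @ emb.matrix, atol=1e-10)


class TestConcat:
    def test_width_and_ordering(self, random_embedding):
        self_emb = random_embedding(10, 4, seed=3)
        local = dw.EmbeddingMatrix(
            list(self_emb.nodes), np.random.default_rng(3).normal(size=(10, 4))
        )
        nodes, mat = dw.concat_representations(self_emb, local)
        assert mat.shape == (10, 8)
        np.testing.assert_array_equal(mat[:, :4], self_emb.matrix)  # self first
        np.testing.assert_array_equal(mat[:, 4:], local.rows(nodes))

    def test_node_set_mismatch_rejected(self, random_embedding):
        self_emb = random_embedding(5, 4, seed=4)
        local = random_embedding(6, 4, seed=4)
        with pytest.raises(ValueError, match="v5"):
            dw.concat_representations(self_emb, local)


class TestPcaFuse:
    def test_output_width(self, random_embedding):
        emb = random_embedding(50, 16, seed=5)
        nodes, mat = emb.nodes, np.hstack([emb.matrix, emb.matrix ** 2])
        fused = dw.pca_fuse(nodes, mat, out_dim=16)
        assert fused.matrix.shape == (50, 16)
        assert fused.out_dim == 16

    def test_components_orthonormal(self, random_embedding):
        emb = random_embedding(40, 10, seed=6)
        fused = dw.pca_fuse(emb.nodes, emb.matrix, out_dim=8)
        gram = fused.components @ fused.components.T
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-10)

    def test_identical_rows_fuse_identically(self):
        row = np.arange(6.0)
        mat = np.tile(row, (20, 1))
        fused = dw.pca_fuse([f"v{i}" for i in range(20)], mat, out_dim=3)
        np.testing.assert_allclose(fused.matrix, 0.0, atol=1e-12)

    def test_variance_bounded_by_input_eigenspectrum(self):
        """Retained variance equals the top eigenvalues of the covariance
        (independent eigendecomposition oracle); total never exceeds input."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 6)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        xc = x - x.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        for out_dim in (2, 4, 6):
            fused = dw.pca_fuse([f"v{i}" for i in range(30)], x, out_dim)
            got = (fused.matrix ** 2).sum()
            np.testing.assert_allclose(got, evals[:out_dim].sum(), rtol=1e-10)
            assert got <= (xc ** 2).sum() + 1e-9

    def test_deterministic_signs(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(25, 5))
        f1 = dw.pca_fuse([f"v{i}" for i in range(25)], x, 4)
        f2 = dw.pca_fuse([f"v{i}" for i in range(25)], x, 4)
        np.testing.assert_array_equal(f1.matrix, f2.matrix)
        # canonical rule: each component's largest-|loading| entry positive
        peaks = f1.components[
            np.arange(4), np.abs(f1.components).argmax(axis=1)
        ]
        assert np.all(peaks > 0)

    def test_excessive_out_dim_rejected(self, random_embedding):
        emb = random_embedding(10, 4, seed=9)
        with pytest.raises(ValueError):
            dw.pca_fuse(emb.nodes, emb.matrix, out_dim=10)
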