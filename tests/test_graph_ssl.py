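"""Stage-2 graph construction, augmentation, GCN and CCA objective."""

import numpy as np
import pytest

from gcbin.graph_ssl import (
    GcnEncoder,
    GraphConfig,
    augment_graph,
    build_adjacency,
    cca_ssg_loss,
    gcn_forward,
    normalize_adjacency,
    standardize,
    train_graph,
)


def _random_graph(rng, n, p=0.3):
    ids = [f"c{i}" for i in range(n)]
    edges = [
        (ids[i], ids[j], float(rng.integers(1, 50)))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return build_adjacency(ids, edges)


class TestAdjacency:
    def test_max_normalization(self):
        g = build_adjacency(["a", "b", "c"], [("a", "b", 10.0), ("b", "c", 40.0)])
        a = g.adjacency.toarray()
        assert a[0, 1] == pytest.approx(0.25)
        assert a[1, 2] == pytest.approx(1.0)
        assert a[0, 2] == 0.0  # no link

    def test_symmetry_random(self, rng):
        g = _random_graph(rng, 12)
        a = g.adjacency.toarray()
        np.testing.assert_array_equal(a, a.T)

    def test_isolated_nodes_kept(self):
        g = build_adjacency(["a", "b", "lonely"], [("a", "b", 1.0)])
        assert g.n_nodes == 3 and g.n_edges == 1


class TestNormalizeAdjacency:
    def test_single_isolated_node(self):
        g = build_adjacency(["a"], [])
        np.testing.assert_allclose(normalize_adjacency(g).toarray(), [[1.0]])

    def test_two_nodes_unit_edge_hand_value(self):
        g = build_adjacency(["a", "b"], [("a", "b", 1.0)])
        np.testing.assert_allclose(
            normalize_adjacency(g).toarray(), [[0.5, 0.5], [0.5, 0.5]], atol=1e-12
        )

    def test_symmetric_on_random_graphs(self, rng):
        a_hat = normalize_adjacency(_random_graph(rng, 15)).toarray()
        np.testing.assert_allclose(a_hat, a_hat.T, atol=1e-12)


class TestAugmentGraph:
    def test_zero_probabilities_identity(self, rng):
        g = _random_graph(rng, 10, p=0.5)
        X = rng.normal(size=(10, 6))
        (xa, aa), (xb, ab) = augment_graph(g, X, 0.0, 0.0, rng)
        np.testing.assert_array_equal(xa, X)
        np.testing.assert_array_equal(xb, X)
        np.testing.assert_allclose(aa.toarray(), g.adjacency.toarray())
        np.testing.assert_allclose(ab.toarray(), g.adjacency.toarray())

    def test_edge_retention_binomial_expectation(self):
        rng = np.random.default_rng(0)
        ids = [f"c{i}" for i in range(101)]
        edges = [(ids[i], ids[i + 1], 1.0) for i in range(100)]
        g = build_adjacency(ids, edges)
        X = np.zeros((101, 2))
        kept = [
            augment_graph(g, X, 0.2, 0.0, rng)[0][1].nnz // 2 for _ in range(1000)
        ]
        assert 78 <= np.mean(kept) <= 82  # 80 +- 2 sigma

    def test_masked_columns_zero_everywhere_others_untouched(self):
        rng = np.random.default_rng(1)
        g = _random_graph(rng, 8, p=0.4)
        X = rng.normal(size=(8, 30)) + 5.0
        (xa, _), _ = augment_graph(g, X, 0.0, 0.5, rng)
        col_zero = (xa == 0).all(axis=0)
        col_same = (xa == X).all(axis=0)
        assert (col_zero | col_same).all() and col_zero.any()

    def test_edge_dropping_never_adds_edges(self, rng):
        g = _random_graph(rng, 12, p=0.5)
        X = np.zeros((12, 2))
        (_, aa), _ = augment_graph(g, X, 0.3, 0.0, rng)
        orig = set(zip(*g.adjacency.nonzero()))
        assert set(zip(*aa.nonzero())) <= orig


class TestGcnForward:
    def test_dense_oracle_on_random_graphs(self, rng):
        for n in [3, 10, 20]:
            g = _random_graph(rng, n, p=0.4)
            a_hat = normalize_adjacency(g)
            enc = GcnEncoder(5, 7, 4, np.random.default_rng(n))
            X = rng.normal(size=(n, 5))
            z = gcn_forward(X, a_hat, enc)
            A = a_hat.toarray()
            w0, w1 = enc.weights[0].data, enc.weights[1].data
            ref = A @ np.maximum(A @ X @ w0, 0.0) @ w1
            np.testing.assert_allclose(z, ref, atol=1e-6)

    def test_single_node_degenerate(self, rng):
        g = build_adjacency(["a"], [])
        enc = GcnEncoder(3, 4, 2, np.random.default_rng(0))
        x = rng.normal(size=(1, 3))
        ref = np.maximum(x @ enc.weights[0].data, 0) @ enc.weights[1].data
        np.testing.assert_allclose(
            gcn_forward(x, normalize_adjacency(g), enc), ref, atol=1e-12
        )

    def test_shape_mismatch_error(self):
        g = build_adjacency(["a", "b"], [("a", "b", 1.0)])
        enc = GcnEncoder(3, 4, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            gcn_forward(np.zeros((3, 3)), normalize_adjacency(g), enc)


class TestStandardize:
    def test_hand_value_two_rows(self):
        out = standardize(np.array([[1.0], [3.0]])).data
        np.testing.assert_allclose(out.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_columns_zero_mean_unit_norm(self, rng):
        z = rng.normal(size=(40, 7)) * 3 + 2
        out = standardize(z).data
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(np.linalg.norm(out, axis=0), 1.0, atol=1e-6)

    def test_constant_column_stays_finite(self):
        z = np.ones((5, 2))
        assert np.isfinite(standardize(z).data).all()


class TestCcaLoss:
    def test_identical_orthonormal_views_zero(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(6, 3)))
        assert cca_ssg_loss(q, q, 0.5).item() == pytest.approx(0.0, abs=1e-12)

    def test_lambda_zero_is_invariance_only(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert cca_ssg_loss(a, b, 0.0).item() == pytest.approx(
            ((a - b) ** 2).sum(), abs=1e-10
        )

    def test_brute_force_oracle(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        lam = 0.37
        eye = np.eye(3)
        ref = (
            ((a - b) ** 2).sum()
            + lam * (((a.T @ a - eye) ** 2).sum() + ((b.T @ b - eye) ** 2).sum())
        )
        assert cca_ssg_loss(a, b, lam).item() == pytest.approx(ref, abs=1e-8)

    def test_linear_decomposition_in_lambda(self, rng):
        a, b = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        l0 = cca_ssg_loss(a, b, 0.0).item()
        l1 = cca_ssg_loss(a, b, 1.0).item()
        lam = 0.25
        assert cca_ssg_loss(a, b, lam).item() == pytest.approx(
            l0 + lam * (l1 - l0), rel=1e-12
        )

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError):
            cca_ssg_loss(np.zeros((3, 2)), np.zeros((4, 2)), 0.1)


def _two_block_graph(n_per=8, dim=6, seed=0):
    """Two genome-pure connected components with block-structured features."""
    rng = np.random.default_rng(seed)
    ids = [f"c{i}" for i in range(2 * n_per)]
    edges = []
    for g in range(2):
        for i in range(n_per - 1):
            edges.append((ids[g * n_per + i], ids[g * n_per + i + 1], 1.0))
    X = np.zeros((2 * n_per, dim))
    X[:n_per, : dim // 2] = 1.0
    X[n_per:, dim // 2 :] = 1.0
    X += rng.normal(scale=0.3, size=X.shape)
    return build_adjacency(ids, edges), X


class TestTrainGraph:
    def test_loss_decreases_and_deterministic(self):
        """Each epoch's loss is measured on freshly drawn stochastic views,
        so the descent is asserted on window means, not single epochs."""
        graph, X = _two_block_graph()
        cfg = GraphConfig(epochs=60, hidden_dim=8, out_dim=8, seed=4)
        z_a, hist = train_graph(graph, X, cfg)
        loss = np.asarray(hist["loss"])
        assert loss[-15:].mean() < loss[:15].mean()
        z_b, _ = train_graph(graph, X, cfg)
        np.testing.assert_array_equal(z_a, z_b)

    def test_separability_margin_exceeds_input_features(self):
        graph, X = _two_block_graph()
        cfg = GraphConfig(epochs=100, hidden_dim=8, out_dim=8, seed=4)
        z, _ = train_graph(graph, X, cfg)
        labels = np.repeat([0, 1], 8)

        def margin(M):
            u = M / np.linalg.norm(M, axis=1, keepdims=True)
            s = u @ u.T
            same = labels[:, None] == labels[None, :]
            off = ~np.eye(len(M), dtype=bool)
            return s[same & off].mean() - s[~same].mean()

        assert margin(z) > margin(X)

    def test_decorrelation_pressure(self):
        """The decorrelation term causally lowers the mean absolute
        off-diagonal of the embedding correlation matrix: training with
        lambda > 0 ends less correlated than the identical run at lambda = 0
        (the invariance term alone pushes toward a low-rank collapse)."""
        graph, X = _two_block_graph()
        off = {}
        for lam in (0.0, 0.05):
            cfg = GraphConfig(epochs=60, hidden_dim=8, out_dim=8, seed=4, lam=lam)
            _, hist = train_graph(graph, X, cfg)
            off[lam] = hist["offdiag_final"]
        assert off[0.05] < off[0.0]

    def test_sage_encoder_runs_and_is_seeded(self):
        graph, X = _two_block_graph()
        cfg = GraphConfig(epochs=5, hidden_dim=8, out_dim=8, seed=4, encoder="sage")
        z_a, _ = train_graph(graph, X, cfg)
        z_b, _ = train_graph(graph, X, cfg)
        assert z_a.shape == (16, 8)
        np.testing.assert_array_equal(z_a, z_b)
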