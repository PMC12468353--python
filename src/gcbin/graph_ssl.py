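"""Stage 2: assembly-graph self-supervision with a CCA-style objective.

The assembly graph (contigs as nodes, GFA links as edges, raw weights
max-normalized into (0, 1]) provides topological evidence that two contigs
belong to the same genome.  Each training iteration draws two stochastic
views of the graph — independent edge dropping and whole-column feature
masking — encodes both with a shared two-layer GCN

    Z = A_hat · ReLU(A_hat · X · W0) · W1,   A_hat = D~^{-1/2} (A + I) D~^{-1/2}

(self-loops are added before symmetric normalization so isolated contigs
keep a well-defined row), standardizes each embedding column to mean 0 and
L2 norm 1, and minimizes

    L = ||Z~A - Z~B||_F^2 + lambda (||Z~A^T Z~A - I||_F^2 + ||Z~B^T Z~B - I||_F^2)

an invariance term aligning the two views plus a decorrelation term pushing
the feature-correlation matrix toward the identity (negative-free
contrastive learning).  The per-column scaling by sigma*sqrt(N) is exactly
what makes diag(Z~^T Z~) = 1, which the decorrelation term presupposes.

A GraphSAGE-style encoder (fixed fan-out sampled mean aggregation) is
available as an alternative for large graphs via ``GraphConfig.encoder``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .nn import Adam, Tensor, glorot

__all__ = [
    "AssemblyGraph",
    "GraphConfig",
    "GcnEncoder",
    "SageEncoder",
    "build_adjacency",
    "normalize_adjacency",
    "augment_graph",
    "gcn_forward",
    "standardize",
    "cca_ssg_loss",
    "train_graph",
    "linear_probe",
]


@dataclass
class AssemblyGraph:
    """Undirected weighted contig graph with max-normalized edge weights."""

    node_ids: list[str]
    adjacency: sp.csr_matrix  # symmetric, weights in [0, 1]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def edge_array(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle edges as (row, col, weight) arrays."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return coo.row, coo.col, coo.data


def build_adjacency(
    node_ids: list[str], edges: list[tuple[str, str, float]]
) -> AssemblyGraph:
    """Assemble the symmetric adjacency from raw-weight edges.

    Raw weights (read counts supporting each link) are divided by the
    maximum raw weight so entries land in (0, 1]; absent links are exactly 0.
    Isolated contigs are kept as degree-0 nodes.
    """
    if not node_ids:
        raise ValueError("empty node set")
    index = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    if edges:
        w_max = max(w for _, _, w in edges)
        rows, cols, vals = [], [], []
        for u, v, w in edges:
            i, j = index[u], index[v]
            if i == j:
                continue
            rows += [i, j]
            cols += [j, i]
            vals += [w / w_max, w / w_max]
        adj = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        # reciprocal duplicates were collapsed upstream; sum any stragglers
        adj.sum_duplicates()
    else:
        adj = sp.csr_matrix((n, n))
    return AssemblyGraph(list(node_ids), adj)


def normalize_adjacency(adj: sp.spmatrix | AssemblyGraph) -> sp.csr_matrix:
    """Symmetric normalization with self-loops: D~^{-1/2} (A + I) D~^{-1/2}."""
    a = adj.adjacency if isinstance(adj, AssemblyGraph) else adj
    a = sp.csr_matrix(a, dtype=float)
    a_tilde = a + sp.identity(a.shape[0], format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    d_mat = sp.diags(d_inv_sqrt)
    return (d_mat @ a_tilde @ d_mat).tocsr()


def augment_graph(
    graph: AssemblyGraph,
    X: np.ndarray,
    drop_edge_p: float,
    drop_feat_p: float,
    rng: np.random.Generator,
) -> tuple[tuple[np.ndarray, sp.csr_matrix], tuple[np.ndarray, sp.csr_matrix]]:
    """Two independent stochastic views (X', A') of the graph.

    Each view independently drops every edge with probability
    ``drop_edge_p`` and zeroes entire feature columns (shared across nodes)
    with probability ``drop_feat_p``.
    """
    if not (0 <= drop_edge_p < 1 and 0 <= drop_feat_p < 1):
        raise ValueError("drop probabilities must lie in [0, 1)")
    rows, cols, vals = graph.edge_array()
    n = graph.n_nodes

    def one_view() -> tuple[np.ndarray, sp.csr_matrix]:
        keep = rng.random(len(vals)) >= drop_edge_p
        r, c, v = rows[keep], cols[keep], vals[keep]
        a = sp.csr_matrix(
            (np.concatenate([v, v]), (np.concatenate([r, c]), np.concatenate([c, r]))),
            shape=(n, n),
        )
        mask = rng.random(X.shape[1]) >= drop_feat_p
        xv = X * mask[None, :]
        return xv, a

    return one_view(), one_view()


class GcnEncoder:
    """Two-layer graph convolutional encoder (ReLU between layers only)."""

    def __init__(
        self,
        in_dim: int,
        hidden_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        n_layers: int = 2,
    ):
        dims = [in_dim] + [hidden_dim] * (n_layers - 1) + [out_dim]
        self.weights = [
            Tensor(glorot(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(n_layers)
        ]
        self.in_dim, self.out_dim = in_dim, out_dim

    @property
    def params(self) -> list[Tensor]:
        return list(self.weights)

    def forward(self, x: Tensor | np.ndarray, a_hat: sp.spmatrix) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        if h.shape[0] != a_hat.shape[0]:
            raise ValueError(
                f"feature rows {h.shape[0]} != graph nodes {a_hat.shape[0]}"
            )
        if h.shape[1] != self.in_dim:
            raise ValueError(f"feature dim {h.shape[1]} != encoder input {self.in_dim}")
        a_dense = Tensor(np.asarray(a_hat.todense()))
        n = len(self.weights)
        for l, w in enumerate(self.weights):
            h = a_dense @ h @ w
            if l < n - 1:
                h = h.relu()
        return h

    def state_dict(self) -> dict:
        return {"weights": [w.data.copy() for w in self.weights]}

    def load_state_dict(self, state: dict) -> None:
        for w, d in zip(self.weights, state["weights"]):
            w.data = d.copy()


class SageEncoder:
    """GraphSAGE-style encoder: sampled mean neighborhood aggregation.

    Each layer computes ReLU(H W_self + mean_{sampled neighbors} H W_neigh)
    with a fixed fan-out per hop (default 10).  Sampling is redrawn per
    forward pass from the provided rng, so large graphs never densify.
    """

    def __init__(
        self,
        in_dim: int,
        hidden_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        n_layers: int = 2,
        fanout: int = 10,
    ):
        dims = [in_dim] + [hidden_dim] * (n_layers - 1) + [out_dim]
        self.w_self = [
            Tensor(glorot(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(n_layers)
        ]
        self.w_neigh = [
            Tensor(glorot(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(n_layers)
        ]
        self.fanout = fanout
        self.in_dim, self.out_dim = in_dim, out_dim
        self._rng = rng

    @property
    def params(self) -> list[Tensor]:
        return [*self.w_self, *self.w_neigh]

    def _sample_mean_matrix(self, a: sp.spmatrix) -> np.ndarray:
        a = sp.csr_matrix(a)
        n = a.shape[0]
        s = np.zeros((n, n))
        for i in range(n):
            neigh = a.indices[a.indptr[i] : a.indptr[i + 1]]
            if len(neigh) == 0:
                s[i, i] = 1.0  # no neighbors: fall back to self
                continue
            if len(neigh) > self.fanout:
                neigh = self._rng.choice(neigh, size=self.fanout, replace=False)
            s[i, neigh] = 1.0 / len(neigh)
        return s

    def forward(self, x: Tensor | np.ndarray, a: sp.spmatrix) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        n = len(self.w_self)
        for l in range(n):
            s = Tensor(self._sample_mean_matrix(a))
            h = h @ self.w_self[l] + (s @ h) @ self.w_neigh[l]
            if l < n - 1:
                h = h.relu()
        return h

    def state_dict(self) -> dict:
        return {
            "w_self": [w.data.copy() for w in self.w_self],
            "w_neigh": [w.data.copy() for w in self.w_neigh],
        }

    def load_state_dict(self, state: dict) -> None:
        for w, d in zip(self.w_self, state["w_self"]):
            w.data = d.copy()
        for w, d in zip(self.w_neigh, state["w_neigh"]):
            w.data = d.copy()


def gcn_forward(
    X: np.ndarray, a_hat: sp.spmatrix, encoder: GcnEncoder
) -> np.ndarray:
    """Encode node features through the GCN without gradient tracking."""
    return encoder.forward(Tensor(X), a_hat).data


def standardize(z: Tensor | np.ndarray) -> Tensor:
    """Column standardization: (Z - mu) / (sigma * sqrt(N)).

    Every column of the result has mean 0 and L2 norm 1 (sigma is the
    population standard deviation, floored at 1e-12 so constant columns stay
    finite), hence diag(Z~^T Z~) = 1 as the decorrelation term requires.
    """
    zt = z if isinstance(z, Tensor) else Tensor(z)
    n = zt.shape[0]
    if n < 2:
        raise ValueError("standardization needs at least 2 rows")
    mu = zt.mean(axis=0, keepdims=True)
    c = zt - mu
    sigma = (c * c).mean(axis=0, keepdims=True).sqrt().clip_min(1e-12)
    return c / (sigma * float(np.sqrt(n)))


def cca_ssg_loss(
    za: Tensor | np.ndarray, zb: Tensor | np.ndarray, lam: float
) -> Tensor:
    """Invariance + decorrelation loss on standardized embeddings.

    ||Z~A - Z~B||_F^2 + lam * (||Z~A^T Z~A - I||_F^2 + ||Z~B^T Z~B - I||_F^2).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    a = za if isinstance(za, Tensor) else Tensor(za)
    b = zb if isinstance(zb, Tensor) else Tensor(zb)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    eye = np.eye(a.shape[1])
    diff = a - b
    invariance = (diff * diff).sum()
    ca = a.T @ a - eye
    cb = b.T @ b - eye
    decorrelation = (ca * ca).sum() + (cb * cb).sum()
    return invariance + float(lam) * decorrelation


@dataclass
class GraphConfig:
    """Stage-2 hyperparameters (paper-scale defaults)."""

    epochs: int = 100
    lr: float = 1e-3
    weight_decay: float = 0.0
    hidden_dim: int = 512
    out_dim: int = 512
    n_layers: int = 2
    drop_edge: float = 0.2
    drop_feat: float = 0.2
    lam: float = 0.001
    encoder: str = "gcn"  # or "sage"
    seed: int = 0


def train_graph(
    graph: AssemblyGraph,
    X: np.ndarray,
    config: GraphConfig,
) -> tuple[np.ndarray, dict]:
    """Self-supervised training on the assembly graph.

    Per epoch: draw two stochastic views, encode both with the shared
    encoder, standardize, minimize the CCA objective.  Returns the final
    embedding Z = f_theta(X, A_hat) on the unperturbed graph plus a history
    dict (loss trajectory, off-diagonal correlation at start/end).
    """
    if X.shape[0] != graph.n_nodes:
        raise ValueError("feature rows must align with graph nodes")
    rng = np.random.default_rng(config.seed)
    if config.encoder == "gcn":
        enc = GcnEncoder(X.shape[1], config.hidden_dim, config.out_dim, rng,
                         config.n_layers)
    elif config.encoder == "sage":
        enc = SageEncoder(X.shape[1], config.hidden_dim, config.out_dim, rng,
                          config.n_layers)
    else:
        raise ValueError(f"unknown encoder {config.encoder!r}")
    opt = Adam(enc.params, lr=config.lr, weight_decay=config.weight_decay)

    def offdiag_mean(z: np.ndarray) -> float:
        zt = standardize(Tensor(z)).data
        corr = zt.T @ zt
        off = corr - np.diag(np.diag(corr))
        return float(np.abs(off).mean())

    history: dict = {"loss": []}
    history["offdiag_init"] = offdiag_mean(
        enc.forward(Tensor(X), normalize_adjacency(graph)).data
    )
    for epoch in range(config.epochs):
        (xa, aa), (xb, ab) = augment_graph(
            graph, X, config.drop_edge, config.drop_feat, rng
        )
        za = enc.forward(Tensor(xa), normalize_adjacency(aa))
        zb = enc.forward(Tensor(xb), normalize_adjacency(ab))
        loss = cca_ssg_loss(standardize(za), standardize(zb), config.lam)
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"non-finite CCA loss at epoch {epoch}; aborting")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history["loss"].append(loss.item())

    z_final = enc.forward(Tensor(X), normalize_adjacency(graph)).data
    history["offdiag_final"] = offdiag_mean(z_final)
    return z_final, history


def linear_probe(
    Z: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    lr: float = 1e-2,
    weight_decay: float = 1e-4,
    epochs: int = 100,
) -> float:
    """Diagnostic linear evaluator: accuracy of a logistic classifier trained
    on frozen embeddings against gold labels.  Plays no role in binning."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(
        max_iter=max(epochs * 10, 1000), C=1.0 / max(weight_decay * len(Z), 1e-12),
        random_state=seed,
    )
    clf.fit(Z, labels)
    return float(clf.score(Z, labels))
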