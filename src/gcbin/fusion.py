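"""Stage 1: multimodal feature fusion trained with a multi-view NT-Xent loss.

Each contig enters as V views (the original sequence plus random crops),
every view carrying [TNF (136) || shared abundance (2M)] features.  A
three-layer fully connected network (2048-2048-128 by default, ReLU between
layers, L2 normalization on the output) maps each view to a unit-norm
embedding z_{i,v}.  Views of the same contig are positives, all other
in-batch embeddings are negatives, and the normalized temperature-scaled
cross entropy (NT-Xent) pulls positives together:

    L = -1/(N V (V-1)) sum_i sum_v sum_{v1 != v}
        log[ exp(cos(z_iv, z_iv1)/tau) / sum_{(j,v2) != (i,v)} exp(cos(z_iv, z_jv2)/tau) ]

The anchor's own term is excluded from the denominator (the defining
NT-Xent convention; the self-similarity exp(1/tau) would otherwise dominate
the sum).  Batches are sampled at contig level so all V views of a sampled
contig share a batch.  After training, a contig's embedding is the
renormalized mean of its view embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Tensor, glorot, l2_normalize_rows

__all__ = ["FusionConfig", "FusionNetwork", "nt_xent_loss", "train_fusion"]


@dataclass
class FusionConfig:
    """Stage-1 hyperparameters.

    Defaults follow the full-scale setting (layers 2048/2048/128, batch 1024
    contigs, 200 epochs with validation-based early stopping); desk-scale
    runs shrink these via the pipeline presets.  ``temperature`` is the
    NT-Xent tau (the sharpness of the contrastive softmax).
    """

    layer_sizes: tuple[int, ...] = (2048, 2048, 128)
    batch_size: int = 1024
    epochs: int = 200
    temperature: float = 0.5
    n_views: int = 6
    early_stop_patience: int = 20
    val_fraction: float = 0.1
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_views < 2:
            raise ValueError("need at least 2 views for a contrastive positive")
        if not (0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must lie in (0, 0.5)")


class FusionNetwork:
    """Fully connected projection network with unit-norm outputs.

    ReLU between hidden layers, no activation before the final L2
    normalization (standard projection-head design).
    """

    def __init__(self, in_dim: int, layer_sizes: tuple[int, ...], rng: np.random.Generator):
        dims = [in_dim, *layer_sizes]
        self.weights = [
            Tensor(glorot(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(len(layer_sizes))
        ]
        self.biases = [
            Tensor(np.zeros(d), requires_grad=True) for d in layer_sizes
        ]
        self.in_dim = in_dim
        self.out_dim = layer_sizes[-1]

    @property
    def params(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        if h.shape[-1] != self.in_dim:
            raise ValueError(
                f"input dim {h.shape[-1]} != network input size {self.in_dim}"
            )
        n = len(self.weights)
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if l < n - 1:
                h = h.relu()
        return l2_normalize_rows(h)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Forward pass without gradient tracking."""
        return self.forward(Tensor(x)).data

    def state_dict(self) -> dict:
        return {
            "weights": [w.data.copy() for w in self.weights],
            "biases": [b.data.copy() for b in self.biases],
        }

    def load_state_dict(self, state: dict) -> None:
        for w, d in zip(self.weights, state["weights"]):
            w.data = d.copy()
        for b, d in zip(self.biases, state["biases"]):
            b.data = d.copy()


def _nt_xent_masks(n_contigs: int, n_views: int) -> tuple[np.ndarray, np.ndarray]:
    n = n_contigs * n_views
    contig = np.repeat(np.arange(n_contigs), n_views)
    same = contig[:, None] == contig[None, :]
    eye = np.eye(n, dtype=bool)
    pos = same & ~eye
    offdiag = ~eye
    return pos.astype(float), offdiag.astype(float)


def nt_xent_loss(
    embeddings: Tensor | np.ndarray,
    n_contigs: int,
    n_views: int,
    temperature: float,
) -> Tensor:
    """Multi-view NT-Xent loss over a batch of unit-norm embeddings.

    ``embeddings`` has one row per (contig, view), contig-major (row
    i*V + v).  Returns a scalar Tensor (use ``.item()`` for the float).
    """
    if n_contigs < 2:
        raise ValueError("NT-Xent needs at least 2 contigs (no negatives otherwise)")
    z = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    n = n_contigs * n_views
    if z.shape[0] != n:
        raise ValueError(f"expected {n} embeddings, got {z.shape[0]}")
    pos, offdiag = _nt_xent_masks(n_contigs, n_views)
    sim = (z @ z.T) * (1.0 / temperature)
    denom = (sim.exp() * offdiag).sum(axis=1)
    log_denom_total = denom.log().sum() * float(n_views - 1)
    pos_total = (sim * pos).sum()
    return (log_denom_total - pos_total) / float(n_contigs * n_views * (n_views - 1))


def train_fusion(
    view_features: np.ndarray,
    config: FusionConfig,
) -> tuple[FusionNetwork, np.ndarray, dict]:
    """Train the fusion network; return (network, contig embeddings, history).

    ``view_features`` is (n_contigs * V) x F, contig-major.  A contig-level
    validation split is monitored for early stopping; the weights returned
    are those of the best validation epoch.  The per-contig embedding matrix
    (n_contigs x out_dim) is the renormalized mean over each contig's view
    embeddings.  Fully deterministic under ``config.seed``.
    """
    V = config.n_views
    total = view_features.shape[0]
    if total % V != 0:
        raise ValueError("row count not divisible by n_views")
    n_contigs = total // V
    if n_contigs < 2:
        raise ValueError("need at least 2 contigs")

    rng = np.random.default_rng(config.seed)
    net = FusionNetwork(view_features.shape[1], tuple(config.layer_sizes), rng)
    opt = Adam(net.params, lr=config.lr)

    order = rng.permutation(n_contigs)
    n_val = int(round(config.val_fraction * n_contigs))
    use_val = n_val >= 2 and n_contigs - n_val >= 2
    val_idx = order[:n_val] if use_val else np.empty(0, dtype=int)
    train_idx = order[n_val:] if use_val else order

    def batch_rows(contig_idx: np.ndarray) -> np.ndarray:
        return (contig_idx[:, None] * V + np.arange(V)[None, :]).ravel()

    def eval_loss(contig_idx: np.ndarray) -> float:
        x = view_features[batch_rows(contig_idx)]
        z = net.forward(Tensor(x))
        return nt_xent_loss(z.detach(), len(contig_idx), V, config.temperature).item()

    history: dict = {"train_loss": [], "val_loss": []}
    best_state = net.state_dict()
    best_val = np.inf
    best_epoch = -1
    patience_left = config.early_stop_patience

    bs = min(config.batch_size, len(train_idx))
    for epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(perm), bs):
            chunk = perm[start : start + bs]
            if len(chunk) < 2:
                continue  # a single contig has no in-batch negatives
            x = view_features[batch_rows(chunk)]
            z = net.forward(Tensor(x, requires_grad=False))
            loss = nt_xent_loss(z, len(chunk), V, config.temperature)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite NT-Xent loss at epoch {epoch}; aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if use_val:
            vl = eval_loss(val_idx)
            history["val_loss"].append(vl)
            if vl < best_val - 1e-12:
                best_val = vl
                best_epoch = epoch
                best_state = net.state_dict()
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if use_val:
        net.load_state_dict(best_state)
        history["best_epoch"] = best_epoch

    # collapse views: renormalized mean of each contig's view embeddings
    z_all = net.embed(view_features)
    z_contig = z_all.reshape(n_contigs, V, -1).mean(axis=1)
    norms = np.linalg.norm(z_contig, axis=1, keepdims=True)
    z_contig = z_contig / np.maximum(norms, 1e-12)
    return net, z_contig, history
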