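"""Clustering of contig embeddings into genome bins.

The default clusterer is length-weighted iterative medoid clustering on
cosine distance: seed each new bin on the longest unassigned contig, absorb
all unassigned contigs within a cosine radius r, re-center on the
length-weighted medoid of the members, and repeat until membership is
stable; then move to the next longest unassigned contig.  Long contigs
carry the most reliable composition/coverage signal, which is why they both
seed bins and dominate the medoid choice.  A k-means alternative with an
explicit k is available.  Bins whose total length falls below
``min_bin_size`` are relabeled unbinned — completeness and contamination
estimates are meaningless for tiny bins.
"""

from __future__ import annotations

import numpy as np

from .io import BinAssignment

__all__ = ["cluster_embeddings", "filter_bins"]


def _cosine_normalize(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    return Z / np.maximum(norms, 1e-12)


def cluster_embeddings(
    Z: np.ndarray,
    contig_ids: list[str],
    lengths: dict[str, int],
    method: str = "medoid",
    radius: float = 0.15,
    k: int | None = None,
    seed: int = 0,
    max_recenter: int = 20,
) -> BinAssignment:
    """Partition contigs by embedding similarity.

    ``medoid`` (default): iterative medoid clustering on cosine distance
    with absorption radius ``radius``; deterministic — seeding order is by
    decreasing length with contig-id tie-break, and contigs equidistant to
    two medoids stay with the earlier-seeded bin.  ``kmeans``: scikit-learn
    k-means on the normalized embeddings with explicit ``k``.
    """
    if len(Z) == 0:
        raise ValueError("no embeddings to cluster")
    if len(Z) != len(contig_ids):
        raise ValueError("embedding rows must match contig_ids")
    U = _cosine_normalize(np.asarray(Z, dtype=float))
    if method == "medoid":
        labels = _medoid_cluster(U, contig_ids, lengths, radius, max_recenter)
    elif method == "kmeans":
        if k is None:
            raise ValueError("kmeans requires an explicit k")
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(U)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # stable bin naming: order of first appearance
    remap: dict[int, str] = {}
    mapping: dict[str, str] = {}
    for cid, lab in zip(contig_ids, labels):
        if lab not in remap:
            remap[lab] = f"bin_{len(remap) + 1}"
        mapping[cid] = remap[lab]
    return BinAssignment(mapping)


def _medoid_cluster(
    U: np.ndarray,
    contig_ids: list[str],
    lengths: dict[str, int],
    radius: float,
    max_recenter: int,
) -> np.ndarray:
    n = len(U)
    lens = np.array([lengths[c] for c in contig_ids], dtype=float)
    labels = np.full(n, -1, dtype=int)
    # seeding order: longest first, contig-id tie-break (permutation invariant)
    rank = {
        i: r
        for r, i in enumerate(sorted(range(n), key=lambda i: (-lens[i], contig_ids[i])))
    }
    next_bin = 0
    while (labels == -1).any():
        unassigned = np.flatnonzero(labels == -1)
        seed_i = min(unassigned, key=rank.__getitem__)
        medoid = int(seed_i)
        members = None
        for _ in range(max_recenter):
            dist = 1.0 - U[unassigned] @ U[medoid]
            new_members = unassigned[dist <= radius + 1e-12]
            if members is not None and np.array_equal(new_members, members):
                break
            members = new_members
            # length-weighted medoid: member minimizing sum_c len_c * d(m, c)
            sub = U[members]
            cost = ((1.0 - sub @ sub.T) * lens[members][None, :]).sum(axis=1)
            medoid = int(members[int(np.argmin(cost))])  # first min: deterministic
        if members is None or len(members) == 0:
            members = np.array([seed_i])
        labels[members] = next_bin  # the medoid is always within radius of itself
        next_bin += 1
    return labels


def filter_bins(
    assignment: BinAssignment,
    lengths: dict[str, int],
    min_bin_size: int = 200_000,
) -> BinAssignment:
    """Relabel bins smaller than ``min_bin_size`` total bases as unbinned."""
    sizes = assignment.bin_sizes(lengths)
    mapping = {}
    for cid, b in assignment.contig_to_bin.items():
        if b != BinAssignment.UNBINNED and sizes.get(b, 0) < min_bin_size:
            mapping[cid] = BinAssignment.UNBINNED
        else:
            mapping[cid] = b
    return BinAssignment(mapping)
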