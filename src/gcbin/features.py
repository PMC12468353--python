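"""Contig feature modalities: canonical tetranucleotide frequency (TNF)
profiles, per-sample abundance profiles, and random-subsequence augmentation.

TNF pipeline per contig of length ``Li``: slide a k=4 window with stride 1
over the sequence (``Li - k + 1`` windows; windows containing N are
skipped), fold each 4-mer onto its reverse complement (256 raw 4-mers -> 136
canonical classes; palindromes are singletons), Laplace-smooth the counts,
and normalize to a 136-dim probability vector.  Canonical merging makes the
profile identical for a sequence and its reverse complement.

Abundance pipeline per contig across M samples: take the mean and standard
deviation of read coverage per sample, add a small epsilon (1e-5) so
zero-coverage samples stay finite, then max-normalize each column over all
contigs so every entry lies in [0, 1].  The final vector is the
concatenation [M normalized means, M normalized stds], i.e. 2M-dimensional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import ContigRecord, DepthTable

__all__ = [
    "CanonicalKmerIndex",
    "TnfVector",
    "AbundanceProfile",
    "ContigViewSet",
    "build_canonical_index",
    "compute_tnf",
    "tnf_matrix",
    "compute_abundance",
    "abundance_matrix",
    "augment_contig",
    "featurize_views",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
DEFAULT_EPSILON = 1e-5


def _revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def _decode(code: int, k: int) -> str:
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


@dataclass(frozen=True)
class CanonicalKmerIndex:
    """Mapping from each of the 4^k raw k-mers to a canonical class.

    A k-mer and its reverse complement share a class; classes are numbered in
    lexicographic order of each class's smaller member, a fixed layout so
    feature vectors are comparable across runs.  For k=4 this yields 136
    classes (120 complementary pairs + 16 palindromes).
    """

    k: int
    class_of: np.ndarray  # int array of length 4**k
    n_classes: int

    def class_index(self, kmer: str) -> int:
        code = 0
        for b in kmer:
            code = (code << 2) | _BASE_CODE[b]
        return int(self.class_of[code])


@lru_cache(maxsize=8)
def build_canonical_index(k: int = 4) -> CanonicalKmerIndex:
    """Enumerate all 4^k raw k-mers and merge reverse-complement pairs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = 4**k
    reps = np.empty(n, dtype=np.int64)
    for code in range(n):
        reps[code] = min(code, _revcomp_code(code, k))
    # class order = lexicographic (== numeric) order of the smaller member
    uniq = np.unique(reps)
    lookup = {int(r): i for i, r in enumerate(uniq)}
    class_of = np.array([lookup[int(r)] for r in reps], dtype=np.int64)
    class_of.setflags(write=False)
    return CanonicalKmerIndex(k=k, class_of=class_of, n_classes=len(uniq))


def _encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> -1."""
    table = np.full(128, -1, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        table[ord(b)] = c
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]


def _window_counts(seq: str, index: CanonicalKmerIndex) -> np.ndarray:
    """Canonical-class counts over all stride-1 windows; N windows skipped."""
    k = index.k
    codes = _encode_sequence(seq)
    n_win = len(codes) - k + 1
    if n_win < 1:
        raise ValueError(f"sequence shorter than k={k}")
    # rolling base-4 window codes
    win = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        col = codes[j : j + n_win]
        win = (win << 2) | np.maximum(col, 0)
        valid &= col >= 0
    counts = np.bincount(
        index.class_of[win[valid]], minlength=index.n_classes
    )
    return counts


@dataclass(frozen=True)
class TnfVector:
    """Canonical 4-mer profile of one contig: integer counts per class, the
    raw relative frequencies, their smoothed form, and the final probability
    vector (sums to 1)."""

    counts: np.ndarray
    raw_freq: np.ndarray
    smoothed: np.ndarray
    probs: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return self.probs


def compute_tnf(
    contig: ContigRecord | str,
    index: CanonicalKmerIndex | None = None,
    smoothing: str = "counts",
) -> TnfVector:
    """Canonical TNF probability vector for one contig.

    ``smoothing="counts"`` (default) applies Laplace smoothing at the count
    level, probs_j = (N_j + 1) / (sum_j N_j + n_classes), which preserves the
    compositional signal.  ``smoothing="freq"`` adds 1 to each relative
    frequency before renormalizing; it is retained for fidelity experiments
    but flattens the profile toward uniform.
    """
    if index is None:
        index = build_canonical_index(4)
    seq = contig.sequence if isinstance(contig, ContigRecord) else contig
    if set(seq) <= {"N"}:
        raise ValueError("all-N sequence has no informative k-mers")
    counts = _window_counts(seq, index)
    n_windows = len(seq) - index.k + 1
    raw = counts / n_windows
    if smoothing == "counts":
        smoothed = counts + 1.0
        probs = smoothed / smoothed.sum()
    elif smoothing == "freq":
        smoothed = raw + 1.0
        probs = smoothed / smoothed.sum()
    else:
        raise ValueError(f"unknown smoothing mode {smoothing!r}")
    return TnfVector(counts=counts, raw_freq=raw, smoothed=smoothed, probs=probs)


def tnf_matrix(
    sequences: list[str],
    index: CanonicalKmerIndex | None = None,
    smoothing: str = "counts",
) -> np.ndarray:
    if index is None:
        index = build_canonical_index(4)
    return np.stack(
        [compute_tnf(s, index, smoothing).probs for s in sequences]
    )


# ---------------------------------------------------------------------------
# Abundance


@dataclass(frozen=True)
class AbundanceProfile:
    """Normalized coverage features of one contig: epsilon-smoothed mean/std
    values and the [0,1] max-normalized 2M-dim vector."""

    smoothed_mean: np.ndarray
    smoothed_std: np.ndarray
    vector: np.ndarray  # [normalized means (M), normalized stds (M)]


def _column_maxima(depths: DepthTable, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    mean_max = (depths.mean_cov + epsilon).max(axis=0)
    std_max = (depths.std_cov + epsilon).max(axis=0)
    return mean_max, std_max


def compute_abundance(
    depths: DepthTable, contig_id: str, epsilon: float = DEFAULT_EPSILON
) -> AbundanceProfile:
    """Per-sample epsilon-smoothed, max-normalized coverage features.

    Contigs absent from the table are treated as all-zero coverage rows; the
    per-sample normalizer is the maximum smoothed value over the contigs in
    the table.  A sample whose coverage is zero for every contig normalizes
    to a column of ones (with a warning).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mean, std = depths.row(contig_id)
    sm_mean = mean + epsilon
    sm_std = std + epsilon
    mean_max, std_max = _column_maxima(depths, epsilon)
    if np.any(mean_max <= epsilon):
        warnings.warn("sample with zero coverage for every contig; column of ones")
    vec = np.concatenate([sm_mean / mean_max, sm_std / std_max])
    return AbundanceProfile(sm_mean, sm_std, vec)


def abundance_matrix(
    depths: DepthTable,
    contig_ids: list[str],
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """N x 2M matrix of abundance vectors, rows ordered as ``contig_ids``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mean_max, std_max = _column_maxima(depths, epsilon)
    if np.any(mean_max <= epsilon):
        warnings.warn("sample with zero coverage for every contig; column of ones")
    rows = []
    for cid in contig_ids:
        mean, std = depths.row(cid)
        rows.append(
            np.concatenate([(mean + epsilon) / mean_max, (std + epsilon) / std_max])
        )
    return np.stack(rows)


# ---------------------------------------------------------------------------
# Augmentation


@dataclass(frozen=True)
class ContigViewSet:
    """Multiple views of one contig: the original plus random crops.

    ``crop_spans`` are half-open 0-based (start, end) into the parent;
    views[0] is always the uncropped parent.
    """

    parent_id: str
    views: tuple[str, ...]
    crop_spans: tuple[tuple[int, int], ...]


def augment_contig(
    contig: ContigRecord,
    n_views: int = 5,
    min_frac: float = 0.5,
    max_frac: float = 0.9,
    rng: np.random.Generator | None = None,
    min_crop: int = 1000,
) -> ContigViewSet:
    """Random Subsequence Extraction: the original plus ``n_views`` crops.

    Crop lengths are uniform in [min_frac*Li, max_frac*Li], floored at
    min(Li, ``min_crop``) so short contigs are never shredded below a usable
    size; crop starts are uniform.  Deterministic under a seeded ``rng``.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if not (0 < min_frac <= max_frac <= 1):
        raise ValueError("need 0 < min_frac <= max_frac <= 1")
    if rng is None:
        rng = np.random.default_rng()
    L = contig.length
    floor = min(L, min_crop)
    views = [contig.sequence]
    spans = [(0, L)]
    for _ in range(n_views):
        lo = max(floor, int(round(min_frac * L)))
        hi = max(lo, int(round(max_frac * L)))
        crop_len = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, L - crop_len + 1))
        views.append(contig.sequence[start : start + crop_len])
        spans.append((start, start + crop_len))
    return ContigViewSet(contig.contig_id, tuple(views), tuple(spans))


def featurize_views(
    views: ContigViewSet,
    abundance: AbundanceProfile | np.ndarray,
    index: CanonicalKmerIndex | None = None,
    smoothing: str = "counts",
) -> np.ndarray:
    """Per-view feature vectors: [TNF of the view (136) || abundance (2M)].

    The abundance half is the parent contig's and is shared across all views
    (crops inherit the parent's coverage; no per-crop read mapping exists).
    """
    if index is None:
        index = build_canonical_index(4)
    ab = abundance.vector if isinstance(abundance, AbundanceProfile) else abundance
    rows = []
    for seq in views.views:
        tnf = compute_tnf(seq, index, smoothing).probs
        rows.append(np.concatenate([tnf, ab]))
    return np.stack(rows)
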