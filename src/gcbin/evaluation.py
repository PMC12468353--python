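"""Gold-standard bin quality assessment (AMBER-style).

Given a predicted bin assignment and a gold-standard contig-to-genome map,
the bins x genomes overlap matrix L accumulates, in bases, how much of each
bin maps to each genome.  From L:

* purity of bin i     = max_j L_ij / sum_j L_ij  (dominant-genome fraction)
* contamination       = 1 - purity
* AP                  = mean purity over bins, reported both unweighted and
                        bp-weighted (each bin weighted by its mapped bases)
* completeness of genome j = sum_i L_ij / G_j, with G_j the genome length;
  AC is the mean over genomes (a best-bin variant scores only the single
  largest bin per genome)
* per-bin completeness (for HQ counting) = L_ij* / G_j* for the bin's
  dominant genome j*
* F1_i                = harmonic mean of bin purity and bin completeness
* HQ bins (MIMAG)     = completeness >= 0.90 and contamination <= 0.05

Unbinned contigs and contigs without a gold label never contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import BinAssignment, GoldStandardMap

__all__ = [
    "OverlapMatrix",
    "BinQualityReport",
    "overlap_matrix",
    "average_purity",
    "average_completeness",
    "bin_f1",
    "count_hq_bins",
    "evaluate_binning",
]


@dataclass
class OverlapMatrix:
    """L[i, j] = total bases of contigs in bin i mapping to genome j."""

    bin_ids: list[str]
    genome_ids: list[str]
    L: np.ndarray  # bins x genomes, bases

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (len(self.bin_ids), len(self.genome_ids)):
            raise ValueError("overlap matrix shape mismatch")
        if (self.L < 0).any():
            raise ValueError("negative overlap")


def overlap_matrix(
    assignment: BinAssignment,
    gold: GoldStandardMap,
    lengths: dict[str, int],
) -> OverlapMatrix:
    """Accumulate bin-vs-genome overlaps in bases.

    Unbinned contigs are excluded; binned contigs without a gold label are
    excluded with a warning.
    """
    genomes = gold.genomes
    g_index = {g: j for j, g in enumerate(genomes)}
    bins = sorted(assignment.bins())
    b_index = {b: i for i, b in enumerate(bins)}
    L = np.zeros((len(bins), len(genomes)))
    unlabeled = 0
    for cid, b in assignment.contig_to_bin.items():
        if b == BinAssignment.UNBINNED:
            continue
        g = gold.contig_to_genome.get(cid)
        if g is None:
            unlabeled += 1
            continue
        L[b_index[b], g_index[g]] += lengths[cid]
    if unlabeled:
        warnings.warn(f"{unlabeled} binned contigs lack a gold label; excluded")
    return OverlapMatrix(bins, genomes, L)


def average_purity(overlap: OverlapMatrix, bp_weighted: bool = False) -> float:
    """Mean over bins of max_j L_ij / sum_j L_ij.

    ``bp_weighted=True`` weights each bin by its mapped bases (the AMBER
    "AP (bp)" convention); bins with zero mapped bases are skipped with a
    warning.
    """
    row_sums = overlap.L.sum(axis=1)
    ok = row_sums > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} bins with zero mapped bases skipped")
    if not ok.any():
        raise ValueError("no bins with mapped bases")
    purity = overlap.L[ok].max(axis=1) / row_sums[ok]
    if bp_weighted:
        return float(np.average(purity, weights=row_sums[ok]))
    return float(purity.mean())


def average_completeness(
    overlap: OverlapMatrix,
    gold: GoldStandardMap,
    best_bin_only: bool = False,
) -> float:
    """Mean over genomes of recovered fraction sum_i L_ij / G_j.

    By default bases from all bins count toward a genome; with
    ``best_bin_only`` each genome is credited only with its single
    best-recovering bin (the stricter AMBER reading).
    """
    g = np.array([gold.genome_lengths[j] for j in overlap.genome_ids], dtype=float)
    if (g <= 0).any():
        raise ValueError("genome with non-positive length")
    if overlap.L.size == 0:
        return 0.0
    recovered = (
        overlap.L.max(axis=0) if best_bin_only else overlap.L.sum(axis=0)
    )
    return float(np.mean(np.minimum(recovered / g, 1.0)))


def bin_f1(purity: float, completeness: float) -> float:
    """Harmonic mean of purity and completeness; 0 when both are 0."""
    if not (0 <= purity <= 1 and 0 <= completeness <= 1):
        raise ValueError("purity and completeness must lie in [0, 1]")
    if purity + completeness == 0:
        return 0.0
    return 2.0 * purity * completeness / (purity + completeness)


@dataclass
class BinQualityReport:
    """Per-bin and summary quality metrics versus a gold standard."""

    bin_ids: list[str]
    purity: np.ndarray
    completeness: np.ndarray  # of each bin's dominant genome
    contamination: np.ndarray
    f1_per_bin: np.ndarray
    dominant_genome: list[str]
    ap: float  # unweighted mean purity
    ap_bp: float  # bp-weighted mean purity (headline)
    ac: float
    ac_best_bin: float
    f1: float
    hq_count: int
    thresholds: tuple[float, float] = (0.90, 0.05)

    def summary(self) -> dict:
        return {
            "n_bins": len(self.bin_ids),
            "average_purity_bp": self.ap_bp,
            "average_purity": self.ap,
            "average_completeness": self.ac,
            "average_completeness_best_bin": self.ac_best_bin,
            "f1": self.f1,
            "hq_bins": self.hq_count,
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_id\tdominant_genome\tpurity\tcompleteness\tcontamination\tf1\n")
            for i, b in enumerate(self.bin_ids):
                fh.write(
                    f"{b}\t{self.dominant_genome[i]}\t{self.purity[i]:.4f}\t"
                    f"{self.completeness[i]:.4f}\t{self.contamination[i]:.4f}\t"
                    f"{self.f1_per_bin[i]:.4f}\n"
                )
            s = self.summary()
            fh.write(
                f"#summary\tAP_bp={s['average_purity_bp']:.4f}\t"
                f"AP={s['average_purity']:.4f}\tAC={s['average_completeness']:.4f}\t"
                f"F1={s['f1']:.4f}\tHQ={s['hq_bins']}\n"
            )


def count_hq_bins(
    completeness: np.ndarray,
    contamination: np.ndarray,
    completeness_min: float = 0.90,
    contamination_max: float = 0.05,
) -> int:
    """MIMAG high-quality bins: completeness >= 90% and contamination <= 5%."""
    c = np.asarray(completeness, dtype=float)
    k = np.asarray(contamination, dtype=float)
    return int(((c >= completeness_min) & (k <= contamination_max)).sum())


def evaluate_binning(
    assignment: BinAssignment,
    gold: GoldStandardMap,
    lengths: dict[str, int],
    completeness_min: float = 0.90,
    contamination_max: float = 0.05,
) -> BinQualityReport:
    """Full AMBER-style report for one bin assignment."""
    overlap = overlap_matrix(assignment, gold, lengths)
    row_sums = overlap.L.sum(axis=1)
    ok = row_sums > 0
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        raise ValueError("no bins with gold-labeled contigs")
    L = overlap.L[idx]
    bins = [overlap.bin_ids[i] for i in idx]
    sums = row_sums[idx]
    dom_j = L.argmax(axis=1)
    purity = L[np.arange(len(L)), dom_j] / sums
    g_len = np.array(
        [gold.genome_lengths[overlap.genome_ids[j]] for j in dom_j], dtype=float
    )
    completeness = np.minimum(L[np.arange(len(L)), dom_j] / g_len, 1.0)
    contamination = 1.0 - purity
    f1_bins = np.array([bin_f1(p, c) for p, c in zip(purity, completeness)])
    return BinQualityReport(
        bin_ids=bins,
        purity=purity,
        completeness=completeness,
        contamination=contamination,
        f1_per_bin=f1_bins,
        dominant_genome=[overlap.genome_ids[j] for j in dom_j],
        ap=average_purity(overlap),
        ap_bp=average_purity(overlap, bp_weighted=True),
        ac=average_completeness(overlap, gold),
        ac_best_bin=average_completeness(overlap, gold, best_bin_only=True),
        f1=float(f1_bins.mean()),
        hq_count=count_hq_bins(
            completeness, contamination, completeness_min, contamination_max
        ),
        thresholds=(completeness_min, contamination_max),
    )
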