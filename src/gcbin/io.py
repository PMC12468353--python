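"""Readers and writers for the on-disk formats the binning pipeline touches.

Formats handled: contig FASTA, assembly graphs in GFA 1.0 (``S``/``L`` lines,
``RC:i`` read-count tags honored), per-sample depth tables (the
``jgi_summarize_bam_contig_depths`` dialect auto-detected by its
``contigName`` header token, or a plain ``contig_id`` + M mean + M std
dialect), gold-standard contig-to-genome maps, and two-column bin
assignment TSVs.  Plain and gzip-compressed streams are supported.

Contig identifiers are truncated at the first whitespace in every format so
that FASTA, GFA, depth tables and gold standards join on a consistent key.
"""

from __future__ import annotations

import gzip
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ContigRecord",
    "DepthTable",
    "GoldStandardMap",
    "BinAssignment",
    "read_fasta",
    "write_fasta",
    "read_gfa",
    "read_depth_table",
    "write_depth_table",
    "read_gold_standard",
    "write_gold_standard",
    "read_bins",
    "write_bins",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _open(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class ContigRecord:
    """One assembled sequence: id (header up to first whitespace), uppercase
    DNA over {A,C,G,T,N}, and its length in bases."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> str:
        return self.sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class DepthTable:
    """Per-contig, per-sample mean and standard-deviation read coverage.

    ``mean_cov`` and ``std_cov`` are N x M arrays (reads per base), row order
    matching ``contig_ids``.
    """

    contig_ids: list[str]
    mean_cov: np.ndarray
    std_cov: np.ndarray
    sample_names: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mean_cov = np.asarray(self.mean_cov, dtype=float)
        self.std_cov = np.asarray(self.std_cov, dtype=float)
        if self.mean_cov.shape != self.std_cov.shape:
            raise ValueError("mean_cov and std_cov shapes differ")
        if self.mean_cov.shape != (len(self.contig_ids), len(self.sample_names)):
            raise ValueError("depth matrix shape inconsistent with ids/samples")
        if (self.mean_cov < 0).any() or (self.std_cov < 0).any():
            raise ValueError("negative depth values")
        self._index = {c: i for i, c in enumerate(self.contig_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def row(self, contig_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Mean/std row for a contig; all-zero rows for contigs absent from
        the table (they received no mapped reads)."""
        i = self._index.get(contig_id)
        if i is None:
            m = np.zeros(self.n_samples)
            return m, m.copy()
        return self.mean_cov[i], self.std_cov[i]


@dataclass
class GoldStandardMap:
    """Ground-truth contig-to-genome assignment with genome lengths Gj."""

    contig_to_genome: dict[str, str]
    genome_lengths: dict[str, int]

    def __post_init__(self) -> None:
        used = set(self.contig_to_genome.values())
        for g in used:
            if self.genome_lengths.get(g, 0) <= 0:
                raise ValueError(f"genome {g!r} lacks a positive length")
        # genomes with no contigs are dropped
        self.genome_lengths = {
            g: int(l) for g, l in self.genome_lengths.items() if g in used
        }

    @property
    def genomes(self) -> list[str]:
        return sorted(self.genome_lengths)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_lengths)


@dataclass
class BinAssignment:
    """Predicted contig-to-bin map; ``UNBINNED`` marks contigs dropped by
    bin-size filtering."""

    contig_to_bin: dict[str, str]
    UNBINNED = "unbinned"

    def bins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for c, b in self.contig_to_bin.items():
            if b != self.UNBINNED:
                out.setdefault(b, []).append(c)
        return out

    def bin_sizes(self, lengths: dict[str, int]) -> dict[str, int]:
        return {
            b: sum(lengths[c] for c in members)
            for b, members in self.bins().items()
        }


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ContigRecord]:
    """Parse a FASTA file into contig records.

    Sequences are uppercased and RNA ``U`` is normalized to ``T``; ids are
    truncated at the first whitespace.  Duplicate ids and empty files are
    errors.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        if name in seen:
            raise ValueError(f"duplicate contig id {name!r} in {path}")
        seen.add(name)
        records.append(ContigRecord(name, "".join(chunks)))

    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line.upper().replace("U", "T"))
        flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[ContigRecord], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFA 1.0


def read_gfa(
    path,
    min_length: int = 1000,
    sequences: dict[str, str] | None = None,
) -> tuple[list[ContigRecord], list[tuple[str, str, float]]]:
    """Parse a GFA 1.0 assembly graph into nodes and undirected edges.

    ``S`` lines become nodes (segments shorter than ``min_length`` are
    dropped, along with their links).  ``L`` lines become undirected edges
    with orientation discarded; reciprocal/duplicate links collapse to a
    single edge with summed raw weight.  Raw edge weight is the ``RC:i``
    read-count tag when present, else 1.  Self-links are dropped.  Segments
    recorded as ``*`` take their sequence from ``sequences`` (e.g. the
    companion FASTA).
    """
    seqs: dict[str, str] = {}
    lengths: dict[str, int] = {}
    raw_edges: dict[tuple[str, str], float] = {}
    n_s = 0
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "#H":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed S line")
                n_s += 1
                name = fields[1].split()[0]
                seq = fields[2]
                if seq == "*":
                    length = None
                    for tag in fields[3:]:
                        if tag.startswith("LN:i:"):
                            length = int(tag[5:])
                    if sequences is not None and name in sequences:
                        seqs[name] = sequences[name]
                        length = len(sequences[name])
                    if length is None:
                        raise ValueError(
                            f"{path}:{lineno}: segment {name!r} has no sequence, "
                            "no LN tag and no FASTA fallback"
                        )
                    lengths[name] = length
                else:
                    seq = seq.upper().replace("U", "T")
                    seqs[name] = seq
                    lengths[name] = len(seq)
            elif fields[0] == "L":
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: malformed L line")
                u, v = fields[1].split()[0], fields[3].split()[0]
                if u not in lengths or v not in lengths:
                    warnings.warn(
                        f"{path}:{lineno}: link references unknown segment; skipped"
                    )
                    continue
                if u == v:
                    continue
                weight = 1.0
                for tag in fields[5:]:
                    if tag.startswith("RC:i:"):
                        weight = float(int(tag[5:]))
                key = (u, v) if u <= v else (v, u)
                raw_edges[key] = raw_edges.get(key, 0.0) + weight
    if n_s == 0:
        raise ValueError(f"{path}: no S lines — not an assembly graph")

    keep = {n for n, l in lengths.items() if l >= min_length}
    records = []
    for n in lengths:
        if n not in keep:
            continue
        if n in seqs:
            records.append(ContigRecord(n, seqs[n]))
        else:
            raise ValueError(
                f"segment {n!r} has no sequence; pass `sequences=` from the FASTA"
            )
    edges = [
        (u, v, w) for (u, v), w in raw_edges.items() if u in keep and v in keep
    ]
    return records, edges


def read_gfa_skeleton(
    path, min_length: int = 0
) -> tuple[list[str], dict[str, int], list[tuple[str, str, float]]]:
    """Topology-only GFA parse: node ids, lengths, and raw-weight edges.

    Accepts ``*`` segments with an ``LN`` tag; used when sequences live in a
    companion FASTA and only the graph structure is needed.
    """
    lengths: dict[str, int] = {}
    raw_edges: dict[tuple[str, str], float] = {}
    n_s = 0
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "#H":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                n_s += 1
                name = fields[1].split()[0]
                if fields[2] == "*":
                    ln = None
                    for tag in fields[3:]:
                        if tag.startswith("LN:i:"):
                            ln = int(tag[5:])
                    if ln is None:
                        raise ValueError(
                            f"{path}:{lineno}: '*' segment without LN tag"
                        )
                    lengths[name] = ln
                else:
                    lengths[name] = len(fields[2])
            elif fields[0] == "L":
                u, v = fields[1].split()[0], fields[3].split()[0]
                if u not in lengths or v not in lengths:
                    warnings.warn(
                        f"{path}:{lineno}: link references unknown segment; skipped"
                    )
                    continue
                if u == v:
                    continue
                weight = 1.0
                for tag in fields[5:]:
                    if tag.startswith("RC:i:"):
                        weight = float(int(tag[5:]))
                key = (u, v) if u <= v else (v, u)
                raw_edges[key] = raw_edges.get(key, 0.0) + weight
    if n_s == 0:
        raise ValueError(f"{path}: no S lines — not an assembly graph")
    keep = {n for n, l in lengths.items() if l >= min_length}
    node_ids = [n for n in lengths if n in keep]
    edges = [(u, v, w) for (u, v), w in raw_edges.items() if u in keep and v in keep]
    return node_ids, {n: lengths[n] for n in node_ids}, edges


# ---------------------------------------------------------------------------
# Depth tables


def read_depth_table(path) -> DepthTable:
    """Read a coverage table, auto-detecting the dialect from the header.

    jgi dialect (``jgi_summarize_bam_contig_depths``): columns contigName,
    contigLen, totalAvgDepth, then (mean, variance) pairs per sample;
    variance is converted to standard deviation.  Plain dialect: contig_id,
    M mean columns, then M std columns.
    """
    with _open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty depth table")
    header = lines[0].split("\t")
    jgi = header[0] == "contigName"
    ids: list[str] = []
    rows: list[list[float]] = []
    ncol = len(header)
    for lineno, line in enumerate(lines[1:], 2):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {ncol})"
            )
        ids.append(fields[0].split()[0])
        vals = [float(x) for x in fields[1:]]
        if any(v < 0 for v in vals[(2 if jgi else 0):]):
            raise ValueError(f"{path}:{lineno}: negative depth")
        rows.append(vals)
    data = np.asarray(rows, dtype=float)
    if jgi:
        if (ncol - 3) % 2 != 0:
            raise ValueError(f"{path}: jgi dialect needs paired mean/var columns")
        m = (ncol - 3) // 2
        mean = data[:, 2::2]
        var = data[:, 3::2]
        names = [header[3 + 2 * k].removesuffix(".bam") for k in range(m)]
        return DepthTable(ids, mean, np.sqrt(var), names)
    if (ncol - 1) % 2 != 0:
        raise ValueError(f"{path}: plain dialect needs M mean + M std columns")
    m = (ncol - 1) // 2
    names = [header[1 + k].removeprefix("mean_") for k in range(m)]
    return DepthTable(ids, data[:, :m], data[:, m:], names)


def write_depth_table(depths: DepthTable, path) -> None:
    """Write the plain dialect: contig_id, mean_<s>... std_<s>..."""
    with _open(path, "wt") as fh:
        cols = (
            ["contig_id"]
            + [f"mean_{s}" for s in depths.sample_names]
            + [f"std_{s}" for s in depths.sample_names]
        )
        fh.write("\t".join(cols) + "\n")
        for i, cid in enumerate(depths.contig_ids):
            vals = list(depths.mean_cov[i]) + list(depths.std_cov[i])
            fh.write(cid + "\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")


# ---------------------------------------------------------------------------
# Gold standards and bin tables


def read_gold_standard(
    path, contig_lengths: dict[str, int] | None = None
) -> GoldStandardMap:
    """Read a contig→genome TSV; optional third column gives genome length.

    Without a length column, Gj falls back to the sum of member contig
    lengths taken from ``contig_lengths``.
    """
    mapping: dict[str, str] = {}
    glen: dict[str, int] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need at least 2 columns")
            cid = fields[0].split()[0]
            genome = fields[1].split()[0]
            if cid in mapping and mapping[cid] != genome:
                raise ValueError(
                    f"{path}:{lineno}: contig {cid!r} mapped to both "
                    f"{mapping[cid]!r} and {genome!r}"
                )
            mapping[cid] = genome
            if len(fields) >= 3 and fields[2]:
                glen[genome] = int(float(fields[2]))
    if not mapping:
        raise ValueError(f"{path}: empty gold standard")
    missing = {g for g in mapping.values() if g not in glen}
    if missing:
        if contig_lengths is None:
            raise ValueError(
                f"{path}: genomes {sorted(missing)} lack a length column and no "
                "contig lengths were provided for the fallback"
            )
        for cid, g in mapping.items():
            if g in missing:
                glen[g] = glen.get(g, 0) + contig_lengths[cid]
    return GoldStandardMap(mapping, glen)


def write_gold_standard(gold: GoldStandardMap, path) -> None:
    with _open(path, "wt") as fh:
        for cid, g in gold.contig_to_genome.items():
            fh.write(f"{cid}\t{g}\t{gold.genome_lengths[g]}\n")


def read_bins(path) -> BinAssignment:
    mapping: dict[str, str] = {}
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig_id\t"):
                continue
            cid, bin_id = line.split("\t")[:2]
            mapping[cid.split()[0]] = bin_id
    if not mapping:
        raise ValueError(f"{path}: empty bin table")
    return BinAssignment(mapping)


def write_bins(
    assignment: BinAssignment,
    out_tsv,
    contigs: Sequence[ContigRecord] | None = None,
    fasta_dir=None,
) -> None:
    """Write a two-column bin TSV and, when contigs are given, one FASTA per
    bin under ``fasta_dir``."""
    if not assignment.contig_to_bin:
        raise ValueError("empty bin assignment")
    if contigs is not None:
        by_id = {c.contig_id: c for c in contigs}
        unknown = set(assignment.contig_to_bin) - set(by_id)
        if unknown:
            raise ValueError(f"assignment references unknown contigs: {sorted(unknown)[:5]}")
    with _open(out_tsv, "wt") as fh:
        fh.write("contig_id\tbin_id\n")
        for cid, b in assignment.contig_to_bin.items():
            fh.write(f"{cid}\t{b}\n")
    if contigs is not None and fasta_dir is not None:
        os.makedirs(fasta_dir, exist_ok=True)
        for b, members in assignment.bins().items():
            write_fasta(
                [by_id[c] for c in members], os.path.join(fasta_dir, f"{b}.fa")
            )
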