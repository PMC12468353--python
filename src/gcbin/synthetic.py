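"""Synthetic labeled communities for offline testing of the whole pipeline.

The generator emulates the statistical structure the binner relies on,
without any external data:

* **Genomes** are emitted by per-genome 3rd-order Markov chains whose
  transition rows are Dirichlet perturbations of uniform; the perturbation
  strength controls how distinguishable genomes are in 4-mer space (0 means
  compositionally indistinguishable genomes).
* **Contigs** are contiguous genome fragments with lengths uniform in a
  configurable range; fragments tile each genome exactly, so per-genome
  contig lengths sum to the genome length.
* **Coverage** follows a Dirichlet community-abundance model: per sample,
  genome proportions are drawn from Dirichlet(alpha), scaled to a total
  depth, and multiplied by per-contig lognormal noise (mean 1, configurable
  CV); std coverage is mean times a per-contig unevenness factor.
* **The assembly graph** links genome-adjacent fragments, plus a
  controllable fraction of spurious inter-genome links.
* **The gold standard** records the true genome of every contig and the
  true genome lengths.

Everything is reproducible bit-for-bit from the CommunitySpec seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .io import (
    ContigRecord,
    DepthTable,
    GoldStandardMap,
    write_depth_table,
    write_fasta,
    write_gold_standard,
)

__all__ = [
    "CommunitySpec",
    "Community",
    "generate_genomes",
    "fragment_genomes",
    "simulate_coverage",
    "generate_community",
    "write_fixture",
    "DESK_SPEC",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one synthetic community.

    ``tnf_bias_strength`` >= 0 scales the Dirichlet perturbation of each
    genome's Markov transition rows (0 = uniform, larger = more distinct
    composition).  ``abundance_concentration`` is the Dirichlet alpha for
    per-sample genome proportions (small alpha = uneven communities).
    ``coverage_noise_cv`` is the coefficient of variation of the lognormal
    per-contig depth noise.  ``spurious_edge_frac`` adds that fraction of
    the true edge count as random inter-genome links.
    """

    n_genomes: int = 8
    genome_length: int = 100_000
    n_samples: int = 3
    contig_length_range: tuple[int, int] = (2_000, 10_000)
    tnf_bias_strength: float = 2.0
    abundance_concentration: float = 1.0
    coverage_noise_cv: float = 0.05
    spurious_edge_frac: float = 0.0
    total_depth: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.contig_length_range
        if min(self.n_genomes, self.genome_length, self.n_samples, lo, hi) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.spurious_edge_frac < 1):
            raise ValueError("spurious_edge_frac must lie in [0, 1)")
        if self.tnf_bias_strength < 0:
            raise ValueError("tnf_bias_strength must be >= 0")
        if lo > hi or self.genome_length < lo:
            raise ValueError("invalid contig length range")


# the default desk-scale community used throughout the test suite
DESK_SPEC = CommunitySpec()


@dataclass
class Community:
    """One fully generated community with its gold labels."""

    spec: CommunitySpec
    genomes: list[str]
    contigs: list[ContigRecord]
    gold: GoldStandardMap
    edges: list[tuple[str, str, float]]  # raw-weight skeleton
    n_true_edges: int
    depths: DepthTable

    @property
    def lengths(self) -> dict[str, int]:
        return {c.contig_id: c.length for c in self.contigs}


def _markov_transitions(
    rng: np.random.Generator, order: int, strength: float
) -> np.ndarray:
    """(4^order, 4) transition rows; uniform when strength is 0."""
    n_ctx = 4**order
    if strength == 0:
        return np.full((n_ctx, 4), 0.25)
    conc = 1.0 / strength
    return rng.dirichlet(np.full(4, conc), size=n_ctx)


def _emit_sequence(
    rng: np.random.Generator, trans: np.ndarray, length: int, order: int
) -> str:
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    ctx = 0
    mask = 4**order - 1
    for i in range(length):
        row = cum[ctx]
        b = 0
        x = u[i]
        while row[b] < x:
            b += 1
        out[i] = b
        ctx = ((ctx << 2) | b) & mask
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[out].tobytes().decode("ascii")


def generate_genomes(spec: CommunitySpec, rng: np.random.Generator) -> list[str]:
    """One Markov-generated genome sequence per community member."""
    order = 3  # 3rd-order chain: biases are expressed at the 4-mer level
    return [
        _emit_sequence(
            rng, _markov_transitions(rng, order, spec.tnf_bias_strength),
            spec.genome_length, order,
        )
        for _ in range(spec.n_genomes)
    ]


def fragment_genomes(
    genomes: list[str], spec: CommunitySpec, rng: np.random.Generator
) -> tuple[list[ContigRecord], GoldStandardMap, list[tuple[str, str, float]], int]:
    """Cut genomes into contigs and build the assembly-graph skeleton.

    Returns (contigs, gold standard, edges with raw weights, true edge
    count).  Edges link genome-adjacent fragments (raw weight 1); then
    ceil(spurious_edge_frac * E) random inter-genome edges are injected.
    """
    lo, hi = spec.contig_length_range
    contigs: list[ContigRecord] = []
    mapping: dict[str, str] = {}
    glen: dict[str, int] = {}
    edges: list[tuple[str, str, float]] = []
    genome_of: list[int] = []
    for gi, seq in enumerate(genomes):
        gname = f"g{gi + 1}"
        glen[gname] = len(seq)
        pos = 0
        prev_id = None
        k = 0
        while pos < len(seq):
            rem = len(seq) - pos
            if rem <= hi:
                length = rem
            else:
                upper = max(lo, min(hi, rem - lo))
                length = int(rng.integers(lo, upper + 1))
            cid = f"{gname}_c{k:03d}"
            contigs.append(ContigRecord(cid, seq[pos : pos + length]))
            mapping[cid] = gname
            genome_of.append(gi)
            if prev_id is not None:
                edges.append((prev_id, cid, 1.0))
            prev_id = cid
            pos += length
            k += 1
    n_true = len(edges)
    n_spurious = math.ceil(spec.spurious_edge_frac * n_true)
    ids = [c.contig_id for c in contigs]
    genome_of_arr = np.array(genome_of)
    existing = {tuple(sorted(e[:2])) for e in edges}
    added = 0
    while added < n_spurious:
        i, j = rng.integers(0, len(ids), size=2)
        if genome_of_arr[i] == genome_of_arr[j]:
            continue
        key = tuple(sorted((ids[i], ids[j])))
        if key in existing:
            continue
        existing.add(key)
        edges.append((key[0], key[1], 1.0))
        added += 1
    gold = GoldStandardMap(mapping, glen)
    return contigs, gold, edges, n_true


def simulate_coverage(
    contigs: list[ContigRecord],
    gold: GoldStandardMap,
    spec: CommunitySpec,
    rng: np.random.Generator,
) -> DepthTable:
    """Dirichlet abundance model with lognormal per-contig depth noise."""
    genomes = gold.genomes
    g_index = {g: i for i, g in enumerate(genomes)}
    G, M = len(genomes), spec.n_samples
    # per-sample genome proportions (sum to 1 before depth scaling)
    props = rng.dirichlet(
        np.full(G, spec.abundance_concentration), size=M
    ).T  # G x M
    cv = spec.coverage_noise_cv
    if cv > 0:
        sigma2 = math.log(1.0 + cv * cv)
        noise = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=(len(contigs), M))
    else:
        noise = np.ones((len(contigs), M))
    unevenness = rng.uniform(0.05, 0.3, size=len(contigs))
    mean = np.empty((len(contigs), M))
    for i, c in enumerate(contigs):
        gi = g_index[gold.contig_to_genome[c.contig_id]]
        mean[i] = props[gi] * spec.total_depth * noise[i]
    std = mean * unevenness[:, None]
    names = [f"S{m + 1}" for m in range(M)]
    return DepthTable([c.contig_id for c in contigs], mean, std, names)


def generate_community(spec: CommunitySpec = DESK_SPEC) -> Community:
    """Run the full generator from the CommunitySpec seed."""
    rng = np.random.default_rng(spec.seed)
    genomes = generate_genomes(spec, rng)
    contigs, gold, edges, n_true = fragment_genomes(genomes, spec, rng)
    depths = simulate_coverage(contigs, gold, spec, rng)
    return Community(spec, genomes, contigs, gold, edges, n_true, depths)


def _write_gfa(community: Community, path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for c in community.contigs:
            fh.write(f"S\t{c.contig_id}\t*\tLN:i:{c.length}\n")
        for u, v, w in community.edges:
            fh.write(f"L\t{u}\t+\t{v}\t+\t0M\tRC:i:{int(w)}\n")


def write_fixture(community: Community, out_dir) -> dict:
    """Write all artifacts (contigs.fa, graph.gfa, depths.tsv, gold.tsv,
    spec.yaml) plus a manifest; byte-identical on regeneration with the same
    seed."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "contigs": os.path.join(out_dir, "contigs.fa"),
        "graph": os.path.join(out_dir, "graph.gfa"),
        "depths": os.path.join(out_dir, "depths.tsv"),
        "gold": os.path.join(out_dir, "gold.tsv"),
        "spec": os.path.join(out_dir, "spec.yaml"),
    }
    write_fasta(community.contigs, paths["contigs"])
    _write_gfa(community, paths["graph"])
    write_depth_table(community.depths, paths["depths"])
    write_gold_standard(community.gold, paths["gold"])
    spec_dict = asdict(community.spec)
    spec_dict["contig_length_range"] = list(spec_dict["contig_length_range"])
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=True)
    manifest = {
        "seed": community.spec.seed,
        "n_contigs": len(community.contigs),
        "n_edges": len(community.edges),
        "n_true_edges": community.n_true_edges,
        "paths": {k: os.path.basename(v) for k, v in paths.items()},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
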