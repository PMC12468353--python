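"""End-to-end orchestration: features -> fusion -> graph SSL -> bins -> report.

The pipeline mirrors the method's two stages.  Stage 1 augments each contig
into V views, featurizes them ([TNF || shared abundance]), and trains the
fusion network under the multi-view NT-Xent objective.  Stage 2 builds the
normalized assembly-graph adjacency and refines the stage-1 embeddings with
the CCA invariance/decorrelation objective.  Final embeddings are clustered
by iterative medoid clustering, small bins are filtered, and — when a gold
standard is available — an AMBER-style report is produced.

Ablation variants (mirroring the method's own component analysis) are
exposed as configuration:

* ``tnf_only`` / ``abund_only`` zero the other feature modality;
* ``step1_only`` skips the graph stage and clusters stage-1 embeddings.

Two presets exist: ``paper`` (full-scale hyperparameters) and ``desk``
(small networks and epoch counts sized for synthetic fixtures).
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .binning import cluster_embeddings, filter_bins
from .evaluation import BinQualityReport, evaluate_binning
from .features import (
    abundance_matrix,
    augment_contig,
    build_canonical_index,
    featurize_views,
)
from .fusion import FusionConfig, train_fusion
from .graph_ssl import GraphConfig, build_adjacency, train_graph
from .io import BinAssignment, ContigRecord, DepthTable, GoldStandardMap, write_bins

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "desk_config", "paper_config"]

ABLATIONS = ("full", "tnf_only", "abund_only", "step1_only")


@dataclass
class BinningConfig:
    method: str = "medoid"
    radius: float = 0.15
    k: int | None = None
    min_bin_size: int = 200_000


@dataclass
class PipelineConfig:
    stage1: FusionConfig = field(default_factory=FusionConfig)
    stage2: GraphConfig = field(default_factory=GraphConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    ablation: str = "full"
    min_contig_length: int = 1000
    augment_min_frac: float = 0.5
    augment_max_frac: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        # one master seed drives every stage deterministically
        self.stage1.seed = self.seed
        self.stage2.seed = self.seed + 1


def paper_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Full-scale hyperparameters (2048/2048/128 fusion, 512-dim GCN)."""
    return PipelineConfig(seed=seed, **overrides)


def desk_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Desk-scale preset for synthetic fixtures: small nets, short training."""
    cfg = PipelineConfig(
        stage1=FusionConfig(
            layer_sizes=(128, 128, 32), batch_size=64, epochs=50,
            early_stop_patience=10,
        ),
        stage2=GraphConfig(hidden_dim=64, out_dim=64),
        # desk genomes are ~100 kb, so the bin-size floor scales down too
        binning=BinningConfig(min_bin_size=50_000),
        seed=seed,
        **overrides,
    )
    return cfg


@dataclass
class PipelineResult:
    assignment: BinAssignment
    stage1_embeddings: np.ndarray
    final_embeddings: np.ndarray
    contig_ids: list[str]
    report: BinQualityReport | None
    manifest: dict


def _check_ids(
    contigs: list[ContigRecord],
    depths: DepthTable,
    edges: list[tuple[str, str, float]],
) -> None:
    fasta_ids = {c.contig_id for c in contigs}
    orphan_edges = {u for u, v, _ in edges for u in (u, v)} - fasta_ids
    if orphan_edges:
        raise ValueError(
            "assembly-graph segments missing from FASTA: "
            f"{sorted(orphan_edges)[:5]}"
        )
    extra_depth = set(depths.contig_ids) - fasta_ids
    if extra_depth:
        raise ValueError(
            f"depth-table contigs missing from FASTA: {sorted(extra_depth)[:5]}"
        )


def run_pipeline(
    contigs: list[ContigRecord],
    depths: DepthTable,
    edges: list[tuple[str, str, float]],
    config: PipelineConfig | None = None,
    gold: GoldStandardMap | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run the two-stage binner on in-memory inputs.

    ``edges`` carry raw (read-count) weights between contig ids, as parsed
    from the GFA.  When ``out_dir`` is given, bins, embeddings, the report
    and a machine-readable run manifest are written there.
    """
    if config is None:
        config = PipelineConfig()
    _check_ids(contigs, depths, edges)
    contigs = [c for c in contigs if c.length >= config.min_contig_length]
    if len(contigs) < 2:
        raise ValueError("fewer than 2 contigs after length filtering")
    ids = [c.contig_id for c in contigs]
    lengths = {c.contig_id: c.length for c in contigs}
    timings: dict[str, float] = {}

    # --- features -----------------------------------------------------------
    t0 = time.perf_counter()
    index = build_canonical_index(4)
    rng = np.random.default_rng(config.seed + 2)
    ab = abundance_matrix(depths, ids)
    v = config.stage1.n_views
    rows = []
    for i, c in enumerate(contigs):
        views = augment_contig(
            c, n_views=v - 1, min_frac=config.augment_min_frac,
            max_frac=config.augment_max_frac, rng=rng,
        )
        rows.append(featurize_views(views, ab[i], index))
    feats = np.concatenate(rows, axis=0)
    n_tnf = index.n_classes
    if config.ablation == "tnf_only":
        feats[:, n_tnf:] = 0.0
    elif config.ablation == "abund_only":
        feats[:, :n_tnf] = 0.0
    timings["features"] = time.perf_counter() - t0

    # --- stage 1: fusion ----------------------------------------------------
    t0 = time.perf_counter()
    _, z1, hist1 = train_fusion(feats, config.stage1)
    timings["fusion"] = time.perf_counter() - t0

    # --- stage 2: graph SSL -------------------------------------------------
    t0 = time.perf_counter()
    if config.ablation == "step1_only":
        z_final = z1
        hist2 = {}
    else:
        graph = build_adjacency(ids, [e for e in edges if e[0] in lengths and e[1] in lengths])
        z_final, hist2 = train_graph(graph, z1, config.stage2)
    timings["graph_ssl"] = time.perf_counter() - t0

    # --- binning ------------------------------------------------------------
    t0 = time.perf_counter()
    b = config.binning
    assignment = cluster_embeddings(
        z_final, ids, lengths, method=b.method, radius=b.radius, k=b.k,
        seed=config.seed + 3,
    )
    assignment = filter_bins(assignment, lengths, b.min_bin_size)
    timings["binning"] = time.perf_counter() - t0

    # --- evaluation ---------------------------------------------------------
    report = None
    if gold is not None:
        report = evaluate_binning(assignment, gold, lengths)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "ablation": config.ablation,
        "n_contigs": len(ids),
        "n_edges": len(edges),
        "config": _config_dict(config),
        "stage1_final_train_loss": hist1["train_loss"][-1],
        "stage2_final_loss": (hist2.get("loss") or [None])[-1],
        "timings_s": {k: round(t, 3) for k, t in timings.items()},
    }
    if report is not None:
        manifest["report"] = report.summary()

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_bins(assignment, os.path.join(out_dir, "bins.tsv"))
        _write_embeddings(os.path.join(out_dir, "embeddings.tsv"), ids, z_final)
        if report is not None:
            report.to_tsv(os.path.join(out_dir, "report.tsv"))
        with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(assignment, z1, z_final, ids, report, manifest)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["stage1"]["layer_sizes"] = list(d["stage1"]["layer_sizes"])
    return d


def _write_embeddings(path, ids, Z) -> None:
    with open(path, "w") as fh:
        for cid, row in zip(ids, Z):
            fh.write(cid + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
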