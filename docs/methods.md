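# Methods

This note documents the models implemented in `gcbin`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing its behavior.

## Feature construction

**Canonical TNF.** For a contig of length *L*, a k = 4 sliding window with
stride 1 yields *L* − 3 windows; any window containing an ambiguous base
(N) contributes no count, but N bases still count toward contig length.
Each 4-mer is folded onto its reverse complement, reducing 256 raw 4-mers
to 136 canonical classes (120 complementary pairs plus 16 palindromic
singletons). Classes are numbered in lexicographic order of each class's
smaller member — a fixed layout, so feature columns are comparable across
runs and machines.

Smoothing is applied at the **count** level: probs\_j = (N\_j + 1) /
(ΣN + 136). An alternative reading — adding 1 to each relative frequency
before renormalizing — is retained behind `smoothing="freq"` for
comparison, but it is not the default: relative 4-mer frequencies are on
the order of 1/136 ≈ 0.007, so adding 1 to each drives every profile to
within ~1 % of uniform and erases the compositional signal the feature
exists to carry. Count-level Laplace smoothing keeps zero classes strictly
positive without flattening the profile.

**Abundance.** Mean and standard-deviation read depth per sample are
smoothed by ε = 10⁻⁵ (so contigs absent from a sample remain finite and
comparable) and max-normalized per sample over all contigs; the std
columns are normalized by the per-sample std maximum, keeping both halves
of the 2M-dim vector in [0, 1]. Max-normalization is order-preserving, so
within-sample depth ranking survives. A sample with zero coverage for
every contig normalizes to a column of ones and emits a warning.

**Augmentation.** Each contig becomes 6 views: the original plus 5 random
crops with lengths uniform in [0.5·L, 0.9·L] (floored at min(L, 1000 bp))
and uniform starts. The range simulates assembly fragmentation without
producing degenerate slivers. Crops inherit the parent's abundance vector:
per-crop depth would require re-mapping reads, and coverage is a property
of the genomic locus, which the crop shares with its parent.

## Stage 1: fusion network and NT-Xent

A three-layer MLP (defaults 2048–2048–128; desk preset 128–128–32) with
ReLU between layers and no activation before the final L2 normalization
maps each view to a unit-norm embedding. Batches are sampled at **contig**
level (default 1024 contigs; all V views of a sampled contig enter the same
batch, as the loss requires). The NT-Xent denominator excludes the
anchor's own term — the defining convention of the loss; keeping the
constant exp(1/τ) self-term would dominate the sum. Training uses Adam
(lr 10⁻³), a 10 % contig-level validation split, and early stopping with
patience 20 (desk: 10); the returned weights are those of the best
validation epoch. The per-contig embedding is the renormalized mean of its
view embeddings.

**Temperature.** τ defaults to **0.5**. This is the single most important
hyperparameter for binning behavior: the contrastive softmax weights each
negative by exp(cos/τ), so small τ concentrates the repulsive gradient on
the *hardest* in-batch negatives — which, in a metagenome, are sibling
contigs of the same genome, precisely the pairs a binner must keep
together. On the synthetic desk community, training at τ = 0.1 drove mean
intra-genome cosine similarity down to ≈ 0.18 (vs ≈ 0.55 at τ = 0.5) while
leaving inter-genome similarity near 0; the embeddings still *rank*
correctly but no longer form clusters tight enough to bin. τ = 0.5 relaxes
instance discrimination enough for genome-level structure to survive.
Larger τ (≥ 2) weakens the gradient signal and degraded downstream
recovery.

## Stage 2: graph self-supervision

The GFA links give an undirected graph (orientations discarded, reciprocal
links collapsed with summed read-count weights, self-links dropped); raw
weights are divided by the maximum, so edges lie in (0, 1] and absent links
are exactly 0. Self-loops are added before symmetric normalization —
Â = D̃^(−1/2)(A + I)D̃^(−1/2) — because isolated contigs are common in
assembly graphs and the normalization is undefined for degree-0 nodes
otherwise; an isolated contig's row reduces to its self-loop, so the GCN
passes its features through unmixed.

Each epoch draws two independent views (every edge dropped with p = 0.2;
whole feature *columns* zeroed with p = 0.2 — column masking shared across
nodes, matching the convention of CCA-style graph SSL), encodes both with
the shared two-layer GCN (hidden = out = 512; desk 64; ReLU between layers
only), standardizes, and minimizes the CCA objective with λ = 0.001 (the
upper end of the 0.0005–0.001 range that works well; within that range
results are insensitive). Node features are the stage-1 embeddings; a
config flag substitutes raw TNF + abundance instead. A GraphSAGE-style
encoder (fan-out 10, mean aggregation, per-pass resampling) is available
via `encoder="sage"` for graphs too large to densify; the GCN is the
default and the reference path. After training, the returned embedding is
the encoder applied to the *unperturbed* graph.

**Standardization convention.** Columns are transformed as
(z − μ)/(σ·√N) with σ the population standard deviation floored at 10⁻¹²
(constant columns map to zero). This is the only scaling under which each
column of Z̃ has unit L2 norm, which the decorrelation term ‖Z̃ᵀZ̃ − I‖²
presupposes — with any other scaling the "identity" target would be
unreachable by construction.

**Loss monitoring.** The per-epoch loss is evaluated on freshly drawn
stochastic views, so its trajectory is noisy by construction; descent is
meaningful only in windowed averages, which is how the tests assert it.

## Clustering and bin filtering

Embeddings are clustered by length-weighted iterative medoid clustering on
cosine distance: seed on the longest unassigned contig (ties broken by
contig id, making the partition invariant to input order), absorb
unassigned contigs within radius **r = 0.15**, re-center on the member
minimizing the length-weighted sum of distances, and iterate to a fixed
point; equidistant contigs stay with the earlier-seeded bin. Long contigs
seed and anchor bins because their TNF and coverage estimates carry the
least sampling noise.

The radius was chosen against the embedding geometry the two stages
actually produce: stage-2 embeddings of same-genome contigs sit at cosine
distance ≲ 0.05–0.10 from their medoid while different genomes sit near
1.0, and r = 0.15 kept bin purity at 1.0 across a multi-seed scan (purity
remained 1.0 up to r = 0.25). Adaptive per-cluster thresholds (histogram
valleys, largest-gap rules) were evaluated and rejected: with only ~16
contigs per genome the distance spectra are too sparse, and such rules
merged adjacent genome clouds on some seeds. A k-means alternative with an
explicit k is available for embeddings without tight cluster structure.

Bins below `min_bin_size` (default 200 kb; desk preset 50 kb, since desk
genomes are 100 kb) are relabeled *unbinned*: completeness and
contamination estimates are not meaningful below that scale.

## Evaluation

From the bins × genomes overlap matrix L (bases of bin *i* mapping to
genome *j*): per-bin purity max\_j L\_ij / Σ\_j L\_ij; contamination
1 − purity; average purity reported both unweighted and bp-weighted (each
bin weighted by its mapped bases — the headline, matching common AMBER
reporting); average completeness Σ\_i L\_ij / G\_j averaged over genomes,
summing over **all** bins by default with a `best_bin_only` flag for the
stricter single-bin reading; per-bin completeness for HQ counting is
measured against the bin's dominant genome; F1 is the harmonic mean of
per-bin purity and completeness; HQ bins satisfy completeness ≥ 0.90 and
contamination ≤ 0.05. Unbinned contigs and contigs without a gold label
never contribute to any metric.

## Synthetic communities

The generator emulates the statistical structure the method exploits, not
the sequencing process:

* **Genomes**: per-genome 3rd-order Markov chains whose transition rows are
  Dirichlet(1/s) draws (s = `tnf_bias_strength`, default 2.0; s = 0 gives
  exactly uniform rows, i.e. compositionally indistinguishable genomes).
  A 3rd-order chain expresses bias precisely at the 4-mer scale the TNF
  feature measures.
* **Contigs**: fragments tiling each genome with lengths uniform in
  2–10 kb; per-genome fragment lengths sum exactly to the genome length.
* **Coverage**: per sample, genome proportions ~ Dirichlet(α = 1) scaled to
  total depth 150×, times per-contig lognormal noise with mean 1 and
  CV = 0.05 (multiplicative, heavy-tailed — the shape real depth tables
  show); std coverage is the mean times a per-contig unevenness factor
  U(0.05, 0.3).
* **Graph**: edges join genome-adjacent fragments; `spurious_edge_frac`
  injects that fraction of the true edge count as random inter-genome
  links.

Default scale: 8 genomes × 100 kb, M = 3 samples (~130 contigs) — small
enough that the whole pipeline trains in seconds on one CPU while leaving
each genome ~16 contigs to cluster. Everything regenerates byte-identically
from the seed.

What the generator does **not** emulate: read-level errors and chimeras,
strain-level haplotype structure, repeat-induced mis-joins, GC-coverage
bias, uneven within-genome composition, or assembly fragmentation bias.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that it recovers structure when the modeled signals are
present — not that it reaches any particular accuracy on real assemblies.

One consequence at fixture scale is worth stating explicitly: because the
synthetic graph is noiseless (complete per-genome paths, no spurious
edges), pipeline variants that keep the graph stage recover near-perfect
partitions even from a single feature modality, while the stage-1-only
variant — with no graph smoothing — produces genome-separated but diffuse
embeddings that fixed-radius clustering fragments. On real, noisy
assemblies the relative ordering of these ablations is expected to differ;
the desk fixture overstates the graph stage and understates feature
fusion.

## Numerical and engineering choices

* All training runs on `gcbin.nn`, a ~300-line reverse-mode autodiff over
  NumPy float64 with an Adam optimizer — chosen for full determinism on
  CPU and zero heavyweight dependencies at this model size. Gradients of
  the composite losses are tested against central finite differences.
* The GCN densifies Â for the forward product; at the intended graph sizes
  (≤ a few thousand nodes) this is faster and simpler than sparse autodiff.
  The SAGE encoder exists for when it is not.
* Every entry point takes an explicit seed; one pipeline seed derives the
  stage seeds by fixed offsets. Two runs with the same inputs and seed
  produce byte-identical artifacts.
* Degenerate inputs: contigs shorter than k are rejected; all-N contigs are
  rejected; constant embedding columns standardize to zero via the σ floor;
  an all-zero coverage sample warns and normalizes to ones; a bin whose
  contigs carry no gold labels is skipped in evaluation with a warning.
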