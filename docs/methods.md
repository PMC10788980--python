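# Methods

## The model

`cellgcn` treats condition assignment in multi-condition scRNA-seq as
semi-supervised node classification. Cells are nodes of a kNN graph; the
classifier is a two-layer graph convolutional network

    H⁽⁰⁾ = σ(Ã X W⁽⁰⁾),   H⁽¹⁾ = softmax(Ã H⁽⁰⁾ W⁽¹⁾),

where `Ã = D̂^{-1/2}(A + I)D̂^{-1/2}` is the self-looped, symmetrically
degree-normalized adjacency. Each layer therefore averages a cell's
(transformed) features with its neighbors', so the probability a cell
receives reflects its transcriptomic neighborhood, not just itself — this
is what turns a classifier into a smooth per-cell *prototypicality* score
and what buffers dropout noise in individual profiles.

Assumptions worth keeping in mind: the graph is built once from PCA space
and never updated (transcriptomic similarity is fixed, only the embedding
is learned); training is transductive — every cell, labeled or not, must be
in the graph at training time; and condition labels are taken at face value
for the labeled subset, so mislabeled training cells directly bias the
score.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 15 | kNN neighbors; standard single-cell practice |
| `n_pcs` | 50 | PCs for graph construction (capped at min(n, m) − 1) |
| `hidden_dim` (h) | 32 | latent width; modest widths suffice for a 2-layer GCN, 32 leaves headroom |
| activation σ | ReLU | canonical GCN choice |
| optimizer | Adam, lr 0.01, L2 5e-4 | standard settings for 2-layer GCNs |
| init | Glorot-uniform, seeded | |
| `budget_per_condition` | 0.03 | labeled fraction per condition (guideline 1–3%) |
| `val_fraction` | 0.2 | of non-training cells; the rest is the test set |
| `max_epochs` / `patience` | 200 / 30 | early stopping on validation loss, strict decrease, tolerance 0 |
| assignment threshold | 0.5 | cell assigned when some class probability ≥ 0.5 |
| `top_n` genes | 25 | length of the reported gene ranking |
| benchmark repeats | 100 | NMI runs per clustering method in protocol mode |

The graph is **binary** with **union symmetrization** (edge if either
endpoint names the other a neighbor): binary weights keep the layer
operation exactly as written above; duplicate points are resolved by index
order. Condition categories map to integer classes in lexicographic order
of their string labels so outputs are comparable across runs and platforms.

Preprocessing defaults (all configurable): drop cells expressing < 300
genes, genes seen in < 10 cells, cells with ≥ 20% mitochondrial counts
(`MT-` prefix, case-insensitive); normalize each cell to 10,000 counts;
log1p; keep highly variable genes with mean in [0.0125, 3] and normalized
dispersion ≥ 0.5. Step order is fixed: cell filter → gene filter → mito
filter → normalize → log1p → HVG. These thresholds presume genome-scale
gene counts; for small panels (a few hundred genes) scale `min_genes` down.

## Numerical choices

- Softmax is computed with max-subtraction; cross-entropy clips predicted
  probabilities at 1e-12 before the log.
- Gradients of the masked cross-entropy w.r.t. W⁽⁰⁾, W⁽¹⁾ are derived
  analytically (see `nn.loss_and_grads`) and verified against central
  finite differences in the tests; `fit()` returns the weights of the best
  validation epoch, not the last one.
- Ties in condition assignment at exactly the threshold break toward the
  lower class index and are flagged in the output; with a threshold > 0.5
  ties are impossible.
- Gene scores are **signed** row-sums of W⁽⁰⁾ by default; signed sums can
  cancel across latent dimensions, so an absolute-value variant
  (`mode="absolute"`) is provided.
- NMI is normalized by the arithmetic mean of the two partition entropies,
  with the convention that a single-class partition yields 0.
- k-means uses seeded restarts (best inertia); `k` is always user-specified
  — there is no universally right number of response groups.
- All pipeline randomness derives from one top-level seed via
  `SeedSequence.spawn`, so identical config + seed reproduces every output
  file byte for byte.

## The synthetic-data generator

Counts are negative-binomial (gamma–Poisson) with per-gene base means drawn
log-normal (σ = 1) around `base_mean` = 5 — a deep-coverage regime in which
a 500-gene panel has ~85% of genes detected per cell, so the default QC
thresholds behave sensibly. Each of the `n_conditions` groups owns a
disjoint set of `n_markers_per_condition` marker genes whose means are
multiplied by `2^log_fold_effect` in that group's cells; `log_fold_effect=0`
removes all signal, giving an exact null. An optional `mixed_fraction` of
each group's cells is drawn from the arithmetic mean of its own and the
cyclically next group's mean vectors — intermediate cells that keep their
condition-of-origin label ("wrong on purpose"), emulating
partially-responding populations. Dispersion defaults to 2 (variance
µ + µ²/2, strongly overdispersed).

What the generator deliberately does **not** emulate: batch effects,
cell-type heterogeneity, library-size gradients, dropout beyond what NB
sampling produces, or doublets. Consequently condition is the *only*
structure in the data; PCA space is then an unrealistically clean
representation of condition, so comparisons that on real data favor the
learned latent space (where PCA is dominated by condition-orthogonal
cell-type variation) can favor PCA here — in particular, with a large
intermediate population, k-means on the latent space tends to carve the
intermediate cells into their own cluster (the very phenomenon the method
is designed to expose), which costs NMI against origin labels. Passing
tests on this generator demonstrate correct mechanics and recoverable
planted signal, not performance on real tissue.

## Problem sizes

Tests and the acceptance script use 3 conditions × 300 cells × 500 genes
(20 markers per condition, log2 effect 2, 3% labeling) — large enough that
held-out accuracy, marker enrichment, and null behavior are stable across
seeds, small enough that a full train is ~0.1 s; clustering comparisons use
20 k-means repeats, and the protocol-scale 100-repeat mode remains
available via `cellgcn benchmark`.

## Known limitations

- Transductive only: scoring new cells requires rebuilding the graph and
  refitting.
- The expression matrix is densified for training; practical up to a few
  ×10⁴ cells × HVG-scale genes on one CPU, not for atlas-scale data.
- Gene ranking reflects linear first-layer weight mass, not statistical
  significance; treat it as a shortlist for differential-expression
  follow-up, and prefer the absolute-sum variant when latent dimensions
  disagree in sign.
- No batch correction; integrate/correct upstream before fitting.
- External community-detection baselines (Leiden/Louvain) enter the
  benchmark only through the plug-in adapter interface; they are not
  bundled.
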