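# cellgcn

Semi-supervised graph convolutional scoring of **condition prototypicality**
in multi-condition single-cell RNA-seq.

When the same biological system is profiled under two or more experimental
conditions (drug vs. control, timepoints of a treatment course), not every
cell responds equally: some cells are archetypal for their condition, others
sit in between. `cellgcn` quantifies this per cell. Cells become nodes of a
kNN graph built in PCA space; a two-layer graph convolutional network (GCN)
is trained to classify each cell's condition from only a small labeled
subset (1–3% of cells per condition), and the resulting softmax
probabilities are a per-cell score of how prototypical the cell is of each
condition. Cells with ambiguous probabilities mark intermediate,
partially-responding populations.

## Model

With expression matrix `X ∈ ℝ^{n×m}` (n cells, m genes), binary kNN
adjacency `A`, `Â = A + I`, `D̂ = diag(Â·1)` and
`Ã = D̂^{-1/2} Â D̂^{-1/2}`:

    H⁽⁰⁾ = ReLU(Ã X W⁽⁰⁾)            latent embedding, n × h
    H⁽¹⁾ = softmax(Ã H⁽⁰⁾ W⁽¹⁾)      condition probabilities, n × c

`W⁽⁰⁾ ∈ ℝ^{m×h}` and `W⁽¹⁾ ∈ ℝ^{h×c}` are trained by Adam on the
categorical cross-entropy over the labeled subset (200 epochs maximum,
early stopping with patience 30 on validation loss). Three read-outs follow:

- **probabilities** `H⁽¹⁾` — the per-cell response score; thresholding at
  0.5 assigns cells to a condition or leaves them "unassigned";
- **latent space** `H⁽⁰⁾` — cells arranged by transcriptome *and*
  condition-prototypicality; k-means here groups cells by response
  (naive / intermediate / responsive), export it for PHATE/UMAP viewing;
- **gene ranking** — row-sums of `W⁽⁰⁾` rank genes by how strongly they
  drive the condition separation (top 25 by default).

Evaluation uses the multiclass Brier score
`(1/N) Σᵢ Σⱼ (pᵢⱼ − δᵢⱼ)²` (0 = perfect, lower is better) and normalized
mutual information (NMI) between clusterings and ground-truth conditions.

## Worked example

```python
import cellgcn as cg

# 3 conditions x 300 cells, 500 genes, 20 planted markers per condition
ds  = cg.generate_multicondition_dataset(cg.SyntheticSpec(seed=0))
pre = cg.standard_preprocess(ds.to_anndata())        # QC, 10k-normalize, log1p, HVG
model = cg.ConditionGCN.from_anndata(pre)            # PCA -> kNN graph -> GCN
res = model.fit(seed=0)                              # 27 labeled cells (3%/condition)
print(res.summary())
```

```
Condition-prototypicality GCN results
==============================================
cells: 900   genes: 51
conditions (3): cond_A, cond_B, cond_C
graph: k=15, n_pcs=50, edges=10126
latent dim h: 32   activation: relu
train/val/test: 27/175/698
epochs run: 94   best epoch: 63
accuracy  train: 1.000  val: 0.994  test: 0.986
Brier score (all cells): 0.0165
```

From 27 labeled cells the network classifies the 698 held-out cells with
98.6% accuracy, and the Brier score of 0.017 says the probability vectors
are nearly one-hot — the three synthetic conditions are cleanly separated.
`res.rank_genes()` then surfaces the planted marker genes, and k-means on
the latent space recovers the condition structure:

```python
res.composition_table(res.cluster_latent(k=3, seed=0)).round(3)
```

```
category  cond_A  cond_B  cond_C
cluster
0          0.000   0.997   0.003
1          0.977   0.017   0.007
2          0.000   0.000   1.000
```

The same pipeline runs from the shell:

```bash
cellgcn simulate --seed 0 --out sim.h5ad
cellgcn run sim.h5ad --seed 0 --outdir out/    # writes probabilities.csv, latent.csv, ...
cellgcn benchmark sim.h5ad --outdir bench/     # 100-repeat NMI clustering comparison
```

Real data loads from `.h5ad` (label in `obs`) or an MTX directory
(`matrix.mtx`, `genes.tsv`, `barcodes.tsv`, `labels.csv`).

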