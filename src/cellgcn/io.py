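"""Dataset loading (h5ad, MTX triplet directories) and result export."""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, io as spio


def load_dataset(path: str, fmt: str | None = None, label_key: str = "condition") -> ad.AnnData:
    """Load an expression matrix plus per-cell condition labels.

    ``fmt`` is 'h5ad' or 'mtx' (a directory holding matrix.mtx, genes.tsv,
    barcodes.tsv, labels.csv); inferred from the path when omitted.
    """
    if fmt is None:
        fmt = "mtx" if os.path.isdir(path) else "h5ad"
    if fmt == "h5ad":
        adata = ad.read_h5ad(path)
        if label_key not in adata.obs:
            raise KeyError(
                f"label key {label_key!r} not found; available obs keys: "
                f"{list(adata.obs.columns)}"
            )
    elif fmt == "mtx":
        X = sparse.csr_matrix(spio.mmread(os.path.join(path, "matrix.mtx")))
        genes = pd.read_csv(os.path.join(path, "genes.tsv"), header=None, sep="\t")[0].tolist()
        barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), header=None, sep="\t")[0].tolist()
        labels = pd.read_csv(os.path.join(path, "labels.csv")).set_index("cell_id")
        if label_key not in labels.columns:
            raise KeyError(
                f"label key {label_key!r} not found in labels.csv; available: "
                f"{list(labels.columns)}"
            )
        obs = pd.DataFrame(index=barcodes)
        obs[label_key] = pd.Categorical(labels.loc[barcodes, label_key])
        adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'h5ad' or 'mtx'")
    if not np.issubdtype(np.asarray(adata.X[0, 0]).dtype, np.number):
        raise ValueError("expression matrix must be numeric")
    return adata


def label_counts(adata: ad.AnnData, label_key: str = "condition") -> pd.Series:
    return adata.obs[label_key].value_counts().sort_index()


def export_results(results, outdir: str, threshold: float = 0.5, k_clusters: int = 3,
                   top_n_genes: int = 25, seed: int = 0) -> dict[str, str]:
    """Write the fitted model's read-outs as CSV/TSV keyed by cell/gene.

    Emits probabilities, latent matrix, cluster labels, gene ranking and the
    cluster-by-assignment composition table; returns name -> path.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    results.probabilities.to_csv(_p("probabilities.csv"), float_format="%.10g")
    results.latent_frame.to_csv(_p("latent.csv"), float_format="%.10g")
    clusters = results.cluster_latent(k=k_clusters, seed=seed)
    pd.DataFrame(
        {"cluster": clusters}, index=pd.Index(results.model.cell_ids, name="cell_id")
    ).to_csv(_p("clusters.csv"))
    results.rank_genes(top_n=top_n_genes).to_csv(
        _p("gene_ranking.tsv"), sep="\t", index=False, float_format="%.10g"
    )
    results.composition_table(clusters, threshold=threshold).to_csv(
        _p("composition.csv"), float_format="%.10g"
    )
    results.assign_condition(threshold).to_csv(_p("assignments.csv"))
    return paths
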