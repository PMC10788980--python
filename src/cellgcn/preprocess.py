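"""Standard scRNA-seq preprocessing and PCA reduction.

Defaults follow common QC practice for droplet data: drop cells expressing
fewer than 300 genes, genes seen in fewer than 10 cells, cells above 20%
mitochondrial reads; library-size normalize each cell to 10,000 counts;
log1p; keep highly variable genes at min mean 0.0125, max mean 3, min
normalized dispersion 0.5.  Every threshold is configurable.  Step order is
fixed: cell filter -> gene filter -> mito filter -> normalize -> log1p -> HVG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scanpy as sc
import anndata as ad
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class PreprocessConfig:
    min_genes: int = 300
    min_cells: int = 10
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"
    target_sum: float = 10_000.0
    hvg_min_mean: float = 0.0125
    hvg_max_mean: float = 3.0
    hvg_min_disp: float = 0.5
    use_hvg: bool = True


class EmptyMatrixError(ValueError):
    """All cells or all genes were removed by filtering."""


def standard_preprocess(adata: ad.AnnData, config: PreprocessConfig = PreprocessConfig()) -> ad.AnnData:
    """QC-filter, normalize, log-transform and HVG-subset raw counts.

    Expects raw counts in ``adata.X``.  Returns a new AnnData; the input is
    not modified.  Raises :class:`EmptyMatrixError` if filtering empties the
    matrix.
    """
    adata = adata.copy()
    if adata.X.min() < 0:
        raise ValueError("negative entries: input must be raw counts")

    sc.pp.filter_cells(adata, min_genes=config.min_genes)
    if adata.n_obs == 0:
        raise EmptyMatrixError("all cells removed by min_genes filter")
    sc.pp.filter_genes(adata, min_cells=config.min_cells)
    if adata.n_vars == 0:
        raise EmptyMatrixError("all genes removed by min_cells filter")

    mito = np.asarray(
        [str(g).upper().startswith(config.mito_prefix.upper()) for g in adata.var_names]
    )
    if mito.any():
        X = adata.X
        total = np.asarray(X.sum(axis=1)).ravel()
        mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel()
        frac = np.divide(mito_counts, total, out=np.zeros_like(mito_counts, dtype=float), where=total > 0)
        adata = adata[frac < config.max_mito_fraction].copy()
        if adata.n_obs == 0:
            raise EmptyMatrixError("all cells removed by mitochondrial filter")

    sc.pp.normalize_total(adata, target_sum=config.target_sum)
    sc.pp.log1p(adata)

    if config.use_hvg:
        sc.pp.highly_variable_genes(
            adata,
            min_mean=config.hvg_min_mean,
            max_mean=config.hvg_max_mean,
            min_disp=config.hvg_min_disp,
        )
        if not bool(adata.var["highly_variable"].any()):
            raise EmptyMatrixError("no genes passed the HVG thresholds")
        adata = adata[:, adata.var["highly_variable"]].copy()

    adata.uns["counts_flag"] = False
    return adata


def reduce_pca(X: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Project cells onto the top ``n_pcs`` principal components.

    Columns are ordered by decreasing explained variance.  ``n_pcs`` must be
    strictly below min(cells, genes).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D cells x genes matrix")
    if not 1 <= n_pcs < min(X.shape):
        raise ValueError(
            f"n_pcs must satisfy 1 <= n_pcs < min(cells, genes) = {min(X.shape)}; got {n_pcs}"
        )
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    return pca.fit_transform(X)
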