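"""Synthetic multi-condition scRNA-seq count data with planted markers.

The generator emulates the experimental designs the model targets: several
treatment conditions profiled jointly, each condition carrying a small
program of marker genes shifted upward on the log2 scale, plus an optional
"intermediate" population whose expression interpolates between two
conditions while keeping its condition-of-origin label.  Counts follow a
negative binomial with log-normal per-gene base means, the standard
generative caricature of UMI count data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, io as spio


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated multi-condition experiment.

    Attributes
    ----------
    n_conditions : number of treatment groups (>= 2).
    cells_per_condition : cells sampled per group.
    n_genes : total genes.
    n_markers_per_condition : planted condition-discriminative genes per group
        (disjoint across groups).
    log_fold_effect : log2 shift applied to a condition's marker genes in its
        own (non-mixed) cells; 0 removes all signal.
    mixed_fraction : fraction of each condition's cells drawn from the
        midpoint of two conditions' mean vectors, labeled with their
        condition of origin ("wrong on purpose").
    dispersion : negative-binomial inverse-dispersion (NB size parameter);
        larger means closer to Poisson.
    base_mean : median of the log-normal per-gene base-mean distribution.
    seed : RNG seed; the dataset is a pure function of the spec.
    """

    n_conditions: int = 3
    cells_per_condition: int = 300
    n_genes: int = 500
    n_markers_per_condition: int = 20
    log_fold_effect: float = 2.0
    mixed_fraction: float = 0.0
    dispersion: float = 2.0
    base_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        if self.cells_per_condition < 1:
            raise ValueError("cells_per_condition must be >= 1")
        if self.n_markers_per_condition * self.n_conditions > self.n_genes:
            raise ValueError(
                "marker overflow: n_markers_per_condition * n_conditions "
                f"({self.n_markers_per_condition * self.n_conditions}) exceeds "
                f"n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.mixed_fraction < 1.0:
            raise ValueError("mixed_fraction must be in [0, 1)")
        if self.log_fold_effect < 0:
            raise ValueError("log_fold_effect must be non-negative")
        if self.dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("dispersion and base_mean must be positive")


@dataclass
class SyntheticDataset:
    """Generated counts plus the planted ground truth."""

    counts: np.ndarray            # cells x genes, non-negative integers
    labels: np.ndarray            # per-cell condition index in [0, n_conditions)
    marker_truth: list[np.ndarray]  # per-condition planted marker gene indices
    mixed_flag: np.ndarray        # per-cell bool: drawn from an interpolated profile
    gene_names: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    condition_names: list[str] = field(default_factory=list)

    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(
            {
                "condition": pd.Categorical(
                    [self.condition_names[i] for i in self.labels],
                    categories=self.condition_names,
                ),
                "mixed": self.mixed_flag,
            },
            index=self.cell_ids,
        )
        var = pd.DataFrame(index=self.gene_names)
        marker_of = np.full(self.counts.shape[1], "", dtype=object)
        for c, idx in enumerate(self.marker_truth):
            marker_of[idx] = self.condition_names[c]
        var["marker_of"] = marker_of
        adata = ad.AnnData(
            X=sparse.csr_matrix(self.counts.astype(np.float32)), obs=obs, var=var
        )
        adata.uns["counts_flag"] = True
        return adata


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    # NB via gamma-Poisson mixture: mean mu, variance mu + mu^2/size
    shape = size_param
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def generate_multicondition_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a multi-condition count matrix with planted marker programs.

    Each condition's marker genes have their NB mean multiplied by
    ``2**log_fold_effect`` in that condition's non-mixed cells.  Mixed cells
    use the arithmetic mean of their own condition's mean vector and the
    next condition's (cyclically), so they sit between two groups in
    expression space while keeping their original label.
    """
    rng = np.random.default_rng(spec.seed)
    n_cond, n_cells_pc, n_genes = (
        spec.n_conditions,
        spec.cells_per_condition,
        spec.n_genes,
    )
    n_cells = n_cond * n_cells_pc

    # log-normal base means give HVG selection real structure to find
    base = spec.base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    marker_pool = rng.permutation(n_genes)
    marker_truth = [
        np.sort(marker_pool[c * spec.n_markers_per_condition:(c + 1) * spec.n_markers_per_condition])
        for c in range(n_cond)
    ]

    cond_means = np.tile(base, (n_cond, 1))
    for c in range(n_cond):
        cond_means[c, marker_truth[c]] *= 2.0 ** spec.log_fold_effect

    labels = np.repeat(np.arange(n_cond), n_cells_pc)
    n_mixed_pc = int(round(spec.mixed_fraction * n_cells_pc))
    mixed_flag = np.zeros(n_cells, dtype=bool)

    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    for c in range(n_cond):
        start = c * n_cells_pc
        mixed_idx = rng.choice(n_cells_pc, size=n_mixed_pc, replace=False)
        is_mixed = np.zeros(n_cells_pc, dtype=bool)
        is_mixed[mixed_idx] = True
        mixed_flag[start:start + n_cells_pc] = is_mixed
        partner = (c + 1) % n_cond
        mean_pure = cond_means[c]
        mean_mixed = 0.5 * (cond_means[c] + cond_means[partner])
        for local in range(n_cells_pc):
            mu = mean_mixed if is_mixed[local] else mean_pure
            counts[start + local] = _nb_sample(rng, mu, spec.dispersion)

    gene_names = [f"gene_{g:04d}" for g in range(n_genes)]
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    condition_names = [f"cond_{chr(ord('A') + c)}" for c in range(n_cond)]
    return SyntheticDataset(
        counts=counts,
        labels=labels,
        marker_truth=marker_truth,
        mixed_flag=mixed_flag,
        gene_names=gene_names,
        cell_ids=cell_ids,
        condition_names=condition_names,
    )


def write_h5ad(dataset: SyntheticDataset, path: str) -> None:
    dataset.to_anndata().write_h5ad(path)


def write_mtx(dataset: SyntheticDataset, directory: str) -> None:
    """Write counts as MatrixMarket plus genes/barcodes/labels sidecars."""
    import os

    os.makedirs(directory, exist_ok=True)
    spio.mmwrite(
        os.path.join(directory, "matrix.mtx"),
        sparse.coo_matrix(dataset.counts),
    )
    with open(os.path.join(directory, "genes.tsv"), "w") as fh:
        fh.write("\n".join(dataset.gene_names) + "\n")
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(dataset.cell_ids) + "\n")
    pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "condition": [dataset.condition_names[i] for i in dataset.labels],
        }
    ).to_csv(os.path.join(directory, "labels.csv"), index=False)
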