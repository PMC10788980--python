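"""kNN cell graph construction and the renormalized adjacency operator.

Cells are nodes; an undirected edge joins i and j when either is among the
other's k nearest Euclidean neighbors in PCA space (union symmetrization,
binary weights).  The graph convolution consumes the self-looped symmetric
normalization A~ = D^(-1/2) (A + I) D^(-1/2), whose largest eigenvalue is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors


@dataclass
class CellGraph:
    """Binary symmetric adjacency plus its normalized form."""

    adjacency: sparse.csr_matrix          # A: symmetric, binary, zero diagonal
    normalized: sparse.csr_matrix | None  # A~ = D^(-1/2)(A+I)D^(-1/2)
    k: int
    n_pcs: int

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


def build_knn_graph(pcs: np.ndarray, k: int) -> sparse.csr_matrix:
    """Union-symmetrized binary kNN adjacency over rows of ``pcs``.

    Edge (i, j) exists iff j is among the k nearest neighbors of i or vice
    versa.  Self-loops are excluded here (the normalization adds them).
    Duplicate points are resolved by index order, never an error.
    """
    pcs = np.asarray(pcs, dtype=np.float64)
    n = pcs.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells ({n}); got {k}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows, cols = [], []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        # with duplicate points i may not appear in its own list; keep k others
        rows.extend([i] * len(neigh))
        cols.extend(neigh)
    A = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    A = A.maximum(A.T)          # union symmetrization
    A.data[:] = 1.0             # binary
    A.setdiag(0)
    A.eliminate_zeros()
    return A


def normalize_adjacency(A: sparse.spmatrix) -> sparse.csr_matrix:
    """Self-looped symmetric degree normalization D^(-1/2)(A+I)D^(-1/2).

    Entry (i, j) of the result is (A+I)_{ij} / sqrt(d_i d_j) with d the
    degree counting the self-loop, so isolated nodes map to 1 on the
    diagonal and the operator's spectrum lies in [-1, 1].
    """
    A = sparse.csr_matrix(A, dtype=np.float64)
    if (abs(A - A.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    A_hat = A + sparse.identity(A.shape[0], format="csr")
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    inv_sqrt = sparse.diags(1.0 / np.sqrt(deg))
    return (inv_sqrt @ A_hat @ inv_sqrt).tocsr()


def write_graph_triplets(A: sparse.spmatrix, path: str) -> None:
    """Dump a sparse matrix as 'i<TAB>j<TAB>value' lines for inspection."""
    coo = sparse.coo_matrix(A)
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")


def read_graph_triplets(path: str, n: int | None = None) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            i, j, v = line.split("\t")
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(v))
    if n is None:
        n = max(max(rows), max(cols)) + 1
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
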