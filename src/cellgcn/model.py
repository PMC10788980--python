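"""Semi-supervised GCN model of condition prototypicality.

`ConditionGCN` is built from a preprocessed expression matrix with per-cell
condition labels (arrays or an AnnData).  It owns the PCA/kNN graph
construction and the two weight matrices; `fit()` runs seeded Adam on the
masked categorical cross-entropy with early stopping and returns a
`GCNResults` carrying per-cell condition probabilities, the latent
embedding, training history and the interpretation surface.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO

import numpy as np
import pandas as pd
from scipy import sparse

from . import nn, interpret as _interpret
from .graph import CellGraph, build_knn_graph, normalize_adjacency
from .metrics import brier_score
from .preprocess import reduce_pca


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: 200 epochs max, stop after 30 without validation
    improvement, Adam at lr 0.01 with 5e-4 L2."""

    max_epochs: int = 200
    patience: int = 30
    learning_rate: float = 0.01
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be positive, weight_decay non-negative")


@dataclass
class MaskSet:
    """Disjoint train/validation/test cell index sets."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    per_condition_budget: float | int = 0.03

    def __post_init__(self) -> None:
        sets = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        if (
            sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]
        ):
            raise ValueError("train/val/test index sets must be pairwise disjoint")


def sample_masks(
    labels: np.ndarray,
    budget_per_condition: float | int = 0.03,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> MaskSet:
    """Draw the semi-supervised split.

    Exactly ``budget_per_condition`` cells per condition (an integer count,
    or a fraction of that condition's size, guideline 1-3%) are drawn
    uniformly without replacement as training nodes; the remaining cells are
    split into validation (``val_fraction``) and test.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    rest: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if isinstance(budget_per_condition, float) and 0 < budget_per_condition < 1:
            budget = max(1, int(round(budget_per_condition * len(idx))))
        else:
            budget = int(budget_per_condition)
        if budget > len(idx):
            raise ValueError(
                f"budget {budget} exceeds size {len(idx)} of condition {c}"
            )
        perm = rng.permutation(idx)
        train.append(perm[:budget])
        rest.append(perm[budget:])
    train_idx = np.sort(np.concatenate(train))
    held = rng.permutation(np.concatenate(rest))
    n_val = int(round(val_fraction * len(held)))
    return MaskSet(
        train_idx=train_idx,
        val_idx=np.sort(held[:n_val]),
        test_idx=np.sort(held[n_val:]),
        per_condition_budget=budget_per_condition,
    )


@dataclass
class ModelState:
    """The learned parameters and their provenance."""

    W0: np.ndarray
    W1: np.ndarray
    h: int
    c: int
    activation: str
    rng_seed: int
    class_names: list[str] = field(default_factory=list)


class ConditionGCN:
    """Two-layer graph convolutional classifier of experimental condition.

    Parameters
    ----------
    X : cells x genes matrix of preprocessed (normalized, log) expression.
    labels : per-cell condition, categorical strings or integer codes.
        Categories map to classes in lexicographic order of their string
        form, so runs are comparable across platforms.
    adjacency : optional precomputed symmetric binary adjacency; when absent
        the graph is built as union-symmetrized kNN (``k``) on the top
        ``n_pcs`` principal components of X.
    hidden_dim : latent dimension h of the first layer.
    activation : first-layer nonlinearity ('relu' default).
    """

    def __init__(
        self,
        X: np.ndarray,
        labels,
        gene_names: list[str] | None = None,
        cell_ids: list[str] | None = None,
        adjacency: sparse.spmatrix | None = None,
        k: int = 15,
        n_pcs: int = 50,
        hidden_dim: int = 32,
        activation: str = "relu",
        pca_seed: int = 0,
    ) -> None:
        X = np.asarray(
            X.toarray() if sparse.issparse(X) else X, dtype=np.float64
        )
        if X.ndim != 2:
            raise ValueError("X must be a 2-D cells x genes matrix")
        n, m = X.shape
        labels = np.asarray(labels)
        if labels.shape[0] != n:
            raise ValueError("labels length must match the number of cells")
        self.class_names = sorted(str(v) for v in np.unique(labels))
        name_to_code = {s: i for i, s in enumerate(self.class_names)}
        self.y = np.array([name_to_code[str(v)] for v in labels])
        if len(self.class_names) < 2:
            raise ValueError("need at least two conditions")

        self.X = X
        self.gene_names = list(gene_names) if gene_names is not None else [
            f"gene_{g}" for g in range(m)
        ]
        self.cell_ids = list(cell_ids) if cell_ids is not None else [
            f"cell_{i}" for i in range(n)
        ]
        if len(self.gene_names) != m or len(self.cell_ids) != n:
            raise ValueError("gene_names/cell_ids lengths must match X")

        if adjacency is None:
            n_pcs_eff = min(n_pcs, min(n, m) - 1)
            pcs = reduce_pca(X, n_pcs_eff, seed=pca_seed)
            adjacency = build_knn_graph(pcs, k=min(k, n - 1))
        else:
            n_pcs_eff = n_pcs
        self.graph = CellGraph(
            adjacency=sparse.csr_matrix(adjacency),
            normalized=normalize_adjacency(adjacency),
            k=k,
            n_pcs=n_pcs_eff,
        )
        self.hidden_dim = hidden_dim
        self.activation = activation

    def results_from_state(self, state: "ModelState") -> "GCNResults":
        """Rebuild a results object from checkpointed parameters (no masks:
        every cell is scored, none is held out)."""
        H0, P = nn.forward(
            self.graph.normalized, self.X, state.W0, state.W1, state.activation
        )
        n = len(self.cell_ids)
        masks = MaskSet(
            train_idx=np.empty(0, dtype=int),
            val_idx=np.empty(0, dtype=int),
            test_idx=np.arange(n),
        )
        return GCNResults(
            model=self,
            state=state,
            masks=masks,
            config=TrainConfig(seed=state.rng_seed),
            latent=H0,
            probability_matrix=P,
            history=pd.DataFrame(
                columns=["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]
            ),
            best_epoch=-1,
        )

    @classmethod
    def from_anndata(
        cls,
        adata,
        label_key: str = "condition",
        **kwargs,
    ) -> "ConditionGCN":
        if label_key not in adata.obs:
            raise KeyError(
                f"label key {label_key!r} not in obs; available: {list(adata.obs.columns)}"
            )
        return cls(
            X=adata.X,
            labels=adata.obs[label_key].to_numpy(),
            gene_names=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            **kwargs,
        )

    # -- training ----------------------------------------------------------

    def fit(
        self,
        masks: MaskSet | None = None,
        budget_per_condition: float | int = 0.03,
        val_fraction: float = 0.2,
        config: TrainConfig | None = None,
        **config_overrides,
    ) -> "GCNResults":
        """Train with masked cross-entropy, early stopping on validation loss.

        Returns the parameters from the best validation epoch.  Fully
        reproducible under ``config.seed`` (which also drives the mask draw
        when ``masks`` is not supplied).
        """
        config = config or TrainConfig(**config_overrides)
        if masks is None:
            masks = sample_masks(
                self.y, budget_per_condition, val_fraction, seed=config.seed
            )
        present = np.unique(self.y[masks.train_idx])
        if len(present) < len(self.class_names):
            raise ValueError("every condition must appear in the training mask")

        rng = np.random.default_rng(config.seed)
        m, h, c = self.X.shape[1], self.hidden_dim, len(self.class_names)
        W0 = nn.glorot_uniform(rng, m, h)
        W1 = nn.glorot_uniform(rng, h, c)
        opt = nn.Adam(
            [(m, h), (h, c)],
            lr=config.learning_rate,
            weight_decay=config.weight_decay,
        )

        A = self.graph.normalized
        history: list[dict] = []
        best = {"val_loss": np.inf, "epoch": -1, "W0": W0.copy(), "W1": W1.copy()}
        stale = 0
        for epoch in range(config.max_epochs):
            loss, dW0, dW1, H0, P = nn.loss_and_grads(
                A, self.X, W0, W1, self.y, masks.train_idx, self.activation
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            val_loss = nn.cross_entropy(P, self.y, masks.val_idx)
            pred = P.argmax(axis=1)
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": loss,
                    "val_loss": val_loss,
                    "train_acc": float((pred[masks.train_idx] == self.y[masks.train_idx]).mean()),
                    "val_acc": float((pred[masks.val_idx] == self.y[masks.val_idx]).mean()),
                }
            )
            if val_loss < best["val_loss"]:
                best = {
                    "val_loss": val_loss,
                    "epoch": epoch,
                    "W0": W0.copy(),
                    "W1": W1.copy(),
                }
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
            opt.step([W0, W1], [dW0, dW1])

        state = ModelState(
            W0=best["W0"],
            W1=best["W1"],
            h=h,
            c=c,
            activation=self.activation,
            rng_seed=config.seed,
            class_names=self.class_names,
        )
        H0, P = nn.forward(A, self.X, state.W0, state.W1, self.activation)
        return GCNResults(
            model=self,
            state=state,
            masks=masks,
            config=config,
            latent=H0,
            probability_matrix=P,
            history=pd.DataFrame(history),
            best_epoch=int(best["epoch"]),
        )


class GCNResults:
    """Fitted-model container: probabilities, latent space, diagnostics."""

    def __init__(
        self,
        model: ConditionGCN,
        state: ModelState,
        masks: MaskSet,
        config: TrainConfig,
        latent: np.ndarray,
        probability_matrix: np.ndarray,
        history: pd.DataFrame,
        best_epoch: int,
    ) -> None:
        self.model = model
        self.state = state
        self.masks = masks
        self.config = config
        self.latent = latent
        self.probability_matrix = probability_matrix
        self.history = history
        self.best_epoch = best_epoch

    # -- frames ------------------------------------------------------------

    @property
    def probabilities(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probability_matrix,
            index=self.model.cell_ids,
            columns=self.state.class_names,
        )

    @property
    def latent_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.latent,
            index=self.model.cell_ids,
            columns=[f"latent_{j}" for j in range(self.state.h)],
        )

    # -- diagnostics -------------------------------------------------------

    def _subset(self, subset: str) -> np.ndarray:
        try:
            return {
                "train": self.masks.train_idx,
                "val": self.masks.val_idx,
                "test": self.masks.test_idx,
                "all": np.arange(len(self.model.y)),
            }[subset]
        except KeyError:
            raise ValueError(f"unknown subset {subset!r}") from None

    def accuracy(self, subset: str = "test") -> float:
        idx = self._subset(subset)
        pred = self.probability_matrix.argmax(axis=1)
        return float((pred[idx] == self.model.y[idx]).mean())

    def brier(self, subset: str = "all") -> float:
        idx = self._subset(subset)
        return brier_score(self.model.y[idx], self.probability_matrix[idx])

    # -- interpretation ----------------------------------------------------

    def assign_condition(self, threshold: float = 0.5) -> pd.DataFrame:
        df = _interpret.assign_condition(
            self.probability_matrix, threshold, self.state.class_names
        )
        df.index = pd.Index(self.model.cell_ids)
        return df

    def rank_genes(self, top_n: int = 25, mode: str = "signed") -> pd.DataFrame:
        return _interpret.rank_genes(
            self.state.W0, self.model.gene_names, top_n=top_n, mode=mode
        )

    def cluster_latent(self, k: int, seed: int = 0, restarts: int = 10) -> np.ndarray:
        return _interpret.cluster_latent(self.latent, k, seed=seed, restarts=restarts)

    def composition_table(self, clusters, threshold: float = 0.5) -> pd.DataFrame:
        assigned = self.assign_condition(threshold)["assigned"].to_numpy()
        return _interpret.composition_table(assigned, clusters)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Condition-prototypicality GCN results",
            "=" * 46,
            f"cells: {len(self.model.cell_ids)}   genes: {len(self.model.gene_names)}",
            f"conditions ({self.state.c}): {', '.join(self.state.class_names)}",
            f"graph: k={self.model.graph.k}, n_pcs={self.model.graph.n_pcs}, "
            f"edges={self.model.graph.adjacency.nnz // 2}",
            f"latent dim h: {self.state.h}   activation: {self.state.activation}",
            f"train/val/test: {len(self.masks.train_idx)}/"
            f"{len(self.masks.val_idx)}/{len(self.masks.test_idx)}",
            f"epochs run: {len(self.history)}   best epoch: {self.best_epoch}",
            f"best val loss: {self.history['val_loss'].min():.4f}",
            f"accuracy  train: {self.accuracy('train'):.3f}  "
            f"val: {self.accuracy('val'):.3f}  test: {self.accuracy('test'):.3f}",
            f"Brier score (all cells): {self.brier('all'):.4f}",
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint: one zip holding W0, W1, class order, config, seed."""
        with zipfile.ZipFile(path, "w") as zf:
            for name, arr in (("W0", self.state.W0), ("W1", self.state.W1)):
                buf = BytesIO()
                np.save(buf, arr)
                zf.writestr(f"{name}.npy", buf.getvalue())
            meta = {
                "class_names": self.state.class_names,
                "activation": self.state.activation,
                "hidden_dim": self.state.h,
                "config": asdict(self.config),
                "best_epoch": self.best_epoch,
                "gene_names": self.model.gene_names,
            }
            zf.writestr("meta.json", json.dumps(meta, indent=1))

    @staticmethod
    def load_state(path: str) -> ModelState:
        with zipfile.ZipFile(path) as zf:
            W0 = np.load(BytesIO(zf.read("W0.npy")))
            W1 = np.load(BytesIO(zf.read("W1.npy")))
            meta = json.loads(zf.read("meta.json"))
        return ModelState(
            W0=W0,
            W1=W1,
            h=meta["hidden_dim"],
            c=W1.shape[1],
            activation=meta["activation"],
            rng_seed=meta["config"]["seed"],
            class_names=meta["class_names"],
        )
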