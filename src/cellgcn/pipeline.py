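"""End-to-end pipeline: preprocess -> PCA -> kNN -> normalize -> train ->
interpret -> evaluate, with a machine-readable run manifest.

All randomness flows from one top-level seed, split deterministically per
stage with ``numpy.random.SeedSequence.spawn``, so identical config + seed
reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time

import numpy as np

from . import __version__
from .benchmark import benchmark_clustering
from .io import export_results, load_dataset
from .model import ConditionGCN, TrainConfig
from .preprocess import PreprocessConfig, standard_preprocess


@dataclasses.dataclass
class RunConfig:
    input_path: str
    input_format: str | None = None          # h5ad | mtx | None (infer)
    label_key: str = "condition"
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    skip_preprocess: bool = False
    k: int = 15
    n_pcs: int = 50
    hidden_dim: int = 32
    activation: str = "relu"
    budget_per_condition: float = 0.03
    val_fraction: float = 0.2
    max_epochs: int = 200
    patience: int = 30
    learning_rate: float = 0.01
    weight_decay: float = 5e-4
    threshold: float = 0.5
    k_clusters: int = 3
    top_n_genes: int = 25
    benchmark_repeats: int = 0               # 0 disables; protocol mode uses 100
    seed: int = 0
    outdir: str = "cellgcn_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig):
    """Execute the full pipeline and write all artifacts plus a manifest.

    Returns (results, report); report is None when benchmarking is off.
    Any stage failure is re-raised wrapped with the stage name.
    """
    os.makedirs(config.outdir, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    timings: dict[str, float] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        adata = load_dataset(config.input_path, config.input_format, config.label_key)
        timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        if not config.skip_preprocess:
            adata = standard_preprocess(adata, config.preprocess)
        timings[stage] = time.perf_counter() - t0

        stage = "train"
        t0 = time.perf_counter()
        model = ConditionGCN.from_anndata(
            adata,
            label_key=config.label_key,
            k=config.k,
            n_pcs=config.n_pcs,
            hidden_dim=config.hidden_dim,
            activation=config.activation,
            pca_seed=seeds[0],
        )
        results = model.fit(
            budget_per_condition=config.budget_per_condition,
            val_fraction=config.val_fraction,
            config=TrainConfig(
                max_epochs=config.max_epochs,
                patience=config.patience,
                learning_rate=config.learning_rate,
                weight_decay=config.weight_decay,
                seed=seeds[1],
            ),
        )
        timings[stage] = time.perf_counter() - t0

        stage = "interpret"
        t0 = time.perf_counter()
        export_results(
            results,
            config.outdir,
            threshold=config.threshold,
            k_clusters=config.k_clusters,
            top_n_genes=config.top_n_genes,
            seed=seeds[2],
        )
        timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        report = None
        if config.benchmark_repeats > 0:
            from .preprocess import reduce_pca

            pcs = reduce_pca(model.X, model.graph.n_pcs, seed=seeds[0])
            report = benchmark_clustering(
                model.y,
                spaces={"pca": pcs, "gcn_latent": results.latent},
                k=config.k_clusters,
                n_repeats=config.benchmark_repeats,
                seed=seeds[3],
                brier=results.brier("all"),
            )
            report.to_json(os.path.join(config.outdir, "benchmark.json"))
            report.summary_frame().to_csv(
                os.path.join(config.outdir, "benchmark_summary.csv"), index=False
            )
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds[:4],
        "version": __version__,
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "n_cells": int(len(model.cell_ids)),
        "n_genes": int(len(model.gene_names)),
        "class_names": results.state.class_names,
        "best_epoch": results.best_epoch,
        "test_accuracy": results.accuracy("test"),
        "brier_all": results.brier("all"),
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    results.save(os.path.join(config.outdir, "checkpoint.zip"))
    return results, report


def expand_grid(base: RunConfig, grid: dict[str, list]) -> list[RunConfig]:
    """Cartesian expansion of a parameter grid into per-combination configs,
    each writing into its own subdirectory of ``base.outdir``."""
    import itertools

    keys = sorted(grid)
    configs = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = dataclasses.replace(base)
        tag = []
        for key, val in zip(keys, combo):
            setattr(cfg, key, val)
            tag.append(f"{key}={val}")
        cfg.outdir = os.path.join(base.outdir, "_".join(tag))
        configs.append(cfg)
    return configs
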