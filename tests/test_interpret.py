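"""Condition assignment, gene ranking, latent clustering, composition tables."""

import numpy as np
import pandas as pd
import pytest

from cellgcn import assign_condition, rank_genes, cluster_latent, composition_table
from cellgcn.metrics import nmi


# -- assignment ------------------------------------------------------------


def test_assignment_basic_threshold():
    P = np.array([[0.7, 0.3], [0.4, 0.6]])
    out = assign_condition(P, 0.5, ["ctrl", "drug"])
    assert list(out["assigned"]) == ["ctrl", "drug"]
    assert not out["tie"].any()


def test_below_threshold_unassigned():
    out = assign_condition(np.array([[0.4, 0.3, 0.3]]), 0.5)
    assert out["assigned"].iloc[0] == "unassigned"


def test_exact_tie_lowest_index_and_flagged():
    out = assign_condition(np.array([[0.5, 0.5]]), 0.5, ["a", "b"])
    assert out["assigned"].iloc[0] == "a"
    assert bool(out["tie"].iloc[0])


def test_threshold_above_half_unique():
    P = np.array([[0.51, 0.49], [0.2, 0.8]])
    out = assign_condition(P, 0.51)
    assert (~out["tie"]).all()


@pytest.mark.parametrize("thr", [0.0, -0.1, 1.5])
def test_threshold_domain(thr):
    with pytest.raises(ValueError):
        assign_condition(np.array([[1.0, 0.0]]), thr)


def test_assigned_fraction_complements_low_confidence(rng):
    """Fraction assigned equals 1 - fraction of max-probability < threshold."""
    logits = rng.normal(size=(200, 3))
    P = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
    out = assign_condition(P, 0.5)
    frac_assigned = (out["assigned"] != "unassigned").mean()
    assert frac_assigned == pytest.approx(1 - (P.max(1) < 0.5).mean())


# -- gene ranking ----------------------------------------------------------


def test_single_positive_row_ranks_first():
    W0 = np.zeros((5, 4))
    W0[3] = 0.5
    out = rank_genes(W0, [f"g{i}" for i in range(5)], top_n=5)
    assert out["gene"].iloc[0] == "g3"


def test_default_top_n_is_25(rng):
    W0 = rng.normal(size=(100, 8))
    assert len(rank_genes(W0, [f"g{i}" for i in range(100)])) == 25


def test_signed_vs_absolute_scores():
    W0 = np.array([[1.0, -1.0], [0.4, 0.4]])
    signed = rank_genes(W0, ["a", "b"], top_n=2, mode="signed")
    absolute = rank_genes(W0, ["a", "b"], top_n=2, mode="absolute")
    assert signed["gene"].iloc[0] == "b"    # 0.8 beats 0.0
    assert absolute["gene"].iloc[0] == "a"  # 2.0 beats 0.8


def test_ties_broken_lexicographically():
    W0 = np.ones((3, 1))
    out = rank_genes(W0, ["zz", "aa", "mm"], top_n=3)
    assert list(out["gene"]) == ["aa", "mm", "zz"]


def test_top_n_overflow_warns_and_truncates(rng):
    with pytest.warns(UserWarning, match="truncating"):
        out = rank_genes(rng.normal(size=(4, 2)), list("abcd"), top_n=10)
    assert len(out) == 4


# -- latent clustering -----------------------------------------------------


def test_k1_single_cluster(rng):
    lat = rng.normal(size=(30, 4))
    assert set(cluster_latent(lat, 1)) == {0}


def test_separable_blobs_recovered(rng):
    centers = np.array([[0, 0], [20, 0], [0, 20]])
    truth = np.repeat([0, 1, 2], 50)
    lat = centers[truth] + rng.normal(scale=0.5, size=(150, 2))
    part = cluster_latent(lat, 3, seed=0)
    assert nmi(truth, part) == pytest.approx(1.0)


def test_rotation_invariance_up_to_relabeling(rng):
    centers = np.array([[0, 0, 0], [15, 0, 0], [0, 15, 0]])
    truth = np.repeat([0, 1, 2], 40)
    lat = centers[truth] + rng.normal(scale=0.3, size=(120, 3))
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    a = cluster_latent(lat, 3, seed=0)
    b = cluster_latent(lat @ Q, 3, seed=0)
    assert nmi(a, b) == pytest.approx(1.0)


def test_k_exceeding_cells_rejected(rng):
    with pytest.raises(ValueError):
        cluster_latent(rng.normal(size=(5, 2)), 6)


def test_clustering_reproducible(rng):
    lat = rng.normal(size=(80, 6))
    a = cluster_latent(lat, 4, seed=7)
    b = cluster_latent(lat, 4, seed=7)
    np.testing.assert_array_equal(a, b)


# -- composition -----------------------------------------------------------


def test_single_cluster_even_split():
    out = composition_table(["a", "a", "b", "b"], [0, 0, 0, 0])
    np.testing.assert_allclose(out.loc[0], [0.5, 0.5])


def test_hand_counted_fractions():
    cats = ["x", "x", "y", "y", "y", "x"]
    clus = [0, 0, 0, 1, 1, 1]
    out = composition_table(cats, clus)
    np.testing.assert_allclose(out.loc[0], [2 / 3, 1 / 3])
    np.testing.assert_allclose(out.loc[1], [1 / 3, 2 / 3])


def test_rows_sum_to_one(rng):
    cats = rng.integers(0, 4, 200)
    clus = rng.integers(0, 5, 200)
    out = composition_table(cats, clus)
    np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)


def test_length_mismatch():
    with pytest.raises(ValueError):
        composition_table(["a"], [0, 1])
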