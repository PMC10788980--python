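"""Network primitives against independent dense/loop oracles.

The forward oracle multiplies matrices entry by entry with Python loops and
never touches the vectorised implementation; gradients are checked against
central finite differences.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from cellgcn import softmax, gcn_layer, forward, cross_entropy
from cellgcn.nn import loss_and_grads
from tests.test_graph import dense_normalize_oracle, random_adjacency


def loop_matmul(A, B):
    n, k = A.shape
    k2, m = B.shape
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for t in range(k):
                s += A[i, t] * B[t, j]
            out[i, j] = s
    return out


def oracle_layer(An, H, W, relu=False):
    Z = loop_matmul(loop_matmul(An, H), W)
    return np.maximum(Z, 0) if relu else Z


def oracle_forward(An, X, W0, W1):
    H0 = oracle_layer(An, X, W0, relu=True)
    logits = oracle_layer(An, H0, W1)
    P = np.zeros_like(logits)
    for i in range(logits.shape[0]):
        e = np.exp(logits[i] - logits[i].max())
        P[i] = e / e.sum()
    return H0, P


# -- softmax ---------------------------------------------------------------


def test_softmax_symmetry_and_closed_form():
    np.testing.assert_allclose(softmax([0.0, 0.0]), [0.5, 0.5])
    np.testing.assert_allclose(softmax([np.log(2), 0.0]), [2 / 3, 1 / 3])


@given(
    st.lists(st.floats(-50, 50), min_size=2, max_size=6),
    st.floats(-100, 100),
)
@settings(deadline=None, max_examples=50)
def test_softmax_shift_invariant_and_normalized(z, c):
    p = softmax(z)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert (p > 0).all()
    np.testing.assert_allclose(softmax(np.asarray(z) + c), p, atol=1e-12)


# -- layers ----------------------------------------------------------------


def test_isolated_node_identity_layer():
    An = np.array([[1.0]])
    H = np.array([[3.0, -2.0]])
    out = gcn_layer(An, H, np.eye(2), "identity")
    np.testing.assert_allclose(out, H)


def test_two_node_edge_averages():
    An = np.array([[0.5, 0.5], [0.5, 0.5]])
    out = gcn_layer(An, np.eye(2), np.eye(2), "identity")
    np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]])


def test_layer_matches_loop_oracle(rng):
    An = dense_normalize_oracle(random_adjacency(rng, 30))
    H = rng.normal(size=(30, 7))
    W = rng.normal(size=(7, 4))
    out = gcn_layer(sparse.csr_matrix(An), H, W, "identity")
    np.testing.assert_allclose(out, oracle_layer(An, H, W), atol=1e-6)


def test_layer_shape_errors(rng):
    An = np.eye(3)
    with pytest.raises(ValueError, match="shape"):
        gcn_layer(An, rng.normal(size=(3, 4)), rng.normal(size=(5, 2)))
    with pytest.raises(ValueError, match="shape"):
        gcn_layer(An, rng.normal(size=(4, 4)), rng.normal(size=(4, 2)))


# -- forward ---------------------------------------------------------------


def test_forward_matches_composed_oracle(rng):
    An = dense_normalize_oracle(random_adjacency(rng, 20))
    X = rng.normal(size=(20, 9))
    W0 = rng.normal(size=(9, 5))
    W1 = rng.normal(size=(5, 3))
    H0, P = forward(sparse.csr_matrix(An), X, W0, W1, "relu")
    H0_o, P_o = oracle_forward(An, X, W0, W1)
    np.testing.assert_allclose(H0, H0_o, atol=1e-6)
    np.testing.assert_allclose(P, P_o, atol=1e-6)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)


def test_forward_zero_output_weights_give_uniform(rng):
    An = dense_normalize_oracle(random_adjacency(rng, 10))
    X = rng.normal(size=(10, 4))
    W0 = rng.normal(size=(4, 3))
    _, P = forward(sparse.csr_matrix(An), X, W0, np.zeros((3, 4)))
    np.testing.assert_allclose(P, 0.25)


# -- loss ------------------------------------------------------------------


def test_cross_entropy_closed_forms():
    labels = np.array([0, 1])
    one_hot = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert cross_entropy(one_hot, labels, np.array([0, 1])) == pytest.approx(0.0, abs=1e-9)
    uniform = np.full((2, 2), 0.5)
    assert cross_entropy(uniform, labels, np.array([0, 1])) == pytest.approx(np.log(2))


def test_cross_entropy_ignores_unmasked(rng):
    P = np.full((4, 2), 0.5)
    labels = np.array([0, 1, 0, 1])
    base = cross_entropy(P, labels, np.array([0, 1]))
    P2 = P.copy()
    P2[2:] = [[0.9, 0.1], [0.1, 0.9]]
    assert cross_entropy(P2, labels, np.array([0, 1])) == base


def test_cross_entropy_requires_mask():
    with pytest.raises(ValueError):
        cross_entropy(np.eye(2), np.array([0, 1]), np.array([], dtype=int))


def test_gradients_match_finite_differences(rng):
    """Hand-derived W0/W1 gradients vs central differences at 1e-5 step."""
    An = sparse.csr_matrix(dense_normalize_oracle(random_adjacency(rng, 12)))
    X = rng.normal(size=(12, 6))
    W0 = rng.normal(size=(6, 4)) * 0.5
    W1 = rng.normal(size=(4, 3)) * 0.5
    y = rng.integers(0, 3, size=12)
    mask = np.array([0, 3, 7, 11])

    _, dW0, dW1, _, _ = loss_and_grads(An, X, W0, W1, y, mask)

    def loss_at(W0_, W1_):
        return loss_and_grads(An, X, W0_, W1_, y, mask)[0]

    eps = 1e-5
    for W, dW in ((W0, dW0), (W1, dW1)):
        num = np.zeros_like(W)
        for i in range(W.shape[0]):
            for j in range(W.shape[1]):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                if W is W0:
                    num[i, j] = (loss_at(Wp, W1) - loss_at(Wm, W1)) / (2 * eps)
                else:
                    num[i, j] = (loss_at(W0, Wp) - loss_at(W0, Wm)) / (2 * eps)
        np.testing.assert_allclose(dW, num, atol=1e-6)
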