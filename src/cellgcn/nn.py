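"""Functional core of the two-layer graph convolutional network.

The model is

    H0 = sigma(A~ X W0)          (latent embedding, cells x h)
    P  = row_softmax(A~ H0 W1)   (condition probabilities, cells x c)

with A~ the self-looped symmetric normalized adjacency, W0 in R^{genes x h},
W1 in R^{h x c}, and sigma = ReLU by default.  Gradients of the masked
categorical cross-entropy with respect to W0 and W1 are derived by hand and
returned alongside the forward pass; there is no autograd dependency.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

_EPS = 1e-12

ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(z.dtype)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax via max-subtraction (shift invariant)."""
    z = np.asarray(z, dtype=np.float64)
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def gcn_layer(
    A_norm: sparse.spmatrix | np.ndarray,
    H_in: np.ndarray,
    W: np.ndarray,
    nonlinearity: str = "identity",
) -> np.ndarray:
    """One graph-convolution step: nonlinearity(A~ . H_in . W)."""
    if H_in.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: H_in is {H_in.shape}, W is {W.shape}"
        )
    if A_norm.shape[1] != H_in.shape[0]:
        raise ValueError(
            f"shape mismatch: A~ is {A_norm.shape}, H_in has {H_in.shape[0]} rows"
        )
    act, _ = ACTIVATIONS[nonlinearity]
    return act(np.asarray(A_norm @ (H_in @ W)))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def forward(
    A_norm: sparse.spmatrix,
    X: np.ndarray,
    W0: np.ndarray,
    W1: np.ndarray,
    activation: str = "relu",
) -> tuple[np.ndarray, np.ndarray]:
    """Full forward pass; returns (H0 latent, P probabilities)."""
    act, _ = ACTIVATIONS[activation]
    H0 = act(np.asarray(A_norm @ (X @ W0)))
    logits = np.asarray(A_norm @ (H0 @ W1))
    return H0, softmax(logits, axis=1)


def cross_entropy(P: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    """Mean over masked cells of -log P[i, label_i], epsilon-clipped."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = np.flatnonzero(mask)
    if len(mask) == 0:
        raise ValueError("mask must be nonempty")
    p_true = np.clip(P[mask, labels[mask]], _EPS, 1.0)
    return float(-np.log(p_true).mean())


def loss_and_grads(
    A_norm: sparse.spmatrix,
    X: np.ndarray,
    W0: np.ndarray,
    W1: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    activation: str = "relu",
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Masked cross-entropy and its gradients w.r.t. W0, W1.

    Derivation (S = A~, symmetric): with Z0 = S X W0, H0 = act(Z0),
    Z1 = S H0 W1, P = softmax(Z1) and L the mean NLL over the train mask,

        dL/dZ1 = (P - Y) / |mask|   on masked rows, 0 elsewhere
        dL/dW1 = (S H0)^T dZ1 = H0^T (S dZ1)
        dL/dH0 = S dZ1 W1^T
        dL/dZ0 = dL/dH0 * act'(Z0)
        dL/dW0 = (S X)^T dZ0 = X^T (S dZ0)

    Returns (loss, dW0, dW1, H0, P).
    """
    act, dact = ACTIVATIONS[activation]
    SX = np.asarray(A_norm @ X)
    Z0 = SX @ W0
    H0 = act(Z0)
    Z1 = np.asarray(A_norm @ (H0 @ W1))
    P = softmax(Z1, axis=1)

    n_mask = len(train_idx)
    loss = cross_entropy(P, labels, train_idx)

    dZ1 = np.zeros_like(P)
    dZ1[train_idx] = P[train_idx]
    dZ1[train_idx, labels[train_idx]] -= 1.0
    dZ1 /= n_mask

    SdZ1 = np.asarray(A_norm @ dZ1)
    dW1 = H0.T @ SdZ1
    dH0 = SdZ1 @ W1.T
    dZ0 = dH0 * dact(Z0)
    dW0 = SX.T @ dZ0
    return loss, dW0, dW1, H0, P


class Adam:
    """Adam optimizer with decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, shapes, lr=0.01, weight_decay=5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
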