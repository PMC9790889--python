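"""Fuzzy neural block: Gaussian rule memberships, product t-norm, and the
between-epoch fuzzy c-means centroid refresh.

Each of K rules holds a centroid ``c^k`` in the flattened feature space.  The
membership of feature vector ``v`` in rule k along dimension j is

    mu_j = exp(-1/4 (v_j - c^k_j)^2 / alpha_j^2)

with a strictly positive learnable scale ``alpha``.  Rule activation is the
product t-norm over dimensions followed by normalization across rules, so the
block outputs a point on the probability simplex.  Products are computed in
the log domain (sum of log-memberships, log-sum-exp normalization) — at large
d the raw products underflow to zero.

Centroids are not gradient-trained: they start at zero and are refreshed
between epochs by fuzzy c-means over the feature vectors collected during the
preceding epoch.  ``alpha`` is trained by backpropagation.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param

__all__ = [
    "fnb_membership", "fnb_forward", "fuzzy_cmeans", "update_fnb_centroids",
    "FNBLayer",
]


def fnb_membership(v: np.ndarray, centroid: np.ndarray,
                   alpha: np.ndarray) -> np.ndarray:
    """Elementwise Gaussian membership ``exp(-1/4 (v-c)^2 / alpha^2)``."""
    v = np.asarray(v, float)
    centroid = np.asarray(centroid, float)
    alpha = np.asarray(alpha, float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    return np.exp(-0.25 * (v - centroid) ** 2 / alpha ** 2)


def _log_activations(v: np.ndarray, centroids: np.ndarray,
                     alpha: np.ndarray) -> np.ndarray:
    """Log of the unnormalized rule activations, ``[B, K]`` for ``v [B, d]``."""
    diff = v[:, None, :] - centroids[None, :, :]          # [B, K, d]
    return -0.25 * np.sum(diff ** 2 / alpha ** 2, axis=-1)


def fnb_forward(v: np.ndarray, centroids: np.ndarray,
                alpha: np.ndarray) -> np.ndarray:
    """Normalized rule activations (sum to 1 across rules).

    Accepts a single vector ``[d]`` or a batch ``[B, d]``.
    """
    v = np.asarray(v, float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    centroids = np.asarray(centroids, float)
    alpha = np.asarray(alpha, float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    if v.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"feature dim {v.shape[1]} != centroid dim {centroids.shape[1]}"
        )
    s = _log_activations(v, centroids, alpha)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    out = e / e.sum(axis=1, keepdims=True)
    return out[0] if single else out


def fuzzy_cmeans(data: np.ndarray, k: int, m: float = 2.0, seed: int = 0,
                 max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Fuzzy c-means centroids (fuzzifier ``m``), deterministic given seed.

    Centroids are initialized on distinct data points drawn with the seeded
    generator; memberships and centroids then alternate until the centroid
    shift falls below ``tol``.
    """
    data = np.atleast_2d(np.asarray(data, float))
    n, d = data.shape
    if n == 0:
        raise ValueError("empty history: nothing to cluster")
    if k < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(k, n), replace=False)
    centroids = data[idx].copy()
    if k > n:  # more rules than samples: jitter duplicates
        extra = data[rng.choice(n, size=k - n)] + rng.normal(0, 1e-6, (k - n, d))
        centroids = np.vstack([centroids, extra])
    exponent = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        dist = np.linalg.norm(data[:, None, :] - centroids[None, :, :], axis=-1)
        dist = np.maximum(dist, 1e-12)
        inv = dist ** (-exponent)
        u = inv / inv.sum(axis=1, keepdims=True)          # [n, k]
        um = u ** m
        new = (um.T @ data) / um.sum(axis=0)[:, None]
        shift = np.max(np.abs(new - centroids))
        centroids = new
        if shift < tol:
            break
    return centroids


def update_fnb_centroids(history: np.ndarray, k: int, epoch_index: int,
                         seed: int = 0) -> np.ndarray:
    """Centroid schedule: zeros before any history exists, c-means afterwards.

    ``history`` holds the flattened feature vectors collected during the
    preceding epoch; ``epoch_index`` 0 denotes the initial period.
    """
    if epoch_index == 0:
        history = np.atleast_2d(np.asarray(history, float))
        return np.zeros((k, history.shape[1]))
    history = np.atleast_2d(np.asarray(history, float))
    if history.size == 0:
        raise ValueError("empty history after the initial epoch")
    return fuzzy_cmeans(history, k, m=2.0, seed=seed)


class FNBLayer(Layer):
    """Fuzzy neural block as a network layer: ``[B, d] -> [B, K]``.

    ``alpha`` is a trainable parameter (kept positive by clipping after
    optimizer steps); centroids are a non-trainable parameter refreshed via
    :func:`update_fnb_centroids`.  Gradients w.r.t. the centroids are still
    computed (and checkable) — they are simply never applied by the optimizer.
    """

    MIN_ALPHA = 1e-3

    def __init__(self, n_rules: int, d_in: int):
        super().__init__()
        self.alpha = Param(np.ones(d_in), "fnb.alpha")
        self.centroids = Param(np.zeros((n_rules, d_in)), "fnb.centroids",
                               trainable=False)
        self.params = [self.alpha, self.centroids]
        self.n_rules = n_rules

    def forward(self, v, training=False, rng=None):
        alpha = self.alpha.value
        diff = v[:, None, :] - self.centroids.value[None, :, :]
        s = -0.25 * np.sum(diff ** 2 / alpha ** 2, axis=-1)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        out = e / e.sum(axis=1, keepdims=True)
        self._v, self._diff, self._out = v, diff, out
        return out

    def backward(self, g):
        out, diff, alpha = self._out, self._diff, self.alpha.value
        ds = out * (g - np.sum(g * out, axis=1, keepdims=True))   # [B, K]
        inv_a2 = 1.0 / alpha ** 2
        # s = -1/4 sum_j diff^2 / alpha^2
        dv = -0.5 * np.einsum("bk,bkj->bj", ds, diff) * inv_a2
        self.centroids.grad += 0.5 * np.einsum("bk,bkj->kj", ds, diff) * inv_a2
        self.alpha.grad += 0.5 * np.einsum("bk,bkj->j", ds, diff ** 2) / alpha ** 3
        return dv

    def clip_alpha(self) -> None:
        np.maximum(self.alpha.value, self.MIN_ALPHA, out=self.alpha.value)

    def set_centroids(self, centroids: np.ndarray) -> None:
        centroids = np.asarray(centroids, float)
        if centroids.shape != self.centroids.value.shape:
            raise ValueError("centroid shape mismatch")
        self.centroids.value[...] = centroids
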