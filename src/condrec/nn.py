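"""Minimal feed-forward network with manual backprop.

The stage models are plain MLPs over binary fingerprint inputs, so the
whole training stack fits in a few hundred lines of numpy: He-initialized
ReLU layers, Adam, and three loss heads —

* ``bce`` — independent sigmoids with binary cross-entropy (multi-label
  agent prediction);
* ``ce`` — softmax cross-entropy over a single categorical head
  (temperature / reactant-amount bins);
* ``masked_ce`` — the output is reshaped to ``(groups, bins)`` and a
  per-example group mask selects which rows contribute: each *present*
  group gets its own softmax cross-entropy, absent groups contribute
  exactly zero loss and zero gradient (per-agent amount bins).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / np.sum(ez, axis=axis, keepdims=True)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean element-wise binary cross-entropy; returns (loss, dloss/dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
    grad = (p - targets) / logits.size
    return float(loss), grad


def softmax_ce(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy with integer labels."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def masked_softmax_ce(
    logits: np.ndarray, labels: np.ndarray, n_bins: int
) -> tuple[float, np.ndarray]:
    """Grouped masked cross-entropy.

    ``logits``: (N, G*n_bins); ``labels``: (N, G) integer bin per group,
    with −1 marking absent groups. The loss is the mean over *present*
    groups of each group's ``n_bins``-way cross-entropy; absent groups
    receive zero gradient, so their logits are free parameters the loss
    never sees.
    """
    n, total = logits.shape
    if total % n_bins:
        raise ValueError("logit width not divisible by n_bins")
    g = total // n_bins
    lg = logits.reshape(n, g, n_bins)
    present = labels >= 0
    n_present = int(np.count_nonzero(present))
    if n_present == 0:
        return 0.0, np.zeros_like(logits)
    p = softmax(lg, axis=2)
    eps = 1e-12
    safe_labels = np.where(present, labels, 0)
    picked = np.take_along_axis(p, safe_labels[:, :, None], axis=2)[:, :, 0]
    loss = -np.sum(np.log(picked + eps) * present) / n_present
    grad = p.copy()
    np.put_along_axis(
        grad,
        safe_labels[:, :, None],
        np.take_along_axis(grad, safe_labels[:, :, None], axis=2) - 1.0,
        axis=2,
    )
    grad *= present[:, :, None]
    return float(loss), (grad / n_present).reshape(n, total)


@dataclass
class TrainConfig:
    """Shared training hyperparameters for all four stage models."""

    hidden_sizes: tuple[int, ...] = (256,)
    learning_rate: float = 1e-3
    epochs: int = 15
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("training hyperparameters must be positive")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


class MLP:
    """ReLU MLP with a linear output layer, trained with Adam."""

    def __init__(self, in_dim: int, hidden_sizes: Sequence[int], out_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [in_dim, *hidden_sizes, out_dim]
        self.weights = [_he_init(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.in_dim = in_dim
        self.out_dim = out_dim
        self._adam_state: Optional[dict] = None

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        acts = [x]
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
            if keep_cache:
                acts.append(h)
        return (h, acts) if keep_cache else h

    def backward(self, acts: list[np.ndarray], dlogits: np.ndarray):
        grads_w, grads_b = [], []
        delta = dlogits
        for i in range(len(self.weights) - 1, -1, -1):
            a_in = acts[i]
            grads_w.append(a_in.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
        return grads_w[::-1], grads_b[::-1]

    def _adam_step(self, grads_w, grads_b, lr: float):
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "mw": [np.zeros_like(w) for w in self.weights],
                "vw": [np.zeros_like(w) for w in self.weights],
                "mb": [np.zeros_like(b) for b in self.biases],
                "vb": [np.zeros_like(b) for b in self.biases],
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bc1 = 1 - b1 ** st["t"]
        bc2 = 1 - b2 ** st["t"]
        for i in range(len(self.weights)):
            for key, params, grads in (("w", self.weights, grads_w), ("b", self.biases, grads_b)):
                m, v = st["m" + key][i], st["v" + key][i]
                m *= b1
                m += (1 - b1) * grads[i]
                v *= b2
                v += (1 - b2) * grads[i] ** 2
                params[i] -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        loss: str,
        cfg: TrainConfig,
        n_bins: Optional[int] = None,
    ) -> list[float]:
        """Train in place; returns the mean loss per epoch."""
        if len(x) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(cfg.seed + 1)
        history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(x))
            losses = []
            for start in range(0, len(x), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits, acts = self.forward(x[idx], keep_cache=True)
                if loss == "bce":
                    l, dlogits = bce_with_logits(logits, y[idx])
                elif loss == "ce":
                    l, dlogits = softmax_ce(logits, y[idx])
                elif loss == "masked_ce":
                    l, dlogits = masked_softmax_ce(logits, y[idx], n_bins)
                else:
                    raise ValueError(f"unknown loss {loss!r}")
                grads_w, grads_b = self.backward(acts, dlogits)
                self._adam_step(grads_w, grads_b, cfg.learning_rate)
                losses.append(l)
            history.append(float(np.mean(losses)))
        return history

    # --- serialization (runtime checkpoints) ----------------------------

    def state_dict(self) -> dict:
        d = {"in_dim": self.in_dim, "out_dim": self.out_dim, "n_layers": len(self.weights)}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            d[f"w{i}"] = w
            d[f"b{i}"] = b
        return d

    @classmethod
    def from_state_dict(cls, d: dict) -> "MLP":
        n = int(d["n_layers"])
        obj = cls.__new__(cls)
        obj.weights = [np.asarray(d[f"w{i}"]) for i in range(n)]
        obj.biases = [np.asarray(d[f"b{i}"]) for i in range(n)]
        obj.in_dim = int(d["in_dim"])
        obj.out_dim = int(d["out_dim"])
        obj._adam_state = None
        return obj
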