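"""Minimal feed-forward softmax networks with analytic gradients.

The decoder family used throughout the package: a fully-connected network
with ReLU (or tanh) hidden layers and a softmax output head, trained with
Adam.  Gradients are computed in closed form, which is all the agreement-
constrained objective needs: both the cross-entropy term and the L1 penalty
between two softmax outputs have simple expressions for dLoss/dlogits.

Everything is deterministic given the ``numpy`` Generator used to initialise
weights and shuffle batches.
"""

from __future__ import annotations

import numpy as np

LN2 = float(np.log(2.0))
PROB_FLOOR = 1e-12  # clamp predicted probabilities before taking logs

_ACTIVATIONS = ("relu", "tanh")


class MLP:
    """Fully-connected net: input -> hidden layers -> K logits -> softmax."""

    def __init__(
        self,
        n_in: int,
        n_classes: int,
        hidden: tuple[int, ...] = (64, 64),
        activation: str = "relu",
        rng: np.random.Generator | None = None,
    ):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if n_in < 1 or n_classes < 2:
            raise ValueError("need n_in >= 1 and n_classes >= 2")
        rng = rng or np.random.default_rng()
        self.n_in, self.n_classes = int(n_in), int(n_classes)
        self.hidden = tuple(int(h) for h in hidden)
        self.activation = activation
        dims = [self.n_in, *self.hidden, self.n_classes]
        # He initialisation (suits ReLU; harmless for tanh at these widths)
        self.W = [
            rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(2.0 / dims[i])
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    # ----------------------------------------------------------- forward
    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.activation == "relu" else np.tanh(z)

    def _act_grad(self, a: np.ndarray) -> np.ndarray:
        # expressed in terms of the activation output a
        return (a > 0).astype(a.dtype) if self.activation == "relu" else 1.0 - a * a

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (softmax probabilities, cached activations for backward)."""
        X = np.asarray(X, dtype=np.float64)
        cache = [X]
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = self._act(h @ W + b)
            cache.append(h)
        logits = h @ self.W[-1] + self.b[-1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    # ---------------------------------------------------------- backward
    def backward(
        self, cache: list[np.ndarray], grad_logits: np.ndarray
    ) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters, given dLoss/dlogits.

        Returns a flat list [dW0, db0, dW1, db1, ...].
        """
        grads: list[np.ndarray] = []
        delta = grad_logits
        for layer in range(len(self.W) - 1, -1, -1):
            a_prev = cache[layer]
            grads.append(delta.sum(axis=0))   # db
            grads.append(a_prev.T @ delta)    # dW
            if layer > 0:
                delta = (delta @ self.W[layer].T) * self._act_grad(a_prev)
        grads.reverse()  # (db, dW) pairs appended last-layer-first -> [dW0, db0, ...]
        return grads

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W, b in zip(self.W, self.b):
            out.extend((W, b))
        return out

    # ------------------------------------------------------- persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            d[f"W{i}"], d[f"b{i}"] = W, b
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for i in range(len(self.W)):
            self.W[i] = np.asarray(d[f"W{i}"], dtype=np.float64)
            self.b[i] = np.asarray(d[f"b{i}"], dtype=np.float64)


class Adam:
    """Adam optimiser over a list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr, self.eps = float(lr), float(eps)
        self.b1, self.b2 = betas
        self.weight_decay = float(weight_decay)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:  # decoupled L2 shrinkage
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class SGD:
    """Plain (optionally momentum) stochastic gradient descent."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-2,
        momentum: float = 0.0,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr, self.momentum = float(lr), float(momentum)
        self.weight_decay = float(weight_decay)
        self.vel = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.vel):
            v *= self.momentum
            v -= self.lr * g
            if self.weight_decay:
                p *= 1.0 - self.lr * self.weight_decay
            p += v


def make_optimizer(name: str, params: list[np.ndarray], lr: float, weight_decay: float = 0.0):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr, weight_decay=weight_decay)
    if name == "sgd":
        return SGD(params, lr=lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}; choose 'adam' or 'sgd'")


def cross_entropy_grad_logits(
    probs: np.ndarray, labels: np.ndarray, weight: float
) -> np.ndarray:
    """d/dlogits of weight * mean_i(-log2 p_i[y_i]).

    The softmax-cross-entropy composite gradient (p - onehot); the 1/ln2
    factor puts the loss on the bits scale.
    """
    n = probs.shape[0]
    g = probs.copy()
    g[np.arange(n), labels] -= 1.0
    return g * (weight / (n * LN2))


L1_SMOOTH = 1e-3  # kink smoothing for the agreement-penalty gradient


def l1_distance_grad_logits(
    probs_a: np.ndarray, probs_b: np.ndarray, weight: float
) -> np.ndarray:
    """d/dlogits_a of weight * mean_i ||p_a,i - p_b,i||_1 (p_b held fixed).

    Uses the pseudo-Huber gradient d / sqrt(d^2 + eps^2) instead of the raw
    sign subgradient: at the kink (agreeing predictions) sign() would inject
    +-weight gradient chatter that biases otherwise-converged decoders, while
    the smoothed form vanishes there.  Chained through the softmax Jacobian
    of decoder a.
    """
    n = probs_a.shape[0]
    d = probs_a - probs_b
    s = d / np.sqrt(d * d + L1_SMOOTH * L1_SMOOTH) * (weight / n)
    # softmax Jacobian: dL/dz = p * (s - sum_j s_j p_j)
    return probs_a * (s - (s * probs_a).sum(axis=1, keepdims=True))
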