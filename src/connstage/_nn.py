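"""Minimal batched reverse-mode layers for the graph encoder.

Everything operates on dense batched arrays: node features ``X`` of
shape ``(B, N, F)`` and adjacency ``A`` of shape ``(B, N, N)``.  Each
block caches what its backward pass needs on ``forward`` and
accumulates parameter gradients on ``backward`` (full-batch training,
single-threaded, so per-instance caches are safe).

Parameter initialization is uniform fan-in scaling, U(−1/√fan_in,
+1/√fan_in), drawn in a fixed order from a seeded generator so that a
given seed always yields bitwise-identical models.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def masked_softmax(logits: np.ndarray, mask: np.ndarray,
                   axis: int) -> np.ndarray:
    """Softmax over ``axis`` restricted to ``mask``; masked entries get 0.

    Every softmax group is assumed nonempty (graph layers always include
    the self-loop).
    """
    neg = np.where(mask, logits, -np.inf)
    neg = neg - neg.max(axis=axis, keepdims=True)
    e = np.exp(neg)
    e = np.where(mask, e, 0.0)
    return e / e.sum(axis=axis, keepdims=True)


class Linear:
    """Affine map applied over the trailing dimension."""

    def __init__(self, rng: np.random.Generator, fan_in: int, fan_out: int,
                 bias: bool = True):
        self.W = Param(_uniform(rng, (fan_in, fan_out), fan_in))
        self.b = Param(_uniform(rng, (fan_out,), fan_in)) if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm:
    """Per-feature normalization over all rows of the (graph×node) batch.

    Training mode normalizes with the current batch statistics and
    stores them; evaluation mode reuses the stored statistics (under
    full-batch training these are exact dataset statistics), falling
    back to batch statistics for a never-trained model.  Keeps every
    feature's variance at unit scale, preventing weight decay from
    erasing embedding directions the classification loss does not use.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps
        self.stored: tuple[np.ndarray, np.ndarray] | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        flat = x.reshape(-1, x.shape[-1])
        if train or self.stored is None:
            mu, var = flat.mean(axis=0), flat.var(axis=0)
            if train:
                self.stored = (mu, var)
        else:
            mu, var = self.stored
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * inv
        self._inv = inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        fd = dy.reshape(-1, dy.shape[-1])
        fx = self._xhat.reshape(-1, dy.shape[-1])
        self.beta.grad += fd.sum(axis=0)
        self.gamma.grad += (fd * fx).sum(axis=0)
        return self.gamma.value * self._inv * (
            dy - fd.mean(axis=0) - self._xhat * (fd * fx).mean(axis=0)
        )


class GINBlock:
    """Sum aggregation with (1+ε) self-weight, then a 2-layer perceptron.

    Node update: ``φ((1+ε)·x_v + Σ_{u∈N(v)} x_u)`` with φ =
    Linear→ReLU→Linear, batch-normalized and rectified before the next
    layer (the conventional GIN stack ordering).  ε is a fixed
    (untrained) scalar.
    """

    def __init__(self, rng: np.random.Generator, fan_in: int,
                 width: int = 128, epsilon: float = 0.0,
                 final_relu: bool = True):
        self.epsilon = float(epsilon)
        self.lin1 = Linear(rng, fan_in, width)
        self.lin2 = Linear(rng, width, width)
        self.norm = BatchNorm(width)
        self.final_relu = final_relu
        self.out_dim = width

    def params(self) -> list[Param]:
        return self.lin1.params() + self.lin2.params() + self.norm.params()

    def forward(self, x: np.ndarray, adj: np.ndarray,
                train: bool = False) -> np.ndarray:
        self._adj = adj
        s = (1.0 + self.epsilon) * x + adj @ x
        h = self.lin1.forward(s)
        self._h_pos = h > 0
        out = self.norm.forward(self.lin2.forward(relu(h)), train)
        if self.final_relu:
            self._o_pos = out > 0
            out = relu(out)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.final_relu:
            dy = dy * self._o_pos
        dh = self.lin2.backward(self.norm.backward(dy)) * self._h_pos
        ds = self.lin1.backward(dh)
        # aggregation matrix (1+ε)I + A is symmetric
        return (1.0 + self.epsilon) * ds + self._adj @ ds


class GCNBlock:
    """Symmetric-normalized graph convolution with self-loops.

    Node update: ``σ(Σ_u Ã_norm[v,u]·(x_u W))`` with ``Ã = A + I`` and
    ``Ã_norm = D̃^{-1/2} Ã D̃^{-1/2}``; σ is a ReLU.
    """

    def __init__(self, rng: np.random.Generator, fan_in: int,
                 width: int = 128):
        self.lin = Linear(rng, fan_in, width)
        self.norm = BatchNorm(width)
        self.out_dim = width

    def params(self) -> list[Param]:
        return self.lin.params() + self.norm.params()

    @staticmethod
    def normalized_adjacency(adj: np.ndarray) -> np.ndarray:
        n = adj.shape[-1]
        a_hat = adj + np.eye(n)
        d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=-1))
        return a_hat * d_inv_sqrt[..., :, None] * d_inv_sqrt[..., None, :]

    def forward(self, x: np.ndarray, adj: np.ndarray,
                train: bool = False) -> np.ndarray:
        self._m = self.normalized_adjacency(adj)
        out = self.norm.forward(self.lin.forward(self._m @ x), train)
        self._pos = out > 0
        return relu(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ds = self.lin.backward(self.norm.backward(dy * self._pos))
        return self._m @ ds  # M is symmetric


class GATBlock:
    """Single-head graph attention over each node's closed neighborhood.

    ``z_u = W x_u``; the attention logit between u and v is
    ``LeakyReLU(a·(z_u ‖ z_v))``, softmax-normalized over
    ``N(v) ∪ {v}``; the update is the attention-weighted sum of the
    ``z_u`` over that same set, batch-normalized on the way out (no
    extra nonlinearity before the readout).
    """

    def __init__(self, rng: np.random.Generator, fan_in: int,
                 out_dim: int = 64, leaky_slope: float = 0.2):
        self.lin = Linear(rng, fan_in, out_dim, bias=False)
        self.a_src = Param(_uniform(rng, (out_dim,), out_dim))
        self.a_dst = Param(_uniform(rng, (out_dim,), out_dim))
        self.norm = BatchNorm(out_dim)
        self.leaky_slope = float(leaky_slope)
        self.out_dim = out_dim

    def params(self) -> list[Param]:
        return self.lin.params() + [self.a_src, self.a_dst] + \
            self.norm.params()

    def forward(self, x: np.ndarray, adj: np.ndarray,
                train: bool = False) -> np.ndarray:
        n = adj.shape[-1]
        z = self.lin.forward(x)
        s = z @ self.a_src.value  # (B, N) source terms
        t = z @ self.a_dst.value  # (B, N) destination terms
        e = s[..., :, None] + t[..., None, :]  # e[b, u, v]
        mask = (adj + np.eye(n)) > 0
        alpha = masked_softmax(leaky_relu(e, self.leaky_slope), mask, axis=-2)
        self._z, self._e, self._alpha = z, e, alpha
        out = np.matmul(alpha.swapaxes(-1, -2), z)  # Σ_u α[u,v]·z_u
        return self.norm.forward(out, train)

    def attention(self, x: np.ndarray, adj: np.ndarray) -> np.ndarray:
        """Attention matrix α[u, v] (columns sum to 1 over N(v) ∪ {v})."""
        self.forward(x, adj)
        return self._alpha

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.norm.backward(dy)
        z, e, alpha = self._z, self._e, self._alpha
        d_alpha = np.matmul(z, dy.swapaxes(-1, -2))
        dz = np.matmul(alpha, dy)
        # softmax backward over the source axis u
        inner = (alpha * d_alpha).sum(axis=-2, keepdims=True)
        d_logit = alpha * (d_alpha - inner)
        de = d_logit * np.where(e >= 0, 1.0, self.leaky_slope)
        ds = de.sum(axis=-1)
        dt = de.sum(axis=-2)
        self.a_src.grad += np.tensordot(ds, z, axes=([0, 1], [0, 1]))
        self.a_dst.grad += np.tensordot(dt, z, axes=([0, 1], [0, 1]))
        dz += ds[..., None] * self.a_src.value
        dz += dt[..., None] * self.a_dst.value
        return self.lin.backward(dz)


class AttentionReadout:
    """Gated pooling: softmax over per-node gate scores weights each node.

    ``x_G = Σ_v softmax_v(φ_gate(x_v)) ⊙ x_v`` with φ_gate a single
    affine map to a scalar.
    """

    def __init__(self, rng: np.random.Generator, dim: int):
        self.gate = Linear(rng, dim, 1)
        self.out_dim = dim

    def params(self) -> list[Param]:
        return self.gate.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = self.gate.forward(x)[..., 0]  # (B, N)
        g = g - g.max(axis=-1, keepdims=True)
        e = np.exp(g)
        alpha = e / e.sum(axis=-1, keepdims=True)
        self._x, self._alpha = x, alpha
        return np.matmul(alpha[..., None, :], x)[..., 0, :]

    def weights(self, x: np.ndarray) -> np.ndarray:
        self.forward(x)
        return self._alpha

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, alpha = self._x, self._alpha
        d_alpha = np.matmul(x, dy[..., None])[..., 0]
        dx = alpha[..., None] * dy[..., None, :]
        dg = alpha * (d_alpha - (alpha * d_alpha).sum(axis=-1, keepdims=True))
        dx += self.gate.backward(dg[..., None])
        return dx


class SumReadout:
    """Column-wise sum over nodes."""

    def __init__(self, dim: int):
        self.out_dim = dim

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._n = x.shape[-2]
        return x.sum(axis=-2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[..., None, :], self._n, axis=-2)


class ReLUBlock:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return relu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns (loss, probabilities, d_logits).
    """
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.log(probs[np.arange(n), y] + 1e-300).mean())
    d = probs.copy()
    d[np.arange(n), y] -= 1.0
    return loss, probs, d / n


class Adam:
    """Adam with L2-coupled weight decay added to the raw gradient."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 weight_decay: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.wd * p.value
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
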