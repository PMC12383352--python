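"""Graph encoder: GIN → GAT → attention readout, plus ablation variants.

Two surfaces live here.  The functional ops (:func:`gin_layer`,
:func:`gat_layer`, :func:`gcn_layer`, :func:`attention_readout`,
:func:`sum_readout`) evaluate a single layer on one graph with
explicitly supplied parameters — convenient for hand-checked algebra
and for inspecting attention weights.  :class:`EncoderModel` is the
trainable composition used by the study pipeline: it pairs the graph
layers with a 2-layer MLP classification head (hidden 32 → 2 softmax
outputs) whose supervision shapes the embedding, and it exposes the
graph-level embedding with the head detached.

Variants (the ablation grid):

==============  =============================================  ====
variant         graph layers → readout                          D
==============  =============================================  ====
baseline        GIN(128) → GAT(64) → attention pool             64
sum_pool        GIN(128) → GAT(64) → sum pool                   64
gin_only        GIN(128) → attention pool                      128
gcn_variant     GCN(128) → GAT(64) → attention pool             64
gat_only        GAT(64) → attention pool                        64
==============  =============================================  ====

A ReLU follows the GIN/GCN block; the GAT output feeds the readout
without a further nonlinearity.  ε in the GIN update is fixed at 0 by
default and not trained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._nn import (
    AttentionReadout,
    GATBlock,
    GCNBlock,
    GINBlock,
    Linear,
    Param,
    ReLUBlock,
    SumReadout,
    leaky_relu,
    masked_softmax,
)
from .core import BinarizedGraph

VARIANTS = ("baseline", "sum_pool", "gin_only", "gcn_variant", "gat_only")


# ---------------------------------------------------------------------------
# functional single-graph ops with explicit parameters

@dataclass
class GINLayerParams:
    """ε plus the 2-layer perceptron φ; ``W1=None`` means φ = identity."""

    epsilon: float = 0.0
    W1: np.ndarray | None = None
    b1: np.ndarray | None = None
    W2: np.ndarray | None = None
    b2: np.ndarray | None = None


@dataclass
class GATLayerParams:
    """Transform ``W`` (F×D), attention kernel ``a`` (length 2D)."""

    weight: np.ndarray
    attn_kernel: np.ndarray
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        d = np.asarray(self.weight).shape[1]
        if np.asarray(self.attn_kernel).size != 2 * d:
            raise ValueError(
                f"attention kernel must have length {2 * d}, "
                f"got {np.asarray(self.attn_kernel).size}"
            )


@dataclass
class ReadoutParams:
    """Affine gate mapping a node-feature vector to a scalar score."""

    gate_weight: np.ndarray
    gate_bias: float = 0.0


def _check_dims(features: np.ndarray, adjacency: np.ndarray) -> None:
    features = np.asarray(features)
    adjacency = np.asarray(adjacency)
    if adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError(f"adjacency must be square, got {adjacency.shape}")
    if features.shape[0] != adjacency.shape[0]:
        raise ValueError(
            f"{features.shape[0]} feature rows for "
            f"{adjacency.shape[0]} nodes"
        )


def gin_layer(features: np.ndarray, adjacency: np.ndarray,
              params: GINLayerParams) -> np.ndarray:
    """One GIN update: ``φ((1+ε)x_v + Σ_{u∈N(v)} x_u)`` per node."""
    _check_dims(features, adjacency)
    x = np.asarray(features, dtype=float)
    a = np.asarray(adjacency, dtype=float)
    s = (1.0 + params.epsilon) * x + a @ x
    if params.W1 is None:
        return s
    h = np.maximum(s @ params.W1 + params.b1, 0.0)
    return h @ params.W2 + params.b2


def gat_attention(features: np.ndarray, adjacency: np.ndarray,
                  params: GATLayerParams) -> np.ndarray:
    """Attention matrix α[u, v]; each column sums to 1 over N(v) ∪ {v}."""
    _check_dims(features, adjacency)
    x = np.asarray(features, dtype=float)
    a = np.asarray(adjacency, dtype=float)
    d = params.weight.shape[1]
    z = x @ params.weight
    kernel = np.asarray(params.attn_kernel, dtype=float)
    s = z @ kernel[:d]
    t = z @ kernel[d:]
    logits = leaky_relu(s[:, None] + t[None, :], params.leaky_slope)
    mask = (a + np.eye(a.shape[0])) > 0
    return masked_softmax(logits, mask, axis=0)


def gat_layer(features: np.ndarray, adjacency: np.ndarray,
              params: GATLayerParams) -> np.ndarray:
    """One GAT update: attention-weighted sum of ``z_u = W x_u`` over
    the closed neighborhood N(v) ∪ {v}."""
    alpha = gat_attention(features, adjacency, params)
    z = np.asarray(features, dtype=float) @ params.weight
    return np.einsum("uv,ud->vd", alpha, z)


def gcn_layer(features: np.ndarray, adjacency: np.ndarray,
              weight: np.ndarray,
              activation: Callable[[np.ndarray], np.ndarray] | None = None,
              ) -> np.ndarray:
    """Symmetric-normalized graph convolution with self-loops."""
    _check_dims(features, adjacency)
    x = np.asarray(features, dtype=float)
    a = np.asarray(adjacency, dtype=float)
    m = GCNBlock.normalized_adjacency(a)
    out = m @ x @ np.asarray(weight, dtype=float)
    return activation(out) if activation is not None else out


def readout_weights(node_features: np.ndarray,
                    params: ReadoutParams) -> np.ndarray:
    """Softmax node weights of the attention readout (sum to 1)."""
    x = np.asarray(node_features, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    g = x @ np.asarray(params.gate_weight, dtype=float) + params.gate_bias
    g = g - g.max()
    e = np.exp(g)
    return e / e.sum()


def attention_readout(node_features: np.ndarray,
                      params: ReadoutParams) -> np.ndarray:
    """Gated pooling: ``x_G = Σ_v softmax_v(φ_gate(x_v)) ⊙ x_v``."""
    alpha = readout_weights(node_features, params)
    return alpha @ np.asarray(node_features, dtype=float)


def sum_readout(node_features: np.ndarray) -> np.ndarray:
    """Column-wise sum over nodes."""
    x = np.asarray(node_features, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    return x.sum(axis=0)


# ---------------------------------------------------------------------------
# trainable encoder

class EncoderModel:
    """Variant-configurable graph encoder with an MLP classification head.

    ``n_nodes`` fixes the one-hot input feature dimension F = N.  The
    embedding dimension D is 64 for variants ending in a GAT layer and
    128 for ``gin_only``.
    """

    def __init__(self, variant: str = "baseline", n_nodes: int = 148,
                 gin_width: int = 128, gat_dim: int = 64,
                 hidden_dim: int = 32, epsilon: float = 0.0,
                 leaky_slope: float = 0.2, seed: int = 0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"expected one of {VARIANTS}")
        self.variant = variant
        self.n_nodes = int(n_nodes)
        self.config = dict(gin_width=gin_width, gat_dim=gat_dim,
                           hidden_dim=hidden_dim, epsilon=epsilon,
                           leaky_slope=leaky_slope, seed=seed)
        rng = np.random.default_rng(seed)
        layers: list = []
        if variant in ("baseline", "sum_pool", "gin_only"):
            layers.append(GINBlock(rng, n_nodes, gin_width, epsilon,
                                   final_relu=True))
        elif variant == "gcn_variant":
            layers.append(GCNBlock(rng, n_nodes, gin_width))
        if variant in ("baseline", "sum_pool", "gcn_variant"):
            layers.append(GATBlock(rng, gin_width, gat_dim, leaky_slope))
        elif variant == "gat_only":
            layers.append(GATBlock(rng, n_nodes, gat_dim, leaky_slope))
        self.graph_layers = layers
        dim = layers[-1].out_dim
        if variant == "sum_pool":
            self.readout = SumReadout(dim)
        else:
            self.readout = AttentionReadout(rng, dim)
        self.embedding_dim = dim
        self.head = [Linear(rng, dim, hidden_dim), ReLUBlock(),
                     Linear(rng, hidden_dim, 2)]
        self.classes_: tuple[str, str] | None = None
        self.train_history_: list[float] = []

    # -- parameters -------------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.graph_layers:
            out.extend(layer.params())
        out.extend(self.readout.params())
        for layer in self.head:
            out.extend(layer.params())
        return out

    # -- forward/backward -------------------------------------------------

    def embed_arrays(self, adjacency: np.ndarray,
                     features: np.ndarray | None = None,
                     train: bool = False) -> np.ndarray:
        """Embed a batch: adjacency (B,N,N), features (B,N,F) → (B,D).

        ``train=True`` runs the normalization layers on current batch
        statistics (and stores them); evaluation reuses the statistics
        of the last training batch.
        """
        adjacency = np.asarray(adjacency, dtype=float)
        if adjacency.ndim == 2:
            adjacency = adjacency[None]
        b, n, _ = adjacency.shape
        if n != self.n_nodes:
            raise ValueError(f"model expects {self.n_nodes} nodes, got {n}")
        if features is None:
            features = np.broadcast_to(np.eye(n), (b, n, n)).copy()
        x = np.asarray(features, dtype=float)
        if x.ndim == 2:
            x = x[None]
        for layer in self.graph_layers:
            x = layer.forward(x, adjacency, train)
        return self.readout.forward(x)

    def forward_logits(self, adjacency: np.ndarray,
                       features: np.ndarray | None = None,
                       train: bool = False) -> np.ndarray:
        h = self.embed_arrays(adjacency, features, train)
        for layer in self.head:
            h = layer.forward(h)
        return h

    def backward(self, d_logits: np.ndarray) -> None:
        d = d_logits
        for layer in reversed(self.head):
            d = layer.backward(d)
        d = self.readout.backward(d)
        for layer in reversed(self.graph_layers):
            d = layer.backward(d)

    # -- convenience ------------------------------------------------------

    def embed(self, graphs: Sequence[BinarizedGraph]) -> np.ndarray:
        """Embed graphs (chunked) → (n_graphs, D)."""
        out = []
        for start in range(0, len(graphs), 32):
            chunk = graphs[start:start + 32]
            adj = np.stack([g.adjacency for g in chunk])
            feat = np.stack([g.features for g in chunk])
            out.append(self.embed_arrays(adj, feat))
        return np.concatenate(out, axis=0)

    def predict_proba(self, graphs: Sequence[BinarizedGraph]) -> np.ndarray:
        """Class probabilities, columns ordered as ``self.classes_``."""
        out = []
        for start in range(0, len(graphs), 32):
            chunk = graphs[start:start + 32]
            adj = np.stack([g.adjacency for g in chunk])
            feat = np.stack([g.features for g in chunk])
            logits = self.forward_logits(adj, feat)
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    # -- persistence ------------------------------------------------------

    def _norm_layers(self):
        return [layer.norm for layer in self.graph_layers
                if hasattr(layer, "norm")]

    def save(self, path) -> None:
        """Persist as an .npz key→array container with config metadata."""
        arrays = {f"param_{i:03d}": p.value
                  for i, p in enumerate(self.params())}
        for i, norm in enumerate(self._norm_layers()):
            if norm.stored is not None:
                arrays[f"norm_{i:03d}_mean"] = norm.stored[0]
                arrays[f"norm_{i:03d}_var"] = norm.stored[1]
        meta = dict(self.config)
        meta["variant"] = self.variant
        meta["n_nodes"] = self.n_nodes
        meta["classes"] = ",".join(self.classes_ or ())
        np.savez(path, _meta=np.array([repr(meta)]), **arrays)

    @classmethod
    def load(cls, path) -> "EncoderModel":
        import ast

        with np.load(path, allow_pickle=False) as data:
            meta = ast.literal_eval(str(data["_meta"][0]))
            classes = tuple(c for c in meta.pop("classes").split(",") if c)
            model = cls(variant=meta.pop("variant"),
                        n_nodes=meta.pop("n_nodes"), **meta)
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i:03d}"]
            for i, norm in enumerate(model._norm_layers()):
                if f"norm_{i:03d}_mean" in data:
                    norm.stored = (data[f"norm_{i:03d}_mean"].copy(),
                                   data[f"norm_{i:03d}_var"].copy())
        model.classes_ = classes or None
        return model


def embed_graph(graph: BinarizedGraph, model: EncoderModel) -> np.ndarray:
    """Graph-level embedding of one binarized connectome (D vector)."""
    return model.embed_arrays(graph.adjacency[None],
                              graph.features[None])[0]
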