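"""Graph encoders for drug molecules.

The default encoder stacks GATv2 attention layers over the molecular graph.
For node ``i`` with neighborhood ``N_i`` (self-loop included), layer weights

.. math::

    \\alpha_{i,j} = \\operatorname{softmax}_{j \\in N_i \\cup \\{i\\}}
        \\big( a^\\top \\mathrm{LeakyReLU}(\\Theta h_i + \\Theta h_j) \\big)

are "dynamic": the logit depends nonlinearly on both endpoints, unlike the
original GAT whose per-node terms make the ranking of neighbors static.
The update is ``h_i' = ELU(Σ_j α_{i,j} Θ h_j)`` with the sum over
``N_i ∪ {i}``. The shared-Θ form applies one linear map to both endpoints,
consistent with a single ``emb_dim × d`` parameter matrix.

A whole-graph embedding is read out hierarchically: each layer's node
states are global-average-pooled into ``g^l``, a learned context vector
``c`` scores the layers (``c·g^l / √d'``), and the softmax-weighted sum of
``g^1..g^L`` is the drug embedding ``z``. The raw input pooling (l = 0) is
excluded from the readout.

GAT and GCN variants expose the same interface for encoder comparisons.
"""

from __future__ import annotations

import numpy as np

from .chem import DrugGraph, NUM_ATOM_FEATURES
from .nn.autodiff import Tensor, concat
from .nn.modules import Linear, Module

__all__ = [
    "GnnConfig",
    "GATv2Layer",
    "GATLayer",
    "GCNLayer",
    "DrugEncoder",
    "elu",
    "layer_pool",
    "hierarchical_readout",
    "gatv2_attention",
]

_MASK_NEG = -1e30


def elu(x, a: float = 1.0):
    """Exponential linear unit: x for x ≥ 0, a·(exp(x) − 1) for x < 0."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x >= 0, x, a * (np.exp(np.minimum(x, 0.0)) - 1.0))


class GnnConfig:
    """Encoder hyperparameters. ``gnn_type`` ∈ {'gatv2', 'gat', 'gcn'}."""

    def __init__(
        self,
        gnn_type: str = "gatv2",
        num_layer: int = 3,
        emb_dim: int = 100,
        heads: int = 1,
        leaky_slope: float = 0.2,
        elu_alpha: float = 1.0,
    ):
        if gnn_type not in ("gatv2", "gat", "gcn"):
            raise ValueError(f"unknown gnn_type {gnn_type!r}")
        if num_layer < 1 or emb_dim < 1 or heads < 1:
            raise ValueError("num_layer, emb_dim and heads must be positive")
        self.gnn_type = gnn_type
        self.num_layer = num_layer
        self.emb_dim = emb_dim
        self.heads = heads
        self.leaky_slope = leaky_slope
        self.elu_alpha = elu_alpha


def _neighborhood_mask(A: np.ndarray) -> np.ndarray:
    """Additive logit mask over N_i ∪ {i}: 0 on edges/self, −inf elsewhere."""
    mask = (A + np.eye(A.shape[0])) > 0
    return np.where(mask, 0.0, _MASK_NEG)


class GATv2Layer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng, leaky_slope: float = 0.2, elu_alpha: float = 1.0):
        super().__init__()
        self.theta = Linear(in_dim, out_dim, rng, bias=False)
        bound = np.sqrt(1.0 / out_dim)
        self.attn_vector = Tensor(rng.uniform(-bound, bound, size=out_dim), requires_grad=True)
        self.leaky_slope = leaky_slope
        self.elu_alpha = elu_alpha

    def attention(self, H: Tensor, A: np.ndarray) -> Tensor:
        """Row-stochastic R×R attention matrix (zero off-neighborhood)."""
        R = A.shape[0]
        S = self.theta(H)  # (R, d)
        d = S.shape[1]
        pair = S.reshape(R, 1, d) + S.reshape(1, R, d)
        logits = (pair.leaky_relu(self.leaky_slope) * self.attn_vector.reshape(1, 1, d)).sum(axis=2)
        return (logits + Tensor(_neighborhood_mask(A))).softmax(axis=1)

    def __call__(self, H: Tensor, A: np.ndarray) -> Tensor:
        alpha = self.attention(H, A)
        return (alpha @ self.theta(H)).elu(self.elu_alpha)


class GATLayer(Module):
    """Original GAT: logits LeakyReLU(a_l·Θh_i + a_r·Θh_j) — static attention."""

    def __init__(self, in_dim: int, out_dim: int, rng, leaky_slope: float = 0.2, elu_alpha: float = 1.0):
        super().__init__()
        self.theta = Linear(in_dim, out_dim, rng, bias=False)
        bound = np.sqrt(1.0 / out_dim)
        self.attn_l = Tensor(rng.uniform(-bound, bound, size=out_dim), requires_grad=True)
        self.attn_r = Tensor(rng.uniform(-bound, bound, size=out_dim), requires_grad=True)
        self.leaky_slope = leaky_slope
        self.elu_alpha = elu_alpha

    def attention(self, H: Tensor, A: np.ndarray) -> Tensor:
        R = A.shape[0]
        S = self.theta(H)
        el = (S @ self.attn_l).reshape(R, 1)
        er = (S @ self.attn_r).reshape(1, R)
        logits = (el + er).leaky_relu(self.leaky_slope)
        return (logits + Tensor(_neighborhood_mask(A))).softmax(axis=1)

    def __call__(self, H: Tensor, A: np.ndarray) -> Tensor:
        alpha = self.attention(H, A)
        return (alpha @ self.theta(H)).elu(self.elu_alpha)


class GCNLayer(Module):
    """Symmetric-normalized convolution: ELU(D̂^-1/2 Â D̂^-1/2 H Θ), Â = A + I."""

    def __init__(self, in_dim: int, out_dim: int, rng, leaky_slope: float = 0.2, elu_alpha: float = 1.0):
        super().__init__()
        self.theta = Linear(in_dim, out_dim, rng, bias=False)
        self.elu_alpha = elu_alpha

    @staticmethod
    def _norm_adj(A: np.ndarray) -> np.ndarray:
        Ahat = A + np.eye(A.shape[0])
        dinv = 1.0 / np.sqrt(Ahat.sum(axis=1))
        return Ahat * dinv[:, None] * dinv[None, :]

    def __call__(self, H: Tensor, A: np.ndarray) -> Tensor:
        return (Tensor(self._norm_adj(A)) @ self.theta(H)).elu(self.elu_alpha)


_LAYER_TYPES = {"gatv2": GATv2Layer, "gat": GATLayer, "gcn": GCNLayer}


def layer_pool(states: Tensor) -> Tensor:
    """Global average pooling over nodes: g = (1/R) Σ_i h_i."""
    if states.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    return states.mean(axis=0)


def hierarchical_readout(per_layer_g: list[Tensor], context_c: Tensor) -> tuple[Tensor, Tensor]:
    """Context-attention over layer summaries; returns (z, ψ).

    score_l = c·g^l / √d', ψ = softmax(score), z = Σ_l ψ_l g^l.
    """
    if not per_layer_g:
        raise ValueError("readout requires at least one layer summary")
    d = context_c.shape[0]
    scores = concat([(context_c @ g).reshape(1) for g in per_layer_g]) * (1.0 / np.sqrt(d))
    psi = scores.softmax(axis=0)
    stacked = concat([g.reshape(1, d) for g in per_layer_g], axis=0)
    z = (psi.reshape(len(per_layer_g), 1) * stacked).sum(axis=0)
    return z, psi


def gatv2_attention(i: int, states: np.ndarray, A: np.ndarray, layer: GATv2Layer) -> np.ndarray:
    """Attention weights of node ``i`` over ``N_i ∪ {i}`` (dense row, zeros
    at non-neighbors)."""
    alpha = layer.attention(Tensor(np.asarray(states, dtype=np.float64)), A)
    return alpha.data[i]


class _MultiHead(Module):
    """Head-averaged wrapper so every variant keeps output dim = emb_dim."""

    def __init__(self, layer_cls, in_dim, out_dim, rng, heads, **kw):
        super().__init__()
        self.heads = [layer_cls(in_dim, out_dim, rng, **kw) for _ in range(heads)]

    def __call__(self, H, A):
        outs = [head(H, A) for head in self.heads]
        if len(outs) == 1:
            return outs[0]
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        return acc * (1.0 / len(outs))

    def attention(self, H, A):
        return self.heads[0].attention(H, A)


class DrugEncoder(Module):
    """Stacked graph layers + per-layer pooling + context-attention readout."""

    def __init__(self, config: GnnConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.emb_dim
        self.input_proj = Linear(NUM_ATOM_FEATURES, d, rng, bias=False)
        layer_cls = _LAYER_TYPES[config.gnn_type]
        kw = {"leaky_slope": config.leaky_slope, "elu_alpha": config.elu_alpha}
        if config.gnn_type == "gcn":
            kw = {"elu_alpha": config.elu_alpha}
        self.layers = [
            _MultiHead(layer_cls, d, d, rng, config.heads, **kw)
            for _ in range(config.num_layer)
        ]
        bound = np.sqrt(1.0 / d)
        self.context_c = Tensor(rng.uniform(-bound, bound, size=d), requires_grad=True)

    def node_states(self, graph: DrugGraph) -> list[Tensor]:
        """States after the input projection and after each layer."""
        H = self.input_proj(Tensor(graph.features_M))
        states = [H]
        for layer in self.layers:
            H = layer(H, graph.adjacency_A)
            states.append(H)
        return states

    def __call__(self, graph: DrugGraph) -> Tensor:
        states = self.node_states(graph)
        per_layer_g = [layer_pool(H) for H in states[1:]]  # l = 1..L only
        z, _ = hierarchical_readout(per_layer_g, self.context_c)
        return z

    def layer_weights(self, graph: DrugGraph) -> np.ndarray:
        """The readout's ψ for one graph (diagnostic)."""
        states = self.node_states(graph)
        per_layer_g = [layer_pool(H) for H in states[1:]]
        _, psi = hierarchical_readout(per_layer_g, self.context_c)
        return psi.data


def encode_drug(graph: DrugGraph, model: DrugEncoder) -> np.ndarray:
    """Fixed-length embedding of one molecule under the current parameters."""
    return model(graph).data
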