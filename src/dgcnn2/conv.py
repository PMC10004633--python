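"""Non-local message-passing (NLMP) graph convolution layer.

One layer maps node features ``Z_t`` (n x c_in) to ``Z_{t+1}`` in four steps:

1. *Attention aggregation.*  Pairwise attention logits over each node's
   neighbourhood (plus itself) are scored GAT-style,
   ``e_ij = LeakyReLU(a^T [Wg z_i || Wg z_j])``, and softmax-normalised per
   row into a row-stochastic attention adjacency ``A``.
2. *Non-local mixing.*  ``Y = alpha * A Z_t + beta * Z_prev + gamma * X0``
   blends the aggregated features with the previous layer's output (dense
   connection) and the stage's initial features (residual connection);
   ``alpha = 1 - beta - gamma``.
3. *Identity-mapped transform.*  ``Y ((1-delta) I + delta W)`` with the
   layer-decaying weight ``delta_l = ln(lambda/l + 1)``, so deep layers stay
   close to a pass-through.  When the layer changes width the identity term
   is undefined and the pure transform ``Y W`` is used.
4. *Nonlinearity* (ReLU by default).

The residual/initial terms and decaying transform are what let 16-layer
stages train without the node representations collapsing (over-smoothing).

Besides the public forward operations this module carries the matching
backward passes (hand-derived, finite-difference-checked in the test suite)
used by the trainer; everything is dense NumPy, adequate for the benchmark
graph sizes (tens to a few hundred nodes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .graph_io import GraphInputError, LabeledGraph

__all__ = [
    "MixingCoefficients",
    "ConvLayerParams",
    "delta_schedule",
    "attention_adjacency",
    "identity_mapped_transform",
    "nlmp_layer_forward",
]

_NEG_INF = -1e30


@dataclass(frozen=True)
class MixingCoefficients:
    """Aggregation proportions: attention term alpha, previous-layer beta, initial gamma."""

    beta: float = 0.1
    gamma: float = 0.1

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta - self.gamma

    def __post_init__(self):
        if self.beta < 0 or self.gamma < 0 or self.beta + self.gamma > 1:
            raise GraphInputError("need beta, gamma >= 0 with beta + gamma <= 1")


@dataclass
class ConvLayerParams:
    """Weights of one layer: transform W, attention projection W_gat, scorer a_vec."""

    W: np.ndarray          # c_in x c_out
    W_gat: np.ndarray      # c_in x c_att
    a_vec: np.ndarray      # 2 * c_att
    delta: float
    leaky_slope: float = 0.2
    #: freeze attention to the uniform (degree-normalised) scheme; with this on,
    #: the aggregation step is exactly D^{-1} (A + I) Z — the plain-GCN ablation.
    uniform: bool = False

    def __post_init__(self):
        if not (0.0 <= self.delta <= 1.0):
            raise GraphInputError(f"delta={self.delta} outside [0,1]")
        if self.leaky_slope <= 0:
            raise GraphInputError("leaky_slope must be positive")
        if self.W.shape[0] != self.W_gat.shape[0]:
            raise GraphInputError("W and W_gat disagree on input channels")
        if self.a_vec.shape != (2 * self.W_gat.shape[1],):
            raise GraphInputError("a_vec must have length 2 * c_att")


def delta_schedule(lambda_: float, layer_index: int) -> float:
    """Identity-mapping decay ``ln(lambda/l + 1)``; decreasing in depth ``l`` (1-based)."""
    if layer_index < 1:
        raise GraphInputError("layer_index is 1-based and must be >= 1")
    if lambda_ < 0:
        raise GraphInputError("lambda must be nonnegative")
    return math.log(lambda_ / layer_index + 1.0)


def _support_mask(graph: LabeledGraph, include_self: bool = True) -> np.ndarray:
    s = graph.adjacency() > 0
    if include_self:
        np.fill_diagonal(s, True)
    return s


def _attention_forward(Z, graph, params, include_self=True):
    """Returns (A, cache) where cache holds what the backward pass needs."""
    n = graph.node_count
    if Z.shape[0] != n:
        raise GraphInputError(f"Z has {Z.shape[0]} rows for {n} nodes")
    if Z.shape[1] != params.W_gat.shape[0]:
        raise GraphInputError(
            f"Z has {Z.shape[1]} channels, W_gat expects {params.W_gat.shape[0]}"
        )
    c_att = params.W_gat.shape[1]
    support = _support_mask(graph, include_self)

    if params.uniform:
        denom = support.sum(axis=1, keepdims=True).astype(float)
        A = np.divide(support.astype(float), denom,
                      out=np.zeros((n, n)), where=denom > 0)
        return A, {"A": A, "Z": Z, "uniform": True}

    U = Z @ params.W_gat                       # n x c_att
    sl = U @ params.a_vec[:c_att]              # source score
    sr = U @ params.a_vec[c_att:]              # target score
    pre = sl[:, None] + sr[None, :]            # raw logits, n x n
    logits = np.where(pre > 0, pre, params.leaky_slope * pre)
    logits = np.where(support, logits, _NEG_INF)

    row_max = logits.max(axis=1, keepdims=True)
    has_support = support.any(axis=1)
    row_max = np.where(has_support[:, None], row_max, 0.0)
    ex = np.exp(logits - row_max) * support
    denom = ex.sum(axis=1, keepdims=True)
    A = np.divide(ex, denom, out=np.zeros_like(ex), where=denom > 0)
    cache = {"U": U, "pre": pre, "support": support, "A": A, "Z": Z}
    return A, cache


def attention_adjacency(Z: np.ndarray, graph: LabeledGraph,
                        params: ConvLayerParams,
                        include_self: bool = True) -> np.ndarray:
    """Row-stochastic attention adjacency; entry (i,j) nonzero only for j in N(i) u {i}."""
    A, _ = _attention_forward(np.asarray(Z, dtype=float), graph, params, include_self)
    return A


def _attention_backward(dA, cache, params):
    """Gradients of sum(dA * A) w.r.t. Z, W_gat, a_vec."""
    if cache.get("uniform"):
        # A is a constant of the graph: nothing flows back through attention.
        return (np.zeros_like(cache["Z"]), np.zeros_like(params.W_gat),
                np.zeros_like(params.a_vec))
    A, U, pre, Z = cache["A"], cache["U"], cache["pre"], cache["Z"]
    c_att = params.W_gat.shape[1]
    # softmax rows: dlogits = A * (dA - sum_k A_ik dA_ik)
    g = A * (dA - np.sum(A * dA, axis=1, keepdims=True))
    g = g * np.where(pre > 0, 1.0, params.leaky_slope)   # LeakyReLU on logits
    r = g.sum(axis=1)   # d(sl)
    c = g.sum(axis=0)   # d(sr)
    da = np.concatenate([U.T @ r, U.T @ c])
    dU = np.outer(r, params.a_vec[:c_att]) + np.outer(c, params.a_vec[c_att:])
    dWg = Z.T @ dU
    dZ = dU @ params.W_gat.T
    return dZ, dWg, da


def identity_mapped_transform(M: np.ndarray, W: np.ndarray,
                              delta: float) -> np.ndarray:
    """``M ((1-delta) I + delta W)`` for square W; plain ``M W`` when W changes width."""
    M = np.asarray(M, dtype=float)
    W = np.asarray(W, dtype=float)
    if M.shape[1] != W.shape[0]:
        raise GraphInputError(
            f"inner dimensions disagree: M is {M.shape}, W is {W.shape}"
        )
    if W.shape[0] == W.shape[1]:
        return (1.0 - delta) * M + delta * (M @ W)
    return M @ W


_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
}


def _get_activation(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise GraphInputError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


def _layer_forward(Z_t, Z_prev, X0, graph, params, mix, activation="relu",
                   include_self=True):
    Z_t = np.asarray(Z_t, dtype=float)
    Z_prev = np.asarray(Z_prev, dtype=float)
    X0 = np.asarray(X0, dtype=float)
    if not (Z_t.shape == Z_prev.shape == X0.shape):
        raise GraphInputError(
            f"Z_t {Z_t.shape}, Z_prev {Z_prev.shape} and X0 {X0.shape} must agree"
        )
    act, _ = _get_activation(activation)
    A, att_cache = _attention_forward(Z_t, graph, params, include_self)
    Y = mix.alpha * (A @ Z_t) + mix.beta * Z_prev + mix.gamma * X0
    T = identity_mapped_transform(Y, params.W, params.delta)
    Z_next = act(T)
    cache = {"att": att_cache, "Y": Y, "T": T, "activation": activation,
             "mix": mix, "params": params}
    return Z_next, cache


def nlmp_layer_forward(Z_t, Z_prev, X0, graph: LabeledGraph,
                       params: ConvLayerParams, mix: MixingCoefficients,
                       activation: str = "relu",
                       include_self: bool = True) -> np.ndarray:
    """One NLMP layer: ``sigma((alpha A Z_t + beta Z_prev + gamma X0)((1-d)I + dW))``."""
    Z_next, _ = _layer_forward(Z_t, Z_prev, X0, graph, params, mix,
                               activation, include_self)
    return Z_next


def _layer_backward(dZ_next, cache):
    """Backward through one layer.

    Returns ``(dZ_t, dZ_prev, dX0, dW, dW_gat, da_vec)`` for the upstream
    gradient ``dZ_next`` on the layer output.
    """
    params, mix = cache["params"], cache["mix"]
    _, dact = _get_activation(cache["activation"])
    Y, T = cache["Y"], cache["T"]
    A, Z_t = cache["att"]["A"], cache["att"]["Z"]

    dT = dZ_next * dact(T)
    W = params.W
    if W.shape[0] == W.shape[1]:
        dW = params.delta * (Y.T @ dT)
        dY = (1.0 - params.delta) * dT + params.delta * (dT @ W.T)
    else:
        dW = Y.T @ dT
        dY = dT @ W.T

    dZ_prev = mix.beta * dY
    dX0 = mix.gamma * dY
    dZ_t = mix.alpha * (A.T @ dY)
    dA = mix.alpha * (dY @ Z_t.T)
    dZ_att, dWg, da = _attention_backward(dA, cache["att"], params)
    return dZ_t + dZ_att, dZ_prev, dX0, dW, dWg, da
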