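"""DGCNNII model assembly: projection, two NLMP stages, SortPooling, readout.

The classification architecture, end to end:

1. one-hot node labels -> linear *input projection* to the hidden width;
2. *stage 1*: a stack of NLMP conv layers (default 16; 128 hidden channels,
   dataset-dependent final width) with ``Z^(0) = Z^(1)`` equal to the
   projected input, which also serves as the residual ``X`` of every layer;
3. *inter-stage bridge*: the stage-1 output is concatenated with the raw
   one-hot features (re-injecting the un-smoothed input) and linearly
   projected back to the hidden width;
4. *stage 2*: a second stack (default 16 layers), whose last layer has a
   single output channel used as the node sort key;
5. *multiscale concatenation*: the per-layer outputs ``Z^(1..K)`` are joined
   column-wise into one "multi-scale feature vector" per node
   (15*128 + 1 = 1921 columns under the defaults);
6. *SortPooling*: rows sorted descending by the last column, ties broken by
   earlier columns (right to left), truncated/zero-padded to ``k`` rows;
7. *readout*: flatten, a 1-D conv whose kernel and stride equal the node
   feature width (one position per pooled node), max-pool 2, a second 1-D
   conv (kernel 5), a dense ReLU layer, dropout, and a softmax classifier.

Everything is NumPy; the module also houses the cached forward / backward
pass used by the trainer and the per-layer feature taps used by the
smoothness diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .conv import (ConvLayerParams, MixingCoefficients, _layer_backward,
                   _layer_forward, delta_schedule, nlmp_layer_forward)
from .graph_io import GraphInputError, LabeledGraph, one_hot_features

__all__ = [
    "ConfigurationError",
    "ReadoutConfig",
    "StageConfig",
    "ModelConfig",
    "make_model_config",
    "ablation_variants",
    "init_params",
    "input_projection",
    "stage_forward",
    "interstage_bridge",
    "multiscale_concat",
    "sort_pooling",
    "readout_forward",
    "model_forward",
    "conv_tower_taps",
    "resolve_sortpool_k",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA_VERSION = 1


class ConfigurationError(ValueError):
    """Inconsistent model configuration detected at build time."""


@dataclass(frozen=True)
class ReadoutConfig:
    """DGCNN-style 1-D convolution readout head."""

    conv1_channels: int = 16
    pool_size: int = 2
    conv2_kernel: int = 5
    conv2_channels: int = 32
    dense_units: int = 128


@dataclass(frozen=True)
class StageConfig:
    """One stack of NLMP conv layers.

    Layers ``1..depth-1`` output ``hidden_channels``; layer ``depth`` outputs
    ``out_channels``.  ``delta_override`` pins the identity-mapping weight
    instead of the ``ln(lambda/l + 1)`` schedule (``delta_override=1`` plus
    ``uniform_attention`` and ``mix=(beta=0, gamma=0)`` is the plain-GCN
    ablation).  The schedule restarts at ``l = 1`` in each stage.
    """

    depth: int
    hidden_channels: int = 128
    out_channels: int = 128
    mix: MixingCoefficients = field(default_factory=MixingCoefficients)
    lambda_: float = 0.5
    activation: str = "relu"
    uniform_attention: bool = False
    delta_override: Optional[float] = None

    def channel_plan(self):
        """(c_in, c_out) per layer."""
        plan = []
        for t in range(1, self.depth + 1):
            c_out = self.out_channels if t == self.depth else self.hidden_channels
            plan.append((self.hidden_channels, c_out))
        return plan

    def delta(self, layer_index: int) -> float:
        if self.delta_override is not None:
            return self.delta_override
        return delta_schedule(self.lambda_, layer_index)


@dataclass(frozen=True)
class ModelConfig:
    """Full architecture; ``sortpool_k=None`` means "resolve from the training set"."""

    stage1: StageConfig
    stage2: StageConfig
    n_classes: int
    sortpool_k: Optional[int] = None
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    dropout_rate: float = 0.5
    concat_scope: str = "stage2_only"   # or "both_stages"
    include_self_attention: bool = True
    leaky_slope: float = 0.2
    conv1_kernel: Optional[int] = None  # None -> kernel = stride = feature width

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.concat_scope not in ("stage2_only", "both_stages"):
            raise ConfigurationError(f"unknown concat_scope {self.concat_scope!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must lie in [0,1)")
        if self.stage2.depth > 0:
            if self.stage2.out_channels != 1:
                raise ConfigurationError(
                    "the final stage must end in a single sort-key channel"
                )
        else:
            if self.stage1.out_channels != 1:
                raise ConfigurationError(
                    "single-stage models need stage1.out_channels == 1 (sort key)"
                )
        if self.stage1.depth < 1:
            raise ConfigurationError("stage 1 needs at least one layer")

    @property
    def single_stage(self) -> bool:
        return self.stage2.depth == 0

    def concat_channels(self) -> int:
        """Total width of the multi-scale feature vector."""
        s1 = sum(c for _, c in self.stage1.channel_plan())
        if self.single_stage:
            return s1
        s2 = sum(c for _, c in self.stage2.channel_plan())
        return s1 + s2 if self.concat_scope == "both_stages" else s2


def make_model_config(n_classes: int, stage1_depth: int = 16,
                      stage2_depth: int = 16, hidden_channels: int = 128,
                      stage1_out_channels: Optional[int] = None,
                      beta: float = 0.1, gamma: float = 0.1,
                      lambda_: float = 0.5, sortpool_k: Optional[int] = None,
                      **kwargs) -> ModelConfig:
    """Convenience constructor mirroring the published default architecture."""
    mix = MixingCoefficients(beta=beta, gamma=gamma)
    if stage1_out_channels is None:
        stage1_out_channels = 1 if stage2_depth == 0 else hidden_channels
    stage1 = StageConfig(depth=stage1_depth, hidden_channels=hidden_channels,
                         out_channels=stage1_out_channels, mix=mix, lambda_=lambda_)
    stage2 = StageConfig(depth=stage2_depth, hidden_channels=hidden_channels,
                         out_channels=1, mix=mix, lambda_=lambda_)
    return ModelConfig(stage1=stage1, stage2=stage2, n_classes=n_classes,
                       sortpool_k=sortpool_k, **kwargs)


def ablation_variants(n_classes: int, stage1_depth: int = 16,
                      hidden_channels: int = 128,
                      stage1_out_channels: int = 32,
                      sortpool_k: Optional[int] = None) -> dict:
    """The published ablation grid: first stage only, single deep stage, and
    a first stage plus second stages of depth 2/6/10/14/16."""
    variants = {
        "first_stage_only": make_model_config(
            n_classes, stage1_depth=stage1_depth, stage2_depth=0,
            hidden_channels=hidden_channels, sortpool_k=sortpool_k),
        "single_stage_32": make_model_config(
            n_classes, stage1_depth=2 * stage1_depth, stage2_depth=0,
            hidden_channels=hidden_channels, sortpool_k=sortpool_k),
    }
    for d2 in (2, 6, 10, 14, 16):
        variants[f"two_stage_{stage1_depth}+{d2}"] = make_model_config(
            n_classes, stage1_depth=stage1_depth, stage2_depth=d2,
            hidden_channels=hidden_channels,
            stage1_out_channels=stage1_out_channels, sortpool_k=sortpool_k)
    return variants


def resolve_sortpool_k(config: ModelConfig, graph_sizes) -> ModelConfig:
    """Fill in ``sortpool_k`` with the smallest k such that at least 60% of the
    training graphs have >= k nodes, floored so the readout convolutions fit."""
    if config.sortpool_k is not None:
        return config
    sizes = np.sort(np.asarray(list(graph_sizes)))
    # largest k with >= 60% of graphs of size >= k: the 40th-percentile size.
    k = int(sizes[min(len(sizes) - 1, int(np.floor(0.4 * len(sizes))))])
    k = max(k, config.readout.pool_size * config.readout.conv2_kernel)
    return replace(config, sortpool_k=k)


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------

def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _readout_lengths(config: ModelConfig):
    """Sequence lengths through the readout; validates divisibility constraints."""
    k = config.sortpool_k
    if k is None or k < 1:
        raise ConfigurationError("sortpool_k must be resolved to a positive integer")
    c_total = config.concat_channels()
    kernel = config.conv1_kernel or c_total
    if (k * c_total) % kernel != 0:
        raise ConfigurationError(
            f"flattened width {k * c_total} is not divisible into conv1 "
            f"positions of kernel/stride {kernel}"
        )
    l1 = (k * c_total) // kernel
    l2 = l1 // config.readout.pool_size
    if l2 < config.readout.conv2_kernel:
        raise ConfigurationError(
            f"after pooling only {l2} positions remain, fewer than the "
            f"second conv kernel {config.readout.conv2_kernel}; increase sortpool_k"
        )
    l3 = l2 - config.readout.conv2_kernel + 1
    return c_total, kernel, l1, l2, l3


def init_params(config: ModelConfig, alphabet_size: int,
                rng: np.random.Generator, a_init: str = "zeros") -> dict:
    """Glorot-uniform weights, zero biases; the attention scorer ``a_vec`` is
    zero by default (uniform attention at initialisation) or Glorot when
    ``a_init='glorot'``."""
    if a_init not in ("zeros", "glorot"):
        raise ConfigurationError(f"unknown a_init {a_init!r}")
    params = {}
    h1 = config.stage1.hidden_channels
    params["proj_w"] = _glorot(rng, (alphabet_size, h1), alphabet_size, h1)
    params["proj_b"] = np.zeros(h1)

    def stage_params(prefix, stage):
        for t, (c_in, c_out) in enumerate(stage.channel_plan(), start=1):
            params[f"{prefix}_{t}_w"] = _glorot(rng, (c_in, c_out), c_in, c_out)
            params[f"{prefix}_{t}_wg"] = _glorot(rng, (c_in, c_in), c_in, c_in)
            if a_init == "glorot":
                params[f"{prefix}_{t}_a"] = _glorot(rng, (2 * c_in,), 2 * c_in, 1)
            else:
                params[f"{prefix}_{t}_a"] = np.zeros(2 * c_in)

    stage_params("s1", config.stage1)
    if not config.single_stage:
        h2 = config.stage2.hidden_channels
        c_bridge = config.stage1.out_channels + alphabet_size
        params["bridge_w"] = _glorot(rng, (c_bridge, h2), c_bridge, h2)
        params["bridge_b"] = np.zeros(h2)
        stage_params("s2", config.stage2)

    c_total, kernel, l1, l2, l3 = _readout_lengths(config)
    ro = config.readout
    params["conv1_w"] = _glorot(rng, (kernel, ro.conv1_channels),
                                kernel, ro.conv1_channels)
    params["conv1_b"] = np.zeros(ro.conv1_channels)
    fan2 = ro.conv2_kernel * ro.conv1_channels
    params["conv2_w"] = _glorot(rng, (ro.conv2_kernel, ro.conv1_channels,
                                      ro.conv2_channels), fan2, ro.conv2_channels)
    params["conv2_b"] = np.zeros(ro.conv2_channels)
    flat3 = l3 * ro.conv2_channels
    params["dense_w"] = _glorot(rng, (flat3, ro.dense_units), flat3, ro.dense_units)
    params["dense_b"] = np.zeros(ro.dense_units)
    params["out_w"] = _glorot(rng, (ro.dense_units, config.n_classes),
                              ro.dense_units, config.n_classes)
    params["out_b"] = np.zeros(config.n_classes)
    return params


def _stage_layer_params(params: dict, prefix: str, stage: StageConfig,
                        leaky_slope: float) -> list:
    out = []
    for t in range(1, stage.depth + 1):
        out.append(ConvLayerParams(
            W=params[f"{prefix}_{t}_w"],
            W_gat=params[f"{prefix}_{t}_wg"],
            a_vec=params[f"{prefix}_{t}_a"],
            delta=stage.delta(t),
            leaky_slope=leaky_slope,
            uniform=stage.uniform_attention,
        ))
    return out


# ---------------------------------------------------------------------------
# forward building blocks (public operations)
# ---------------------------------------------------------------------------

def input_projection(X_onehot: np.ndarray, W_in: np.ndarray,
                     bias: Optional[np.ndarray] = None) -> np.ndarray:
    """Row-wise linear map of the one-hot features into the hidden width."""
    X_onehot = np.asarray(X_onehot, dtype=float)
    if X_onehot.shape[1] != W_in.shape[0]:
        raise GraphInputError(
            f"features have {X_onehot.shape[1]} columns, W_in expects {W_in.shape[0]}"
        )
    out = X_onehot @ W_in
    if bias is not None:
        out = out + bias
    return out


def stage_forward(X_in: np.ndarray, graph: LabeledGraph, stage: StageConfig,
                  layer_params: list, include_self: bool = True):
    """Run a stage with ``Z^(0) = Z^(1) = X_in``; returns (final, all outputs)."""
    if len(layer_params) != stage.depth:
        raise GraphInputError(
            f"stage of depth {stage.depth} got {len(layer_params)} parameter sets"
        )
    outs, _ = _stage_forward_cache(X_in, graph, stage, layer_params, include_self)
    return outs[-1], outs


def _stage_forward_cache(X_in, graph, stage, layer_params, include_self):
    outs, caches = [], []
    for i, lp in enumerate(layer_params):
        z_t = outs[i - 1] if i >= 1 else X_in
        z_prev = outs[i - 2] if i >= 2 else X_in
        try:
            z_next, cache = _layer_forward(z_t, z_prev, X_in, graph, lp,
                                           stage.mix, stage.activation,
                                           include_self)
        except Exception as exc:
            raise type(exc)(f"layer {i + 1}: {exc}") from exc
        outs.append(z_next)
        caches.append(cache)
    return outs, caches


def _stage_backward(X_in, caches, tap_grads, extra_final_grad=None):
    """Backpropagate a stage.  ``tap_grads`` has one gradient (or None) per
    layer output; returns (dX_in, {layer index (1-based): param grads})."""
    depth = len(caches)
    g = [np.array(t, copy=True) if t is not None else None for t in tap_grads]
    if extra_final_grad is not None:
        g[-1] = extra_final_grad if g[-1] is None else g[-1] + extra_final_grad
    dX_in = np.zeros_like(X_in)
    layer_grads = {}
    for i in reversed(range(depth)):
        if g[i] is None:
            g[i] = np.zeros_like(caches[i]["T"])
        dZt, dZp, dX0, dW, dWg, da = _layer_backward(g[i], caches[i])
        layer_grads[i + 1] = (dW, dWg, da)
        if i - 1 >= 0:
            g[i - 1] = dZt if g[i - 1] is None else g[i - 1] + dZt
        else:
            dX_in += dZt
        if i - 2 >= 0:
            g[i - 2] = dZp if g[i - 2] is None else g[i - 2] + dZp
        else:
            dX_in += dZp
        dX_in += dX0
    return dX_in, layer_grads


def interstage_bridge(Z_stage1_final: np.ndarray, X_onehot: np.ndarray,
                      W_bridge: np.ndarray,
                      bias: Optional[np.ndarray] = None) -> np.ndarray:
    """Concatenate [stage-1 output || one-hot input] and project to the hidden width."""
    Z_stage1_final = np.asarray(Z_stage1_final, dtype=float)
    X_onehot = np.asarray(X_onehot, dtype=float)
    if Z_stage1_final.shape[0] != X_onehot.shape[0]:
        raise GraphInputError("row counts of stage-1 output and one-hot input differ")
    cat = np.hstack([Z_stage1_final, X_onehot])
    if cat.shape[1] != W_bridge.shape[0]:
        raise GraphInputError(
            f"bridge input has {cat.shape[1]} columns, W_bridge expects "
            f"{W_bridge.shape[0]}"
        )
    out = cat @ W_bridge
    if bias is not None:
        out = out + bias
    return out


def multiscale_concat(Z_list) -> np.ndarray:
    """Column-wise concatenation of per-layer outputs, in layer order."""
    if not Z_list:
        raise GraphInputError("empty layer-output list")
    rows = {z.shape[0] for z in Z_list}
    if len(rows) != 1:
        raise GraphInputError(f"row counts differ across layers: {sorted(rows)}")
    return np.hstack(Z_list)


def _sort_order(Z: np.ndarray) -> np.ndarray:
    """Node order for SortPooling: descending on the last column, ties broken
    by earlier columns right-to-left, final ties by ascending node index."""
    n, c = Z.shape
    keys = [np.arange(n)] + [-Z[:, col] for col in range(c)]
    return np.lexsort(keys)


def sort_pooling(Z_cat: np.ndarray, k: int) -> np.ndarray:
    """Sort rows (see :func:`_sort_order`), keep the first ``k``; zero-pad if short."""
    Z_cat = np.asarray(Z_cat, dtype=float)
    if Z_cat.ndim != 2 or Z_cat.shape[0] == 0:
        raise GraphInputError("sort_pooling needs a nonempty 2-D matrix")
    if k < 1:
        raise GraphInputError("k must be at least 1")
    order = _sort_order(Z_cat)
    n, c = Z_cat.shape
    pooled = np.zeros((k, c))
    kept = min(n, k)
    pooled[:kept] = Z_cat[order[:kept]]
    return pooled


# ---------------------------------------------------------------------------
# readout head
# ---------------------------------------------------------------------------

def _softmax(x):
    e = np.exp(x - x.max())
    return e / e.sum()


def _readout_forward_cache(pooled, config: ModelConfig, params, train_mode,
                           dropout_rng):
    ro = config.readout
    c_total, kernel, l1, l2, l3 = _readout_lengths(config)
    if pooled.shape != (config.sortpool_k, c_total):
        raise GraphInputError(
            f"pooled matrix is {pooled.shape}, expected "
            f"({config.sortpool_k}, {c_total})"
        )
    flat = pooled.reshape(-1)
    F = flat.reshape(l1, kernel)
    S1 = F @ params["conv1_w"] + params["conv1_b"]
    R1 = np.maximum(S1, 0.0)

    P = R1[: l2 * ro.pool_size].reshape(l2, ro.pool_size, ro.conv1_channels)
    pool_idx = P.argmax(axis=1)
    M1 = np.take_along_axis(P, pool_idx[:, None, :], axis=1)[:, 0, :]

    X3 = np.stack([M1[p: p + ro.conv2_kernel].reshape(-1) for p in range(l3)])
    W2r = params["conv2_w"].reshape(-1, ro.conv2_channels)
    S3 = X3 @ W2r + params["conv2_b"]
    R3 = np.maximum(S3, 0.0)

    f3 = R3.reshape(-1)
    S4 = f3 @ params["dense_w"] + params["dense_b"]
    R4 = np.maximum(S4, 0.0)
    if train_mode and config.dropout_rate > 0.0:
        if dropout_rng is None:
            raise GraphInputError("train_mode dropout needs a random generator")
        mask = (dropout_rng.random(R4.shape) >= config.dropout_rate) / (
            1.0 - config.dropout_rate)
    else:
        mask = np.ones_like(R4)
    D4 = R4 * mask
    logits = D4 @ params["out_w"] + params["out_b"]
    probs = _softmax(logits)
    cache = {"F": F, "S1": S1, "pool_idx": pool_idx, "M1": M1, "X3": X3,
             "S3": S3, "f3": f3, "S4": S4, "mask": mask, "D4": D4,
             "lengths": (c_total, kernel, l1, l2, l3)}
    return probs, cache


def _readout_backward(dlogits, cache, config, params):
    ro = config.readout
    c_total, kernel, l1, l2, l3 = cache["lengths"]
    grads = {}
    grads["out_w"] = np.outer(cache["D4"], dlogits)
    grads["out_b"] = dlogits.copy()
    dD4 = params["out_w"] @ dlogits
    dS4 = dD4 * cache["mask"] * (cache["S4"] > 0)
    grads["dense_w"] = np.outer(cache["f3"], dS4)
    grads["dense_b"] = dS4
    df3 = params["dense_w"] @ dS4

    dR3 = df3.reshape(l3, ro.conv2_channels)
    dS3 = dR3 * (cache["S3"] > 0)
    W2r = params["conv2_w"].reshape(-1, ro.conv2_channels)
    grads["conv2_w"] = (cache["X3"].T @ dS3).reshape(params["conv2_w"].shape)
    grads["conv2_b"] = dS3.sum(axis=0)
    dX3 = dS3 @ W2r.T
    dM1 = np.zeros_like(cache["M1"])
    for p in range(l3):
        dM1[p: p + ro.conv2_kernel] += dX3[p].reshape(ro.conv2_kernel,
                                                      ro.conv1_channels)

    dP = np.zeros((l2, ro.pool_size, ro.conv1_channels))
    np.put_along_axis(dP, cache["pool_idx"][:, None, :], dM1[:, None, :], axis=1)
    dR1 = np.zeros((l1, ro.conv1_channels))
    dR1[: l2 * ro.pool_size] = dP.reshape(l2 * ro.pool_size, ro.conv1_channels)
    dS1 = dR1 * (cache["S1"] > 0)
    grads["conv1_w"] = cache["F"].T @ dS1
    grads["conv1_b"] = dS1.sum(axis=0)
    dF = dS1 @ params["conv1_w"].T
    dpooled = dF.reshape(config.sortpool_k, c_total)
    return dpooled, grads


def readout_forward(pooled: np.ndarray, config: ModelConfig, params: dict,
                    train_mode: bool = False,
                    dropout_rng: Optional[np.random.Generator] = None
                    ) -> np.ndarray:
    """Class-probability vector from the pooled node-feature matrix."""
    probs, _ = _readout_forward_cache(np.asarray(pooled, dtype=float), config,
                                      params, train_mode, dropout_rng)
    return probs


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def _model_forward_cache(graph, config, params, train_mode=False,
                         dropout_rng=None):
    alphabet_size = params["proj_w"].shape[0]
    X_oh = one_hot_features(graph, alphabet_size)
    X1 = input_projection(X_oh, params["proj_w"], params["proj_b"])
    lp1 = _stage_layer_params(params, "s1", config.stage1, config.leaky_slope)
    outs1, caches1 = _stage_forward_cache(X1, graph, config.stage1, lp1,
                                          config.include_self_attention)
    cache = {"X_oh": X_oh, "X1": X1, "outs1": outs1, "caches1": caches1}

    if config.single_stage:
        concat_list = outs1
    else:
        B = interstage_bridge(outs1[-1], X_oh, params["bridge_w"],
                              params["bridge_b"])
        lp2 = _stage_layer_params(params, "s2", config.stage2,
                                  config.leaky_slope)
        outs2, caches2 = _stage_forward_cache(B, graph, config.stage2, lp2,
                                              config.include_self_attention)
        cache.update({"B": B, "outs2": outs2, "caches2": caches2})
        if config.concat_scope == "both_stages":
            concat_list = outs1 + outs2
        else:
            concat_list = outs2

    Z_cat = multiscale_concat(concat_list)
    order = _sort_order(Z_cat)
    k = config.sortpool_k
    kept = min(Z_cat.shape[0], k)
    pooled = np.zeros((k, Z_cat.shape[1]))
    pooled[:kept] = Z_cat[order[:kept]]
    probs, r_cache = _readout_forward_cache(pooled, config, params,
                                            train_mode, dropout_rng)
    cache.update({"concat_widths": [z.shape[1] for z in concat_list],
                  "order": order, "kept": kept, "readout": r_cache})
    return probs, cache


def _model_backward(dlogits, cache, config, params):
    grads = {}
    dpooled, r_grads = _readout_backward(dlogits, cache["readout"], config,
                                         params)
    grads.update(r_grads)

    n = cache["X_oh"].shape[0]
    c_total = dpooled.shape[1]
    dZ_cat = np.zeros((n, c_total))
    kept, order = cache["kept"], cache["order"]
    dZ_cat[order[:kept]] = dpooled[:kept]

    splits = np.cumsum(cache["concat_widths"])[:-1]
    tap_grads = np.split(dZ_cat, splits, axis=1)

    def store_stage(prefix, layer_grads):
        for t, (dW, dWg, da) in layer_grads.items():
            grads[f"{prefix}_{t}_w"] = dW
            grads[f"{prefix}_{t}_wg"] = dWg
            grads[f"{prefix}_{t}_a"] = da

    if config.single_stage:
        dX1, lg1 = _stage_backward(cache["X1"], cache["caches1"], tap_grads)
        store_stage("s1", lg1)
    else:
        d1 = len(cache["outs1"])
        if config.concat_scope == "both_stages":
            taps1, taps2 = tap_grads[:d1], tap_grads[d1:]
        else:
            taps1 = [None] * d1
            taps2 = tap_grads
        dB, lg2 = _stage_backward(cache["B"], cache["caches2"], taps2)
        store_stage("s2", lg2)
        cat = np.hstack([cache["outs1"][-1], cache["X_oh"]])
        grads["bridge_w"] = cat.T @ dB
        grads["bridge_b"] = dB.sum(axis=0)
        dcat = dB @ params["bridge_w"].T
        dZ1f = dcat[:, : cache["outs1"][-1].shape[1]]
        dX1, lg1 = _stage_backward(cache["X1"], cache["caches1"], taps1,
                                   extra_final_grad=dZ1f)
        store_stage("s1", lg1)

    grads["proj_w"] = cache["X_oh"].T @ dX1
    grads["proj_b"] = dX1.sum(axis=0)
    return grads


def model_forward(graph: LabeledGraph, config: ModelConfig, params: dict,
                  train_mode: bool = False,
                  dropout_rng: Optional[np.random.Generator] = None
                  ) -> np.ndarray:
    """End-to-end forward pass for one graph: class-probability vector."""
    probs, _ = _model_forward_cache(graph, config, params, train_mode,
                                    dropout_rng)
    return probs


def conv_tower_taps(graph: LabeledGraph, config: ModelConfig,
                    params: dict) -> dict:
    """Per-layer node representations of the convolutional tower, for the
    smoothness diagnostic: projection, every stage-1 layer, the bridge, every
    stage-2 layer — in forward order."""
    _, cache = _model_forward_cache(graph, config, params, train_mode=False)
    taps = {"proj": cache["X1"]}
    for t, z in enumerate(cache["outs1"], start=1):
        taps[f"s1_l{t}"] = z
    if not config.single_stage:
        taps["bridge"] = cache["B"]
        for t, z in enumerate(cache["outs2"], start=1):
            taps[f"s2_l{t}"] = z
    return taps


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _mix_to_dict(m: MixingCoefficients):
    return {"beta": m.beta, "gamma": m.gamma}


def _stage_to_dict(s: StageConfig):
    return {"depth": s.depth, "hidden_channels": s.hidden_channels,
            "out_channels": s.out_channels, "mix": _mix_to_dict(s.mix),
            "lambda_": s.lambda_, "activation": s.activation,
            "uniform_attention": s.uniform_attention,
            "delta_override": s.delta_override}


def config_to_dict(config: ModelConfig) -> dict:
    ro = config.readout
    return {
        "stage1": _stage_to_dict(config.stage1),
        "stage2": _stage_to_dict(config.stage2),
        "n_classes": config.n_classes,
        "sortpool_k": config.sortpool_k,
        "readout": {"conv1_channels": ro.conv1_channels,
                    "pool_size": ro.pool_size,
                    "conv2_kernel": ro.conv2_kernel,
                    "conv2_channels": ro.conv2_channels,
                    "dense_units": ro.dense_units},
        "dropout_rate": config.dropout_rate,
        "concat_scope": config.concat_scope,
        "include_self_attention": config.include_self_attention,
        "leaky_slope": config.leaky_slope,
        "conv1_kernel": config.conv1_kernel,
    }


def config_from_dict(d: dict) -> ModelConfig:
    def stage(sd):
        return StageConfig(depth=sd["depth"],
                           hidden_channels=sd["hidden_channels"],
                           out_channels=sd["out_channels"],
                           mix=MixingCoefficients(**sd["mix"]),
                           lambda_=sd["lambda_"],
                           activation=sd.get("activation", "relu"),
                           uniform_attention=sd.get("uniform_attention", False),
                           delta_override=sd.get("delta_override"))

    return ModelConfig(stage1=stage(d["stage1"]), stage2=stage(d["stage2"]),
                       n_classes=d["n_classes"], sortpool_k=d["sortpool_k"],
                       readout=ReadoutConfig(**d["readout"]),
                       dropout_rate=d.get("dropout_rate", 0.5),
                       concat_scope=d.get("concat_scope", "stage2_only"),
                       include_self_attention=d.get("include_self_attention",
                                                    True),
                       leaky_slope=d.get("leaky_slope", 0.2),
                       conv1_kernel=d.get("conv1_kernel"))


def save_checkpoint(path, params: dict, config: ModelConfig,
                    alphabet_size: int, seed: Optional[int] = None) -> None:
    meta = {"schema_version": CHECKPOINT_SCHEMA_VERSION,
            "config": config_to_dict(config),
            "alphabet_size": alphabet_size, "seed": seed}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(),
                                          dtype=np.uint8),
             **params)


def load_checkpoint(path):
    """Returns (params, config, meta dict)."""
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    params = {k: data[k] for k in data.files if k != "__meta__"}
    return params, config_from_dict(meta["config"]), meta
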