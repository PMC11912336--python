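"""Graph-attention network with a global multihead-attention readout.

Architecture: stacked graph-attention convolution layers (closed-neighborhood
attention with self-loops, each followed by a linear transform and batch
normalization), a scaled-dot-product global multihead attention block with a
residual connection, concatenated global max + mean pooling, and a two-layer
prediction head (regression output or classification logit).

All forward passes run through a single padded batched implementation;
evaluation-mode predictions use stored normalization statistics and are
therefore independent of batch composition.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .mol_graph import MoleculeGraph, NUM_NODE_FEATURES

__all__ = [
    "ModelConfig",
    "ModelState",
    "AttentionTrace",
    "init_model",
    "forward",
    "predict_batch",
    "predict_proba_batch",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = "toxgat-ckpt-1"
_NEG_INF = -1e9
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    n_conv_layers: int = 3
    embed_dim: int = 128
    n_global_heads: int = 4
    n_conv_heads: int = 1
    dropout_conv: float = 0.1
    dropout_attention: float = 0.2
    head_kind: str = "regression"  # or "binary-classification"
    n_node_features: int = NUM_NODE_FEATURES

    def validate(self) -> None:
        if self.embed_dim % self.n_global_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by "
                f"n_global_heads {self.n_global_heads}"
            )
        if self.n_conv_layers < 1 or self.n_conv_heads < 1:
            raise ValueError("layer and head counts must be >= 1")
        for rate in (self.dropout_conv, self.dropout_attention):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"dropout rate {rate} outside [0, 1)")
        if self.head_kind not in ("regression", "binary-classification"):
            raise ValueError(f"unknown head_kind {self.head_kind!r}")


@dataclass
class AttentionTrace:
    """Attention matrices captured during one forward pass.

    ``local[l]`` is the list of per-head m x m row-stochastic matrices of
    convolution layer ``l`` (support restricted to closed neighborhoods);
    ``global_heads`` holds the N m x m row-stochastic global attention
    matrices.
    """

    local: list[list[np.ndarray]] = field(default_factory=list)
    global_heads: list[np.ndarray] = field(default_factory=list)


class ModelState:
    """Learnable weights + batch-norm statistics + config + init seed."""

    def __init__(self, config: ModelConfig, params: dict[str, Tensor],
                 bn_stats: dict[str, np.ndarray], seed: int,
                 target_mean: float = 0.0, target_sd: float = 1.0):
        self.config = config
        self.params = params
        self.bn_stats = bn_stats
        self.seed = seed
        # regression target standardization used during pretraining; raw
        # model output is in standardized units (sign-preserving, sd > 0)
        self.target_mean = target_mean
        self.target_sd = target_sd

    def copy(self) -> "ModelState":
        params = {k: Tensor(v.data.copy(), requires_grad=True)
                  for k, v in self.params.items()}
        stats = {k: v.copy() for k, v in self.bn_stats.items()}
        return ModelState(copy.deepcopy(self.config), params, stats, self.seed,
                          self.target_mean, self.target_sd)

    def n_parameters(self) -> int:
        return sum(int(np.prod(v.data.shape)) for v in self.params.values())


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_model(config: ModelConfig, seed: int) -> ModelState:
    """Reproducibly initialize all weights from ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    H = config.embed_dim
    params: dict[str, Tensor] = {}
    bn_stats: dict[str, np.ndarray] = {}

    def add(name: str, arr: np.ndarray) -> None:
        params[name] = Tensor(arr, requires_grad=True)

    f_in = config.n_node_features
    for layer in range(config.n_conv_layers):
        for head in range(config.n_conv_heads):
            prefix = f"conv{layer}.h{head}"
            add(f"{prefix}.W", _glorot(rng, f_in, H, (f_in, H)))
            add(f"{prefix}.b", np.zeros(H))
            add(f"{prefix}.a_src", _glorot(rng, H, 1, (H, 1)))
            add(f"{prefix}.a_dst", _glorot(rng, H, 1, (H, 1)))
        add(f"conv{layer}.lin.W", _glorot(rng, H, H, (H, H)))
        add(f"conv{layer}.lin.b", np.zeros(H))
        add(f"conv{layer}.bn.gamma", np.ones(H))
        add(f"conv{layer}.bn.beta", np.zeros(H))
        bn_stats[f"conv{layer}.bn.mean"] = np.zeros(H)
        bn_stats[f"conv{layer}.bn.var"] = np.ones(H)
        f_in = H

    for name in ("Wq", "Wk", "Wv", "Wo"):
        add(f"glob.{name}", _glorot(rng, H, H, (H, H)))
        add(f"glob.b{name[1]}", np.zeros(H))

    head_names = head_param_names()
    add(head_names[0], _glorot(rng, 2 * H, H, (2 * H, H)))
    add(head_names[1], np.zeros(H))
    add(head_names[2], _glorot(rng, H, 1, (H, 1)))
    add(head_names[3], np.zeros(1))
    return ModelState(config, params, bn_stats, seed)


def head_param_names() -> list[str]:
    """Names of the two fully connected prediction-head layers."""
    return ["head.W1", "head.b1", "head.W2", "head.b2"]


def reinit_head(state: ModelState, seed: int) -> None:
    """Re-initialize the prediction head in place (used when fine-tuning)."""
    rng = np.random.default_rng(seed)
    H = state.config.embed_dim
    w1, b1, w2, b2 = head_param_names()
    state.params[w1] = Tensor(_glorot(rng, 2 * H, H, (2 * H, H)), requires_grad=True)
    state.params[b1] = Tensor(np.zeros(H), requires_grad=True)
    state.params[w2] = Tensor(_glorot(rng, H, 1, (H, 1)), requires_grad=True)
    state.params[b2] = Tensor(np.zeros(1), requires_grad=True)


# ---------------------------------------------------------------------------
# batched forward pass
# ---------------------------------------------------------------------------

def _pad_batch(graphs: list[MoleculeGraph], n_features: int):
    """Stack variable-size graphs into padded arrays with masks."""
    B = len(graphs)
    M = max(g.num_atoms for g in graphs)
    X = np.zeros((B, M, n_features))
    closed = np.zeros((B, M, M))  # adjacency + self-loops
    node_mask = np.zeros((B, M))
    for b, g in enumerate(graphs):
        m = g.num_atoms
        if g.node_features.shape[1] != n_features:
            raise ValueError(
                f"graph has {g.node_features.shape[1]} node features, "
                f"model expects {n_features}"
            )
        X[b, :m] = g.node_features
        closed[b, :m, :m] = g.adjacency + np.eye(m)
        node_mask[b, :m] = 1.0
    return X, closed, node_mask


def _masked_batchnorm(z: Tensor, mask3: np.ndarray, n_real: float,
                      gamma: Tensor, beta: Tensor,
                      stats: dict[str, np.ndarray], key: str,
                      training: bool) -> Tensor:
    if training:
        mean = (z * mask3).sum(axis=(0, 1)) * (1.0 / n_real)
        centered = (z - mean.reshape(1, 1, -1)) * mask3
        var = (centered * centered).sum(axis=(0, 1)) * (1.0 / n_real)
        stats[key + ".mean"] = (
            (1 - _BN_MOMENTUM) * stats[key + ".mean"] + _BN_MOMENTUM * mean.data
        )
        stats[key + ".var"] = (
            (1 - _BN_MOMENTUM) * stats[key + ".var"] + _BN_MOMENTUM * var.data
        )
        denom = (var + _BN_EPS) ** 0.5
        zhat = (z - mean.reshape(1, 1, -1)) / denom.reshape(1, 1, -1)
    else:
        mean = stats[key + ".mean"]
        denom = np.sqrt(stats[key + ".var"] + _BN_EPS)
        zhat = (z - mean.reshape(1, 1, -1)) * (1.0 / denom.reshape(1, 1, -1))
    return zhat * gamma.reshape(1, 1, -1) + beta.reshape(1, 1, -1)


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * keep


def _forward_batch(state: ModelState, graphs: list[MoleculeGraph],
                   training: bool = False, capture: bool = False,
                   dropout_rng: np.random.Generator | None = None,
                   bn_training: bool | None = None):
    """Run the padded batched forward pass.

    Returns ``(predictions, traces)`` where predictions is a Tensor of shape
    (B,) (regression output or classification logit) and traces is a list of
    :class:`AttentionTrace` (empty unless ``capture``).
    """
    cfg = state.config
    P = state.params
    if bn_training is None:
        bn_training = training  # freeze flag: train with stored statistics
    Xnp, closed, node_mask = _pad_batch(graphs, cfg.n_node_features)
    B, M, _ = Xnp.shape
    mask3 = node_mask[:, :, None]
    n_real = float(node_mask.sum())
    rng = dropout_rng if training else None

    traces = [AttentionTrace() for _ in graphs] if capture else []

    x = Tensor(Xnp)
    attn_bias = np.where(closed > 0, 0.0, _NEG_INF)  # (B, M, M)

    for layer in range(cfg.n_conv_layers):
        head_outputs = []
        head_alphas = []
        for head in range(cfg.n_conv_heads):
            prefix = f"conv{layer}.h{head}"
            h = x @ P[f"{prefix}.W"] + P[f"{prefix}.b"]  # (B, M, H)
            e_src = h @ P[f"{prefix}.a_src"]  # (B, M, 1)
            e_dst = h @ P[f"{prefix}.a_dst"]  # (B, M, 1)
            e = (e_src + e_dst.swapaxes(1, 2)).leaky_relu(0.2) + Tensor(attn_bias)
            alpha = e.softmax(axis=-1)  # rows of padded atoms are uniform; unused
            head_outputs.append(alpha @ h)
            head_alphas.append(alpha)
        if cfg.n_conv_heads == 1:
            aggregated = head_outputs[0]
        else:
            total = head_outputs[0]
            for extra in head_outputs[1:]:
                total = total + extra
            aggregated = total * (1.0 / cfg.n_conv_heads)
        if capture:
            for b, g in enumerate(graphs):
                m = g.num_atoms
                traces[b].local.append(
                    [a.data[b, :m, :m].copy() for a in head_alphas]
                )
        z = aggregated.elu() @ P[f"conv{layer}.lin.W"] + P[f"conv{layer}.lin.b"]
        z = _masked_batchnorm(
            z, mask3, n_real,
            P[f"conv{layer}.bn.gamma"], P[f"conv{layer}.bn.beta"],
            state.bn_stats, f"conv{layer}.bn", bn_training,
        )
        x = _dropout(z.relu() * mask3, cfg.dropout_conv, rng)

    # global multihead attention with residual connection
    H = cfg.embed_dim
    N = cfg.n_global_heads
    d = H // N
    q = (x @ P["glob.Wq"] + P["glob.bq"]).reshape(B, M, N, d).transpose((0, 2, 1, 3))
    k = (x @ P["glob.Wk"] + P["glob.bk"]).reshape(B, M, N, d).transpose((0, 2, 1, 3))
    v = (x @ P["glob.Wv"] + P["glob.bv"]).reshape(B, M, N, d).transpose((0, 2, 1, 3))
    scores = (q @ k.swapaxes(2, 3)) * (1.0 / np.sqrt(d))  # (B, N, M, M)
    key_bias = np.where(node_mask[:, None, None, :] > 0, 0.0, _NEG_INF)
    attn = (scores + Tensor(key_bias)).softmax(axis=-1)
    if capture:
        for b, g in enumerate(graphs):
            m = g.num_atoms
            traces[b].global_heads = [
                attn.data[b, h, :m, :m].copy() for h in range(N)
            ]
    out = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, M, H) @ P["glob.Wo"]
    out = out + P["glob.bo"]
    out = _dropout(out, cfg.dropout_attention, rng)
    x = (out + x) * mask3  # residual connection

    # readout: concat(global max pool, global mean pool)
    counts = node_mask.sum(axis=1, keepdims=True)  # (B, 1)
    mean_pool = (x * mask3).sum(axis=1) * Tensor(1.0 / counts)
    max_pool = (x + Tensor((1.0 - mask3) * _NEG_INF)).max(axis=1)
    pooled = concat([max_pool, mean_pool], axis=1)  # (B, 2H)

    w1, b1, w2, b2 = head_param_names()
    hidden = (pooled @ P[w1] + P[b1]).relu()
    preds = (hidden @ P[w2] + P[b2]).reshape(B)
    return preds, traces


# ---------------------------------------------------------------------------
# public inference API
# ---------------------------------------------------------------------------

def forward(state: ModelState, graph: MoleculeGraph, capture: bool = False):
    """Evaluation-mode forward pass for one molecule.

    Returns the scalar prediction (regression value or classification
    logit), or ``(prediction, AttentionTrace)`` when ``capture`` is set.
    """
    preds, traces = _forward_batch(state, [graph], training=False, capture=capture)
    value = float(preds.data[0])
    if capture:
        return value, traces[0]
    return value


def predict_batch(state: ModelState, graphs: list[MoleculeGraph],
                  chunk_size: int = 256) -> np.ndarray:
    """Evaluation-mode predictions for a list of graphs (chunked internally)."""
    if len(graphs) == 0:
        raise ValueError("predict_batch requires a nonempty list of graphs")
    outputs = []
    for start in range(0, len(graphs), chunk_size):
        chunk = graphs[start:start + chunk_size]
        preds, _ = _forward_batch(state, chunk, training=False, capture=False)
        outputs.append(preds.data)
    return np.concatenate(outputs)


def predict_proba_batch(state: ModelState, graphs: list[MoleculeGraph]) -> np.ndarray:
    """Class-1 probabilities via the logistic map (classification head only)."""
    if state.config.head_kind != "binary-classification":
        raise ValueError("probabilities require a binary-classification head")
    logits = predict_batch(state, graphs)
    return 1.0 / (1.0 + np.exp(-logits))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(state: ModelState, path) -> None:
    """Serialize config, seed, weights and normalization statistics."""
    meta = {
        "format": _FORMAT_VERSION,
        "config": asdict(state.config),
        "seed": state.seed,
        "target_mean": state.target_mean,
        "target_sd": state.target_sd,
    }
    arrays = {f"param::{k}": v.data for k, v in state.params.items()}
    arrays.update({f"bn::{k}": v for k, v in state.bn_stats.items()})
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_model(path) -> ModelState:
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta.get("format") != _FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format')!r}")
        config = ModelConfig(**meta["config"])
        params = {}
        bn_stats = {}
        for key in archive.files:
            if key.startswith("param::"):
                params[key[len("param::"):]] = Tensor(archive[key], requires_grad=True)
            elif key.startswith("bn::"):
                bn_stats[key[len("bn::"):]] = archive[key].copy()
    return ModelState(config, params, bn_stats, meta["seed"],
                      meta.get("target_mean", 0.0), meta.get("target_sd", 1.0))
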