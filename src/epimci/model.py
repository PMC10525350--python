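"""Dual-channel hyperedge scorer.

A candidate hyperedge (a tuple of 3-6 bins, padded to the maximum order with
a mask) is scored from two complementary views:

* the *separating* view looks only at the tuple itself: masked multi-head
  self-attention produces dependent embeddings ``E_d`` (each vertex attends
  to its tuple mates), a per-vertex MLP produces independent embeddings
  ``E_I``, and a KL alignment loss pulls the two pooled distributions onto a
  common subspace; their average is the discrete embedding ``D``;
* the *coupling* view propagates vertex features through the positive
  hypergraph with symmetric-normalized hypergraph convolutions, yielding
  structural embeddings ``S`` shared across tuples.

Per real vertex the fused representation ``dense([D_i || S_i])`` feeds a
scalar head; the per-vertex sigmoid outputs are averaged over the mask into
the tuple probability. The ablation variants route only one channel into the
head (``noSHE``: structural only, ``noCHE``: discrete only).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import (
    Tensor,
    concat,
    gather_rows,
    leaky_relu,
    relu,
    sigmoid,
    softmax,
    spmm,
)
from .genome_io import ValidationError
from .hypergraph import Hypergraph, propagation_matrix
from .sampling import LabeledSample

LOSS_EPS = 1e-7
_MASK_NEG = -1e30
_LN2 = float(np.log(2.0))

VARIANTS = ("full", "noSHE", "noCHE")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the scorer."""

    feature_dim: int = 64
    embed_dim: int = 64
    n_heads: int = 4
    hconv_layers: int = 3
    dropout: float = 0.4
    lambda_kl: float = 1.0
    leaky_slope: float = 0.01
    max_order: int = 6
    variant: str = "full"
    pool: str = "mean"  # discrete embedding D: "mean" or "concat" of E_d, E_I

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValidationError("embed_dim must be divisible by n_heads")
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}")
        if self.pool not in ("mean", "concat"):
            raise ValidationError("pool must be 'mean' or 'concat'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")

    @property
    def discrete_dim(self) -> int:
        return self.embed_dim if self.pool == "mean" else 2 * self.embed_dim

    @property
    def fusion_in(self) -> int:
        if self.variant == "noSHE":
            return self.embed_dim
        if self.variant == "noCHE":
            return self.discrete_dim
        return self.discrete_dim + self.embed_dim


@dataclass
class TupleBatch:
    """Padded batch of candidate hyperedges."""

    features: np.ndarray    # (B, S, F) vertex features, zero in padded slots
    mask: np.ndarray        # (B, S) 1.0 for real vertices
    vertex_ids: np.ndarray  # (B, S) global bin ids, 0 in padded slots
    labels: np.ndarray | None = None  # (B,)

    def __post_init__(self):
        counts = self.mask.sum(axis=1)
        if self.labels is not None and len(self.labels) != len(self.mask):
            raise ValidationError("labels length must match batch size")
        if (counts < 2).any():
            raise ValidationError("every tuple needs at least 2 real vertices")


def make_batch(
    tuples: Sequence[tuple[int, ...]],
    embeddings: np.ndarray,
    max_order: int = 6,
    labels: Sequence[int] | None = None,
) -> TupleBatch:
    """Pad bin tuples to ``max_order`` and attach their vertex features."""
    b = len(tuples)
    f = embeddings.shape[1]
    features = np.zeros((b, max_order, f))
    mask = np.zeros((b, max_order))
    vertex_ids = np.zeros((b, max_order), dtype=int)
    for i, tup in enumerate(tuples):
        k = len(tup)
        if k > max_order:
            raise ValidationError(f"tuple of order {k} exceeds max_order {max_order}")
        features[i, :k] = embeddings[list(tup)]
        mask[i, :k] = 1.0
        vertex_ids[i, :k] = tup
    lab = None if labels is None else np.asarray(labels, dtype=float)
    return TupleBatch(features, mask, vertex_ids, lab)


def batch_from_samples(
    samples: Sequence[LabeledSample], embeddings: np.ndarray, max_order: int = 6
) -> TupleBatch:
    return make_batch(
        [s.bins for s in samples], embeddings, max_order, [s.label for s in samples]
    )


# -- parameters ---------------------------------------------------------------


@dataclass
class ModelParams:
    """All learnable tensors, keyed by name, plus the configuration echo."""

    config: ModelConfig
    tensors: dict[str, Tensor] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def all_tensors(self) -> list[Tensor]:
        return [self.tensors[k] for k in sorted(self.tensors)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.tensors.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.tensors[k].data = v.copy()


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    scale = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-scale, scale, size=shape)


def init_params(config: ModelConfig, seed: int = 0) -> ModelParams:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    f, e = config.feature_dim, config.embed_dim
    head_dim = e // config.n_heads
    t: dict[str, Tensor] = {}
    if config.variant != "noSHE":
        for h in range(config.n_heads):
            t[f"attn_q{h}"] = Tensor(_glorot(rng, (f, head_dim)), requires_grad=True)
            t[f"attn_k{h}"] = Tensor(_glorot(rng, (f, head_dim)), requires_grad=True)
            t[f"attn_v{h}"] = Tensor(_glorot(rng, (f, head_dim)), requires_grad=True)
        t["attn_out"] = Tensor(_glorot(rng, (e, e)), requires_grad=True)
        t["mlp_w1"] = Tensor(_glorot(rng, (f, e)), requires_grad=True)
        t["mlp_b1"] = Tensor(np.zeros(e), requires_grad=True)
        t["mlp_w2"] = Tensor(_glorot(rng, (e, e)), requires_grad=True)
        t["mlp_b2"] = Tensor(np.zeros(e), requires_grad=True)
        t["mlp_w3"] = Tensor(_glorot(rng, (e, e)), requires_grad=True)
        t["mlp_b3"] = Tensor(np.zeros(e), requires_grad=True)
    if config.variant != "noCHE":
        dims = [f] + [e] * config.hconv_layers
        for layer in range(config.hconv_layers):
            t[f"hconv_w{layer}"] = Tensor(
                _glorot(rng, (dims[layer], dims[layer + 1])), requires_grad=True
            )
    t["fusion_w"] = Tensor(_glorot(rng, (config.fusion_in, e)), requires_grad=True)
    t["fusion_b"] = Tensor(np.zeros(e), requires_grad=True)
    t["head_w"] = Tensor(_glorot(rng, (e, 1)), requires_grad=True)
    t["head_b"] = Tensor(np.zeros(1), requires_grad=True)
    return ModelParams(config, t)


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


# -- separating-hyperedge channel ---------------------------------------------


def attention_masks(mask: np.ndarray) -> np.ndarray:
    """(B, S, S) additive mask: 0 where j is real and j != i, -inf-like else."""
    s = mask.shape[1]
    allowed = mask[:, None, :] * (1.0 - np.eye(s))
    return (1.0 - allowed) * _MASK_NEG


def attention_embed(batch: TupleBatch, params: ModelParams) -> Tensor:
    """Masked multi-head self-attention: dependent embeddings E_d (B, S, E).

    Raw scores are the unscaled dot products of per-head query/key
    projections; the softmax runs over real non-self slots only; per-head
    context vectors are concatenated, projected, and squashed with tanh.
    """
    cfg = params.config
    x = Tensor(batch.features)
    additive = Tensor(attention_masks(batch.mask))
    heads = []
    for h in range(cfg.n_heads):
        q = x @ params[f"attn_q{h}"]
        k = x @ params[f"attn_k{h}"]
        v = x @ params[f"attn_v{h}"]
        scores = q @ k.swapaxes(-1, -2)
        alpha = softmax(scores + additive, axis=-1)
        heads.append(alpha @ v)
    return (concat(heads, axis=-1) @ params["attn_out"]).tanh()


def attention_weights(batch: TupleBatch, params: ModelParams, head: int = 0) -> np.ndarray:
    """Normalized attention matrix of one head (for inspection/testing)."""
    x = Tensor(batch.features)
    q = x @ params[f"attn_q{head}"]
    k = x @ params[f"attn_k{head}"]
    scores = q @ k.swapaxes(-1, -2)
    return softmax(scores + Tensor(attention_masks(batch.mask)), axis=-1).data


def mlp_embed(
    batch: TupleBatch,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Per-vertex MLP: independent embeddings E_I (B, S, E).

    Each vertex is transformed in isolation, so its embedding does not
    depend on the rest of the tuple. Dropout acts on the hidden layers when
    an rng is supplied (training mode).
    """
    cfg = params.config
    x = Tensor(batch.features)
    h1 = _dropout(relu(x @ params["mlp_w1"] + params["mlp_b1"]), cfg.dropout, rng)
    h2 = _dropout(relu(h1 @ params["mlp_w2"] + params["mlp_b2"]), cfg.dropout, rng)
    return h2 @ params["mlp_w3"] + params["mlp_b3"]


def kl_align(e_dep: Tensor, e_ind: Tensor, mask: np.ndarray) -> Tensor:
    """Base-2 KL divergence between pooled channel distributions.

    Both embeddings are masked-mean-pooled per tuple, softmaxed over the
    embedding dimension, and compared one-directionally
    D(P_Ed || P_EI); the batch mean is returned.
    """
    if e_dep.shape != e_ind.shape:
        raise ValidationError("channel embeddings must have equal shapes")
    m = Tensor(mask[:, :, None])
    denom = Tensor(mask.sum(axis=1, keepdims=True))
    pooled_dep = (e_dep * m).sum(axis=1) / denom
    pooled_ind = (e_ind * m).sum(axis=1) / denom
    p = softmax(pooled_dep, axis=-1)
    q = softmax(pooled_ind, axis=-1)
    per_tuple = (p * ((p.log() - q.log()) * (1.0 / _LN2))).sum(axis=-1)
    return per_tuple.mean()


# -- coupling-hyperedge channel -----------------------------------------------


def _propagation(graph: Hypergraph):
    cached = getattr(graph, "_prop_cache", None)
    if cached is None:
        cached = propagation_matrix(graph)
        graph._prop_cache = cached
    return cached


def hconv(
    x: np.ndarray,
    graph: Hypergraph,
    params: ModelParams,
    layers: int | None = None,
) -> Tensor:
    """Hypergraph convolution stack: structural embeddings S (N, E).

    Each layer applies the symmetric-normalized propagation
    ``Dv^-1/2 H W De^-1 H^T Dv^-1/2 X W_t`` followed by a leaky rectifier.
    Isolated vertices propagate nothing (pseudo-inverse convention).
    """
    cfg = params.config
    n_layers = cfg.hconv_layers if layers is None else layers
    if x.shape[0] != graph.n_bins:
        raise ValidationError(
            f"feature rows {x.shape[0]} do not match hypergraph vertices {graph.n_bins}"
        )
    prop = _propagation(graph)
    out = x if isinstance(x, Tensor) else Tensor(x)
    for layer in range(n_layers):
        out = leaky_relu(spmm(prop, out) @ params[f"hconv_w{layer}"], cfg.leaky_slope)
    return out


# -- fusion and scoring -------------------------------------------------------


def fuse_and_score(
    e_dep: Tensor | None,
    e_ind: Tensor | None,
    structural: Tensor | None,
    batch: TupleBatch,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Fuse channels and score: per-tuple probability p (B,).

    The discrete embedding D combines E_d and E_I (mean by default); per
    real vertex the fused dense layer sees ``[D_i || S_i]``, the scalar head
    applies a sigmoid, and per-vertex probabilities are averaged over the
    mask.
    """
    cfg = params.config
    parts: list[Tensor] = []
    if cfg.variant != "noSHE":
        if cfg.pool == "mean":
            parts.append((e_dep + e_ind) * 0.5)
        else:
            parts.append(concat([e_dep, e_ind], axis=-1))
    if cfg.variant != "noCHE":
        parts.append(gather_rows(structural, batch.vertex_ids))
    fused_in = parts[0] if len(parts) == 1 else concat(parts, axis=-1)
    hidden = relu(fused_in @ params["fusion_w"] + params["fusion_b"])
    hidden = _dropout(hidden, cfg.dropout, rng)
    logits = (hidden @ params["head_w"]).reshape(batch.mask.shape) + params["head_b"]
    p_vertex = sigmoid(logits)
    m = Tensor(batch.mask)
    return (p_vertex * m).sum(axis=1) / m.sum(axis=1)


def forward(
    params: ModelParams,
    batch: TupleBatch,
    vertex_features: np.ndarray | None = None,
    graph: Hypergraph | None = None,
    structural: Tensor | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Full forward pass: (p, kl_loss).

    ``structural`` may be supplied directly (e.g. precomputed for scoring);
    otherwise it is derived from ``vertex_features`` and ``graph``. The KL
    term is zero for the noSHE variant (it has no channel pair to align).
    """
    cfg = params.config
    e_dep = e_ind = None
    kl = Tensor(0.0)
    if cfg.variant != "noSHE":
        e_dep = attention_embed(batch, params)
        e_ind = mlp_embed(batch, params, rng)
        kl = kl_align(e_dep, e_ind, batch.mask)
    if cfg.variant != "noCHE" and structural is None:
        if vertex_features is None or graph is None:
            raise ValidationError("coupling channel needs vertex_features and graph")
        structural = hconv(vertex_features, graph, params)
    p = fuse_and_score(e_dep, e_ind, structural, batch, params, rng)
    return p, kl


def total_loss(p: Tensor, labels: np.ndarray, kl: Tensor, lambda_kl: float) -> Tensor:
    """Binary cross-entropy plus weighted KL alignment term.

    Probabilities are clamped to [eps, 1-eps] before the logs.
    """
    y = np.asarray(labels, dtype=np.float64)
    pc = p.clip(LOSS_EPS, 1.0 - LOSS_EPS)
    bce = -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()).mean()
    if lambda_kl == 0.0:
        return bce
    return bce + lambda_kl * kl


def classify(p, threshold: float = 0.5) -> np.ndarray:
    """Binarize probability scores: label 1 iff p >= threshold."""
    return (np.asarray(p, dtype=float) >= threshold).astype(int)


def score_tuples(
    params: ModelParams,
    tuples: Sequence[tuple[int, ...]],
    embeddings: np.ndarray,
    graph: Hypergraph | None,
    batch_size: int = 4096,
) -> np.ndarray:
    """Score arbitrary bin tuples in evaluation mode (no dropout)."""
    structural = None
    if params.config.variant != "noCHE":
        if graph is None:
            raise ValidationError("coupling channel needs a hypergraph")
        structural = hconv(embeddings, graph, params).detach()
    out = np.empty(len(tuples))
    for start in range(0, len(tuples), batch_size):
        chunk = tuples[start : start + batch_size]
        batch = make_batch(chunk, embeddings, params.config.max_order)
        p, _ = forward(params, batch, structural=structural)
        out[start : start + len(chunk)] = p.data
    return out


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(params: ModelParams, path: str | Path) -> None:
    """Versioned npz checkpoint with a JSON config echo."""
    arrays = {f"tensor__{k}": t.data for k, t in params.tensors.items()}
    meta = json.dumps({"format_version": 1, "config": asdict(params.config)})
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> ModelParams:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != 1:
            raise ValidationError(f"unsupported checkpoint version: {meta.get('format_version')}")
        config = ModelConfig(**meta["config"])
        params = init_params(config, seed=0)
        state = {
            k.removeprefix("tensor__"): data[k] for k in data.files if k.startswith("tensor__")
        }
        params.load_state(state)
    return params
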