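"""Condition-encoder / masked-decoder transformer with four output heads.

The architecture is a sequence-to-sequence transformer specialised for
keyword- and year-conditioned language modeling of scientific abstracts:

* a shallow *condition encoder* — self-attention blocks over the set of
  condition embeddings (keywords + publication year).  Condition inputs get
  **no** positional encoding: a condition set is unordered, and all outputs
  are invariant to permuting it;
* a deep *text decoder* — masked (causal) self-attention blocks over token
  embeddings plus sinusoidal positional encodings, each followed by
  encoder–decoder attention onto the encoded conditions;
* four linear classification heads on the final decoder states, predicting
  at each position the next subword token and that token's part-of-speech,
  dependency and entity labels.

Blocks use the post-norm residual layout ``LayerNorm(f(x) + x)``.  The
training objective is the sum of the four per-head cross-entropies (mean
negative log-likelihood over non-padding positions).

Default sizes follow a GPT-2-medium-like configuration (embedding 1024,
16 heads, 2 encoder and 16 decoder blocks, feed-forward 3072, dropout 0.1,
maximum sequence length 128); tests and desk-scale runs shrink these.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from . import labels as L
from .corpus import PAD_CONDITION, TrainingWindow

_NEG = -1e30  # additive mask value; exp() underflows to exactly 0


@dataclass
class ModelConfig:
    """Architecture sizes and the label-track vocabulary widths."""

    embed_dim: int = 1024
    heads: int = 16
    encoder_layers: int = 2
    decoder_layers: int = 16
    ff_dim: int = 3072
    dropout: float = 0.1
    max_seq: int = 128
    vocab_size: int = 16000
    n_conditions: int = 48364          # keywords + years + padding row
    n_pos: int = len(L.POS_TAGS)
    n_dep: int = len(L.DEP_TAGS)
    n_ent: int = len(L.ENTITY_LABELS)

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("embed_dim", "heads", "encoder_layers", "decoder_layers",
                     "ff_dim", "max_seq", "vocab_size", "n_conditions",
                     "n_pos", "n_dep", "n_ent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _attn_params(rng, d: int) -> dict:
    std = 0.02
    return {k: Tensor(rng.normal(0.0, std, size=(d, d)), requires_grad=True)
            for k in ("wq", "wk", "wv", "wo")}


def _ln_params(d: int) -> dict:
    return {"g": Tensor(np.ones(d), requires_grad=True),
            "b": Tensor(np.zeros(d), requires_grad=True)}


def _ff_params(rng, d: int, ff: int) -> dict:
    std = 0.02
    return {"w1": Tensor(rng.normal(0.0, std, size=(d, ff)), requires_grad=True),
            "w2": Tensor(rng.normal(0.0, std, size=(ff, d)), requires_grad=True)}


@dataclass
class ModelParams:
    """All trainable weight groups, as a nested tree of Tensors."""

    config: ModelConfig
    tree: dict = field(repr=False)

    def tensors(self):
        yield from ag.parameters(self.tree)

    def named_tensors(self):
        def walk(node, prefix):
            if isinstance(node, Tensor):
                yield prefix, node
            elif isinstance(node, dict):
                for k, v in node.items():
                    yield from walk(v, f"{prefix}/{k}" if prefix else k)
            elif isinstance(node, list):
                for i, v in enumerate(node):
                    yield from walk(v, f"{prefix}/{i}")
        yield from walk(self.tree, "")


def init_params(config: ModelConfig, seed: int = 0) -> ModelParams:
    """GPT-2-style initialization: N(0, 0.02) matrices, unit norm gains."""
    rng = np.random.default_rng(seed)
    d, ff = config.embed_dim, config.ff_dim
    std = 0.02
    tree: dict = {
        "tok_emb": Tensor(rng.normal(0.0, std, size=(config.vocab_size, d)),
                          requires_grad=True),
        "cond_emb": Tensor(rng.normal(0.0, std, size=(config.n_conditions, d)),
                           requires_grad=True),
        "enc": [
            {"attn": _attn_params(rng, d), "ln1": _ln_params(d),
             "ff": _ff_params(rng, d, ff), "ln2": _ln_params(d)}
            for _ in range(config.encoder_layers)
        ],
        "dec": [
            {"self": _attn_params(rng, d), "ln1": _ln_params(d),
             "cross": _attn_params(rng, d), "ln2": _ln_params(d),
             "ff": _ff_params(rng, d, ff), "ln3": _ln_params(d)}
            for _ in range(config.decoder_layers)
        ],
        "heads": {
            "tok": Tensor(rng.normal(0.0, std, size=(d, config.vocab_size)),
                          requires_grad=True),
            "pos": Tensor(rng.normal(0.0, std, size=(d, config.n_pos)),
                          requires_grad=True),
            "dep": Tensor(rng.normal(0.0, std, size=(d, config.n_dep)),
                          requires_grad=True),
            "ent": Tensor(rng.normal(0.0, std, size=(d, config.n_ent)),
                          requires_grad=True),
        },
    }
    return ModelParams(config=config, tree=tree)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Sinusoidal position codes: ``PE[pos, 2i] = sin(pos / 10000^(2i/dim))``
    and ``PE[pos, 2i+1] = cos`` of the same argument."""
    if dim % 2 != 0:
        raise ValueError("positional encoding dimension must be even")
    if length < 1:
        raise ValueError("length must be at least 1")
    pos = np.arange(length)[:, None]
    i2 = np.arange(0, dim, 2)[None, :]
    angle = pos / np.power(10000.0, i2 / dim)
    pe = np.empty((length, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def attention(Q, K, V, mask: np.ndarray | None = None) -> Tensor:
    """Scaled dot-product attention ``softmax(Q K^T / sqrt(d)) V``.

    ``mask`` is boolean with True marking *allowed* key positions, broadcast
    against the (..., queries, keys) score shape; masked keys get exactly
    zero weight.  A query row with every key masked is undefined and raises.
    """
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    d = Q.shape[-1]
    if K.shape[-1] != d:
        raise ValueError("Q and K must share embedding dimensionality")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must share key count")
    scores = ag.matmul(Q, K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2))
    scores = scores * (1.0 / np.sqrt(d))
    additive = None
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        full = np.broadcast_to(mask, scores.shape)
        if np.any(~full.any(axis=-1)):
            raise ValueError("attention row with all keys masked is undefined")
        additive = np.where(mask, 0.0, _NEG)
    weights = ag.exp(ag.log_softmax(scores, additive_mask=additive))
    return ag.matmul(weights, V)


def _project(X: Tensor, W: Tensor, heads: int) -> Tensor:
    """(B, S, d) @ W, split into heads -> (B, heads, S, d/heads)."""
    B, S, d = X.shape
    H = ag.matmul(X, W)
    return H.reshape(B, S, heads, d // heads).transpose(0, 2, 1, 3)


def multi_head(X, Y, params: dict, heads: int,
               mask: np.ndarray | None = None) -> Tensor:
    """Multi-headed attention: queries from ``X``, keys/values from ``Y``;
    heads are concatenated and mixed by the output matrix."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    Y = Y if isinstance(Y, Tensor) else Tensor(Y)
    squeeze = X.ndim == 2
    if squeeze:
        X = X.reshape(1, *X.shape)
        Y = Y.reshape(1, *Y.shape)
    if X.shape[-1] != Y.shape[-1]:
        raise ValueError("X and Y must share embedding dimensionality")
    B, S, d = X.shape
    q = _project(X, params["wq"], heads)
    k = _project(Y, params["wk"], heads)
    v = _project(Y, params["wv"], heads)
    if mask is not None and np.asarray(mask).ndim == 3:
        mask = np.asarray(mask)[:, None, :, :]  # broadcast over heads
    att = attention(q, k, v, mask=mask)                      # (B, h, S, dh)
    att = att.transpose(0, 2, 1, 3).reshape(B, S, d)
    out = ag.matmul(att, params["wo"])
    return out.reshape(*out.shape[1:]) if squeeze else out


def feed_forward(X, params: dict) -> Tensor:
    """Position-wise expansion with ReLU: ``max(0, X W1) W2``."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    return ag.matmul(ag.relu(ag.matmul(X, params["w1"])), params["w2"])


def _dropout(X: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return X
    keep = (rng.random(X.shape) >= rate) / (1.0 - rate)
    return X * keep


def encoder_block(X, layer: dict, heads: int, mask: np.ndarray | None = None,
                  dropout: float = 0.0,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Self-attention block, post-norm: LN(FF(a) + a), a = LN(MH(X,X) + X)."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    a = _dropout(multi_head(X, X, layer["attn"], heads, mask), dropout, rng)
    a = ag.layer_norm(a + X, layer["ln1"]["g"], layer["ln1"]["b"])
    f = _dropout(feed_forward(a, layer["ff"]), dropout, rng)
    return ag.layer_norm(f + a, layer["ln2"]["g"], layer["ln2"]["b"])


def decoder_block(X, Y, layer: dict, heads: int,
                  self_mask: np.ndarray | None = None,
                  cross_mask: np.ndarray | None = None,
                  dropout: float = 0.0,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Masked self-attention, then attention onto the encoder output ``Y``,
    then feed-forward; each sublayer post-normed with a residual."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    Y = Y if isinstance(Y, Tensor) else Tensor(Y)
    b = _dropout(multi_head(X, X, layer["self"], heads, self_mask), dropout, rng)
    b = ag.layer_norm(b + X, layer["ln1"]["g"], layer["ln1"]["b"])
    a = _dropout(multi_head(b, Y, layer["cross"], heads, cross_mask), dropout, rng)
    a = ag.layer_norm(a + b, layer["ln2"]["g"], layer["ln2"]["b"])
    f = _dropout(feed_forward(a, layer["ff"]), dropout, rng)
    return ag.layer_norm(f + a, layer["ln3"]["g"], layer["ln3"]["b"])


def causal_mask(n: int) -> np.ndarray:
    """Lower-triangular boolean mask: position i attends to keys <= i."""
    return np.tril(np.ones((n, n), dtype=bool))


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Padded arrays for a batch of training windows."""

    token_ids: np.ndarray        # (B, S) int
    token_mask: np.ndarray       # (B, S) bool, True = real token
    cond_ids: np.ndarray         # (B, M) int
    cond_mask: np.ndarray        # (B, M) bool
    token_targets: np.ndarray | None = None
    pos_targets: np.ndarray | None = None
    dep_targets: np.ndarray | None = None
    ent_targets: np.ndarray | None = None


def collate(windows: list[TrainingWindow], pad_token: int = 0) -> Batch:
    """Pad a list of windows to rectangular arrays plus validity masks."""
    if not windows:
        raise ValueError("cannot collate an empty batch")
    B = len(windows)
    S = max(len(w) for w in windows)
    M = max(len(w.condition_ids) for w in windows)

    def pad2(rows, pad, width):
        out = np.full((B, width), pad, dtype=np.int64)
        for i, row in enumerate(rows):
            out[i, :len(row)] = row
        return out

    token_ids = pad2([w.input_ids for w in windows], pad_token, S)
    token_mask = pad2([[1] * len(w) for w in windows], 0, S).astype(bool)
    cond_ids = pad2([w.condition_ids for w in windows], PAD_CONDITION, M)
    cond_mask = pad2([[1] * len(w.condition_ids) for w in windows], 0, M).astype(bool)
    return Batch(
        token_ids=token_ids, token_mask=token_mask,
        cond_ids=cond_ids, cond_mask=cond_mask,
        token_targets=pad2([w.token_targets for w in windows], 0, S),
        pos_targets=pad2([w.pos_targets for w in windows], 0, S),
        dep_targets=pad2([w.dep_targets for w in windows], 0, S),
        ent_targets=pad2([w.ent_targets for w in windows], 0, S),
    )


@dataclass
class ForwardOutput:
    """Per-position logits for the four prediction heads."""

    token_logits: Tensor
    pos_logits: Tensor
    dep_logits: Tensor
    ent_logits: Tensor


def forward(batch: Batch, params: ModelParams, mode: str = "eval",
            rng: np.random.Generator | None = None) -> ForwardOutput:
    """Run the full model on a padded batch.

    Encoder input is the set of condition embeddings (no positional code);
    decoder input is token embeddings plus the sinusoidal positional code,
    processed under a causal mask so position ``i`` sees only tokens
    ``<= i`` and the conditions.  ``mode="train"`` enables dropout (requires
    ``rng``); ``mode="eval"`` is deterministic.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = params.config
    B, S = batch.token_ids.shape
    if S > cfg.max_seq:
        raise ValueError(f"window length {S} exceeds max_seq {cfg.max_seq}")
    drop = cfg.dropout if mode == "train" else 0.0
    if mode == "train" and drop > 0.0 and rng is None:
        raise ValueError("training mode with dropout requires an rng")
    tree = params.tree

    # condition encoder: E_0 = c (an unordered set; no positional encoding)
    E = ag.embedding(tree["cond_emb"], batch.cond_ids)           # (B, M, d)
    enc_mask = batch.cond_mask[:, None, :]                       # (B, 1, M)
    for layer in tree["enc"]:
        E = encoder_block(E, layer, cfg.heads, mask=enc_mask,
                          dropout=drop, rng=rng)

    # text decoder: D_0 = t + PE
    D = ag.embedding(tree["tok_emb"], batch.token_ids)
    D = D + positional_encoding(S, cfg.embed_dim)[None, :, :]
    D = _dropout(D, drop, rng)
    self_mask = (causal_mask(S)[None, :, :]
                 & batch.token_mask[:, None, :])                  # (B, S, S)
    # padded query rows still need one key: they can see themselves
    self_mask = self_mask | np.eye(S, dtype=bool)[None, :, :]
    cross_mask = np.broadcast_to(batch.cond_mask[:, None, :], (B, S, batch.cond_ids.shape[1]))
    for layer in tree["dec"]:
        D = decoder_block(D, E, layer, cfg.heads, self_mask=self_mask,
                          cross_mask=cross_mask, dropout=drop, rng=rng)

    return ForwardOutput(
        token_logits=ag.matmul(D, tree["heads"]["tok"]),
        pos_logits=ag.matmul(D, tree["heads"]["pos"]),
        dep_logits=ag.matmul(D, tree["heads"]["dep"]),
        ent_logits=ag.matmul(D, tree["heads"]["ent"]),
    )


def forward_window(window: TrainingWindow, params: ModelParams,
                   mode: str = "eval",
                   rng: np.random.Generator | None = None) -> ForwardOutput:
    """Convenience single-window forward pass (batch of one)."""
    return forward(collate([window]), params, mode=mode, rng=rng)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _head_nll(logits: Tensor, targets: np.ndarray, mask: np.ndarray,
              width: int) -> Tensor:
    targets = np.asarray(targets, dtype=np.int64)
    if targets.min() < 0 or targets.max() >= width:
        raise ValueError(f"target label out of range [0, {width})")
    logp = ag.log_softmax(logits)
    nll = -ag.take_last_axis(logp, targets)          # (B, S)
    w = mask.astype(float)
    return (nll * w).sum() / max(w.sum(), 1.0)


def multitask_loss(output: ForwardOutput, batch: Batch,
                   ) -> tuple[Tensor, dict[str, Tensor]]:
    """Sum of the four per-head mean cross-entropies over real positions.

    Returns ``(total, components)`` with components keyed ``token``,
    ``pos``, ``dep``, ``ent``; the total is exactly their sum.
    """
    mask = batch.token_mask
    comp = {
        "token": _head_nll(output.token_logits, batch.token_targets, mask,
                           output.token_logits.shape[-1]),
        "pos": _head_nll(output.pos_logits, batch.pos_targets, mask,
                         output.pos_logits.shape[-1]),
        "dep": _head_nll(output.dep_logits, batch.dep_targets, mask,
                         output.dep_logits.shape[-1]),
        "ent": _head_nll(output.ent_logits, batch.ent_targets, mask,
                         output.ent_logits.shape[-1]),
    }
    total = comp["token"] + comp["pos"] + comp["dep"] + comp["ent"]
    return total, comp


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, params: ModelParams, step: int = 0,
                    optimizer_state: dict | None = None) -> None:
    """Single-archive checkpoint: config JSON + every tensor by tree path."""
    arrays = {f"param:{name}": t.data for name, t in params.named_tensors()}
    if optimizer_state:
        for k, v in optimizer_state.items():
            arrays[f"opt:{k}"] = np.asarray(v)
    arrays["step"] = np.asarray(step)
    arrays["config"] = np.frombuffer(
        json.dumps(asdict(params.config)).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str) -> tuple[ModelParams, int, dict]:
    with open(path, "rb") as fh:
        data = np.load(io.BytesIO(fh.read()))
    config = ModelConfig(**json.loads(bytes(data["config"]).decode()))
    params = init_params(config, seed=0)
    named = dict(params.named_tensors())
    for key in data.files:
        if key.startswith("param:"):
            named[key[len("param:"):]].data = data[key].astype(np.float64)
    opt_state = {k[len("opt:"):]: data[k] for k in data.files
                 if k.startswith("opt:")}
    return params, int(data["step"]), opt_state
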