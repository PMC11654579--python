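"""The toxicity classifier network.

The encoder stacks two kinds of residual blocks over learned token +
position embeddings:

* a **convolutional-modulation block**, where a depthwise convolution of a
  linear projection gates a second projection elementwise,

      A = DConv_k(X W1),   V = X W2,   Z = A ⊙ V,

  giving each position a weighted aggregate of the residues in the window
  of width ``k`` centred on it; and

* a standard **multi-head self-attention block**,

      S = softmax(Q Kᵀ / sqrt(d_k)),   out = S V,

  with padded key positions excluded from the softmax.

Both block kinds use post-layer-norm residual wiring with a GELU
feed-forward sublayer. A pooling layer (max by default; min / mean /
attention / CLS available) collapses the L×d feature matrix to a single
d-vector, and a two-logit softmax head yields P(toxic).

Everything runs on the package's numpy autodiff engine; all masked
positions are inert — altering padding content never changes any output.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from ._autodiff import Parameter, Tensor, no_grad
from .sequence_io import (
    CLS_INDEX,
    DEFAULT_MAX_LEN,
    EncodedBatch,
    PeptideRecord,
    encode_batch,
    validate_record,
)

POOLING_METHODS = ("cls", "max", "mean", "min", "attention")
_NEG = 1e9
CHECKPOINT_FORMAT = "captox-checkpoint-v1"


@dataclass
class ModelConfig:
    """Every architectural hyperparameter in one validated object.

    d: embedding width; k: depthwise kernel size (odd, so the window is
    centred); n_heads divides d; pooling picks the sequence summary;
    encoder_order controls whether convolutional blocks precede attention
    blocks (the default) or follow them.
    """

    d: int = 64
    k: int = 3
    n_heads: int = 4
    n_conv_blocks: int = 1
    n_attn_blocks: int = 1
    pooling: str = "max"
    dropout: float = 0.1
    max_len: int = DEFAULT_MAX_LEN
    ffn_expansion: int = 4
    encoder_order: str = "conv_first"
    attention_scaling: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.d % self.n_heads != 0:
            raise ValueError(f"d={self.d} not divisible by n_heads={self.n_heads}")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"kernel size must be odd and >= 1, got {self.k}")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.pooling not in POOLING_METHODS:
            raise ValueError(f"pooling must be one of {POOLING_METHODS}")
        if self.encoder_order not in ("conv_first", "attn_first"):
            raise ValueError("encoder_order must be 'conv_first' or 'attn_first'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def d_k(self) -> int:
        return self.d // self.n_heads

    @property
    def add_cls(self) -> bool:
        # the CLS token is only worth a slot when its row is the summary
        return self.pooling == "cls"


# --------------------------------------------------------------------------
# tensor-level building blocks (shared by training and the numpy-facing API)
# --------------------------------------------------------------------------

def depthwise_conv(u: Tensor, kernel: Tensor) -> Tensor:
    """Per-channel 1-D convolution, zero-padded, 'same' length, centred.

    u: (B, L, d); kernel: (k, d). Output position p aggregates rows
    p-h .. p+h (h = k//2) of u, each channel with its own weights.
    """
    k = kernel.shape[0]
    h = k // 2
    out = None
    for j in range(k):
        term = u.shift(h - j, axis=1) * kernel.gather(np.full(1, j)).reshape(1, 1, -1)
        out = term if out is None else out + term
    return out


def conv_modulation_t(
    x: Tensor, w1: Tensor, w2: Tensor, kernel: Tensor, mask: np.ndarray
) -> Tensor:
    """Gated convolution Z = DConv_k(X W1) ⊙ (X W2), masked before and after."""
    m = Tensor(mask.astype(np.float64)[..., None])
    xm = x * m
    a = depthwise_conv(xm @ w1, kernel)
    v = xm @ w2
    return a * v * m


def masked_softmax(logits: Tensor, key_mask: np.ndarray) -> Tensor:
    """Row softmax over the last axis with masked keys forced to ~zero weight.

    key_mask broadcasts over the last axis of `logits`; the max-subtraction
    constant is detached, so gradients flow only through the exponentials.
    """
    bias = Tensor((key_mask.astype(np.float64) - 1.0) * _NEG)
    shifted = logits + bias
    stable = shifted - Tensor(shifted.data.max(axis=-1, keepdims=True))
    e = stable.exp()
    return e / e.sum(axis=-1, keepdims=True)


def multi_head_attention_t(
    x: Tensor,
    wq: Tensor,
    wk: Tensor,
    wv: Tensor,
    wo: Tensor,
    n_heads: int,
    mask: np.ndarray,
    scaling: bool = True,
) -> Tensor:
    b, l, d = x.shape
    d_k = d // n_heads

    def split(t: Tensor) -> Tensor:  # (B, L, d) -> (B, heads, L, d_k)
        return t.reshape(b, l, n_heads, d_k).swapaxes(1, 2)

    m = Tensor(mask.astype(np.float64)[..., None])
    xm = x * m
    q, k, v = split(xm @ wq), split(xm @ wk), split(xm @ wv)
    scores = q @ k.swapaxes(-1, -2)
    if scaling:
        scores = scores * (1.0 / math.sqrt(d_k))
    s = masked_softmax(scores, mask[:, None, None, :])
    ctx = (s @ v).swapaxes(1, 2).reshape(b, l, d)
    return (ctx @ wo) * m


def gelu(x: Tensor) -> Tensor:
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + (c * (x + 0.044715 * x ** 3.0)).tanh())


def pool_t(features: Tensor, mask: np.ndarray, method: str, score_w: Tensor | None = None) -> Tensor:
    """Collapse (B, L, d) features to (B, d) over unmasked rows."""
    if not mask.any(axis=1).all():
        raise ValueError("pooling needs at least one unmasked row per sequence")
    mf = mask.astype(np.float64)[..., None]
    if method == "max":
        return (features * Tensor(mf) + Tensor((mf - 1.0) * _NEG)).max(axis=1)
    if method == "min":
        return -((-features) * Tensor(mf) + Tensor((mf - 1.0) * _NEG)).max(axis=1)
    if method == "mean":
        return (features * Tensor(mf)).sum(axis=1) / Tensor(mf.sum(axis=1))
    if method == "attention":
        if score_w is None:
            raise ValueError("attention pooling needs a scoring vector")
        scores = (features @ score_w.reshape(-1, 1)).reshape(features.shape[0], -1)
        w = masked_softmax(scores, mask)
        return (features * w.reshape(*w.shape, 1)).sum(axis=1)
    if method == "cls":
        onehot = np.zeros(mask.shape[1])
        onehot[0] = 1.0  # CLS is always the first row
        return (features * Tensor(onehot[None, :, None])).sum(axis=1)
    raise ValueError(f"unknown pooling method {method!r}")


def softmax_rows(logits: Tensor) -> Tensor:
    stable = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    e = stable.exp()
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# numpy-facing functional API (forward only)
# --------------------------------------------------------------------------

def conv_modulation(x, w1, w2, kernel, mask=None) -> np.ndarray:
    """Forward pass of the gated-convolution operator on plain arrays.

    x: (L, d) or (B, L, d); kernel: (k, d); mask defaults to all-true.
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if mask is None:
        mask = np.ones(x.shape[:2], dtype=bool)
    out = conv_modulation_t(Tensor(x), Tensor(w1), Tensor(w2), Tensor(kernel), np.asarray(mask))
    return out.data[0] if squeeze else out.data


def multi_head_attention(x, wq, wk, wv, wo, n_heads=1, mask=None, scaling=True) -> np.ndarray:
    """Forward pass of masked multi-head self-attention on plain arrays."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if mask is None:
        mask = np.ones(x.shape[:2], dtype=bool)
    out = multi_head_attention_t(
        Tensor(x), Tensor(wq), Tensor(wk), Tensor(wv), Tensor(wo),
        n_heads, np.asarray(mask), scaling,
    )
    return out.data[0] if squeeze else out.data


def pool(features, mask, method: str, score_w=None) -> np.ndarray:
    """Forward pooling on plain arrays; see :func:`pool_t`."""
    features = np.asarray(features, dtype=np.float64)
    squeeze = features.ndim == 2
    if squeeze:
        features = features[None]
        mask = np.asarray(mask)[None]
    sw = None if score_w is None else Tensor(score_w)
    out = pool_t(Tensor(features), np.asarray(mask), method, sw)
    return out.data[0] if squeeze else out.data


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class _Linear:
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.w = Parameter(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out if self.b is None else out + self.b

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class _LayerNorm:
    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Parameter(np.ones(d))
        self.b = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred ** 2.0).mean(axis=-1, keepdims=True)
        return centred * (var + self.eps) ** -0.5 * self.g + self.b

    def params(self):
        return [self.g, self.b]


class _FeedForward:
    def __init__(self, rng, d: int, expansion: int):
        self.fc1 = _Linear(rng, d, expansion * d)
        self.fc2 = _Linear(rng, expansion * d, d)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))

    def params(self):
        return self.fc1.params() + self.fc2.params()


class _ConvModBlock:
    def __init__(self, rng, cfg: ModelConfig):
        limit = math.sqrt(6.0 / (2 * cfg.d))
        self.w1 = Parameter(rng.uniform(-limit, limit, size=(cfg.d, cfg.d)))
        self.w2 = Parameter(rng.uniform(-limit, limit, size=(cfg.d, cfg.d)))
        self.kernel = Parameter(rng.normal(0.0, 1.0 / math.sqrt(cfg.k), size=(cfg.k, cfg.d)))
        self.ffn = _FeedForward(rng, cfg.d, cfg.ffn_expansion)
        self.ln1 = _LayerNorm(cfg.d)
        self.ln2 = _LayerNorm(cfg.d)

    def __call__(self, x: Tensor, mask: np.ndarray, drop) -> Tensor:
        z = conv_modulation_t(x, self.w1, self.w2, self.kernel, mask)
        x = self.ln1(x + drop(z))
        return self.ln2(x + drop(self.ffn(x)))

    def params(self):
        return [self.w1, self.w2, self.kernel] + self.ffn.params() + self.ln1.params() + self.ln2.params()


class _AttentionBlock:
    def __init__(self, rng, cfg: ModelConfig):
        limit = math.sqrt(6.0 / (2 * cfg.d))
        self.wq, self.wk, self.wv, self.wo = (
            Parameter(rng.uniform(-limit, limit, size=(cfg.d, cfg.d))) for _ in range(4)
        )
        self.n_heads = cfg.n_heads
        self.scaling = cfg.attention_scaling
        self.ffn = _FeedForward(rng, cfg.d, cfg.ffn_expansion)
        self.ln1 = _LayerNorm(cfg.d)
        self.ln2 = _LayerNorm(cfg.d)

    def __call__(self, x: Tensor, mask: np.ndarray, drop) -> Tensor:
        z = multi_head_attention_t(
            x, self.wq, self.wk, self.wv, self.wo, self.n_heads, mask, self.scaling
        )
        x = self.ln1(x + drop(z))
        return self.ln2(x + drop(self.ffn(x)))

    def params(self):
        return [self.wq, self.wk, self.wv, self.wo] + self.ffn.params() + self.ln1.params() + self.ln2.params()


class CAPTPModel:
    """Sequence-in, toxicity-probability-out classifier."""

    VOCAB_SIZE = 22  # PAD + 20 residues + CLS

    def __init__(self, config: ModelConfig | None = None):
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        width = cfg.max_len + (1 if cfg.add_cls else 0)
        self.token_emb = Parameter(rng.normal(0.0, 0.1, size=(self.VOCAB_SIZE, cfg.d)))
        self.pos_emb = Parameter(rng.normal(0.0, 0.1, size=(width, cfg.d)))
        conv = [_ConvModBlock(rng, cfg) for _ in range(cfg.n_conv_blocks)]
        attn = [_AttentionBlock(rng, cfg) for _ in range(cfg.n_attn_blocks)]
        self.blocks = conv + attn if cfg.encoder_order == "conv_first" else attn + conv
        self.pool_w = Parameter(rng.normal(0.0, 0.1, size=cfg.d)) if cfg.pooling == "attention" else None
        self.head = _Linear(rng, cfg.d, 2)
        self._drop_rng = np.random.default_rng(rng.integers(2 ** 31))
        self.training = False

    # ----------------------------------------------------------- parameters
    def parameters(self) -> list[Parameter]:
        out = [self.token_emb, self.pos_emb]
        for blk in self.blocks:
            out.extend(blk.params())
        if self.pool_w is not None:
            out.append(self.pool_w)
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -------------------------------------------------------------- forward
    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p == 0.0:
            return x
        keep = self._drop_rng.random(x.shape) >= p
        return x * Tensor(keep.astype(np.float64) / (1.0 - p))

    def embed(self, batch: EncodedBatch) -> Tensor:
        """Token + position embeddings, padded rows zeroed; shape (B, L, d)."""
        tokens = batch.tokens
        if tokens.size and (tokens.min() < 0 or tokens.max() >= self.VOCAB_SIZE):
            raise ValueError("token index outside vocabulary")
        if tokens.shape[1] > self.pos_emb.shape[0]:
            raise ValueError(
                f"sequence width {tokens.shape[1]} exceeds positional table "
                f"{self.pos_emb.shape[0]}"
            )
        tok = self.token_emb.gather(tokens)
        pos = self.pos_emb.gather(np.arange(tokens.shape[1]))
        return (tok + pos.reshape(1, *pos.shape)) * Tensor(batch.mask.astype(np.float64)[..., None])

    def encoder_forward(self, batch: EncodedBatch) -> Tensor:
        x = self._dropout(self.embed(batch))
        for blk in self.blocks:
            x = blk(x, batch.mask, self._dropout)
        return x * Tensor(batch.mask.astype(np.float64)[..., None])

    def forward(self, batch: EncodedBatch) -> tuple[Tensor, Tensor]:
        """Returns (logits (B, 2), pooled representation (B, d))."""
        features = self.encoder_forward(batch)
        pooled = pool_t(features, batch.mask, self.config.pooling, self.pool_w)
        return self.head(pooled), pooled

    # ------------------------------------------------------------ inference
    def _encode(self, sequences) -> EncodedBatch:
        records = [
            s if isinstance(s, PeptideRecord) else PeptideRecord(f"seq{i}", s)
            for i, s in enumerate(sequences)
        ]
        for r in records:
            if not validate_record(r, self.config.max_len):
                raise ValueError(f"invalid sequence for record {r.id!r}")
        return encode_batch(records, self.config.max_len, self.config.add_cls)

    def predict_proba(self, sequences, batch_size: int = 512) -> np.ndarray:
        """P(toxic) per sequence; accepts strings, records, or an EncodedBatch."""
        self.training = False
        if isinstance(sequences, EncodedBatch):
            batch = sequences
        else:
            batch = self._encode(list(sequences))
        probs = np.empty(len(batch))
        with no_grad():
            for lo in range(0, len(batch), batch_size):
                sub = EncodedBatch(
                    batch.tokens[lo : lo + batch_size],
                    batch.mask[lo : lo + batch_size],
                    batch.labels[lo : lo + batch_size],
                    batch.lengths[lo : lo + batch_size],
                )
                logits, _ = self.forward(sub)
                probs[lo : lo + batch_size] = softmax_rows(logits).data[:, 1]
        return probs

    def predict(self, sequences, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(sequences) >= threshold).astype(int)

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with open(path, "wb") as fh:
            header = json.dumps({"format": CHECKPOINT_FORMAT, "config": asdict(self.config)})
            fh.write(header.encode() + b"\n")
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "CAPTPModel":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            if header.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"not a {CHECKPOINT_FORMAT} file: {path}")
            payload = np.load(io.BytesIO(fh.read()))
        model = cls(ModelConfig(**header["config"]))
        for i, p in enumerate(model.parameters()):
            arr = payload[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint parameter shapes do not match config")
            p.data = arr.astype(np.float64)
        return model
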