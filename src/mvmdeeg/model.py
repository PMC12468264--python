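"""Hybrid spatial-temporal classifier: CNN -> BiGRU -> Transformer -> dense.

The spectrogram tensor (one slab per channel/mode pair) passes through a
single 3x3 convolution block with batch normalization, ReLU and adaptive
average pooling to a pool_out x pool_out grid; the pooled time axis
becomes a short sequence that a 2-layer bidirectional GRU models for
short-range dependencies; the BiGRU output is re-chunked into
token_dim-wide tokens, a learned class token is prepended, sinusoidal
positions are added, and a multi-head self-attention encoder models
long-range structure. The class token's final embedding is classified by
a dense layer. Residual skips (a projected input added around the BiGRU,
and the encoder input added around the encoder stack) and every stage
are individually switchable for ablations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor

__all__ = [
    "ModelConfig",
    "GRUCellParams",
    "gru_step",
    "sinusoidal_positions",
    "HybridClassifier",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters, including ablation switches.

    ``in_maps`` is K*C (modes times channels); ``in_freqs``/``in_frames``
    are the spectrogram axes. The flattened BiGRU output
    (pool_out * 2*gru_hidden values) must re-chunk evenly into
    ``token_dim``-wide tokens, and ``token_dim`` must split across
    ``n_heads``.
    """

    in_maps: int = 8
    in_freqs: int = 51
    in_frames: int = 9
    conv_filters: int = 16
    kernel: int = 3
    padding: int = 1
    pool_out: int = 6
    gru_hidden: int = 512
    gru_layers: int = 2
    token_dim: int = 128
    n_heads: int = 8
    encoder_layers: int = 3
    n_classes: int = 2
    use_cnn: bool = True
    use_bigru: bool = True
    use_transformer: bool = True
    use_residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.pool_out * 2 * self.gru_hidden) % self.token_dim:
            raise ValueError("pool_out * 2*gru_hidden must divide into token_dim tokens")
        if self.token_dim % self.n_heads:
            raise ValueError("token_dim must be divisible by n_heads")

    @property
    def n_tokens(self) -> int:
        return self.pool_out * 2 * self.gru_hidden // self.token_dim

    @classmethod
    def focal_pair(cls, **kw) -> "ModelConfig":
        """Binary focal/non-focal configuration (2 channels x 4 modes)."""
        return cls(in_maps=8, conv_filters=16, n_classes=2, **kw)

    @classmethod
    def seizure_types(cls, **kw) -> "ModelConfig":
        """Six-class seizure-type configuration (7 channels x 8 modes)."""
        return cls(in_maps=56, conv_filters=128, n_classes=6, **kw)


# -- GRU ---------------------------------------------------------------
@dataclass
class GRUCellParams:
    """Weights of one GRU cell acting on the concatenation [h_prev, x_t]."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray


def gru_step(x_t: Tensor, h_prev: Tensor, p: "GRUCell") -> Tensor:
    """One gated-recurrent update.

    z = sigmoid(W_z [h, x]), r = sigmoid(W_r [h, x]),
    h~ = tanh(W_h [r*h, x]), h_t = (1 - z)*h_prev + z*h~.
    The update gate z blends old state against the candidate; the reset
    gate r limits how much history enters the candidate.
    """
    hx = ad.concat([h_prev, x_t], axis=-1)
    z = ad.sigmoid(hx @ p.W_z + p.b_z)
    r = ad.sigmoid(hx @ p.W_r + p.b_r)
    rhx = ad.concat([r * h_prev, x_t], axis=-1)
    h_cand = ad.tanh(rhx @ p.W_h + p.b_h)
    return (1.0 - z) * h_prev + z * h_cand


class GRUCell(Module):
    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(hidden)
        d = hidden + input_size
        self.W_z = Parameter(rng.uniform(-bound, bound, (d, hidden)))
        self.W_r = Parameter(rng.uniform(-bound, bound, (d, hidden)))
        self.W_h = Parameter(rng.uniform(-bound, bound, (d, hidden)))
        self.b_z = Parameter(np.zeros(hidden))
        self.b_r = Parameter(np.zeros(hidden))
        self.b_h = Parameter(np.zeros(hidden))
        self.hidden = hidden

    def forward(self, x_t: Tensor, h_prev: Tensor) -> Tensor:
        return gru_step(x_t, h_prev, self)


class BiGRU(Module):
    """Stacked bidirectional GRU; per-step outputs concatenate both
    directions, so the feature size is 2 * hidden."""

    def __init__(
        self, input_size: int, hidden: int, n_layers: int, rng: np.random.Generator
    ):
        super().__init__()
        self.layers = []
        d = input_size
        for _ in range(n_layers):
            self.layers.append((GRUCell(d, hidden, rng), GRUCell(d, hidden, rng)))
            d = 2 * hidden
        # flatten for Module discovery
        self.cells = [c for pair in self.layers for c in pair]
        self.hidden = hidden

    def forward(self, seq: Tensor) -> Tensor:
        B, L, _ = seq.shape
        for fwd, bwd in self.layers:
            h = Tensor(np.zeros((B, fwd.hidden)))
            fwd_states = []
            for t in range(L):
                h = fwd(seq[:, t, :], h)
                fwd_states.append(h)
            h = Tensor(np.zeros((B, bwd.hidden)))
            bwd_states = [None] * L
            for t in reversed(range(L)):
                h = bwd(seq[:, t, :], h)
                bwd_states[t] = h
            steps = [
                ad.concat([f, b], axis=-1).reshape(B, 1, 2 * fwd.hidden)
                for f, b in zip(fwd_states, bwd_states)
            ]
            seq = ad.concat(steps, axis=1)
        return seq


# -- attention ---------------------------------------------------------
class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.qkv = ad.Linear(dim, 3 * dim, rng)
        self.proj = ad.Linear(dim, dim, rng)
        self.n_heads = n_heads
        self.dim = dim
        self.last_weights: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        H = self.n_heads
        dh = D // H
        qkv = self.qkv(x)  # (B, L, 3D)
        q = qkv[:, :, :D].reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, D : 2 * D].reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * D :].reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        att = ad.softmax((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh)), axis=-1)
        self.last_weights = att.data
        y = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.proj(y)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: self-attention and position-wise
    feed-forward, each wrapped in residual + layer norm."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, ff_mult: int = 4):
        super().__init__()
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.ff1 = ad.Linear(dim, ff_mult * dim, rng)
        self.ff2 = ad.Linear(ff_mult * dim, dim, rng)
        self.norm1 = ad.LayerNorm(dim)
        self.norm2 = ad.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        x = self.norm2(x + self.ff2(ad.relu(self.ff1(x))))
        return x


def sinusoidal_positions(n_pos: int, dim: int) -> np.ndarray:
    """PE(pos, 2i) = sin(pos / 10000^(2i/d)), PE(pos, 2i+1) = cos(same)."""
    pos = np.arange(n_pos)[:, None]
    i = np.arange(0, dim, 2)[None, :]
    angle = pos / 10000.0 ** (i / dim)
    pe = np.zeros((n_pos, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : pe[:, 1::2].shape[1]])
    return pe


# -- the full model ----------------------------------------------------
class HybridClassifier(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        F, T, P = cfg.in_freqs, cfg.in_frames, cfg.pool_out

        if cfg.use_cnn:
            self.conv = ad.Conv2d(cfg.in_maps, cfg.conv_filters, cfg.kernel, cfg.padding, rng)
            self.bn = ad.BatchNorm2d(cfg.conv_filters)
        else:
            # dimension-matching projection from the raw flattened tensor
            self.flat_proj = ad.Linear(cfg.in_maps * F * T, cfg.conv_filters * P * P, rng)

        seq_feat = cfg.conv_filters * P
        if cfg.use_bigru:
            self.bigru = BiGRU(seq_feat, cfg.gru_hidden, cfg.gru_layers, rng)
        else:
            self.seq_proj = ad.Linear(seq_feat, 2 * cfg.gru_hidden, rng)
        if cfg.use_residual and cfg.use_bigru:
            self.gru_skip = ad.Linear(seq_feat, 2 * cfg.gru_hidden, rng)

        # learned class token: zero plus small noise
        self.cls_token = Parameter(0.02 * rng.standard_normal((1, 1, cfg.token_dim)))
        self.pos_encoding = sinusoidal_positions(cfg.n_tokens + 1, cfg.token_dim)

        if cfg.use_transformer:
            self.encoder = [
                TransformerEncoderLayer(cfg.token_dim, cfg.n_heads, rng)
                for _ in range(cfg.encoder_layers)
            ]
        self.head = ad.Linear(cfg.token_dim, cfg.n_classes, rng)

    # stage-by-stage forward, recording intermediate shapes
    def forward(
        self, x, return_intermediates: bool = False
    ) -> Tensor | tuple[Tensor, dict]:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        cfg = self.cfg
        shapes: dict[str, tuple] = {"input": x.shape[1:]}
        B = x.shape[0]
        P = cfg.pool_out

        if cfg.use_cnn:
            maps = ad.adaptive_avg_pool2d(ad.relu(self.bn(self.conv(x))), P)
        else:
            maps = self.flat_proj(x.reshape(B, -1)).reshape(B, cfg.conv_filters, P, P)
        shapes["conv_block"] = maps.shape[1:]

        # pooled time-frame axis becomes the step axis; features are
        # (filter, pooled-frequency) row-major
        seq = maps.transpose(0, 3, 1, 2).reshape(B, P, cfg.conv_filters * P)
        shapes["sequence"] = seq.shape[1:]

        if cfg.use_bigru:
            out = self.bigru(seq)
            if cfg.use_residual:
                out = out + self.gru_skip(seq)
        else:
            out = self.seq_proj(seq)
        shapes["bigru"] = out.shape[1:]

        tokens = out.reshape(B, cfg.n_tokens, cfg.token_dim)
        shapes["tokens"] = tokens.shape[1:]

        cls = self.cls_token + Tensor(np.zeros((B, 1, cfg.token_dim)))
        tokens = ad.concat([cls, tokens], axis=1) + Tensor(self.pos_encoding)
        shapes["with_cls"] = tokens.shape[1:]

        if cfg.use_transformer:
            enc = tokens
            for layer in self.encoder:
                enc = layer(enc)
            if cfg.use_residual:
                enc = enc + tokens
        else:
            enc = tokens
        shapes["encoder"] = enc.shape[1:]

        cls_repr = enc[:, 0, :]
        shapes["cls"] = cls_repr.shape[1:]
        logits = self.head(cls_repr)
        shapes["logits"] = logits.shape[1:]
        if return_intermediates:
            return logits, shapes
        return logits

    def predict_proba(self, x) -> np.ndarray:
        self.eval()
        return ad.softmax(self.forward(x)).data

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


# -- checkpointing -----------------------------------------------------
def _named_buffers(model: HybridClassifier) -> dict[str, np.ndarray]:
    out = {}
    for i, m in enumerate(model.modules()):
        if isinstance(m, ad.BatchNorm2d):
            out[f"buf{i}.running_mean"] = m.running_mean
            out[f"buf{i}.running_var"] = m.running_var
    return out


def save_checkpoint(model: HybridClassifier, path) -> None:
    """Self-describing container: config JSON + named weight arrays."""
    arrays = {k: p.data for k, p in model.named_parameters().items()}
    arrays.update(_named_buffers(model))
    np.savez(path, __config__=json.dumps(asdict(model.cfg)), **arrays)


def load_checkpoint(path) -> HybridClassifier:
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig(**json.loads(str(z["__config__"])))
        model = HybridClassifier(cfg)
        params = model.named_parameters()
        for k, p in params.items():
            p.data = z[k].copy()
        bufs = _named_buffers(model)
        for k, arr in bufs.items():
            if k in z.files:
                arr[...] = z[k]
    return model
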