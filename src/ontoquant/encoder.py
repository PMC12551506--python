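"""A small deterministic text encoder with interchangeable FP32 and
quantized execution paths.

The encoder realizes the contracts the alignment pipeline needs from a
sentence encoder — a deterministic tokenizer with [CLS]/[SEP]/[PAD]
handling, padding and truncation to a fixed length, a layered forward
pass built purely from matmul / bias-add / relu, and mean pooling over
the sequence — while staying small enough that every number it produces
can be checked by hand.  It is positionwise (no cross-token attention):
token content plus a fixed sinusoidal positional signal flow through
seeded random linear layers.  This is a stand-in for large pretrained
transformers, which are deliberately outside this package's scope; the
operator set (matmul, add, relu) is exactly the one the quantized
execution path supports.

Weights are drawn from a seeded standard normal scaled by 1/sqrt(fan-in)
so activations stay O(1) and the int8 grid is exercised meaningfully.
Forward passes are computed one sequence at a time so results are
bit-identical regardless of how a corpus is batched.
"""

from __future__ import annotations

import functools
import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import normalize_text

__all__ = [
    "PAD_ID", "CLS_ID", "SEP_ID",
    "EncoderConfig", "TokenizedBatch", "EmbeddingMatrix", "Encoder",
    "small_config", "sinusoidal_positions", "tokenize_batch",
    "encode_batch", "encode_corpus", "mean_pool", "load_encoder",
]

PAD_ID, CLS_ID, SEP_ID = 0, 1, 2
_N_SPECIAL = 3


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the toy encoder.

    ``max_len`` defaults to 512, the sequence budget typical of the
    transformer encoders this model stands in for; desk-scale runs use
    :func:`small_config`.
    """

    vocab_size: int = 2048
    embed_dim: int = 256
    hidden_dim: int = 256
    n_layers: int = 2
    max_len: int = 512
    seed: int = 0
    mask_aware_mean: bool = False

    def __post_init__(self) -> None:
        for name in ("vocab_size", "embed_dim", "hidden_dim", "n_layers",
                     "max_len"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_len < 3:
            raise ValidationError("max_len must leave room for special tokens")
        if self.vocab_size <= _N_SPECIAL:
            raise ValidationError("vocab_size must exceed the special tokens")


def small_config(seed: int = 0, **overrides) -> EncoderConfig:
    """Desk-scale default configuration used by the synthetic pipeline:
    short sequences, 256-dimensional states, two layers."""
    params = dict(vocab_size=2048, embed_dim=256, hidden_dim=256,
                  n_layers=2, max_len=16, seed=seed)
    params.update(overrides)
    return EncoderConfig(**params)


@dataclass
class TokenizedBatch:
    """Fixed-width id grid with its padding mask.

    ``ids[:, 0]`` is always [CLS]; every row holds at least one [SEP];
    the mask is 0 exactly on [PAD] positions.
    """

    ids: np.ndarray    # int64, B x L
    mask: np.ndarray   # int8, B x L
    pair_mode: bool = False


@dataclass
class EmbeddingMatrix:
    """Stacked mean-pooled text vectors, one row per input text."""

    e: np.ndarray              # N x H
    provenance: str | None = None


@functools.lru_cache(maxsize=1 << 16)
def _token_id(token: str, vocab_size: int) -> int:
    # blake2b is stable across processes and platforms, unlike hash().
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
    return _N_SPECIAL + int.from_bytes(digest, "big") % (vocab_size - _N_SPECIAL)


def tokenize_batch(texts, cfg: EncoderConfig) -> TokenizedBatch:
    """Deterministically tokenize texts (or (A, B) text pairs).

    Normalizes, whitespace-splits and hashes each token to a stable id.
    Single texts lay out as [CLS] tokens [SEP]; pairs as
    [CLS] A [SEP] B [SEP].  Rows are truncated to ``cfg.max_len`` and
    padded with [PAD].
    """
    if not texts:
        raise ValidationError("texts must be non-empty")
    pair_flags = [isinstance(t, (tuple, list)) for t in texts]
    if any(pair_flags) and not all(pair_flags):
        raise ValidationError("cannot mix single texts and text pairs")
    pair_mode = all(pair_flags)
    L = cfg.max_len
    ids = np.full((len(texts), L), PAD_ID, dtype=np.int64)
    for i, text in enumerate(texts):
        if pair_mode:
            a, b = text
            toks_a = [_token_id(t, cfg.vocab_size)
                      for t in normalize_text(a).split()]
            toks_b = [_token_id(t, cfg.vocab_size)
                      for t in normalize_text(b).split()]
            budget = L - 3
            toks_a = toks_a[:budget]
            toks_b = toks_b[:budget - len(toks_a)]
            row = [CLS_ID] + toks_a + [SEP_ID] + toks_b + [SEP_ID]
        else:
            toks = [_token_id(t, cfg.vocab_size)
                    for t in normalize_text(text).split()]
            row = [CLS_ID] + toks[:L - 2] + [SEP_ID]
        ids[i, :len(row)] = row
    mask = (ids != PAD_ID).astype(np.int8)
    return TokenizedBatch(ids=ids, mask=mask, pair_mode=pair_mode)


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional signal, shape (max_len, dim)."""
    pos = np.arange(max_len, dtype=np.float64)[:, None]
    i = np.arange(dim, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    signal = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return signal.astype(np.float32)


@dataclass
class LinearLayer:
    W: np.ndarray      # fan_in x fan_out, float32
    b: np.ndarray      # fan_out, float32
    relu: bool


class Encoder:
    """FP32 reference encoder.

    Forward pass: token-embedding lookup plus the sinusoidal positional
    signal, then ``n_layers`` positionwise blocks of matmul -> bias-add
    -> relu (the final block omits relu), then mean pooling over the
    sequence.
    """

    kind = "fp32"

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.token_emb = rng.standard_normal(
            (config.vocab_size, config.embed_dim)).astype(np.float32)
        self.pos = sinusoidal_positions(config.max_len, config.embed_dim)
        self.layers: list[LinearLayer] = []
        fan_in = config.embed_dim
        for l in range(config.n_layers):
            W = (rng.standard_normal((fan_in, config.hidden_dim))
                 / math.sqrt(fan_in)).astype(np.float32)
            b = (0.1 * rng.standard_normal(config.hidden_dim)).astype(np.float32)
            self.layers.append(LinearLayer(W=W, b=b,
                                           relu=l < config.n_layers - 1))
            fan_in = config.hidden_dim

    # -- forward ----------------------------------------------------------

    def embed(self, batch: TokenizedBatch) -> np.ndarray:
        """Pre-layer activations: embedding lookup + positional signal."""
        self._check_batch(batch)
        return self.token_emb[batch.ids] + self.pos[None, :, :]

    def hidden_states(self, batch: TokenizedBatch) -> np.ndarray:
        """Final-layer hidden states, shape (B, L, H).

        Sequences are processed one at a time so the result is
        bit-identical for any batch partition of the same corpus.
        """
        h0 = self.embed(batch)
        B, L = batch.ids.shape
        out = np.empty((B, L, self.config.hidden_dim), dtype=np.float32)
        for i in range(B):
            X = h0[i]
            for layer in self.layers:
                X = X @ layer.W + layer.b
                if layer.relu:
                    X = np.maximum(X, 0.0)
            out[i] = X
        return out

    def linear_inputs(self, texts) -> list[np.ndarray]:
        """Per-layer input activations over all tokens of ``texts``
        (rows = tokens, columns = input channels).  Used for calibration."""
        batch = tokenize_batch(texts, self.config)
        h = self.embed(batch).astype(np.float64)
        outs: list[np.ndarray] = []
        for layer in self.layers:
            outs.append(h.reshape(-1, h.shape[-1]))
            h = h @ layer.W + layer.b
            if layer.relu:
                h = np.maximum(h, 0.0)
        return outs

    # -- bookkeeping ------------------------------------------------------

    def _check_batch(self, batch: TokenizedBatch) -> None:
        if batch.ids.shape[1] != self.config.max_len:
            raise ValidationError(
                f"batch width {batch.ids.shape[1]} != max_len "
                f"{self.config.max_len}")
        if batch.ids.max() >= self.config.vocab_size:
            raise ValidationError("token id outside vocabulary")

    def weight_payload_bytes(self) -> int:
        """Serialized size of the linear-layer weight matrices (float32)."""
        return int(sum(layer.W.nbytes for layer in self.layers))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self.config), sort_keys=True).encode()
        ).hexdigest()

    def save(self, path: str | Path) -> None:
        """Serialize weights and config into a single archive."""
        arrays = {"kind": np.array(self.kind),
                  "config": np.array(json.dumps(asdict(self.config))),
                  "config_hash": np.array(self.config_hash()),
                  "token_emb": self.token_emb}
        for l, layer in enumerate(self.layers):
            arrays[f"W{l}"] = layer.W
            arrays[f"b{l}"] = layer.b
        np.savez(path, **arrays)


def load_encoder(path: str | Path) -> Encoder:
    """Load an FP32 encoder archive written by :meth:`Encoder.save`."""
    with np.load(path) as data:
        if str(data["kind"][()]) != "fp32":
            raise ValidationError("archive does not hold an FP32 encoder")
        config = EncoderConfig(**json.loads(str(data["config"][()])))
        enc = Encoder(config)
        enc.token_emb = data["token_emb"]
        for l, layer in enumerate(enc.layers):
            layer.W = data[f"W{l}"]
            layer.b = data[f"b{l}"]
    return enc


# ---------------------------------------------------------------------------
# Pooling and corpus encoding


def mean_pool(h: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Mean over the sequence axis of (B, L, H) hidden states.

    Without a mask this is the literal full-length mean, padding
    positions included; with a mask only unpadded positions contribute.
    """
    if mask is None:
        return h.mean(axis=1)
    w = mask.astype(h.dtype)[:, :, None]
    return (h * w).sum(axis=1) / w.sum(axis=1)


def encode_batch(batch: TokenizedBatch, model) -> np.ndarray:
    """Encode one tokenized batch into per-text embedding rows (B, H)."""
    h = model.hidden_states(batch)
    if getattr(model.config, "mask_aware_mean", False):
        return mean_pool(h, batch.mask)
    return mean_pool(h)


def encode_corpus(texts, model, batch_size: int = 10,
                  provenance: str | None = None) -> EmbeddingMatrix:
    """Encode a corpus in batches of ``batch_size`` and stack the rows.

    The partition into ceil(N / B) batches never changes the values:
    embeddings are identical for any batch size.
    """
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    texts = list(texts)
    if not texts:
        raise ValidationError("corpus must be non-empty")
    blocks = []
    for start in range(0, len(texts), batch_size):
        chunk = texts[start:start + batch_size]
        blocks.append(encode_batch(tokenize_batch(chunk, model.config), model))
    return EmbeddingMatrix(e=np.vstack(blocks), provenance=provenance)
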