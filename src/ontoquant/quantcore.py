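"""Simulated INT8 (W8A8) quantization arithmetic.

This module implements symmetric signed-int8 quantization on the grid
[-127, 127] with zero-point 0, in two granularities:

* **per-tensor** — one scale ``s = maxabs(x) / 127`` for the whole
  tensor (used dynamically for activations, one scale per sequence);
* **per-channel** — one scale per channel along a chosen axis (used for
  weights, along the output-column axis).

Linear layers execute with genuine integer accumulation:
``y_int = q_x @ q_W`` in int64 (exact), then a float rescale by the
product of the operand scales.  When the activation scales vary along
the contraction axis (per-channel activations), the scales cannot be
factored out of the accumulation and the combination is rejected as
non-dequantizable.

Activation outliers are handled by smoothing-factor redistribution: a
per-input-channel vector ``s_j = maxabs(X_j)^alpha / maxabs(W_j)^(1-alpha)``
divides the activations and multiplies the corresponding weight rows,
leaving the layer's product mathematically unchanged while migrating
range difficulty from activations into the weights.  ``alpha = 0.5``
splits the difficulty evenly and is the default.

Everything is simulated in ordinary NumPy arithmetic — no hardware
kernels.  The goal is desk-scale verifiability, not speed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import SchemeCombinationError, ValidationError

__all__ = [
    "GRID_MAX", "QuantScheme", "QuantizedTensor", "SmoothingConfig",
    "ActivationStats", "quantize", "dequantize", "qlinear_matmul",
    "qlinear_elementwise", "collect_activation_stats",
    "compute_smoothing_scales", "apply_smoothing", "QuantizedLinear",
    "QuantizedEncoder", "quantize_encoder", "save_quantized",
    "load_quantized", "PER_TENSOR", "per_channel",
]

GRID_MAX = 127


@dataclass(frozen=True)
class QuantScheme:
    """Granularity, channel axis and bit width of a quantization."""

    granularity: Literal["per_tensor", "per_channel"]
    axis: int | None = None
    bits: int = 8
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.granularity not in ("per_tensor", "per_channel"):
            raise ValidationError(f"unknown granularity {self.granularity!r}")
        if self.bits != 8:
            raise ValidationError("only 8-bit quantization is supported")
        if not self.symmetric:
            raise ValidationError("only symmetric quantization is supported")
        if (self.axis is None) == (self.granularity == "per_channel"):
            raise ValidationError(
                "axis must be given exactly for per_channel schemes")


PER_TENSOR = QuantScheme("per_tensor")


def per_channel(axis: int) -> QuantScheme:
    return QuantScheme("per_channel", axis=axis)


@dataclass
class QuantizedTensor:
    """Integer grid plus scale(s): the unit of all W8A8 arithmetic."""

    q: np.ndarray           # int8 grid, |q| <= 127
    scales: np.ndarray      # scalar () for per_tensor, (C,) for per_channel
    scheme: QuantScheme
    shape: tuple[int, ...]

    def broadcast_scales(self) -> np.ndarray:
        if self.scheme.granularity == "per_tensor":
            return self.scales
        shape = [1] * self.q.ndim
        shape[self.scheme.axis] = -1
        return self.scales.reshape(shape)


def quantize(x: np.ndarray, scheme: QuantScheme = PER_TENSOR,
             epsilon: float = 1e-12) -> QuantizedTensor:
    """Quantize a real tensor onto the symmetric int8 grid.

    Per-tensor: one scale maxabs(x)/127 (``epsilon`` for an all-zero
    tensor).  Per-channel: one such scale per slice along the scheme's
    axis.  Values are divided by the scale, rounded half-to-even and
    clamped to [-127, 127].
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValidationError("input tensor must be finite")
    if scheme.granularity == "per_tensor":
        m = float(np.max(np.abs(x))) if x.size else 0.0
        scales = np.float64(m / GRID_MAX if m > 0 else epsilon)
        denom = scales
    else:
        if not -x.ndim <= scheme.axis < x.ndim:
            raise ValidationError(
                f"axis {scheme.axis} invalid for shape {x.shape}")
        axis = scheme.axis % x.ndim
        other = tuple(i for i in range(x.ndim) if i != axis)
        m = np.abs(x).max(axis=other)
        scales = np.where(m > 0, m / GRID_MAX, epsilon)
        shape = [1] * x.ndim
        shape[axis] = -1
        denom = scales.reshape(shape)
    q = np.clip(np.rint(x / denom), -GRID_MAX, GRID_MAX).astype(np.int8)
    return QuantizedTensor(q=q, scales=scales, scheme=scheme, shape=x.shape)


def dequantize(t: QuantizedTensor) -> np.ndarray:
    """Map a quantized tensor back to floats: q times its scale(s).

    The round trip satisfies ``|x - dequantize(quantize(x))| <= scale/2``
    elementwise (up to float epsilon).
    """
    return t.q.astype(np.float64) * t.broadcast_scales()


def qlinear_matmul(xq: QuantizedTensor, Wq: QuantizedTensor) -> np.ndarray:
    """Quantized linear matmul with exact integer accumulation.

    Activations must be per-tensor quantized; weights may be per-tensor
    or per-channel along their output-column (last) axis.  The result is
    ``(q_x @ q_W) * s_x * s_j`` and equals the real product of the two
    dequantized operands up to float rounding.

    A per-channel activation operand, or weights quantized per-channel
    along the contraction axis, leave scales inside the accumulation and
    raise :class:`SchemeCombinationError`.
    """
    if xq.scheme.granularity == "per_channel":
        raise SchemeCombinationError(
            "non-dequantizable scheme combination: per-channel activation "
            "scales vary along the contraction axis and cannot be factored "
            "out of the integer accumulation")
    if Wq.scheme.granularity == "per_channel":
        if Wq.scheme.axis % Wq.q.ndim != Wq.q.ndim - 1:
            raise SchemeCombinationError(
                "non-dequantizable scheme combination: weight scales on the "
                "contraction axis cannot be factored out of the integer "
                "accumulation")
    if xq.q.shape[-1] != Wq.q.shape[0]:
        raise ValidationError(
            f"inner dimensions disagree: {xq.q.shape} @ {Wq.q.shape}")
    y_int = xq.q.astype(np.int64) @ Wq.q.astype(np.int64)
    return y_int * float(xq.scales) * Wq.scales


def qlinear_elementwise(a, b=None, op: Literal["add", "relu"] = "add"
                        ) -> np.ndarray:
    """Elementwise add / relu with dequantize-then-apply semantics."""
    def deq(t):
        return dequantize(t) if isinstance(t, QuantizedTensor) else \
            np.asarray(t, dtype=np.float64)

    if op == "relu":
        if b is not None:
            raise ValidationError("relu takes a single operand")
        return np.maximum(deq(a), 0.0)
    if op == "add":
        if b is None:
            raise ValidationError("add requires two operands")
        av, bv = deq(a), deq(b)
        try:
            np.broadcast_shapes(av.shape, bv.shape)
        except ValueError as exc:
            raise ValidationError(
                f"shapes not broadcastable: {av.shape} vs {bv.shape}") from exc
        return av + bv
    raise ValidationError(f"unknown op {op!r}")


# ---------------------------------------------------------------------------
# Calibration and smoothing


@dataclass
class ActivationStats:
    """Per-input-channel activation statistics from a calibration pass."""

    per_channel_maxabs: np.ndarray
    per_channel_variance: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if self.per_channel_maxabs.shape != self.per_channel_variance.shape:
            raise ValidationError("stats vectors must have equal length")
        if np.any(self.per_channel_maxabs < 0):
            raise ValidationError("maxabs must be non-negative")


@dataclass(frozen=True)
class SmoothingConfig:
    """Smoothing factor alpha in [0, 1] and a positive scale floor."""

    alpha: float = 0.5
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")


def collect_activation_stats(encoder, calibration_texts) -> list[ActivationStats]:
    """Run the FP32 forward pass over calibration texts and record, for
    every linear layer, the per-input-channel maxabs and variance over
    all calibration tokens."""
    calibration_texts = list(calibration_texts)
    if not calibration_texts:
        raise ValidationError("calibration set must be non-empty")
    stats = []
    for A in encoder.linear_inputs(calibration_texts):
        stats.append(ActivationStats(
            per_channel_maxabs=np.abs(A).max(axis=0),
            per_channel_variance=A.var(axis=0),
            n_samples=A.shape[0]))
    return stats


def compute_smoothing_scales(stats: ActivationStats, W: np.ndarray,
                             cfg: SmoothingConfig = SmoothingConfig()
                             ) -> np.ndarray:
    """Per-input-channel smoothing scales.

    ``s_j = max(maxabs_X_j, eps)^alpha / max(maxabs_W_row_j, eps)^(1-alpha)``
    where row j of W consumes input channel j.  alpha = 1 puts the whole
    burden on the activations' side, alpha = 0 on the weights'.
    """
    W = np.asarray(W, dtype=np.float64)
    if stats.per_channel_maxabs.shape[0] != W.shape[0]:
        raise ValidationError(
            f"stats cover {stats.per_channel_maxabs.shape[0]} channels but "
            f"W has {W.shape[0]} input rows")
    x_max = np.maximum(stats.per_channel_maxabs, cfg.epsilon)
    w_max = np.maximum(np.abs(W).max(axis=1), cfg.epsilon)
    return x_max ** cfg.alpha / w_max ** (1.0 - cfg.alpha)


def apply_smoothing(X: np.ndarray, W: np.ndarray, s: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Divide activation columns and multiply weight rows by ``s``.

    Exact in exact arithmetic: ``X' W' = X W``; in floats the relative
    error stays below 1e-6.
    """
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if np.any(s <= 0):
        raise ValidationError("smoothing scales must be strictly positive")
    if s.shape[0] != X.shape[-1] or s.shape[0] != W.shape[0]:
        raise ValidationError("smoothing vector length must match the "
                              "shared inner dimension")
    return X / s, W * s[:, None]


# ---------------------------------------------------------------------------
# Quantized encoder


@dataclass
class QuantizedLinear:
    """One linear layer of the quantized model: int8 weights, FP bias,
    optional smoothing vector, and whether a relu follows."""

    Wq: QuantizedTensor
    bias: np.ndarray
    smooth: np.ndarray | None
    relu: bool


class QuantizedEncoder:
    """W8A8 execution path of the toy encoder.

    Embedding lookup and positional signal stay in FP32 (they are table
    reads, not matmuls).  Every linear layer holds smoothed, int8
    weights; activations are quantized dynamically per-tensor, with one
    scale per individual sequence so results are batch-size invariant.
    The forward pass routes exclusively through :func:`qlinear_matmul`
    and :func:`qlinear_elementwise`.
    """

    kind = "int8"

    def __init__(self, config, token_emb: np.ndarray, pos: np.ndarray,
                 layers: list[QuantizedLinear],
                 weight_scheme: QuantScheme,
                 smoothing: SmoothingConfig | None):
        self.config = config
        self.token_emb = token_emb
        self.pos = pos
        self.layers = layers
        self.weight_scheme = weight_scheme
        self.smoothing = smoothing

    def embed(self, batch) -> np.ndarray:
        if batch.ids.shape[1] != self.config.max_len:
            raise ValidationError(
                f"batch width {batch.ids.shape[1]} != max_len "
                f"{self.config.max_len}")
        return self.token_emb[batch.ids] + self.pos[None, :, :]

    def hidden_states(self, batch) -> np.ndarray:
        h0 = self.embed(batch)
        B, L = batch.ids.shape
        H = self.layers[-1].Wq.q.shape[1]
        out = np.empty((B, L, H), dtype=np.float64)
        for i in range(B):
            X = h0[i].astype(np.float64)
            for layer in self.layers:
                if layer.smooth is not None:
                    X = X / layer.smooth
                xq = quantize(X, PER_TENSOR)
                Y = qlinear_matmul(xq, layer.Wq)
                Y = qlinear_elementwise(Y, layer.bias, op="add")
                if layer.relu:
                    Y = qlinear_elementwise(Y, op="relu")
                X = Y
            out[i] = X
        return out

    def weight_payload_bytes(self) -> int:
        """Serialized weight payload: int8 grids plus float32 scale and
        smoothing vectors."""
        total = 0
        for layer in self.layers:
            total += layer.Wq.q.nbytes
            total += int(np.asarray(layer.Wq.scales).size) * 4
            if layer.smooth is not None:
                total += layer.smooth.size * 4
        return total

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self.config), sort_keys=True).encode()
        ).hexdigest()


def quantize_encoder(encoder, calibration_texts,
                     scheme: QuantScheme | None = None,
                     smoothing: SmoothingConfig | None = None
                     ) -> QuantizedEncoder:
    """Build the W8A8 twin of an FP32 encoder.

    Calibration texts drive one FP32 forward pass to collect per-layer
    activation statistics; with a :class:`SmoothingConfig` these yield
    per-channel smoothing vectors folded into the weights before
    quantization.  ``scheme`` picks the weight granularity (default:
    per-channel along output columns).
    """
    if scheme is None:
        scheme = per_channel(axis=1)
    stats = collect_activation_stats(encoder, calibration_texts)
    qlayers: list[QuantizedLinear] = []
    for layer_stats, layer in zip(stats, encoder.layers):
        W = layer.W.astype(np.float64)
        smooth = None
        if smoothing is not None:
            smooth = compute_smoothing_scales(layer_stats, W, smoothing)
            W = W * smooth[:, None]
        qlayers.append(QuantizedLinear(
            Wq=quantize(W, scheme),
            bias=layer.b.astype(np.float64),
            smooth=smooth,
            relu=layer.relu))
    return QuantizedEncoder(config=encoder.config,
                            token_emb=encoder.token_emb,
                            pos=encoder.pos,
                            layers=qlayers,
                            weight_scheme=scheme,
                            smoothing=smoothing)


# ---------------------------------------------------------------------------
# Serialization (versioned archive layout, see docs/methods.md)

_ARCHIVE_VERSION = 1


def save_quantized(qenc: QuantizedEncoder, path: str | Path) -> None:
    """Serialize a quantized encoder: integer grids, scale vectors,
    scheme metadata and a config hash, in one archive."""
    arrays = {
        "kind": np.array(qenc.kind),
        "version": np.array(_ARCHIVE_VERSION),
        "config": np.array(json.dumps(asdict(qenc.config))),
        "config_hash": np.array(qenc.config_hash()),
        "scheme": np.array(json.dumps(asdict(qenc.weight_scheme))),
        "smoothing": np.array(json.dumps(
            asdict(qenc.smoothing) if qenc.smoothing is not None else None)),
        "token_emb": qenc.token_emb,
        "relu": np.array([layer.relu for layer in qenc.layers]),
    }
    for l, layer in enumerate(qenc.layers):
        arrays[f"q{l}"] = layer.Wq.q
        arrays[f"scales{l}"] = np.atleast_1d(layer.Wq.scales).astype(np.float32)
        arrays[f"bias{l}"] = layer.bias.astype(np.float32)
        arrays[f"smooth{l}"] = (np.zeros(0, np.float32) if layer.smooth is None
                                else layer.smooth.astype(np.float32))
    np.savez(path, **arrays)


def load_quantized(path: str | Path) -> QuantizedEncoder:
    from .encoder import EncoderConfig, sinusoidal_positions

    with np.load(path) as data:
        if str(data["kind"][()]) != "int8":
            raise ValidationError("archive does not hold a quantized encoder")
        config = EncoderConfig(**json.loads(str(data["config"][()])))
        scheme = QuantScheme(**json.loads(str(data["scheme"][()])))
        smooth_cfg = json.loads(str(data["smoothing"][()]))
        smoothing = SmoothingConfig(**smooth_cfg) if smooth_cfg else None
        relu = data["relu"]
        layers = []
        for l in range(config.n_layers):
            scales = data[f"scales{l}"].astype(np.float64)
            if scheme.granularity == "per_tensor":
                scales = np.float64(scales[0])
            smooth = data[f"smooth{l}"].astype(np.float64)
            layers.append(QuantizedLinear(
                Wq=QuantizedTensor(q=data[f"q{l}"], scales=scales,
                                   scheme=scheme,
                                   shape=data[f"q{l}"].shape),
                bias=data[f"bias{l}"].astype(np.float64),
                smooth=smooth if smooth.size else None,
                relu=bool(relu[l])))
        return QuantizedEncoder(
            config=config, token_emb=data["token_emb"],
            pos=sinusoidal_positions(config.max_len, config.embed_dim),
            layers=layers, weight_scheme=scheme, smoothing=smoothing)
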