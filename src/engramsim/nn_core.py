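"""Minimal convolutional-network engine.

Implements, in plain NumPy, the small classifier used throughout this
package to model memory formation: two valid (no-padding) convolution
layers with 2x2 max pooling, global max pooling to a per-channel latent
vector, one fully connected hidden layer, and a class-score output layer.
For 28x28x1 input at the default shapes the feature maps are exactly
26x26x32 -> 13x13x32 -> 11x11x64 -> 5x5x64 -> 64 -> 100 -> n_classes.

The engine is deliberately explicit: forward passes return a cache of
every intermediate (including pooling argmax records), and the backward
pass is checked against central finite differences by
:func:`gradient_check`.  All arithmetic is float64.

Only plain stochastic gradient descent is provided; dropout — the one
regularizer this package studies — lives in :mod:`engramsim.engram_dropout`.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "LayerShapes",
    "LossSpec",
    "NetworkParams",
    "ForwardCache",
    "init_network",
    "conv2d_forward",
    "conv2d_backward",
    "relu",
    "maxpool2x2_forward",
    "maxpool2x2_backward",
    "global_maxpool_forward",
    "global_maxpool_backward",
    "dense_forward",
    "loss_and_output",
    "batch_loss",
    "forward_pass",
    "backward_pass",
    "sgd_update",
    "gradient_check",
    "save_params",
    "load_params",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent layer shapes or invalid hyperparameters."""


@dataclass(frozen=True)
class LayerShapes:
    """Architecture hyperparameters.

    Defaults give the study architecture for 28x28 single-channel glyphs.
    The reduced configurations used by the gradient-check oracle shrink
    ``input_hw``/``kernel`` and may disable the intermediate poolings.
    """

    input_hw: int = 28
    in_channels: int = 1
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: int = 3
    pool_after_conv1: bool = True
    pool_after_conv2: bool = True
    fc_units: int = 100

    def feature_chain(self) -> list[tuple[int, int, int]]:
        """Spatial/channel shape after each stage, validating feasibility.

        Returns [(h, w, c) after conv1, after pool1, after conv2, after
        pool2]; pooling stages that are disabled repeat the previous shape.
        """
        h = self.input_hw
        chain = []
        h1 = h - self.kernel + 1
        if h1 < 1:
            raise ConfigurationError(
                f"kernel {self.kernel} larger than input {h}"
            )
        chain.append((h1, h1, self.conv1_filters))
        p1 = h1 // 2 if self.pool_after_conv1 else h1
        if self.pool_after_conv1 and h1 < 2:
            raise ConfigurationError("spatial dim < 2 before 2x2 pooling")
        chain.append((p1, p1, self.conv1_filters))
        h2 = p1 - self.kernel + 1
        if h2 < 1:
            raise ConfigurationError(
                f"kernel {self.kernel} larger than {p1}x{p1} feature map"
            )
        chain.append((h2, h2, self.conv2_filters))
        p2 = h2 // 2 if self.pool_after_conv2 else h2
        if self.pool_after_conv2 and h2 < 2:
            raise ConfigurationError("spatial dim < 2 before 2x2 pooling")
        chain.append((p2, p2, self.conv2_filters))
        return chain

    @property
    def latent_dim(self) -> int:
        # global max pooling keeps one feature per conv2 channel
        return self.conv2_filters


@dataclass(frozen=True)
class LossSpec:
    """Loss variant and numerical guard.

    ``sigmoid_bce`` (default): independent per-class sigmoid outputs
    scored against a one-hot target with mean binary cross-entropy.
    ``softmax_ce``: softmax output with categorical cross-entropy.
    Probabilities are clipped to [clip_epsilon, 1 - clip_epsilon] so the
    loss stays finite at saturated outputs; the reported gradient is the
    exact gradient of the clipped loss (zero where the clip is active).
    """

    variant: Literal["sigmoid_bce", "softmax_ce"] = "sigmoid_bce"
    clip_epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 < self.clip_epsilon <= 0.01:
            raise ConfigurationError("clip_epsilon must be in (0, 0.01]")


@dataclass
class NetworkParams:
    """All trainable weights and biases, plus shape metadata.

    Weight layouts: conv weights are (kh, kw, c_in, c_out); dense weights
    are (n_in, n_out); biases are one-dimensional per output unit.
    """

    shapes: LayerShapes
    n_classes: int
    init_seed: int
    conv1_w: np.ndarray
    conv1_b: np.ndarray
    conv2_w: np.ndarray
    conv2_b: np.ndarray
    fc_w: np.ndarray
    fc_b: np.ndarray
    out_w: np.ndarray
    out_b: np.ndarray

    _ARRAYS = ("conv1_w", "conv1_b", "conv2_w", "conv2_b",
               "fc_w", "fc_b", "out_w", "out_b")

    def arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._ARRAYS}

    def copy(self) -> "NetworkParams":
        return replace(self, **{k: v.copy() for k, v in self.arrays().items()})

    def allclose(self, other: "NetworkParams") -> bool:
        return all(
            np.array_equal(getattr(self, n), getattr(other, n))
            for n in self._ARRAYS
        )


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def init_network(shapes: LayerShapes, n_classes: int, seed: int,
                 dtype: np.dtype = np.float64) -> NetworkParams:
    """Seeded fan-in-scaled uniform initialization with zero biases.

    Deterministic: the same (shapes, n_classes, seed) always yields
    bit-identical parameters.  ``dtype`` sets the working precision of
    the whole network (float32 roughly halves training time; float64 is
    the default and what the finite-difference oracle requires).
    """
    if n_classes < 2:
        raise ConfigurationError(f"n_classes must be >= 2, got {n_classes}")
    shapes.feature_chain()  # validates kernel vs input
    rng = np.random.default_rng(seed)
    k, c_in = shapes.kernel, shapes.in_channels
    f1, f2 = shapes.conv1_filters, shapes.conv2_filters
    latent, fc = shapes.latent_dim, shapes.fc_units
    return NetworkParams(
        shapes=shapes,
        n_classes=n_classes,
        init_seed=seed,
        conv1_w=_he_uniform(rng, (k, k, c_in, f1), k * k * c_in).astype(dtype),
        conv1_b=np.zeros(f1, dtype=dtype),
        conv2_w=_he_uniform(rng, (k, k, f1, f2), k * k * f1).astype(dtype),
        conv2_b=np.zeros(f2, dtype=dtype),
        fc_w=_he_uniform(rng, (latent, fc), latent).astype(dtype),
        fc_b=np.zeros(fc, dtype=dtype),
        out_w=_he_uniform(rng, (fc, n_classes), fc).astype(dtype),
        out_b=np.zeros(n_classes, dtype=dtype),
    )


# ---------------------------------------------------------------------------
# layer primitives


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0)."""
    return np.maximum(x, 0.0)


def _conv_patches(x: np.ndarray, k: int) -> np.ndarray:
    # (N, H', W', C, k, k) view over valid kernel placements
    return sliding_window_view(x, (k, k), axis=(1, 2))


def _conv_cols(x: np.ndarray, k: int) -> np.ndarray:
    # (N*H'*W', C_in*k*k) patch matrix; the copy here dominates conv cost,
    # so forward passes cache it for reuse in backward
    patches = _conv_patches(x, k)
    n, hp, wp = patches.shape[:3]
    return patches.reshape(n * hp * wp, -1)


def conv2d_forward(x: np.ndarray, weights: np.ndarray,
                   biases: np.ndarray,
                   cols: np.ndarray | None = None) -> np.ndarray:
    """Valid-mode cross-correlation.

    x: (N, H, W, C_in); weights: (k, k, C_in, C_out); biases: (C_out,).
    Output spatial dims shrink by kernel - 1.
    """
    k = weights.shape[0]
    n, h, w, c_in = x.shape
    if k > h or k > w:
        raise ConfigurationError(f"kernel {k} larger than input {h}x{w}")
    hp, wp = h - k + 1, w - k + 1
    if cols is None:
        cols = _conv_cols(x, k)
    # weight rows match patch layout (C_in, k, k)
    w_mat = weights.transpose(2, 0, 1, 3).reshape(c_in * k * k, -1)
    out = cols @ w_mat
    return out.reshape(n, hp, wp, -1) + biases


def conv2d_backward(x: np.ndarray, weights: np.ndarray, d_out: np.ndarray,
                    need_dx: bool = True, cols: np.ndarray | None = None):
    """Gradients of a valid convolution: (d_weights, d_biases, d_x)."""
    k = weights.shape[0]
    n, h, w, c_in = x.shape
    hp, wp, c_out = d_out.shape[1], d_out.shape[2], d_out.shape[3]
    if cols is None:
        cols = _conv_cols(x, k)
    d_flat = d_out.reshape(n * hp * wp, c_out)
    d_w = (cols.T @ d_flat).reshape(c_in, k, k, c_out).transpose(1, 2, 0, 3)
    d_b = d_flat.sum(axis=0)
    d_x = None
    if need_dx:
        w_mat = weights.transpose(2, 0, 1, 3).reshape(c_in * k * k, c_out)
        d_cols = (d_flat @ w_mat.T).reshape(n, hp, wp, c_in, k, k)
        d_x = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                d_x[:, i:i + hp, j:j + wp, :] += d_cols[:, :, :, :, i, j]
    return d_w, d_b, d_x


def maxpool2x2_forward(x: np.ndarray):
    """Non-overlapping 2x2 max pooling, stride 2.

    Odd trailing rows/columns are dropped (floor division), which is what
    takes an 11x11 map to 5x5.  Returns (pooled, argmax) where argmax
    holds, per output cell and channel, the winning index 0..3 within its
    2x2 window (row-major; ties break to the lowest index, matching
    ``np.argmax``) — enough to route gradients back.
    """
    n, h, w, c = x.shape
    if h < 2 or w < 2:
        raise ConfigurationError(f"spatial dims {h}x{w} too small for 2x2 pool")
    h2, w2 = h // 2, w // 2
    # strided views of the four window corners avoid any large copy
    tl = x[:, 0:2 * h2:2, 0:2 * w2:2, :]
    tr = x[:, 0:2 * h2:2, 1:2 * w2:2, :]
    bl = x[:, 1:2 * h2:2, 0:2 * w2:2, :]
    br = x[:, 1:2 * h2:2, 1:2 * w2:2, :]
    top = np.maximum(tl, tr)
    bot = np.maximum(bl, br)
    pooled = np.maximum(top, bot)
    arg = np.where(bot > top, 2 + (br > bl), (tr > tl).astype(np.int8))
    return pooled, arg.astype(np.int8, copy=False)


def maxpool2x2_backward(d_pooled: np.ndarray, arg: np.ndarray,
                        input_shape: tuple[int, ...]) -> np.ndarray:
    """Scatter pooled gradients back to the argmax positions only."""
    n, h, w, c = input_shape
    h2, w2 = d_pooled.shape[1], d_pooled.shape[2]
    d_x = np.zeros(input_shape, dtype=d_pooled.dtype)
    for k, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        d_x[:, i:2 * h2:2, j:2 * w2:2, :] = d_pooled * (arg == k)
    return d_x


def global_maxpool_forward(x: np.ndarray):
    """Maximum over all spatial positions per channel.

    Returns (latent, argmax) with latent of shape (N, C) and argmax the
    flat spatial index of each winning position.
    """
    n, h, w, c = x.shape
    flat = x.reshape(n, h * w, c)
    arg = flat.argmax(axis=1)
    latent = np.take_along_axis(flat, arg[:, None, :], axis=1)[:, 0, :]
    return latent, arg


def global_maxpool_backward(d_latent: np.ndarray, arg: np.ndarray,
                            input_shape: tuple[int, ...]) -> np.ndarray:
    n, h, w, c = input_shape
    d_flat = np.zeros((n, h * w, c), dtype=d_latent.dtype)
    np.put_along_axis(d_flat, arg[:, None, :], d_latent[:, None, :], axis=1)
    return d_flat.reshape(input_shape)


def dense_forward(x: np.ndarray, weights: np.ndarray,
                  biases: np.ndarray) -> np.ndarray:
    """Affine map x @ W + b; accepts (N, n_in) or a single (n_in,) vector."""
    if x.shape[-1] != weights.shape[0]:
        raise ConfigurationError(
            f"dense input width {x.shape[-1]} != weight rows {weights.shape[0]}"
        )
    return x @ weights + biases


# ---------------------------------------------------------------------------
# loss


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def batch_loss(logits: np.ndarray, labels: np.ndarray, spec: LossSpec):
    """Mean loss over a batch plus probabilities and the logit gradient.

    Returns (loss, probs, d_logits) where d_logits is the gradient of the
    batch-mean loss (mean over samples, and over classes for the sigmoid
    variant) with respect to the logits.
    """
    n, k = logits.shape
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("target class out of range")
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    eps = spec.clip_epsilon
    if spec.variant == "sigmoid_bce":
        p = _sigmoid(logits)
        pc = np.clip(p, eps, 1.0 - eps)
        loss = -(onehot * np.log(pc) + (1.0 - onehot) * np.log1p(-pc))
        active = (p > eps) & (p < 1.0 - eps)  # clip inactive
        d_logits = np.where(active, p - onehot, 0.0) / (n * k)
        return loss.mean(), p, d_logits
    elif spec.variant == "softmax_ce":
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        pt = p[np.arange(n), labels]
        loss = -np.log(np.clip(pt, eps, 1.0))
        active = pt > eps
        d_logits = (p - onehot) * (active[:, None] / n)
        return loss.mean(), p, d_logits
    raise ConfigurationError(f"unknown loss variant {spec.variant!r}")


def loss_and_output(logits: np.ndarray, target_class: int, spec: LossSpec):
    """Single-sample loss and probability vector.

    The predicted class is the argmax of the returned probabilities.
    """
    loss, probs, _ = batch_loss(np.asarray(logits, dtype=float)[None, :],
                                np.asarray([target_class]), spec)
    return loss, probs[0]


# ---------------------------------------------------------------------------
# full network forward / backward


@dataclass
class ForwardCache:
    """Every intermediate needed by the backward pass."""

    x: np.ndarray
    cols1: np.ndarray
    cols2: np.ndarray
    z1: np.ndarray
    a1: np.ndarray
    p1: np.ndarray
    arg1: np.ndarray | None
    z2: np.ndarray
    a2: np.ndarray
    p2: np.ndarray
    arg2: np.ndarray | None
    latent: np.ndarray
    arg_g: np.ndarray
    z_fc: np.ndarray
    a_fc: np.ndarray
    a_drop: np.ndarray
    drop_scale: np.ndarray | None  # per-unit multiplier actually applied
    logits: np.ndarray


def forward_pass(params: NetworkParams, x: np.ndarray,
                 drop_multiplier: np.ndarray | None = None) -> ForwardCache:
    """Run the network on a batch, recording all intermediates.

    ``drop_multiplier`` — a per-unit multiplier over the fully connected
    layer (0 for dropped units, 1/(1-rate) for kept units under inverted
    dropout) — is applied to the FC activations when given.  Without it
    the pass is fully deterministic.
    """
    sh = params.shapes
    x = np.asarray(x, dtype=params.conv1_w.dtype)
    k = sh.kernel
    if k > x.shape[1] or k > x.shape[2]:
        raise ConfigurationError(
            f"kernel {k} larger than input {x.shape[1]}x{x.shape[2]}")
    cols1 = _conv_cols(x, k)
    z1 = conv2d_forward(x, params.conv1_w, params.conv1_b, cols=cols1)
    a1 = relu(z1)
    if sh.pool_after_conv1:
        p1, arg1 = maxpool2x2_forward(a1)
    else:
        p1, arg1 = a1, None
    cols2 = _conv_cols(p1, k)
    z2 = conv2d_forward(p1, params.conv2_w, params.conv2_b, cols=cols2)
    a2 = relu(z2)
    if sh.pool_after_conv2:
        p2, arg2 = maxpool2x2_forward(a2)
    else:
        p2, arg2 = a2, None
    latent, arg_g = global_maxpool_forward(p2)
    z_fc = dense_forward(latent, params.fc_w, params.fc_b)
    a_fc = relu(z_fc)
    if drop_multiplier is not None:
        drop_multiplier = np.asarray(drop_multiplier, dtype=a_fc.dtype)
        a_drop = a_fc * drop_multiplier
    else:
        a_drop = a_fc
    logits = dense_forward(a_drop, params.out_w, params.out_b)
    return ForwardCache(x=x, cols1=cols1, cols2=cols2,
                        z1=z1, a1=a1, p1=p1, arg1=arg1, z2=z2, a2=a2,
                        p2=p2, arg2=arg2, latent=latent, arg_g=arg_g,
                        z_fc=z_fc, a_fc=a_fc, a_drop=a_drop,
                        drop_scale=drop_multiplier, logits=logits)


def backward_pass(params: NetworkParams, cache: ForwardCache,
                  d_logits: np.ndarray) -> dict[str, np.ndarray]:
    """Backpropagate the logit gradient to every parameter.

    Gradients route through pooling argmax positions only, and any unit
    zeroed by the dropout multiplier contributes zero gradient.
    """
    sh = params.shapes
    d_out_w = cache.a_drop.T @ d_logits
    d_out_b = d_logits.sum(axis=0)
    d_a_drop = d_logits @ params.out_w.T
    if cache.drop_scale is not None:
        d_a_fc = d_a_drop * cache.drop_scale
    else:
        d_a_fc = d_a_drop
    d_z_fc = d_a_fc * (cache.z_fc > 0)
    d_fc_w = cache.latent.T @ d_z_fc
    d_fc_b = d_z_fc.sum(axis=0)
    d_latent = d_z_fc @ params.fc_w.T
    d_p2 = global_maxpool_backward(d_latent, cache.arg_g, cache.p2.shape)
    if sh.pool_after_conv2:
        d_a2 = maxpool2x2_backward(d_p2, cache.arg2, cache.a2.shape)
    else:
        d_a2 = d_p2
    d_z2 = d_a2 * (cache.z2 > 0)
    d_conv2_w, d_conv2_b, d_p1 = conv2d_backward(cache.p1, params.conv2_w,
                                                 d_z2, need_dx=True,
                                                 cols=cache.cols2)
    if sh.pool_after_conv1:
        d_a1 = maxpool2x2_backward(d_p1, cache.arg1, cache.a1.shape)
    else:
        d_a1 = d_p1
    d_z1 = d_a1 * (cache.z1 > 0)
    d_conv1_w, d_conv1_b, _ = conv2d_backward(cache.x, params.conv1_w,
                                              d_z1, need_dx=False,
                                              cols=cache.cols1)
    return {
        "conv1_w": d_conv1_w, "conv1_b": d_conv1_b,
        "conv2_w": d_conv2_w, "conv2_b": d_conv2_b,
        "fc_w": d_fc_w, "fc_b": d_fc_b,
        "out_w": d_out_w, "out_b": d_out_b,
    }


def sgd_update(params: NetworkParams, grads: dict[str, np.ndarray],
               learning_rate: float) -> NetworkParams:
    """Plain gradient step: params - learning_rate * grads."""
    if learning_rate <= 0:
        raise ConfigurationError("learning_rate must be positive")
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {name}")
    new = {name: getattr(params, name) - learning_rate * g
           for name, g in grads.items()}
    return replace(params, **new)


# ---------------------------------------------------------------------------
# finite-difference oracle


def gradient_check(params: NetworkParams, x: np.ndarray, labels: np.ndarray,
                   spec: LossSpec | None = None,
                   drop_multiplier: np.ndarray | None = None,
                   step: float = 1e-5, tolerance: float = 1e-4) -> dict:
    """Compare analytic gradients to central finite differences.

    Perturbs every parameter entry by ±step, holding any dropout
    multiplier fixed, and reports the worst relative error
    |analytic - numeric| / max(|analytic|, |numeric|, 1e-8).
    Only meant for small networks and batches.
    """
    spec = spec or LossSpec()
    cache = forward_pass(params, x, drop_multiplier)
    _, _, d_logits = batch_loss(cache.logits, labels, spec)
    grads = backward_pass(params, cache, d_logits)

    def loss_at(p: NetworkParams) -> float:
        c = forward_pass(p, x, drop_multiplier)
        loss, _, _ = batch_loss(c.logits, labels, spec)
        return loss

    worst = 0.0
    worst_name = None
    for name in NetworkParams._ARRAYS:
        arr = getattr(params, name)
        analytic = grads[name]
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            p_hi = params.copy()
            getattr(p_hi, name)[idx] += step
            p_lo = params.copy()
            getattr(p_lo, name)[idx] -= step
            numeric = (loss_at(p_hi) - loss_at(p_lo)) / (2 * step)
            a = analytic[idx]
            rel = abs(a - numeric) / max(abs(a), abs(numeric), 1e-8)
            if rel > worst:
                worst, worst_name = rel, (name, idx)
    return {
        "max_relative_error": worst,
        "worst_parameter": worst_name,
        "passed": bool(worst < tolerance),
        "tolerance": tolerance,
    }


# ---------------------------------------------------------------------------
# serialization: zip of raw float64 buffers + JSON shape manifest


def save_params(params: NetworkParams, path: str) -> None:
    """Write parameters to a zip archive with a JSON manifest."""
    manifest = {
        "format": "engramsim-params-v1",
        "n_classes": params.n_classes,
        "init_seed": params.init_seed,
        "shapes": {
            "input_hw": params.shapes.input_hw,
            "in_channels": params.shapes.in_channels,
            "conv1_filters": params.shapes.conv1_filters,
            "conv2_filters": params.shapes.conv2_filters,
            "kernel": params.shapes.kernel,
            "pool_after_conv1": params.shapes.pool_after_conv1,
            "pool_after_conv2": params.shapes.pool_after_conv2,
            "fc_units": params.shapes.fc_units,
        },
        "arrays": {name: list(a.shape) for name, a in params.arrays().items()},
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        for name, arr in params.arrays().items():
            zf.writestr(f"{name}.f64",
                        np.ascontiguousarray(arr, dtype="<f8").tobytes())


def load_params(path: str) -> NetworkParams:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format") != "engramsim-params-v1":
            raise ValueError(f"{path}: not an engramsim parameter archive")
        shapes = LayerShapes(**manifest["shapes"])
        arrays = {}
        for name, shape in manifest["arrays"].items():
            buf = np.frombuffer(zf.read(f"{name}.f64"), dtype="<f8")
            arrays[name] = buf.reshape(shape).copy()
    return NetworkParams(shapes=shapes, n_classes=manifest["n_classes"],
                         init_seed=manifest["init_seed"], **arrays)
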