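"""Two-class patch CNN, implemented directly in numpy.

Architecture: two 5x5 convolution blocks (batch norm + leaky ReLU + 2x2 max
pool) followed by three fully connected layers of 1600, 500 and 2 units
with a softmax output.  Training is plain minibatch SGD (batch 32) with

* cross-entropy + (eta/2)*||w||^2 loss, eta = 1.0 on conv/FC weight
  matrices (biases and batch-norm scale/shift excluded);
* dropout keep probability 0.6 on the FC activations;
* exponential learning-rate decay by 0.9997 at every 10000-step boundary;
* moving-average "shadow" weights with the same 0.9997 decay (batch-norm
  running statistics use it too); inference always goes through the shadow
  weights and frozen statistics;
* truncated-Gaussian weight init, sigma = 0.1, biases zero.

Forward and backward passes are exact (the gradient is checked against
central differences in the test suite), so nothing here depends on an
autodiff framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import truncnorm

from .preprocess import ENHANCED_SIZE, LABELS, Patch

__all__ = [
    "CNNSpec",
    "TrainingConfig",
    "CNNModel",
    "LabeledPatchSet",
    "build_model",
    "loss",
    "train",
    "predict",
    "predict_batch",
    "save_checkpoint",
    "load_checkpoint",
]

_BN_EPS = 1e-5
_PROB_FLOOR = 1e-12
_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class CNNSpec:
    """Architecture hyperparameters.

    The conv depths and the second stride are free choices; the defaults
    d1=16, d2=25, s2=1 make the flattened block-2 output exactly
    8x8x25 = 1600, matching the width of the first fully connected layer.
    """

    input_size: int = ENHANCED_SIZE
    kernel: int = 5
    d1: int = 16
    d2: int = 25
    s2: int = 1
    fc1: int = 1600
    fc2: int = 500
    n_classes: int = 2
    leaky_slope: float = 0.01
    #: optional explicit flatten size; must match the computed one
    flatten_size: int | None = None

    def computed_flatten(self) -> int:
        side = self.input_size // 2  # block 1: same conv, pool 2
        side = side // self.s2 // 2  # block 2: strided conv, pool 2
        return side * side * self.d2

    def validate(self) -> None:
        if self.input_size % 4 != 0:
            raise ValueError(f"input_size {self.input_size} must be divisible by 4")
        if self.s2 not in (1, 2):
            raise ValueError(f"s2 must be 1 or 2, got {self.s2}")
        flat = self.computed_flatten()
        if self.flatten_size is not None and self.flatten_size != flat:
            raise ValueError(
                f"declared flatten size {self.flatten_size} != computed {flat} "
                f"(input {self.input_size}, d2={self.d2}, s2={self.s2})"
            )
        if self.n_classes != 2:
            raise ValueError("classifier is two-class (boundary, lesion)")


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 32
    initial_lr: float = 0.01
    #: shared decay constant: LR schedule, shadow weights, BN statistics
    decay: float = 0.9997
    lr_decay_every: int = 10000
    keep_prob: float = 0.6
    init_sigma: float = 0.1
    #: L2 coefficient eta in the loss (eta/2)*||w||^2
    l2_coefficient: float = 1.0
    #: "mean" normalises ||w||^2 by the number of regularised weights;
    #: with the raw sum and eta = 1.0 the penalty exceeds the data term by
    #: three orders of magnitude and erodes the classifier (see methods)
    l2_mode: str = "mean"
    max_steps: int = 3000
    val_fraction: float = 0.1
    log_every: int = 100
    #: ramp the moving-average decay as min(decay, (1+t)/(10+t))
    ema_ramp: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.keep_prob <= 1:
            raise ValueError(f"keep_prob must be in (0,1], got {self.keep_prob}")
        if not 0 < self.decay < 1:
            raise ValueError(f"decay must be in (0,1), got {self.decay}")

    def lr_at(self, step: int) -> float:
        return self.initial_lr * self.decay ** (step // self.lr_decay_every)

    def ema_decay_at(self, step: int) -> float:
        """Moving-average decay with the classic num_updates ramp.

        min(decay, (1+t)/(10+t)) keeps the shadow weights tracking the
        parameters early in training instead of clinging to the random
        init; the asymptotic decay is the configured 0.9997.
        """
        if not self.ema_ramp:
            return self.decay
        return min(self.decay, (1.0 + step) / (10.0 + step))


@dataclass
class LabeledPatchSet:
    """Stacked 32x32 patches with integer labels (0=boundary, 1=lesion)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.intp)
        if self.X.ndim != 3 or self.X.shape[1:] != (ENHANCED_SIZE, ENHANCED_SIZE):
            raise ValueError(f"X must be (N, {ENHANCED_SIZE}, {ENHANCED_SIZE}), got {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match X")
        if self.X.size and (self.X.min() < -1e-9 or self.X.max() > 1 + 1e-9):
            raise ValueError("patch intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.X.shape[0])

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=2)

    @classmethod
    def from_patches(cls, patches: list[Patch]) -> "LabeledPatchSet":
        X = np.stack([p.enhanced for p in patches])
        y = np.array([LABELS.index(p.label) for p in patches], dtype=np.intp)
        return cls(X=X, y=y)

    def subset(self, idx: np.ndarray) -> "LabeledPatchSet":
        return LabeledPatchSet(X=self.X[idx], y=self.y[idx])

    def concat(self, other: "LabeledPatchSet") -> "LabeledPatchSet":
        return LabeledPatchSet(
            X=np.concatenate([self.X, other.X]), y=np.concatenate([self.y, other.y])
        )


# weight tensors subject to L2 (biases and BN scale/shift excluded)
_L2_KEYS = ("W_conv1", "W_conv2", "W_fc1", "W_fc2", "W_fc3")
_BN_STAT_KEYS = ("bn1_mean", "bn1_var", "bn2_mean", "bn2_var")


@dataclass
class CNNModel:
    spec: CNNSpec
    params: dict[str, np.ndarray]
    shadow: dict[str, np.ndarray]
    bn_stats: dict[str, np.ndarray]
    step: int = 0
    label_order: tuple[str, str] = LABELS

    @property
    def trained(self) -> bool:
        return self.step > 0

    def predict_patch(self, patch: Patch) -> tuple[float, float]:
        """(p_boundary, p_lesion) for one preprocessed patch."""
        return predict(self, patch)


def _truncated_normal(rng: np.random.Generator, shape: tuple[int, ...], sigma: float) -> np.ndarray:
    return truncnorm.rvs(-2.0, 2.0, scale=sigma, size=shape, random_state=rng)


def build_model(
    spec: CNNSpec | None = None, seed: int = 0, dtype: np.dtype = np.float32
) -> CNNModel:
    """Initialise a model with truncated-Gaussian weights (sigma 0.1).

    ``dtype`` is the compute precision; float32 halves the training cost,
    float64 is available for gradient checking.
    """
    spec = spec or CNNSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    k = spec.kernel
    flat = spec.computed_flatten()
    sigma = 0.1
    params: dict[str, np.ndarray] = {
        "W_conv1": _truncated_normal(rng, (k * k * 1, spec.d1), sigma),
        "b_conv1": np.zeros(spec.d1),
        "bn1_gamma": np.ones(spec.d1),
        "bn1_beta": np.zeros(spec.d1),
        "W_conv2": _truncated_normal(rng, (k * k * spec.d1, spec.d2), sigma),
        "b_conv2": np.zeros(spec.d2),
        "bn2_gamma": np.ones(spec.d2),
        "bn2_beta": np.zeros(spec.d2),
        "W_fc1": _truncated_normal(rng, (flat, spec.fc1), sigma),
        "b_fc1": np.zeros(spec.fc1),
        "W_fc2": _truncated_normal(rng, (spec.fc1, spec.fc2), sigma),
        "b_fc2": np.zeros(spec.fc2),
        "W_fc3": _truncated_normal(rng, (spec.fc2, spec.n_classes), sigma),
        "b_fc3": np.zeros(spec.n_classes),
    }
    bn_stats = {
        "bn1_mean": np.zeros(spec.d1),
        "bn1_var": np.ones(spec.d1),
        "bn2_mean": np.zeros(spec.d2),
        "bn2_var": np.ones(spec.d2),
    }
    params = {k: np.asarray(v, dtype=dtype) for k, v in params.items()}
    bn_stats = {k: np.asarray(v, dtype=dtype) for k, v in bn_stats.items()}
    shadow = {key: value.copy() for key, value in params.items()}
    return CNNModel(spec=spec, params=params, shadow=shadow, bn_stats=bn_stats)


# ---------------------------------------------------------------------------
# conv / pooling primitives (NHWC layout)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B*H*W, k*k*C) with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B,H,W,C,k,k)
    b, h, w, c = x.shape
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, k * k * c)


def _col2im(dcols: np.ndarray, x_shape: tuple[int, ...], k: int) -> np.ndarray:
    b, h, w, c = x_shape
    p = k // 2
    dcols = dcols.reshape(b, h, w, k, k, c)
    dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
    return dxp[:, p : p + h, p : p + w, :]


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b, h, w, c = x.shape
    xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    # split gradient evenly on exact ties so the backward pass stays exact
    counts = mask.sum(axis=(2, 4), keepdims=True)
    return out, (mask / counts).astype(x.dtype)


def _maxpool_back(dout: np.ndarray, mask: np.ndarray, x_shape: tuple[int, ...]) -> np.ndarray:
    b, h, w, c = x_shape
    grad = mask * dout[:, :, None, :, None, :]
    return grad.reshape(b, h, w, c)


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_back(dout: np.ndarray, x: np.ndarray, slope: float) -> np.ndarray:
    one = x.dtype.type(1.0)
    return dout * np.where(x > 0, one, x.dtype.type(slope))


def _bn_forward_train(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray):
    axes = tuple(range(x.ndim - 1))
    mean = x.mean(axis=axes)
    var = x.var(axis=axes)
    ivstd = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean) * ivstd
    return gamma * xhat + beta, (xhat, ivstd, mean, var, gamma)


def _bn_backward(dout: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, ivstd, _, _, gamma = cache
    axes = tuple(range(dout.ndim - 1))
    n = dout.size // dout.shape[-1]
    dgamma = np.sum(dout * xhat, axis=axes)
    dbeta = np.sum(dout, axis=axes)
    dxhat = dout * gamma
    dx = ivstd / n * (n * dxhat - np.sum(dxhat, axis=axes) - xhat * np.sum(dxhat * xhat, axis=axes))
    return dx, dgamma, dbeta


def _bn_forward_infer(x, gamma, beta, mean, var):
    return gamma * (x - mean) / np.sqrt(var + _BN_EPS) + beta


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# forward / backward


def _forward_train(model: CNNModel, X: np.ndarray, keep_prob: float, rng: np.random.Generator):
    """Training-mode forward pass; returns probs and a cache for backward."""
    p = model.params
    spec = model.spec
    k = spec.kernel
    x0 = np.asarray(X, dtype=p["W_conv1"].dtype)[..., None]

    cols1 = _im2col(x0, k)
    z1 = (cols1 @ p["W_conv1"] + p["b_conv1"]).reshape(*x0.shape[:3], spec.d1)
    bn1, bn1_cache = _bn_forward_train(z1, p["bn1_gamma"], p["bn1_beta"])
    a1 = _leaky(bn1, spec.leaky_slope)
    p1, pool1_mask = _maxpool(a1)

    cols2 = _im2col(p1, k)
    z2_full = (cols2 @ p["W_conv2"] + p["b_conv2"]).reshape(*p1.shape[:3], spec.d2)
    z2 = z2_full[:, :: spec.s2, :: spec.s2, :]
    bn2, bn2_cache = _bn_forward_train(z2, p["bn2_gamma"], p["bn2_beta"])
    a2 = _leaky(bn2, spec.leaky_slope)
    p2, pool2_mask = _maxpool(a2)

    flat = p2.reshape(X.shape[0], -1)
    h1 = _leaky(flat @ p["W_fc1"] + p["b_fc1"], spec.leaky_slope)
    if keep_prob < 1.0:
        drop1 = ((rng.random(h1.shape) < keep_prob) / keep_prob).astype(h1.dtype)
    else:
        drop1 = np.ones_like(h1)
    h1d = h1 * drop1
    h2 = _leaky(h1d @ p["W_fc2"] + p["b_fc2"], spec.leaky_slope)
    if keep_prob < 1.0:
        drop2 = ((rng.random(h2.shape) < keep_prob) / keep_prob).astype(h2.dtype)
    else:
        drop2 = np.ones_like(h2)
    h2d = h2 * drop2
    logits = h2d @ p["W_fc3"] + p["b_fc3"]
    probs = _softmax(logits)
    cache = dict(
        x0=x0, cols1=cols1, z1=z1, bn1=bn1, bn1_cache=bn1_cache, a1_shape=a1.shape,
        pool1_mask=pool1_mask, p1=p1, cols2=cols2, z2_full_shape=z2_full.shape, z2=z2,
        bn2=bn2, bn2_cache=bn2_cache, a2_shape=a2.shape, pool2_mask=pool2_mask,
        p2_shape=p2.shape, flat=flat, h1=h1, drop1=drop1, h1d=h1d, h2=h2, drop2=drop2,
        h2d=h2d, probs=probs,
    )
    return probs, cache


def _backward(model: CNNModel, cache: dict, T: np.ndarray, eta: float) -> dict[str, np.ndarray]:
    """Gradient of CE + (eta/2)||w||^2 with respect to every parameter."""
    p = model.params
    spec = model.spec
    k = spec.kernel
    n = T.shape[0]
    grads: dict[str, np.ndarray] = {}

    dlogits = (cache["probs"] - T) / n
    grads["W_fc3"] = cache["h2d"].T @ dlogits
    grads["b_fc3"] = dlogits.sum(axis=0)
    dh2d = dlogits @ p["W_fc3"].T
    dh2 = dh2d * cache["drop2"]
    dz_fc2 = _leaky_back(dh2, cache["h1d"] @ p["W_fc2"] + p["b_fc2"], spec.leaky_slope)
    grads["W_fc2"] = cache["h1d"].T @ dz_fc2
    grads["b_fc2"] = dz_fc2.sum(axis=0)
    dh1d = dz_fc2 @ p["W_fc2"].T
    dh1 = dh1d * cache["drop1"]
    dz_fc1 = _leaky_back(dh1, cache["flat"] @ p["W_fc1"] + p["b_fc1"], spec.leaky_slope)
    grads["W_fc1"] = cache["flat"].T @ dz_fc1
    grads["b_fc1"] = dz_fc1.sum(axis=0)
    dflat = dz_fc1 @ p["W_fc1"].T

    dp2 = dflat.reshape(cache["p2_shape"])
    da2 = _maxpool_back(dp2, cache["pool2_mask"], cache["a2_shape"])
    dbn2 = _leaky_back(da2, cache["bn2"], spec.leaky_slope)
    dz2, grads["bn2_gamma"], grads["bn2_beta"] = _bn_backward(dbn2, cache["bn2_cache"])
    dz2_full = np.zeros(cache["z2_full_shape"], dtype=dz2.dtype)
    dz2_full[:, :: spec.s2, :: spec.s2, :] = dz2
    dz2_flat = dz2_full.reshape(-1, spec.d2)
    grads["W_conv2"] = cache["cols2"].T @ dz2_flat
    grads["b_conv2"] = dz2_flat.sum(axis=0)
    dp1 = _col2im(dz2_flat @ p["W_conv2"].T, cache["p1"].shape, k)

    da1 = _maxpool_back(dp1, cache["pool1_mask"], cache["a1_shape"])
    dbn1 = _leaky_back(da1, cache["bn1"], spec.leaky_slope)
    dz1, grads["bn1_gamma"], grads["bn1_beta"] = _bn_backward(dbn1, cache["bn1_cache"])
    dz1_flat = dz1.reshape(-1, spec.d1)
    grads["W_conv1"] = cache["cols1"].T @ dz1_flat
    grads["b_conv1"] = dz1_flat.sum(axis=0)

    for key in _L2_KEYS:
        grads[key] = grads[key] + eta * p[key]
    return grads


def _forward_infer(
    spec: CNNSpec, params: dict[str, np.ndarray], bn_stats: dict[str, np.ndarray], X: np.ndarray
) -> np.ndarray:
    """Inference forward pass: shadow/frozen statistics, no dropout."""
    k = spec.kernel
    x0 = np.asarray(X, dtype=params["W_conv1"].dtype)[..., None]
    z1 = (_im2col(x0, k) @ params["W_conv1"] + params["b_conv1"]).reshape(*x0.shape[:3], spec.d1)
    a1 = _leaky(
        _bn_forward_infer(z1, params["bn1_gamma"], params["bn1_beta"], bn_stats["bn1_mean"], bn_stats["bn1_var"]),
        spec.leaky_slope,
    )
    p1, _ = _maxpool(a1)
    z2_full = (_im2col(p1, k) @ params["W_conv2"] + params["b_conv2"]).reshape(*p1.shape[:3], spec.d2)
    z2 = z2_full[:, :: spec.s2, :: spec.s2, :]
    a2 = _leaky(
        _bn_forward_infer(z2, params["bn2_gamma"], params["bn2_beta"], bn_stats["bn2_mean"], bn_stats["bn2_var"]),
        spec.leaky_slope,
    )
    p2, _ = _maxpool(a2)
    flat = p2.reshape(X.shape[0], -1)
    h1 = _leaky(flat @ params["W_fc1"] + params["b_fc1"], spec.leaky_slope)
    h2 = _leaky(h1 @ params["W_fc2"] + params["b_fc2"], spec.leaky_slope)
    return _softmax(h2 @ params["W_fc3"] + params["b_fc3"])


def _one_hot(y: np.ndarray, n_classes: int = 2, dtype=np.float64) -> np.ndarray:
    T = np.zeros((y.shape[0], n_classes), dtype=dtype)
    T[np.arange(y.shape[0]), y] = 1.0
    return T


def _n_regularized(model: CNNModel) -> int:
    return sum(model.params[key].size for key in _L2_KEYS)


def effective_eta(model: CNNModel, eta: float, l2_mode: str) -> float:
    """eta as applied to the raw sum of squares; "mean" divides by the
    number of regularised weights."""
    if l2_mode == "sum":
        return eta
    if l2_mode == "mean":
        return eta / _n_regularized(model)
    raise ValueError(f"unknown l2_mode {l2_mode!r}")


def loss(
    model: CNNModel,
    batch: LabeledPatchSet,
    eta: float = 1.0,
    keep_prob: float = 1.0,
    rng: np.random.Generator | None = None,
    l2_mode: str = "sum",
    _return_cache: bool = False,
):
    """Cross-entropy + (eta/2)||w||^2 on one batch (training-mode forward).

    ``l2_mode="sum"`` is the literal sum of squared weights; ``"mean"``
    normalises by the weight count (the form used for training).
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    rng = rng or np.random.default_rng(0)
    eta = effective_eta(model, eta, l2_mode)
    probs, cache = _forward_train(model, batch.X, keep_prob, rng)
    T = _one_hot(batch.y, model.spec.n_classes, dtype=probs.dtype)
    ce = -np.mean(np.sum(T * np.log(np.maximum(probs, _PROB_FLOOR)), axis=1))
    l2 = 0.5 * eta * sum(float(np.sum(model.params[key] ** 2)) for key in _L2_KEYS)
    value = float(ce + l2)
    if _return_cache:
        return value, cache, T
    return value


def loss_and_grads(
    model: CNNModel,
    batch: LabeledPatchSet,
    eta: float = 1.0,
    keep_prob: float = 1.0,
    rng: np.random.Generator | None = None,
    l2_mode: str = "sum",
) -> tuple[float, dict[str, np.ndarray], dict]:
    value, cache, T = loss(
        model, batch, eta=eta, keep_prob=keep_prob, rng=rng, l2_mode=l2_mode,
        _return_cache=True,
    )
    return value, _backward(model, cache, T, effective_eta(model, eta, l2_mode)), cache


def train(
    model: CNNModel, data: LabeledPatchSet, cfg: TrainingConfig | None = None
) -> tuple[CNNModel, list[dict]]:
    """Train in place with the SGD schedule; returns (model, training log)."""
    cfg = cfg or TrainingConfig()
    cfg.validate()
    counts = data.class_counts
    if (counts == 0).any():
        raise ValueError(f"training data must contain both classes, got counts {counts.tolist()}")

    rng = np.random.default_rng(cfg.seed)
    # stratified validation split
    val_idx_parts = []
    for cls in (0, 1):
        idx = np.flatnonzero(data.y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(cfg.val_fraction * idx.size)))
        val_idx_parts.append(idx[:n_val])
    val_idx = np.concatenate(val_idx_parts)
    train_mask = np.ones(len(data), dtype=bool)
    train_mask[val_idx] = False
    train_set = data.subset(np.flatnonzero(train_mask))
    val_set = data.subset(val_idx)

    log: list[dict] = []
    for _ in range(cfg.max_steps):
        lr = cfg.lr_at(model.step)
        batch_idx = rng.integers(0, len(train_set), size=cfg.batch_size)
        batch = train_set.subset(batch_idx)
        value, grads, cache = loss_and_grads(
            model, batch, eta=cfg.l2_coefficient, keep_prob=cfg.keep_prob, rng=rng,
            l2_mode=cfg.l2_mode,
        )
        # BN running statistics and shadow weights: moving averages with
        # the shared (ramped) decay
        d = cfg.ema_decay_at(model.step)
        for name in ("bn1", "bn2"):
            _, _, mean, var, _ = cache[f"{name}_cache"]
            model.bn_stats[f"{name}_mean"] = d * model.bn_stats[f"{name}_mean"] + (1 - d) * mean
            model.bn_stats[f"{name}_var"] = d * model.bn_stats[f"{name}_var"] + (1 - d) * var
        for key, g in grads.items():
            model.params[key] -= lr * g
        for key in model.params:
            model.shadow[key] = d * model.shadow[key] + (1 - d) * model.params[key]
        model.step += 1
        if model.step % cfg.log_every == 0 or model.step == cfg.max_steps:
            acc = accuracy(model, val_set) if len(val_set) else float("nan")
            log.append({"step": model.step, "lr": lr, "train_loss": value, "val_accuracy": acc})
    return model, log


def accuracy(model: CNNModel, data: LabeledPatchSet) -> float:
    probs = predict_batch(model, data.X)
    return float(np.mean(probs.argmax(axis=1) == data.y))


def predict_batch(model: CNNModel, X: np.ndarray) -> np.ndarray:
    """(N,32,32) -> (N,2) softmax probabilities, inference mode."""
    if not model.trained:
        raise RuntimeError("model has not been trained (no steps taken, no checkpoint loaded)")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    return _forward_infer(model.spec, model.shadow, model.bn_stats, X)


def predict(model: CNNModel, patch: Patch) -> tuple[float, float]:
    """Class probabilities (p_boundary, p_lesion) for one patch."""
    probs = predict_batch(model, patch.enhanced)[0]
    return float(probs[0]), float(probs[1])


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON sidecar


def save_checkpoint(model: CNNModel, path: str | Path) -> None:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for prefix, group in (("param", model.params), ("shadow", model.shadow), ("bn", model.bn_stats)):
        for key, value in group.items():
            arrays[f"{prefix}:{key}"] = value
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "version": _CHECKPOINT_VERSION,
        "step": model.step,
        "label_order": list(model.label_order),
        "spec": {
            "input_size": model.spec.input_size, "kernel": model.spec.kernel,
            "d1": model.spec.d1, "d2": model.spec.d2, "s2": model.spec.s2,
            "fc1": model.spec.fc1, "fc2": model.spec.fc2,
            "n_classes": model.spec.n_classes, "leaky_slope": model.spec.leaky_slope,
        },
        "preprocessing": {"raw_size": 10, "enhanced_size": ENHANCED_SIZE, "clahe_clip_limit": 0.02, "clahe_tile_grid": [4, 4]},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> CNNModel:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    npz_path = path.with_suffix(".npz")
    if not sidecar_path.exists() or not npz_path.exists():
        raise IOError(f"checkpoint incomplete: need {npz_path} and {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("version") != _CHECKPOINT_VERSION:
        raise IOError(
            f"checkpoint version {sidecar.get('version')} != supported {_CHECKPOINT_VERSION}"
        )
    spec = CNNSpec(**sidecar["spec"])
    spec.validate()
    try:
        arrays = np.load(npz_path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"corrupted checkpoint weights {npz_path}: {exc}") from exc
    model = build_model(spec, seed=0)
    for group_name, group in (("param", model.params), ("shadow", model.shadow), ("bn", model.bn_stats)):
        for key in group:
            full = f"{group_name}:{key}"
            if full not in arrays:
                raise IOError(f"checkpoint missing tensor {full}")
            stored = arrays[full]
            if stored.shape != group[key].shape:
                raise IOError(
                    f"checkpoint tensor {full} shape {stored.shape} does not match spec "
                    f"shape {group[key].shape}"
                )
            group[key] = stored
    model.step = int(sidecar["step"])
    model.label_order = tuple(sidecar["label_order"])
    return model
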