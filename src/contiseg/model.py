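"""Compact encoder–decoder segmentation network with a body/head split.

A small U-Net-style fully-convolutional network (three resolution levels,
base 8 channels, leaky activations, skip connections) operating on whole
2-D or 3-D images.  Forward and backward passes are written directly in
NumPy with im2col convolutions; with a single-threaded BLAS this makes every
training run bitwise deterministic for a fixed seed, which the continual
learning reduction identities rely on.

The network is split into a shared *body* (encoder, decoder) and one or more
per-task *heads* (the final per-class 1x1 projection, parameter names
prefixed ``seg_head``).  Heads are architecturally interchangeable: a new
head is always created as a value-copy of the active one, and inference
selects a head by task id.
"""

from __future__ import annotations

import copy
import hashlib
import io
import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic import TaskDataset, derive_seed

__all__ = [
    "ArchConfig", "TrainConfig", "SegModel",
    "build_model", "add_head", "freeze_body", "predict",
    "zscore", "forward_features", "head_logits", "forward_logits",
    "backward", "loss_and_grad", "softmax",
    "save_model", "load_model", "METHOD_DEFAULTS",
]

LEAKY_SLOPE = 0.01
HEAD_PREFIX = "seg_head"


def zscore(image: np.ndarray) -> np.ndarray:
    """Per-case intensity standardisation; the network always consumes
    z-scored inputs."""
    image = np.asarray(image, dtype=np.float32)
    return (image - image.mean()) / (image.std() + 1e-8)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchConfig:
    """Architecture fixed from the FIRST task and never changed after."""

    ndim: int
    n_classes: int
    in_channels: int = 1
    base_channels: int = 8
    depth: int = 3  # resolution levels incl. bottleneck

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.ndim not in (2, 3):
            raise ValueError("only 2-D and 3-D images are supported")


#: paper-default hyperparameters per continual-learning method
METHOD_DEFAULTS: dict[str, dict[str, float]] = {
    "sequential": {},
    "rehearsal": {"fraction": 0.25},
    "ewc": {"lam": 0.4, "fisher_samples": 10},
    "lwf": {"temperature": 8.0, "warmup_fraction": 0.1},
    "rw": {"lam": 0.4, "alpha": 0.9},
    "mib": {"alpha": 0.9, "kd_weight": 1.0},
}

METHODS = tuple(METHOD_DEFAULTS)


@dataclass(frozen=True)
class TrainConfig:
    """Per-run training configuration.

    ``method_params`` is merged over the method's defaults, which are the
    reference settings: rehearsal fraction 0.25, EWC/RW lambda 0.4, RW alpha
    0.9, distillation temperature 8, hardening alpha 0.9.
    """

    epochs: int = 10
    steps_per_epoch: int = 20
    batch_size: int = 2
    learning_rate: float = 0.2
    seed: int = 0
    method: str = "sequential"
    method_params: Mapping[str, float] = field(default_factory=dict)
    head_mode: str = "single"
    freeze_body_after_first: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.head_mode not in ("single", "multi"):
            raise ValueError("head_mode must be 'single' or 'multi'")
        merged = dict(METHOD_DEFAULTS[self.method])
        unknown = set(self.method_params) - set(merged)
        if unknown:
            raise ValueError(f"unknown method_params for {self.method}: {sorted(unknown)}")
        merged.update({k: float(v) for k, v in self.method_params.items()})
        object.__setattr__(self, "method_params", merged)

    @property
    def steps_per_stage(self) -> int:
        return self.epochs * self.steps_per_epoch


# ---------------------------------------------------------------------------
# layer primitives (stride 1, 'same' padding, odd kernels)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, ksize: tuple[int, ...]) -> np.ndarray:
    """(N, C, *S) -> (N * prod(S), C * prod(k)) patch matrix."""
    nd = x.ndim - 2
    pad = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in ksize]
    xp = np.pad(x, pad)
    win = sliding_window_view(xp, ksize, axis=tuple(range(2, 2 + nd)))
    # (N, C, *S, *k) -> (N, *S, C, *k)
    order = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    win = win.transpose(order)
    n_pos = int(np.prod(win.shape[: 1 + nd]))
    return np.ascontiguousarray(win).reshape(n_pos, -1)


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x (N, Cin, *S), w (Cout, Cin, *k) -> (y, cols) with y (N, Cout, *S)."""
    nd = x.ndim - 2
    spatial = x.shape[2:]
    cols = _im2col(x, w.shape[2:])
    y = cols @ w.reshape(w.shape[0], -1).T + b
    y = y.reshape(x.shape[0], *spatial, w.shape[0])
    y = np.moveaxis(y, -1, 1)
    return np.ascontiguousarray(y), cols


def conv_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    """Gradients of conv_forward. Returns (dx, dw, db)."""
    nd = len(x_shape) - 2
    cout = w.shape[0]
    dyf = np.moveaxis(dy, 1, -1).reshape(-1, cout)
    dw = (dyf.T @ cols).reshape(w.shape)
    db = dyf.sum(axis=0)
    # dx = 'same' convolution of dy with spatially flipped, channel-swapped w
    wt = np.flip(w, axis=tuple(range(2, 2 + nd))).swapaxes(0, 1)
    dx, _ = conv_forward(dy, np.ascontiguousarray(wt), np.zeros(wt.shape[0], w.dtype))
    return dx, dw, db


def _down(x: np.ndarray) -> np.ndarray:
    """2x average pooling along every spatial axis."""
    n, c = x.shape[:2]
    if x.ndim == 4:
        h, w = x.shape[2:]
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    d, h, w = x.shape[2:]
    return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))


def _down_back(g: np.ndarray, ndim: int) -> np.ndarray:
    for ax in range(2, 2 + ndim):
        g = np.repeat(g, 2, axis=ax)
    return g / (2.0**ndim)


def _up(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling along every spatial axis."""
    for ax in range(2, x.ndim):
        x = np.repeat(x, 2, axis=ax)
    return x


def _up_back(g: np.ndarray) -> np.ndarray:
    n, c = g.shape[:2]
    if g.ndim == 4:
        h, w = g.shape[2:]
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
    d, h, w = g.shape[2:]
    return g.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


def _leaky(x: np.ndarray):
    mask = x > 0
    return np.where(mask, x, LEAKY_SLOPE * x), mask


def _leaky_back(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.where(mask, g, LEAKY_SLOPE * g)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

_BODY_LAYERS = ("enc1", "enc2", "bott", "dec2", "dec1")


def _init_params(arch: ArchConfig, seed: int):
    """He-style deterministic initialisation; returns (body, head) dicts."""
    rng = np.random.default_rng(seed)
    c1, c2, c3 = arch.base_channels, 2 * arch.base_channels, 4 * arch.base_channels
    k = (3,) * arch.ndim
    shapes = {
        "enc1": (c1, arch.in_channels) + k,
        "enc2": (c2, c1) + k,
        "bott": (c3, c2) + k,
        "dec2": (c2, c3 + c2) + k,
        "dec1": (c1, c2 + c1) + k,
    }
    body: dict[str, np.ndarray] = {}
    for name, shp in shapes.items():
        fan_in = int(np.prod(shp[1:]))
        body[f"{name}.w"] = (rng.standard_normal(shp) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        body[f"{name}.b"] = np.zeros(shp[0], dtype=np.float32)
    hshape = (arch.n_classes, c1) + (1,) * arch.ndim
    head = {
        f"{HEAD_PREFIX}.w": (rng.standard_normal(hshape) * np.sqrt(2.0 / c1)).astype(np.float32),
        f"{HEAD_PREFIX}.b": np.zeros(arch.n_classes, dtype=np.float32),
    }
    return body, head


def forward_features(body: Mapping[str, np.ndarray], x: np.ndarray):
    """Shared-body forward pass; returns (features, cache)."""
    cache: dict = {"x_shape": x.shape}
    h, cache["enc1_cols"] = conv_forward(x, body["enc1.w"], body["enc1.b"])
    a1, cache["enc1_mask"] = _leaky(h)
    p1 = _down(a1)
    h, cache["enc2_cols"] = conv_forward(p1, body["enc2.w"], body["enc2.b"])
    cache["p1_shape"] = p1.shape
    a2, cache["enc2_mask"] = _leaky(h)
    p2 = _down(a2)
    h, cache["bott_cols"] = conv_forward(p2, body["bott.w"], body["bott.b"])
    cache["p2_shape"] = p2.shape
    a3, cache["bott_mask"] = _leaky(h)
    u2 = np.concatenate([_up(a3), a2], axis=1)
    h, cache["dec2_cols"] = conv_forward(u2, body["dec2.w"], body["dec2.b"])
    cache["u2_shape"] = u2.shape
    a4, cache["dec2_mask"] = _leaky(h)
    u1 = np.concatenate([_up(a4), a1], axis=1)
    h, cache["dec1_cols"] = conv_forward(u1, body["dec1.w"], body["dec1.b"])
    cache["u1_shape"] = u1.shape
    feat, cache["dec1_mask"] = _leaky(h)
    cache["feat"] = feat
    return feat, cache


def head_logits(head: Mapping[str, np.ndarray], feat: np.ndarray):
    logits, cols = conv_forward(feat, head[f"{HEAD_PREFIX}.w"], head[f"{HEAD_PREFIX}.b"])
    return logits, cols


def forward_logits(body, head, x: np.ndarray):
    feat, cache = forward_features(body, x)
    logits, hcols = head_logits(head, feat)
    cache["head_cols"] = hcols
    return logits, cache


def backward(body, head, cache, dlogits, *, extra_dfeat: np.ndarray | None = None):
    """Backprop through head and body; returns named gradient dict.

    ``extra_dfeat`` lets additional heads (e.g. distilled old heads) inject
    their feature-gradient contribution into the shared body.
    """
    grads: dict[str, np.ndarray] = {}
    nd = len(cache["x_shape"]) - 2
    dfeat, dw, db = conv_backward(dlogits, cache["head_cols"], head[f"{HEAD_PREFIX}.w"],
                                  cache["feat"].shape)
    grads[f"{HEAD_PREFIX}.w"], grads[f"{HEAD_PREFIX}.b"] = dw, db
    if extra_dfeat is not None:
        dfeat = dfeat + extra_dfeat
    d = _leaky_back(dfeat, cache["dec1_mask"])
    du1, grads["dec1.w"], grads["dec1.b"] = conv_backward(d, cache["dec1_cols"],
                                                          body["dec1.w"], cache["u1_shape"])
    c1 = body["enc1.w"].shape[0]
    c2 = body["enc2.w"].shape[0]
    da4 = _up_back(du1[:, : du1.shape[1] - c1])
    da1_skip = du1[:, du1.shape[1] - c1:]
    d = _leaky_back(da4, cache["dec2_mask"])
    du2, grads["dec2.w"], grads["dec2.b"] = conv_backward(d, cache["dec2_cols"],
                                                          body["dec2.w"], cache["u2_shape"])
    da3 = _up_back(du2[:, : du2.shape[1] - c2])
    da2_skip = du2[:, du2.shape[1] - c2:]
    d = _leaky_back(da3, cache["bott_mask"])
    dp2, grads["bott.w"], grads["bott.b"] = conv_backward(d, cache["bott_cols"],
                                                          body["bott.w"], cache["p2_shape"])
    da2 = _down_back(dp2, nd) + da2_skip
    d = _leaky_back(da2, cache["enc2_mask"])
    dp1, grads["enc2.w"], grads["enc2.b"] = conv_backward(d, cache["enc2_cols"],
                                                          body["enc2.w"], cache["p1_shape"])
    da1 = _down_back(dp1, nd) + da1_skip
    d = _leaky_back(da1, cache["enc1_mask"])
    _, grads["enc1.w"], grads["enc1.b"] = conv_backward(d, cache["enc1_cols"],
                                                        body["enc1.w"], cache["x_shape"])
    return grads


# ---------------------------------------------------------------------------
# loss: voxel-wise cross-entropy + soft Dice (composite segmentation loss)
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def loss_and_grad(logits: np.ndarray, targets: np.ndarray, n_classes: int,
                  dice_eps: float = 1e-5):
    """Composite CE + soft-Dice loss over a batch.

    ``logits`` (N, K, *S); ``targets`` integer (N, *S).  Returns
    (loss, dlogits).  Soft Dice is computed per class over the whole batch
    and averaged unweighted over classes.
    """
    p = softmax(logits, axis=1)
    onehot = np.moveaxis(np.eye(n_classes, dtype=np.float32)[targets], -1, 1)
    nvox = float(targets.size)
    # cross-entropy
    p_true = np.take_along_axis(p, targets[:, None], axis=1)
    ce = float(-np.log(np.maximum(p_true, 1e-12)).mean())
    dlogits = (p - onehot) / nvox
    # soft Dice (batch-level, per class)
    axes = (0,) + tuple(range(2, logits.ndim))
    inter = (p * onehot).sum(axis=axes)
    psum = p.sum(axis=axes)
    gsum = onehot.sum(axis=axes)
    num = 2.0 * inter + dice_eps
    den = psum + gsum + dice_eps
    dice_loss = float(1.0 - (num / den).mean())
    # d(dice_loss)/dp_c(v) = -(1/K) * (2*g - num/den) / den
    shape = (1, n_classes) + (1,) * (logits.ndim - 2)
    dLdp = -(2.0 * onehot - (num / den).reshape(shape)) / den.reshape(shape) / n_classes
    # chain through softmax: dz = p * (dLdp - sum_c dLdp_c * p_c)
    inner = (dLdp * p).sum(axis=1, keepdims=True)
    dlogits = dlogits + p * (dLdp - inner)
    return ce + dice_loss, dlogits.astype(logits.dtype)


# ---------------------------------------------------------------------------
# model object and multi-head bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SegModel:
    """Shared body + per-task heads; ``head_mode`` 'single' keeps one shared
    head that is merely re-keyed at task boundaries."""

    arch: ArchConfig
    body: dict[str, np.ndarray]
    heads: dict[str, dict[str, np.ndarray]]
    active_head: str
    head_mode: str = "single"
    body_frozen: bool = False
    split_prefix: str = HEAD_PREFIX
    provenance: dict = field(default_factory=dict)

    def head(self, task_id: str | None = None) -> dict[str, np.ndarray]:
        if self.head_mode == "single" or task_id is None:
            return self.heads[self.active_head]
        if task_id not in self.heads:
            raise KeyError(
                f"no head for task {task_id!r}; available: {sorted(self.heads)}")
        return self.heads[task_id]

    def trainable(self) -> dict[str, np.ndarray]:
        """Named view of the parameters the optimiser may update: the body
        (unless frozen) and the active head — every trainable parameter
        belongs to exactly one of the two."""
        out: dict[str, np.ndarray] = {}
        if not self.body_frozen:
            out.update(self.body)
        out.update(self.heads[self.active_head])
        return out

    def all_named(self) -> dict[str, np.ndarray]:
        out = dict(self.body)
        out.update(self.heads[self.active_head])
        return out

    def copy(self) -> "SegModel":
        return SegModel(
            arch=self.arch,
            body={k: v.copy() for k, v in self.body.items()},
            heads={t: {k: v.copy() for k, v in h.items()} for t, h in self.heads.items()},
            active_head=self.active_head,
            head_mode=self.head_mode,
            body_frozen=self.body_frozen,
            split_prefix=self.split_prefix,
            provenance=copy.deepcopy(self.provenance),
        )

    def checksum(self, which: str = "all") -> str:
        h = hashlib.sha256()
        items = self.body if which == "body" else self.all_named()
        for k in sorted(items):
            h.update(k.encode())
            h.update(np.ascontiguousarray(items[k]).tobytes())
        return h.hexdigest()


def build_model(first_task: TaskDataset, seed: int = 0, *, head_mode: str = "single",
                n_classes: int | None = None, base_channels: int = 8) -> SegModel:
    """Construct the model from the FIRST task; the architecture is frozen
    thereafter (later tasks reuse it regardless of their own statistics)."""
    if n_classes is None:
        n_classes = max(first_task.labels_present() | {0}) + 1
    shape = first_task.spec.image_shape
    if any(s % 4 != 0 or s < 8 for s in shape):
        raise ValueError(f"image shape {shape} must be multiples of 4, >= 8")
    arch = ArchConfig(ndim=len(shape), n_classes=int(n_classes),
                      base_channels=base_channels)
    body, head = _init_params(arch, derive_seed("init", seed))
    tid = first_task.task_id
    return SegModel(arch=arch, body=body, heads={tid: head}, active_head=tid,
                    head_mode=head_mode,
                    provenance={"first_task": tid, "seed": int(seed),
                                "task_order": [tid]})


def add_head(model: SegModel, task_id: str) -> SegModel:
    """At a task boundary: replicate the active head for the new task
    (multi-head) or re-key the shared head (single-head)."""
    if task_id in model.heads:
        raise ValueError(f"head for task {task_id!r} already exists")
    if model.head_mode == "single":
        model.heads = {task_id: model.heads[model.active_head]}
    else:
        model.heads[task_id] = {k: v.copy() for k, v in model.heads[model.active_head].items()}
    model.active_head = task_id
    model.provenance.setdefault("task_order", []).append(task_id)
    return model


def freeze_body(model: SegModel) -> SegModel:
    model.body_frozen = True
    return model


def predict(model: SegModel, image: np.ndarray, task_id: str | None = None) -> np.ndarray:
    """Arg-max segmentation of one raw image; ties break toward the lowest
    class index. The head is selected by ``task_id`` in multi-head mode."""
    head = model.head(task_id)
    x = zscore(image)[None, None]
    logits, _ = forward_logits(model.body, head, x)
    return np.argmax(logits[0], axis=0).astype(np.int16)


# ---------------------------------------------------------------------------
# checkpointing: single-file .npz archive with a JSON metadata entry
# ---------------------------------------------------------------------------

def save_model(model: SegModel, path) -> None:
    arrays = {f"body/{k}": v for k, v in model.body.items()}
    for tid, head in model.heads.items():
        for k, v in head.items():
            arrays[f"heads/{tid}/{k}"] = v
    meta = {
        "arch": {"ndim": model.arch.ndim, "n_classes": model.arch.n_classes,
                 "in_channels": model.arch.in_channels,
                 "base_channels": model.arch.base_channels, "depth": model.arch.depth},
        "active_head": model.active_head,
        "head_mode": model.head_mode,
        "body_frozen": model.body_frozen,
        "split_prefix": model.split_prefix,
        "provenance": model.provenance,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> SegModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        body = {}
        heads: dict[str, dict[str, np.ndarray]] = {}
        for key in data.files:
            if key.startswith("body/"):
                body[key[5:]] = data[key]
            elif key.startswith("heads/"):
                _, tid, pname = key.split("/", 2)
                heads.setdefault(tid, {})[pname] = data[key]
    return SegModel(arch=ArchConfig(**meta["arch"]), body=body, heads=heads,
                    active_head=meta["active_head"], head_mode=meta["head_mode"],
                    body_frozen=meta["body_frozen"], split_prefix=meta["split_prefix"],
                    provenance=meta["provenance"])
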