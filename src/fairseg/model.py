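"""Mini U-Net backbone, Adam training loop and per-sample IoU evaluation.

The backbone is a deliberately small encoder-decoder segmentation network
(default: 3 resolution levels, 8 base channels, ~30k parameters) exposing a
pluggable interface — build / forward / flatten / restore — so that larger
backbones can be swapped in without touching the curricula, losses or
federated machinery.  The flattened parameter vector has a stable ordering
across runs of the same descriptor, which the federated aggregators rely on.

Training consumes a :class:`~fairseg.curriculum.CurriculumOrder` verbatim:
samples are visited exactly in the given order, batched sequentially without
reshuffling, and after the pass a gradient-free forward sweep records the
per-sample hard IoU that drives the next epoch's curriculum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import SampleRecord
from .losses import LossSchedule, soft_iou_with_grad, spl_multiplier, tpl_multiplier, weight_at
from .metrics import iou_multiclass


@dataclass(frozen=True)
class ModelDescriptor:
    """Backbone shape.  ``in_channels=2`` feeds the grayscale intensities
    plus a normalized horizontal-coordinate channel (CoordConv-style), so
    that left/right paired structures are separable even at the small
    receptive field of a miniature network."""

    depth: int = 3
    base_channels: int = 8
    n_classes: int = 7  # 6 foreground + background
    in_channels: int = 2

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes (background + 1)")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("invalid descriptor")

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "ModelDescriptor":
        return cls(**json.loads(s))


class MiniUNet:
    """Encoder-decoder with skip connections on a numpy backend."""

    def __init__(self, descriptor: ModelDescriptor, seed: int = 0):
        self.descriptor = descriptor
        self.step_counter = 0
        rng = np.random.default_rng(seed)
        d, b = descriptor.depth, descriptor.base_channels
        ch = [b * 2**i for i in range(d)]
        self.layers: dict[str, nn.Conv2d] = {}
        c_prev = descriptor.in_channels
        for i in range(d):
            self.layers[f"enc{i}a"] = nn.Conv2d(c_prev, ch[i], 3, rng)
            self.layers[f"enc{i}b"] = nn.Conv2d(ch[i], ch[i], 3, rng)
            c_prev = ch[i]
        for i in range(d - 2, -1, -1):
            self.layers[f"dec{i}a"] = nn.Conv2d(ch[i + 1] + ch[i], ch[i], 3, rng)
            self.layers[f"dec{i}b"] = nn.Conv2d(ch[i], ch[i], 3, rng)
        self.layers["head"] = nn.Conv2d(ch[0], descriptor.n_classes, 1, rng)
        self._order = list(self.layers)  # stable parameter ordering

    # -- parameter vector view ------------------------------------------------

    def param_items(self):
        for name in self._order:
            layer = self.layers[name]
            yield f"{name}.W", layer.W
            yield f"{name}.b", layer.b

    def flatten(self) -> np.ndarray:
        return np.concatenate([p.ravel() for _, p in self.param_items()]).astype(
            np.float64
        )

    def restore(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=np.float64)
        offset = 0
        for name in self._order:
            layer = self.layers[name]
            for attr in ("W", "b"):
                arr = getattr(layer, attr)
                n = arr.size
                setattr(
                    layer, attr, vec[offset : offset + n].reshape(arr.shape).astype(np.float32)
                )
                offset += n
        if offset != vec.size:
            raise ValueError(f"parameter vector length {vec.size}, expected {offset}")

    @property
    def n_params(self) -> int:
        return sum(p.size for _, p in self.param_items())

    def copy(self) -> "MiniUNet":
        clone = MiniUNet(self.descriptor, seed=0)
        clone.restore(self.flatten())
        clone.step_counter = self.step_counter
        return clone

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray, need_cache: bool = False):
        d = self.descriptor.depth
        if x.shape[-1] % 2 ** (d - 1) or x.shape[-2] % 2 ** (d - 1):
            raise ValueError(
                f"input size {x.shape[-2:]} must be divisible by {2 ** (d - 1)}"
            )
        cache: dict = {}
        skips = []
        h = x.astype(np.float32)
        for i in range(d):
            h, cache[f"enc{i}a"] = self.layers[f"enc{i}a"].forward(h)
            h, cache[f"enc{i}a.relu"] = nn.relu(h)
            h, cache[f"enc{i}b"] = self.layers[f"enc{i}b"].forward(h)
            h, cache[f"enc{i}b.relu"] = nn.relu(h)
            if i < d - 1:
                skips.append(h)
                h, cache[f"pool{i}"] = nn.avgpool2(h)
        for i in range(d - 2, -1, -1):
            h, cache[f"up{i}"] = nn.upsample2(h)
            skip = skips[i]
            cache[f"cat{i}"] = (h.shape[1], skip.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h, cache[f"dec{i}a"] = self.layers[f"dec{i}a"].forward(h)
            h, cache[f"dec{i}a.relu"] = nn.relu(h)
            h, cache[f"dec{i}b"] = self.layers[f"dec{i}b"].forward(h)
            h, cache[f"dec{i}b.relu"] = nn.relu(h)
        logits, cache["head"] = self.layers["head"].forward(h)
        return (logits, cache) if need_cache else logits

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        d = self.descriptor.depth
        grads: dict[str, np.ndarray] = {}

        def conv_back(name, dy):
            dx, dW, db = self.layers[name].backward(dy, cache[name])
            grads[f"{name}.W"] = dW
            grads[f"{name}.b"] = db
            return dx

        dh = conv_back("head", dlogits.astype(np.float32))
        dskips = [None] * (d - 1)
        for i in range(0, d - 1):
            dh = nn.relu_back(dh, cache[f"dec{i}b.relu"])
            dh = conv_back(f"dec{i}b", dh)
            dh = nn.relu_back(dh, cache[f"dec{i}a.relu"])
            dh = conv_back(f"dec{i}a", dh)
            c_up, _ = cache[f"cat{i}"]
            dup, dskip = dh[:, :c_up], dh[:, c_up:]
            dskips[i] = dskip
            dh = nn.upsample2_back(dup, cache[f"up{i}"])
        for i in range(d - 1, -1, -1):
            if i < d - 1:
                dh = nn.avgpool2_back(dh, cache[f"pool{i}"])
                dh = dh + dskips[i]
            dh = nn.relu_back(dh, cache[f"enc{i}b.relu"])
            dh = conv_back(f"enc{i}b", dh)
            dh = nn.relu_back(dh, cache[f"enc{i}a.relu"])
            dh = conv_back(f"enc{i}a", dh)
        return grads

    def prepare(self, images: np.ndarray) -> np.ndarray:
        """Stack a (N, H, W) grayscale batch into the network input,
        appending the x-coordinate channel when the descriptor asks for it."""
        if images.ndim == 3:
            images = images[:, None]
        n_extra = self.descriptor.in_channels - images.shape[1]
        if n_extra == 1:
            H, W = images.shape[-2:]
            xs = np.linspace(-1.0, 1.0, W, dtype=np.float32)
            coord = np.broadcast_to(xs, (images.shape[0], 1, H, W))
            images = np.concatenate([images.astype(np.float32), coord], axis=1)
        elif n_extra != 0:
            raise ValueError(
                f"cannot map {images.shape[1]} image channels to "
                f"{self.descriptor.in_channels} input channels"
            )
        return images

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax label maps for a (N, H, W) or (N, 1, H, W) image batch."""
        logits = self.forward(self.prepare(images))
        return logits.argmax(axis=1)

    # -- checkpointing --------------------------------------------------------

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            descriptor=np.frombuffer(self.descriptor.to_json().encode(), dtype=np.uint8),
            params=self.flatten(),
            step_counter=self.step_counter,
        )

    @classmethod
    def load(cls, path) -> "MiniUNet":
        with np.load(path) as z:
            desc = ModelDescriptor.from_json(bytes(z["descriptor"]).decode())
            model = cls(desc, seed=0)
            model.restore(z["params"])
            model.step_counter = int(z["step_counter"])
        return model


def build_model(descriptor: ModelDescriptor, seed: int) -> MiniUNet:
    """Deterministically initialized backbone for the given descriptor."""
    return MiniUNet(descriptor, seed=seed)


# ---------------------------------------------------------------------------
# Optimizer and loss plumbing
# ---------------------------------------------------------------------------


@dataclass
class OptimizerConfig:
    """Adam hyperparameters. The learning rate and weight decay are validated
    against the explored ranges (lr in [1e-4, 1e-2], weight decay in
    [1e-8, 1e-3]); zero is additionally allowed for either to disable it.

    ``clip_norm`` caps the global gradient norm per step (0 disables) and
    ``lr_decay="cosine"`` anneals the learning rate to zero over the planned
    step budget — both standard stabilizers against rare exploding updates
    late in training on a small, noisy dataset.
    """

    lr: float = 1e-3
    weight_decay: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 8
    clip_norm: float = 5.0
    lr_decay: str = "none"  # "none" | "cosine"

    def __post_init__(self):
        if self.lr != 0.0 and not (1e-4 <= self.lr <= 1e-2):
            raise ValueError(f"learning rate {self.lr} outside [1e-4, 1e-2] (or 0)")
        if self.weight_decay != 0.0 and not (1e-8 <= self.weight_decay <= 1e-3):
            raise ValueError(
                f"weight decay {self.weight_decay} outside [1e-8, 1e-3] (or 0)"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.clip_norm < 0:
            raise ValueError("clip_norm must be >= 0")
        if self.lr_decay not in ("cosine", "none"):
            raise ValueError("lr_decay must be 'cosine' or 'none'")


class Adam:
    """Adam with optional global-norm clipping and cosine annealing.

    ``total_steps``/``step_offset`` position the decay schedule; without a
    total the learning rate stays constant.
    """

    def __init__(
        self,
        model: MiniUNet,
        config: OptimizerConfig,
        total_steps: int | None = None,
        step_offset: int = 0,
    ):
        self.cfg = config
        self.total_steps = total_steps
        self.m = {k: np.zeros_like(p) for k, p in model.param_items()}
        self.v = {k: np.zeros_like(p) for k, p in model.param_items()}
        self.t = 0
        self.step_offset = step_offset

    def current_lr(self) -> float:
        lr = self.cfg.lr
        if self.cfg.lr_decay == "cosine" and self.total_steps:
            frac = min(self.t + self.step_offset, self.total_steps) / self.total_steps
            lr = lr * 0.5 * (1.0 + np.cos(np.pi * frac))
        return lr

    def step(self, model: MiniUNet, grads: dict[str, np.ndarray]) -> None:
        if self.cfg.lr == 0.0:
            return
        c = self.cfg
        if c.clip_norm > 0:
            sq = 0.0
            for g in grads.values():
                sq += float((g.astype(np.float64) ** 2).sum())
            norm = np.sqrt(sq)
            if norm > c.clip_norm:
                scale = np.float32(c.clip_norm / norm)
                grads = {k: g * scale for k, g in grads.items()}
        lr = self.current_lr()
        self.t += 1
        b1t = 1 - c.beta1**self.t
        b2t = 1 - c.beta2**self.t
        for name in self.m:
            layer_name, attr = name.rsplit(".", 1)
            layer = model.layers[layer_name]
            p = getattr(layer, attr)
            g = grads[name] + c.weight_decay * p
            self.m[name] = c.beta1 * self.m[name] + (1 - c.beta1) * g
            self.v[name] = c.beta2 * self.v[name] + (1 - c.beta2) * g * g
            update = lr * (self.m[name] / b1t) / (np.sqrt(self.v[name] / b2t) + c.eps)
            setattr(layer, attr, (p - update).astype(np.float32))


@dataclass
class LossSpec:
    """What the epoch loop should optimize.

    ``kind`` is ``ce`` (plain cross-entropy) or a progressive variant
    (``spl``/``tpl``) driven by ``schedule``.  ``ref_mean_iou`` is the
    previous completed epoch's mean per-sample IoU (the detached epoch-mean
    reference for the performance gaps); ``None`` makes all gaps zero, so the
    first epoch trains on the plain loss.  ``prox_mu``/``prox_ref`` add the
    federated proximal pull toward the last global parameters.
    """

    kind: str = "ce"
    schedule: LossSchedule | None = None
    ref_mean_iou: float | None = None
    prox_mu: float = 0.0
    prox_ref: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("ce", "spl", "tpl"):
            raise ValueError(f"loss kind must be ce/spl/tpl, got {self.kind!r}")
        if self.kind != "ce" and self.schedule is None:
            raise ValueError(f"loss kind {self.kind!r} requires a LossSchedule")


@dataclass
class EpochPerformance:
    """Per-sample hard IoU cache from the latest completed epoch."""

    per_sample: dict[str, float]
    epoch: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_sample.values())))


def _soft_iou_grad_to_logits(probs_i, gprobs_i):
    # chain rule through channelwise softmax: dz = p * (g - sum_c g_c p_c)
    inner = (gprobs_i * probs_i).sum(axis=0, keepdims=True)
    return probs_i * (gprobs_i - inner)


def train_epoch(
    model: MiniUNet,
    dataset: dict[str, SampleRecord],
    order: list[str],
    loss_spec: LossSpec,
    optimizer: Adam | OptimizerConfig | None = None,
    seed: int = 0,
    epoch: int = 1,
) -> tuple[MiniUNet, EpochPerformance, float]:
    """One training pass over ``order`` (visited verbatim, batched
    sequentially).  Returns the updated model, the post-epoch per-sample
    hard-IoU cache, and the mean training loss.

    The epoch loop itself draws no randomness (ordering and initialization
    carry all of it); ``seed`` is accepted for interface stability.
    """
    if not order:
        raise ValueError("empty curriculum order")
    missing = [i for i in order if i not in dataset]
    if missing:
        raise KeyError(f"order references unknown samples: {missing[:5]}")
    if optimizer is None:
        optimizer = OptimizerConfig()
    if isinstance(optimizer, OptimizerConfig):
        optimizer = Adam(model, optimizer)
    cfg = optimizer.cfg
    total_loss, n_batches = 0.0, 0
    for start in range(0, len(order), cfg.batch_size):
        batch_ids = order[start : start + cfg.batch_size]
        imgs = model.prepare(np.stack([dataset[i].image for i in batch_ids]).astype(np.float32))
        masks = np.stack([dataset[i].mask for i in batch_ids])
        logits, cache = model.forward(imgs, need_cache=True)
        probs = nn.softmax_channels(logits.astype(np.float64))
        ce_losses, dce = nn.cross_entropy_per_sample(probs, masks)
        N = len(batch_ids)
        if loss_spec.kind == "ce":
            batch_loss = float(ce_losses.mean())
            dlogits = dce / N
        else:
            sched = loss_spec.schedule
            step = min(model.step_counter, sched.total_steps)
            w = weight_at(sched, step)
            ref = loss_spec.ref_mean_iou
            softs, sgrads = [], []
            for i in range(N):
                val, g = soft_iou_with_grad(probs[i], masks[i])
                softs.append(val)
                sgrads.append(g)
            deltas = (
                np.zeros(N) if ref is None else np.asarray(softs) - float(ref)
            )
            if sched.mode == "reweight":
                mult_fn = spl_multiplier if sched.variant == "spl" else tpl_multiplier
                mults = np.array([mult_fn(d, w) for d in deltas])
                batch_loss = float((mults * ce_losses).mean())
                dlogits = (mults[:, None, None, None] * dce) / N
            else:  # additive: literal formula, gradient via soft IoU
                if sched.variant == "spl":
                    pen_coeff = np.where(deltas > 0, w, 0.0)
                    pen = w * np.maximum(deltas, 0.0).sum()
                else:
                    pen_coeff = np.where(w * deltas > 0, w, 0.0)
                    pen = np.maximum(w * deltas, 0.0).sum()
                batch_loss = float(ce_losses.mean() + pen / N)
                dlogits = dce.copy()
                for i in range(N):
                    if pen_coeff[i] != 0.0:
                        dlogits[i] += pen_coeff[i] * _soft_iou_grad_to_logits(
                            probs[i], sgrads[i]
                        )
                dlogits /= N
        grads = model.backward(dlogits, cache)
        if loss_spec.prox_mu > 0.0 and loss_spec.prox_ref is not None:
            # proximal pull mu*(theta - theta_global), added per parameter
            offset = 0
            ref_vec = np.asarray(loss_spec.prox_ref, dtype=np.float64)
            for name, p in model.param_items():
                n = p.size
                grads[name] = grads[name] + loss_spec.prox_mu * (
                    p.astype(np.float64) - ref_vec[offset : offset + n].reshape(p.shape)
                ).astype(np.float32)
                offset += n
        optimizer.step(model, grads)
        model.step_counter += 1
        total_loss += batch_loss
        n_batches += 1
    perf = EpochPerformance(
        per_sample=evaluate(model, [dataset[i] for i in order]), epoch=epoch
    )
    return model, perf, total_loss / n_batches


def evaluate(
    model: MiniUNet, samples: list[SampleRecord], batch_size: int = 16
) -> dict[str, float]:
    """Gradient-free per-sample hard IoU of the model on ``samples``."""
    if not samples:
        raise ValueError("evaluate requires at least one sample")
    out: dict[str, float] = {}
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        preds = model.predict(np.stack([s.image for s in chunk]).astype(np.float32))
        for s, p in zip(chunk, preds):
            out[s.sample_id] = iou_multiclass(p, s.mask)
    return out
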