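"""Progressive loss functions with a +alpha -> -alpha weight schedule.

Two variants modulate a standard pixelwise cross-entropy by the per-sample
performance gap ``dP_i = softIoU_i - IoU_avg`` (the sample's differentiable
IoU minus the previous epoch's mean IoU):

* **SPL** (selective):  ``L = L_std + w * sum_i max(dP_i, 0)``
* **TPL** (tiered):     ``L = L_std + sum_i max(w * dP_i, 0)``

The weight ``w`` sweeps linearly from ``+alpha`` at the first optimizer step
to ``-alpha`` at the last, moving the emphasis from easier (above-average)
samples early in training to harder (below-average) samples late.

Because a hard IoU term would contribute no gradient, two gradient
semantics are provided:

* ``additive`` — the literal formulas above, with ``dP_i`` flowing gradients
  through a differentiable soft IoU and the epoch mean detached;
* ``reweight`` (default) — per-sample loss multipliers
  ``1 + w*max(dP_i,0)`` (SPL) or ``1 + max(w*dP_i,0)`` (TPL), floored at 0,
  with ``dP_i`` fully detached, so easy/hard samples scale their own
  cross-entropy gradients.

At ``w = 0`` (mid-schedule) both variants and both modes reduce exactly to
the standard loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VARIANTS = ("spl", "tpl")
MODES = ("reweight", "additive")


@dataclass(frozen=True)
class LossSchedule:
    """Linear weight schedule w(step) = alpha - 2*alpha*step/total_steps."""

    alpha: float = 1.0
    total_steps: int = 1
    variant: str = "tpl"
    mode: str = "reweight"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def weight_at(schedule: LossSchedule, step: int) -> float:
    """Interpolated loss weight: +alpha at step 0, 0 at the midpoint,
    -alpha at the final step."""
    if not (0 <= step <= schedule.total_steps):
        raise ValueError(f"step {step} outside [0, {schedule.total_steps}]")
    a = schedule.alpha
    return a - 2.0 * a * step / schedule.total_steps


def soft_iou(pred_probs: np.ndarray, true_mask: np.ndarray) -> float:
    """Differentiable IoU surrogate on per-class probability maps.

    ``pred_probs`` has shape (C, H, W) with classes summing to 1 per pixel.
    Per foreground class, softIoU = sum(p*y) / sum(p + y - p*y), macro
    averaged over the classes present in the truth plus any foreground class
    the prediction's argmax asserts — the same class-selection rule as the
    hard metric, so one-hot probabilities reproduce hard IoU exactly.
    """
    value, _ = soft_iou_with_grad(pred_probs, true_mask)
    return value


def _soft_iou_classes(pred_probs: np.ndarray, true_mask: np.ndarray) -> np.ndarray:
    hard_pred = pred_probs.argmax(axis=0)
    classes = np.union1d(np.unique(true_mask), np.unique(hard_pred))
    return classes[classes != 0].astype(int)


def soft_iou_with_grad(
    pred_probs: np.ndarray, true_mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Soft IoU and its gradient with respect to ``pred_probs``."""
    probs = np.asarray(pred_probs, dtype=np.float64)
    true = np.asarray(true_mask)
    if probs.ndim != 3 or probs.shape[1:] != true.shape:
        raise ValueError(
            f"pred_probs shape {probs.shape} incompatible with mask {true.shape}"
        )
    classes = _soft_iou_classes(probs, true)
    grad = np.zeros_like(probs)
    if classes.size == 0:
        return 1.0, grad
    vals = []
    for c in classes:
        y = (true == c).astype(np.float64)
        p = probs[c]
        inter = float((p * y).sum())
        union = float((p + y - p * y).sum())
        if union <= 0:
            continue
        vals.append(inter / union)
        # d(I/U)/dp = (y*U - I*(1-y)) / U^2
        grad[c] += (y * union - inter * (1.0 - y)) / union**2
    if not vals:
        return 1.0, grad
    grad /= len(vals)
    return float(np.mean(vals)), grad


def spl_multiplier(delta: float, w: float) -> float:
    """Per-sample loss multiplier for SPL in reweight mode (floored at 0)."""
    return max(1.0 + w * max(delta, 0.0), 0.0)


def tpl_multiplier(delta: float, w: float) -> float:
    """Per-sample loss multiplier for TPL in reweight mode (floored at 0)."""
    return max(1.0 + max(w * delta, 0.0), 0.0)


def penalty(deltas: np.ndarray, w: float, variant: str) -> float:
    """The progressive penalty term over a batch of performance gaps."""
    d = np.asarray(deltas, dtype=float)
    if variant == "spl":
        return float(w * np.maximum(d, 0.0).sum())
    if variant == "tpl":
        return float(np.maximum(w * d, 0.0).sum())
    raise ValueError(f"variant must be one of {VARIANTS}")


def progressive_term(
    batch_losses,
    deltas,
    w: float,
    variant: str = "tpl",
    mode: str = "reweight",
) -> float:
    """Total batch loss under a progressive variant.

    Additive mode returns ``mean(losses) + penalty / batch_size`` — the
    dataset-level sum of the formula is estimated per batch and normalized
    by batch size so the term is invariant to batching.  Reweight mode
    returns the mean of the per-sample losses scaled by their progressive
    multipliers.
    """
    losses = np.asarray(batch_losses, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if losses.shape != d.shape:
        raise ValueError("batch_losses and deltas must align")
    if losses.size == 0:
        raise ValueError("empty batch")
    if mode == "additive":
        return float(losses.mean() + penalty(d, w, variant) / losses.size)
    if mode == "reweight":
        mult = {"spl": spl_multiplier, "tpl": tpl_multiplier}[variant]
        return float(np.mean([m * l for m, l in zip((mult(x, w) for x in d), losses)]))
    raise ValueError(f"mode must be one of {MODES}")
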