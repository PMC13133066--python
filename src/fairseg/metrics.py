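"""Segmentation accuracy and subgroup fairness metrics.

Accuracy is measured by multi-class Intersection over Union (IoU).  Fairness
is summarized over the protected race-gender subgroups by:

* **SER** (Skewed Error Ratio): max over min group error rate, where the
  error rate of group *g* is ``1 - IoU_g``; 1 means no skew.
* **MMD** (Min-Max Disparity): difference between the best and worst group
  mean IoU; 0 means parity.
* **IoU SD**: population standard deviation of the four race-gender group
  mean IoUs (group-level, not sample-level spread).

Per-sample IoU vectors from two configurations are compared with a
two-tailed paired t-test at the conventional 0.05 threshold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .groups import GroupKey

logger = logging.getLogger(__name__)

#: clamp for the SER denominator so a group at IoU 1.0 does not divide by zero
SER_EPS = 1e-6


def iou_multiclass(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Macro-averaged IoU over foreground classes.

    For each non-background class present in the truth (and any foreground
    class present only in the prediction), the per-class IoU is pixel
    intersection over union of the binarized masks; classes with an empty
    union are skipped.  If neither mask contains foreground the score is 1.0
    by convention (nothing to segment, nothing segmented).
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs true {true.shape}")
    classes = np.union1d(np.unique(true), np.unique(pred))
    classes = classes[classes != 0]
    if classes.size == 0:
        return 1.0
    scores = []
    for c in classes:
        p = pred == c
        t = true == c
        union = np.logical_or(p, t).sum()
        if union == 0:
            continue
        scores.append(np.logical_and(p, t).sum() / union)
    return float(np.mean(scores)) if scores else 1.0


def group_mean_ious(
    scores: dict[str, float],
    metadata: dict[str, GroupKey],
    grouping: str = "race_gender",
) -> dict:
    """Arithmetic mean IoU per group under the requested grouping
    (``race_gender``, ``race`` or ``gender``); empty groups are omitted."""
    if grouping not in ("race_gender", "race", "gender"):
        raise ValueError(f"unknown grouping {grouping!r}")
    buckets: dict[object, list[float]] = {}
    for sid, score in scores.items():
        if sid not in metadata:
            raise KeyError(f"sample {sid!r} has a score but no metadata")
        g = metadata[sid]
        key = {"race_gender": g, "race": g.race, "gender": g.gender}[grouping]
        buckets.setdefault(key, []).append(score)
    return {k: float(np.mean(v)) for k, v in buckets.items()}


def ser(group_means: dict) -> float:
    """Skewed Error Ratio: max_g(1 - IoU_g) / min_g(1 - IoU_g).

    The denominator is clamped at ``SER_EPS``; a single group gives 1.0.
    """
    if not group_means:
        raise ValueError("ser requires at least one group")
    if len(group_means) == 1:
        return 1.0
    errors = np.array([1.0 - v for v in group_means.values()])
    return float(errors.max() / max(errors.min(), SER_EPS))


def mmd(group_means: dict) -> float:
    """Min-Max Disparity: max_g IoU_g - min_g IoU_g (0 for a single group)."""
    if not group_means:
        raise ValueError("mmd requires at least one group")
    vals = np.array(list(group_means.values()))
    return float(vals.max() - vals.min())


def paired_t_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-tailed paired t-test on aligned per-sample score vectors.

    Uses the sample SD (n-1 denominator) and the t distribution with n-1 df.
    Degenerate zero-variance differences: p = 1.0 when the mean difference is
    zero (identical performance) and p = 0.0 otherwise (a systematic shift
    with no noise).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired t-test requires equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        return (0.0, 1.0) if mean == 0 else (math.inf * np.sign(mean), 0.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


#: significance threshold for per-sample IoU comparisons
P_THRESHOLD = 0.05


@dataclass
class FairnessReport:
    """Accuracy + fairness summary in the standard table column order:
    Mean IoU, IoU SD, R&G mean SER, MMD."""

    mean_iou: float
    iou_sd: float
    ser_race: float
    ser_gender: float
    rg_mean_ser: float
    mmd: float
    group_means: dict[GroupKey, float] = field(default_factory=dict)
    n_samples: int = 0

    COLUMNS = ("mean_iou", "iou_sd", "rg_mean_ser", "mmd")

    def to_row(self) -> list[float]:
        return [self.mean_iou, self.iou_sd, self.rg_mean_ser, self.mmd]

    def to_dict(self) -> dict:
        return {
            "mean_iou": self.mean_iou,
            "iou_sd": self.iou_sd,
            "ser_race": self.ser_race,
            "ser_gender": self.ser_gender,
            "rg_mean_ser": self.rg_mean_ser,
            "mmd": self.mmd,
            "group_means": {g.code: v for g, v in self.group_means.items()},
            "n_samples": self.n_samples,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def fairness_report(
    scores: dict[str, float],
    metadata: dict[str, GroupKey],
    iou_sd_over: str = "groups",
) -> FairnessReport:
    """Full fairness summary of a per-sample IoU map.

    ``iou_sd`` is the population SD of the race-gender group means
    (``iou_sd_over="groups"``, the default) or of the raw per-sample scores
    (``"samples"``); ``rg_mean_ser`` averages the race-wise and gender-wise
    SER.  With fewer than two race-gender groups present the SER fields
    default to 1.0 (no measurable skew) and a warning is logged.
    """
    if not scores:
        raise ValueError("fairness_report requires at least one scored sample")
    if iou_sd_over not in ("groups", "samples"):
        raise ValueError("iou_sd_over must be 'groups' or 'samples'")
    rg_means = group_mean_ious(scores, metadata, "race_gender")
    if len(rg_means) < 2:
        logger.warning(
            "fewer than two race-gender groups present; SER fields default to 1.0"
        )
        ser_race = ser_gender = 1.0
    else:
        ser_race = ser(group_mean_ious(scores, metadata, "race"))
        ser_gender = ser(group_mean_ious(scores, metadata, "gender"))
    group_vals = np.array(list(rg_means.values()))
    sd_basis = group_vals if iou_sd_over == "groups" else np.array(list(scores.values()))
    return FairnessReport(
        mean_iou=float(np.mean(list(scores.values()))),
        iou_sd=float(sd_basis.std(ddof=0)),
        ser_race=ser_race,
        ser_gender=ser_gender,
        rg_mean_ser=(ser_race + ser_gender) / 2.0,
        mmd=mmd(rg_means),
        group_means=rg_means,
        n_samples=len(scores),
    )
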