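"""Per-epoch training-order schedulers: shuffled baseline, demographic
interleaving, self-paced, teacher-student and balanced growing-subset
curricula.

All schedulers emit a :class:`CurriculumOrder` — a permutation of the active
training ids — consumed verbatim by the training loop.  Sample "ease" is
proxied by per-sample IoU from the previous epoch: higher IoU means easier,
and curricula present easier samples first.  Demographic interleaving cycles
the four race-gender groups in a fixed order so that consecutive samples
alternate between subgroups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .groups import GROUP_ORDER, GroupKey, substream

logger = logging.getLogger(__name__)

CurriculumOrder = list[str]  # permutation of the active sample ids
EaseScore = dict[str, float]  # sample_id -> ease, higher = easier


def _check_permutation(order: list[str], ids) -> None:
    if len(order) != len(set(order)) or set(order) != set(ids):
        raise AssertionError("curriculum order is not a permutation of the active set")


def order_shuffled(ids: list[str], seed: int) -> CurriculumOrder:
    """Uniform random permutation; the standard-baseline ordering."""
    if not ids:
        raise ValueError("cannot order an empty id list")
    rng = substream(seed, "shuffle")
    ids_sorted = sorted(ids)
    return [ids_sorted[i] for i in rng.permutation(len(ids_sorted))]


def order_interleaved(
    ids: list[str],
    groups: dict[str, GroupKey],
    seed: int,
    ease: EaseScore | None = None,
) -> CurriculumOrder:
    """Round-robin demographic interleaving over the four subgroups.

    Within each group the next sample is drawn uniformly at random (no ease
    given) or taken in descending ease order (ease given; ties broken by
    sample_id).  Groups that run out are skipped, so the order covers every
    id exactly once.
    """
    missing = [i for i in ids if i not in groups]
    if missing:
        raise KeyError(f"samples without a group: {missing[:5]}")
    rng = substream(seed, "interleave")
    queues: dict[GroupKey, list[str]] = {g: [] for g in GROUP_ORDER}
    for sid in sorted(ids):
        queues.setdefault(groups[sid], []).append(sid)
    for g, q in queues.items():
        if ease is not None:
            q.sort(key=lambda s: (-ease[s], s))
        else:
            rng_g = substream(seed, "interleave", g.code)
            perm = rng_g.permutation(len(q))
            queues[g] = [q[i] for i in perm]
    cursors = {g: 0 for g in queues}
    out: CurriculumOrder = []
    cycle = [g for g in GROUP_ORDER if queues.get(g)] + [
        g for g in queues if g not in GROUP_ORDER and queues[g]
    ]
    while len(out) < len(ids):
        for g in cycle:
            q = queues[g]
            if cursors[g] < len(q):
                out.append(q[cursors[g]])
                cursors[g] += 1
    _check_permutation(out, ids)
    return out


def score_self_paced(prev_iou: dict[str, float], ids: list[str]) -> EaseScore:
    """Self-paced ease: previous-epoch per-sample IoU (higher = easier).

    The caller falls back to :func:`order_shuffled` for epoch 1, when no
    previous-epoch performance exists.
    """
    missing = [i for i in ids if i not in prev_iou]
    if missing:
        raise KeyError(f"previous-epoch IoU missing for: {missing[:5]}")
    return {i: float(prev_iou[i]) for i in ids}


def score_teacher_student(
    teacher: dict[str, float], student: dict[str, float]
) -> EaseScore:
    """Teacher-student ease: negated performance gap (teacher - student).

    A small gap means the student is close to the teacher's attainable
    accuracy on that sample, classifying it as easy; a student exceeding the
    teacher (negative gap) is easier still.  Recomputed after every epoch, so
    the signal tracks the evolving gap rather than the teacher's absolute
    score.
    """
    if set(teacher) != set(student):
        raise KeyError("teacher and student IoU maps cover different samples")
    return {i: float(-(teacher[i] - student[i])) for i in teacher}


@dataclass
class BCLState:
    """Growing-subset state for the balanced curriculum.

    ``active`` holds the ids trained on this epoch; ``pool`` the unseen rest.
    The active fraction starts at ``start_fraction`` of the training set and
    grows linearly to 1 by the final epoch.
    """

    all_ids: list[str]
    active: list[str] = field(default_factory=list)
    pool: list[str] = field(default_factory=list)
    epoch: int = 0
    start_fraction: float = 0.2

    @property
    def fraction(self) -> float:
        return len(self.active) / max(len(self.all_ids), 1)


def bcl_target_size(n: int, epoch: int, total_epochs: int, start_fraction: float = 0.2) -> int:
    """Linear growth schedule: ``start_fraction`` of the data at epoch 1,
    the full set at the final epoch."""
    if total_epochs <= 1:
        return n
    frac = start_fraction + (1.0 - start_fraction) * (epoch - 1) / (total_epochs - 1)
    # guard against float dust (e.g. 0.6000000000000001) inflating the ceil
    return min(n, math.ceil(n * frac - 1e-9))


def bcl_init(
    ids: list[str],
    groups: dict[str, GroupKey],
    seed: int,
    start_fraction: float = 0.2,
    total_epochs: int = 1,
) -> BCLState:
    """Epoch-1 state: a demographically balanced random subset.

    Per-group quotas are equal shares of the target size (largest-remainder
    rounding, ties by group order), capped at group availability.
    """
    if not ids:
        raise ValueError("cannot initialize BCL on an empty training set")
    all_ids = sorted(ids)
    target = bcl_target_size(len(all_ids), 1, total_epochs, start_fraction)
    by_group: dict[GroupKey, list[str]] = {}
    for sid in all_ids:
        by_group.setdefault(groups[sid], []).append(sid)
    present = [g for g in GROUP_ORDER if g in by_group] + [
        g for g in by_group if g not in GROUP_ORDER
    ]
    raw = target / len(present)
    quotas = {g: math.floor(raw) for g in present}
    short = target - sum(quotas.values())
    for g in present[:short]:
        quotas[g] += 1
    active: list[str] = []
    for g in present:
        rng = substream(seed, "bcl-init", g.code)
        members = by_group[g]
        take = min(quotas[g], len(members))
        picks = rng.permutation(len(members))[:take]
        active.extend(members[i] for i in picks)
    # spill unmet quotas into remaining samples, keeping the target size
    if len(active) < target:
        leftovers = sorted(set(all_ids) - set(active))
        rng = substream(seed, "bcl-init", "spill")
        picks = rng.permutation(len(leftovers))[: target - len(active)]
        active.extend(leftovers[i] for i in picks)
    active = sorted(active)
    pool = sorted(set(all_ids) - set(active))
    return BCLState(
        all_ids=all_ids, active=active, pool=pool, epoch=1, start_fraction=start_fraction
    )


def bcl_update(
    state: BCLState,
    pool_ease: EaseScore,
    epoch: int,
    total_epochs: int,
    seed: int = 0,
) -> BCLState:
    """Advance the growing subset to ``epoch``.

    The target size follows the linear schedule; the easiest pool samples
    (highest ease, i.e. highest IoU under a gradient-free forward pass) are
    admitted until the target is met.  The final epoch always activates the
    full training set.  If the pool is smaller than the required admission,
    everything left is admitted and a log entry records it.
    """
    if epoch > total_epochs:
        raise ValueError(f"epoch {epoch} exceeds total_epochs {total_epochs}")
    n = len(state.all_ids)
    target = n if epoch >= total_epochs else bcl_target_size(
        n, epoch, total_epochs, state.start_fraction
    )
    needed = max(0, target - len(state.active))
    pool = list(state.pool)
    if needed > len(pool):
        logger.info(
            "BCL pool exhausted at epoch %d: admitting all %d remaining (needed %d)",
            epoch, len(pool), needed,
        )
        needed = len(pool)
    missing = [i for i in pool if i not in pool_ease]
    if needed and missing:
        raise KeyError(f"pool ease missing for: {missing[:5]}")
    pool.sort(key=lambda s: (-pool_ease.get(s, -np.inf), s))
    admitted = pool[:needed]
    active = sorted(state.active + admitted)
    remaining = sorted(set(state.all_ids) - set(active))
    return BCLState(
        all_ids=state.all_ids,
        active=active,
        pool=remaining,
        epoch=epoch,
        start_fraction=state.start_fraction,
    )
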