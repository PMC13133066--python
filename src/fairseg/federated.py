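"""Multi-site federated training simulation with six aggregation strategies.

Each communication round broadcasts the global parameters, trains every
client locally (optionally under a curriculum and a progressive loss),
optionally perturbs updates with Gaussian noise for differential privacy,
and aggregates a convex combination of the client parameter vectors:

* ``fedavg``          — weights proportional to local sample counts n_k;
* ``fedprox``         — FedAvg aggregation, plus a proximal term
                        (mu/2)*||theta - theta_global||^2 in each local step;
* ``feddp``           — FedAvg on noise-perturbed updates;
* ``feddpfair``       — noise-perturbed updates weighted by 1/SER_k, so
                        clients with fairer local performance count more;
* ``fediou``          — weights proportional to the client's local mean IoU;
* ``fediou_outlier``  — FedIoU restricted to clients whose local IoU is not
                        an IQR outlier (IoU_k >= Q1 - 1.5*IQR).

Client scores (IoU_k, SER_k) are computed on a small local validation split
held out from each client's data.  Excluded outlier clients still receive
the new global model next round — exclusion is per-round, never permanent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .curriculum import bcl_init, bcl_update, order_interleaved, order_shuffled, score_self_paced
from .data import SampleRecord, metadata_groups
from .groups import substream
from .losses import LossSchedule
from .metrics import FairnessReport, fairness_report, group_mean_ious, ser
from .model import Adam, LossSpec, MiniUNet, ModelDescriptor, OptimizerConfig, build_model, evaluate, train_epoch

logger = logging.getLogger(__name__)

STRATEGIES = ("fedavg", "fedprox", "feddp", "feddpfair", "fediou", "fediou_outlier")


@dataclass
class ClientUpdate:
    """One client's post-training contribution to a round."""

    client_id: str
    params: np.ndarray  # flat parameter vector
    n_k: int  # local training sample count
    iou_k: float  # mean hard IoU on the local validation split
    ser_k: float  # R&G mean SER on that split

    def __post_init__(self):
        if self.n_k < 1:
            raise ValueError("n_k must be >= 1")
        if not (0.0 <= self.iou_k <= 1.0):
            raise ValueError("iou_k must lie in [0, 1]")
        if self.ser_k < 1.0:
            raise ValueError("ser_k must be >= 1")


@dataclass
class AggregationConfig:
    strategy: str = "fedavg"
    sigma: float = 0.001  # DP noise SD (within the explored 1e-5..0.1 range)
    mu: float = 0.01  # FedProx proximal coefficient
    iqr_multiplier: float = 1.5
    rounds: int = 20
    local_epochs: int = 1
    curriculum: str = "base"  # base | ri | scl | bcl
    loss: str = "ce"  # ce | spl | tpl
    alpha: float = 1.0
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class FederationHistory:
    """Per-round audit trail of a federation run."""

    reports: list[FairnessReport] = field(default_factory=list)
    weights: list[dict[str, float]] = field(default_factory=list)
    excluded: list[list[str]] = field(default_factory=list)
    client_ious: list[dict[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Aggregation algebra
# ---------------------------------------------------------------------------


def fedprox_penalty(local_params: np.ndarray, global_params: np.ndarray, mu: float) -> float:
    """Proximal term (mu/2) * ||theta - theta_global||^2."""
    a = np.asarray(local_params, dtype=np.float64)
    b = np.asarray(global_params, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("parameter vectors differ in length")
    d = a - b
    return float(mu / 2.0 * (d @ d))


def dp_perturb(params: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise (SD sigma) to every parameter."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    params = np.asarray(params, dtype=np.float64)
    if sigma == 0:
        return params.copy()
    rng = substream(seed, "dp-noise")
    return params + rng.normal(0.0, sigma, size=params.shape)


def client_weights(updates: list[ClientUpdate], strategy: str) -> np.ndarray:
    """Normalized aggregation weights for a round.

    Raw scores: sample counts (fedavg/fedprox/feddp), 1/SER_k (feddpfair) or
    IoU_k (fediou variants), normalized to sum to one.  If all raw scores
    vanish the weights fall back to uniform with a warning.
    """
    if not updates:
        raise ValueError("client_weights requires at least one update")
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    if strategy in ("fedavg", "fedprox", "feddp"):
        raw = np.array([u.n_k for u in updates], dtype=float)
    elif strategy == "feddpfair":
        raw = np.array([1.0 / u.ser_k for u in updates])
    else:  # fediou, fediou_outlier
        raw = np.array([u.iou_k for u in updates])
    total = raw.sum()
    if total <= 0:
        logger.warning("all raw aggregation scores are zero; using uniform weights")
        return np.full(len(updates), 1.0 / len(updates))
    return raw / total


def iqr_filter(iou_scores, multiplier: float = 1.5) -> list[int]:
    """Indices of clients whose IoU is not a low outlier.

    Quartiles use linear interpolation between closest ranks; the retention
    threshold is Q1 - multiplier*IQR and boundary scores are retained.  The
    retained set is never empty (the maximum cannot fall below the
    threshold).
    """
    scores = np.asarray(iou_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("iqr_filter requires at least one score")
    q1, q3 = np.percentile(scores, [25, 75])
    threshold = q1 - multiplier * (q3 - q1)
    return [int(i) for i in np.flatnonzero(scores >= threshold)]


def aggregate(
    updates: list[ClientUpdate], weights: np.ndarray, subset: list[int] | None = None
) -> np.ndarray:
    """Convex combination of client parameter vectors over ``subset``
    (weights re-normalized over the subset)."""
    if subset is None:
        subset = list(range(len(updates)))
    if not subset:
        raise ValueError("cannot aggregate an empty client subset")
    w = np.asarray(weights, dtype=float)[subset]
    w = w / w.sum()
    stacked = np.stack([np.asarray(updates[i].params, dtype=np.float64) for i in subset])
    return w @ stacked


# ---------------------------------------------------------------------------
# Local training
# ---------------------------------------------------------------------------


def split_local_validation(
    samples: list[SampleRecord], fraction: float, seed: int
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Hold out a stratified (per-group) validation share of a client's data.
    Every group keeps at least one training sample; singleton groups are not
    held out."""
    by_group: dict = {}
    for rec in samples:
        by_group.setdefault(rec.group, []).append(rec)
    train, val = [], []
    for g in sorted(by_group, key=lambda k: (k.race, k.gender)):
        members = sorted(by_group[g], key=lambda r: r.sample_id)
        n_val = int(round(len(members) * fraction))
        n_val = min(n_val, len(members) - 1)
        rng = substream(seed, "local-val", g.code)
        perm = rng.permutation(len(members))
        val.extend(members[i] for i in perm[:n_val])
        train.extend(members[i] for i in perm[n_val:])
    if not val:  # tiny client: reuse training data for scoring
        val = list(train)
    return train, val


def _local_order(curriculum, ids, groups, prev_perf, bcl_state, seed, epoch, total_epochs, model, dataset):
    """Resolve the curriculum into (order, new_bcl_state) for one local epoch."""
    if curriculum == "base":
        return order_shuffled(ids, seed), bcl_state
    if curriculum == "scl" and prev_perf is None:
        # epoch 1 has no previous-epoch IoU: fall back to a shuffle
        return order_shuffled(ids, seed), bcl_state
    if curriculum == "ri":
        return order_interleaved(ids, groups, seed), bcl_state
    if curriculum == "scl":
        ease = score_self_paced(prev_perf.per_sample, ids)
        return order_interleaved(ids, groups, seed, ease=ease), bcl_state
    if curriculum == "bcl":
        if bcl_state is None:
            bcl_state = bcl_init(ids, groups, seed, total_epochs=total_epochs)
        elif epoch > 1:
            pool_recs = [dataset[i] for i in bcl_state.pool]
            pool_ease = evaluate(model, pool_recs) if pool_recs else {}
            bcl_state = bcl_update(bcl_state, pool_ease, epoch, total_epochs, seed)
        active = bcl_state.active
        ease = None
        if prev_perf is not None:
            latest = dict(prev_perf.per_sample)
            missing = [i for i in active if i not in latest]
            if missing:
                latest.update(evaluate(model, [dataset[i] for i in missing]))
            ease = {i: latest[i] for i in active}
        return order_interleaved(active, groups, seed, ease=ease), bcl_state
    raise ValueError(f"unknown curriculum {curriculum!r}")


def local_update(
    global_params: np.ndarray,
    client_id: str,
    samples: list[SampleRecord],
    descriptor: ModelDescriptor,
    config: AggregationConfig,
    round_idx: int = 1,
    total_steps: int | None = None,
    step_offset: int = 0,
) -> ClientUpdate | None:
    """Train one client from the current global parameters.

    Runs ``local_epochs`` epochs under the configured curriculum and loss
    (FedProx adds the proximal pull each step), then scores mean IoU and
    R&G mean SER on the client's held-out validation split.  Empty clients
    are skipped with a log entry (returns None).
    """
    if not samples:
        logger.info("client %s has no data; skipped this round", client_id)
        return None
    train, val = split_local_validation(samples, config.val_fraction, config.seed)
    if not train:
        train = list(samples)
    dataset = {r.sample_id: r for r in train}
    ids = sorted(dataset)
    groups = metadata_groups(train)
    model = build_model(descriptor, seed=0)
    model.restore(global_params)
    model.step_counter = step_offset
    opt = Adam(model, config.optimizer, total_steps=total_steps, step_offset=step_offset)
    schedule = None
    if config.loss in ("spl", "tpl"):
        if total_steps is None:
            import math

            steps_per_epoch = math.ceil(len(ids) / config.optimizer.batch_size)
            total_steps = max(1, config.rounds * config.local_epochs * steps_per_epoch)
        schedule = LossSchedule(
            alpha=config.alpha,
            total_steps=total_steps,
            variant=config.loss,
            mode="reweight",
        )
    prev_perf = None
    bcl_state = None
    if config.local_epochs == 0:
        # no-op training: score the global model itself
        perf_map = evaluate(model, val)
    else:
        for epoch in range(1, config.local_epochs + 1):
            epoch_seed = int(
                substream(config.seed, "fed-order", client_id, round_idx, epoch).integers(
                    2**31
                )
            )
            order, bcl_state = _local_order(
                config.curriculum, ids, groups, prev_perf, bcl_state,
                epoch_seed, epoch, config.local_epochs, model, dataset,
            )
            spec = LossSpec(
                kind=config.loss,
                schedule=schedule,
                ref_mean_iou=prev_perf.mean if prev_perf is not None else None,
                prox_mu=config.mu if config.strategy == "fedprox" else 0.0,
                prox_ref=global_params if config.strategy == "fedprox" else None,
            )
            model, prev_perf, _ = train_epoch(
                model, dataset, order, spec, opt, epoch=epoch
            )
        perf_map = evaluate(model, val)
    val_groups = metadata_groups(val)
    rg_means = group_mean_ious(perf_map, val_groups, "race_gender")
    if len(rg_means) < 2:
        ser_k = 1.0  # single-group client: no measurable local skew
    else:
        ser_race = ser(group_mean_ious(perf_map, val_groups, "race"))
        ser_gender = ser(group_mean_ious(perf_map, val_groups, "gender"))
        ser_k = (ser_race + ser_gender) / 2.0
    return ClientUpdate(
        client_id=client_id,
        params=model.flatten(),
        n_k=len(train),
        iou_k=float(np.mean(list(perf_map.values()))),
        ser_k=ser_k,
    )


# ---------------------------------------------------------------------------
# Federation driver
# ---------------------------------------------------------------------------


def run_federation(
    partition: dict[str, list[SampleRecord]],
    test_samples: list[SampleRecord],
    descriptor: ModelDescriptor,
    config: AggregationConfig,
    adversarial_clients: dict | None = None,
) -> tuple[MiniUNet, FederationHistory]:
    """Simulate ``config.rounds`` communication rounds over the site partition.

    Per round: broadcast -> local update on every client -> (feddp/feddpfair)
    Gaussian perturbation -> (fediou_outlier) IQR filter on local IoU ->
    strategy weights -> convex aggregation -> global fairness report on the
    pooled test split.  ``adversarial_clients`` maps a client id to a stub
    callable ``(global_params, round_idx) -> ClientUpdate`` used in
    robustness experiments.

    Fully seeded: equal configs and seeds give identical trajectories.
    """
    clients = {c: s for c, s in sorted(partition.items()) if s}
    if not clients:
        raise ValueError("run_federation requires at least one nonempty client")
    global_model = build_model(descriptor, seed=config.seed)
    global_params = global_model.flatten()
    history = FederationHistory()
    test_groups = metadata_groups(test_samples) if test_samples else {}
    steps_per_epoch = {
        c: int(np.ceil(len(s) * (1 - config.val_fraction) / config.optimizer.batch_size)) or 1
        for c, s in clients.items()
    }
    for rnd in range(1, config.rounds + 1):
        updates: list[ClientUpdate] = []
        for cid, samples in clients.items():
            if adversarial_clients and cid in adversarial_clients:
                upd = adversarial_clients[cid](global_params, rnd)
            else:
                total = max(1, config.rounds * config.local_epochs * steps_per_epoch[cid])
                upd = local_update(
                    global_params, cid, samples, descriptor, config,
                    round_idx=rnd, total_steps=total,
                    step_offset=(rnd - 1) * config.local_epochs * steps_per_epoch[cid],
                )
            if upd is None:
                continue
            if config.strategy in ("feddp", "feddpfair"):
                noise_seed = int(
                    substream(config.seed, "dp", cid, rnd).integers(2**31)
                )
                upd.params = dp_perturb(upd.params, config.sigma, noise_seed)
            updates.append(upd)
        if not updates:
            raise ValueError(f"round {rnd}: every client was empty")
        weights = client_weights(updates, config.strategy)
        if config.strategy == "fediou_outlier":
            retained = iqr_filter([u.iou_k for u in updates], config.iqr_multiplier)
        else:
            retained = list(range(len(updates)))
        excluded = [updates[i].client_id for i in range(len(updates)) if i not in retained]
        global_params = aggregate(updates, weights, retained)
        global_model.restore(global_params)
        w_norm = np.asarray(weights)[retained]
        w_norm = w_norm / w_norm.sum()
        history.weights.append(
            {updates[i].client_id: float(w) for i, w in zip(retained, w_norm)}
        )
        history.excluded.append(excluded)
        history.client_ious.append({u.client_id: u.iou_k for u in updates})
        if test_samples:
            scores = evaluate(global_model, test_samples)
            history.reports.append(fairness_report(scores, test_groups))
    return global_model, history
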