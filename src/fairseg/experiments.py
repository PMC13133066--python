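"""Experiment orchestration: centralized training under every curriculum x
loss combination, demographically tailored models, federated settings, and
results tables in the standard column order (Mean IoU, IoU SD, R&G mean SER,
MMD, p vs reference)."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .curriculum import bcl_init, bcl_update, order_interleaved, order_shuffled, score_self_paced, score_teacher_student
from .data import SampleRecord, metadata_groups
from .groups import GROUP_ORDER, substream
from .losses import LossSchedule
from .metrics import FairnessReport, fairness_report, paired_t_test
from .model import Adam, EpochPerformance, LossSpec, MiniUNet, ModelDescriptor, OptimizerConfig, build_model, evaluate, train_epoch

logger = logging.getLogger(__name__)

CURRICULA = ("base", "ri", "ds", "scl", "tcl", "bcl")
LOSSES = ("ce", "spl", "tpl")


@dataclass
class ExperimentConfig:
    """One training configuration.

    ``epochs`` is validated against the explored range [25, 200] unless
    ``allow_any_epochs`` is set (the small synthetic benchmarks use shorter
    schedules).
    """

    curriculum: str = "base"
    loss: str = "ce"
    loss_mode: str = "reweight"
    alpha: float = 1.0
    epochs: int = 25
    descriptor: ModelDescriptor = field(default_factory=ModelDescriptor)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 0
    allow_any_epochs: bool = False
    label: str | None = None

    def __post_init__(self):
        if self.curriculum not in CURRICULA:
            raise ValueError(f"curriculum must be one of {CURRICULA}")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if not self.allow_any_epochs and not (25 <= self.epochs <= 200):
            raise ValueError(
                f"epochs {self.epochs} outside [25, 200]; set allow_any_epochs to override"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.label is None:
            tag = self.curriculum.upper() if self.curriculum != "base" else "Base"
            if self.loss != "ce":
                tag += f"+{self.loss.upper()}"
            self.label = tag


def _resolve_order(config, model, dataset, ids, groups, epoch, prev_perf, bcl_state, teacher_perf):
    """Curriculum order for one centralized epoch; returns (order, bcl_state)."""
    seed = int(substream(config.seed, "order", epoch).integers(2**31))
    cur = config.curriculum
    if cur in ("base", "ds"):
        return order_shuffled(ids, seed), bcl_state
    if cur == "ri":
        return order_interleaved(ids, groups, seed), bcl_state
    if cur == "scl":
        if prev_perf is None:
            return order_shuffled(ids, seed), bcl_state
        ease = score_self_paced(prev_perf.per_sample, ids)
        return order_interleaved(ids, groups, seed, ease=ease), bcl_state
    if cur == "tcl":
        if prev_perf is None:
            return order_shuffled(ids, seed), bcl_state
        ease = score_teacher_student(
            {i: teacher_perf[i] for i in ids}, {i: prev_perf.per_sample[i] for i in ids}
        )
        return order_interleaved(ids, groups, seed, ease=ease), bcl_state
    if cur == "bcl":
        if bcl_state is None:
            bcl_state = bcl_init(ids, groups, seed, total_epochs=config.epochs)
        else:
            pool_recs = [dataset[i] for i in bcl_state.pool]
            pool_ease = evaluate(model, pool_recs) if pool_recs else {}
            bcl_state = bcl_update(bcl_state, pool_ease, epoch, config.epochs, seed)
        ease = None
        if prev_perf is not None:
            latest = dict(prev_perf.per_sample)
            missing = [i for i in bcl_state.active if i not in latest]
            if missing:
                latest.update(evaluate(model, [dataset[i] for i in missing]))
            ease = {i: latest[i] for i in bcl_state.active}
        return order_interleaved(bcl_state.active, groups, seed, ease=ease), bcl_state
    raise ValueError(f"unknown curriculum {cur!r}")


def train_centralized(
    train_samples: list[SampleRecord],
    config: ExperimentConfig,
    teacher_perf: dict[str, float] | None = None,
    log: list | None = None,
    log_orders: bool = False,
) -> tuple[MiniUNet, EpochPerformance]:
    """Train one model on the training split under the configured curriculum
    and loss.  For the teacher-student curriculum, ``teacher_perf`` carries
    the frozen teacher's per-sample IoU map."""
    dataset = {r.sample_id: r for r in train_samples}
    ids = sorted(dataset)
    groups = metadata_groups(train_samples)
    model = build_model(config.descriptor, seed=config.seed)
    bs = config.optimizer.batch_size
    if config.curriculum == "bcl":
        # the growing subset takes fewer steps per epoch; span schedules
        # over the planned total so w still ends at -alpha
        from .curriculum import bcl_target_size

        planned = sum(
            math.ceil(bcl_target_size(len(ids), e, config.epochs) / bs)
            for e in range(1, config.epochs + 1)
        )
    else:
        planned = config.epochs * math.ceil(len(ids) / bs)
    opt = Adam(model, config.optimizer, total_steps=max(1, planned))
    schedule = None
    if config.loss in ("spl", "tpl"):
        schedule = LossSchedule(
            alpha=config.alpha,
            total_steps=max(1, planned),
            variant=config.loss,
            mode=config.loss_mode,
        )
    if config.curriculum == "tcl" and teacher_perf is None:
        raise ValueError("TCL requires a teacher per-sample IoU map")
    prev_perf: EpochPerformance | None = None
    bcl_state = None
    for epoch in range(1, config.epochs + 1):
        order, bcl_state = _resolve_order(
            config, model, dataset, ids, groups, epoch, prev_perf, bcl_state, teacher_perf
        )
        spec = LossSpec(
            kind=config.loss,
            schedule=schedule,
            ref_mean_iou=prev_perf.mean if prev_perf is not None else None,
        )
        model, prev_perf, mean_loss = train_epoch(
            model, dataset, order, spec, opt, epoch=epoch
        )
        if log is not None:
            w = None
            if schedule is not None:
                from .losses import weight_at

                w = weight_at(schedule, min(model.step_counter, schedule.total_steps))
            entry = {
                "epoch": epoch,
                "mean_loss": mean_loss,
                "mean_train_iou": prev_perf.mean,
                "n_active": len(order),
                "w": w,
            }
            if log_orders:
                entry["order"] = list(order)
            log.append(entry)
    return model, prev_perf


def train_demographic_specific(
    train_samples: list[SampleRecord], config: ExperimentConfig
) -> dict:
    """Four independent per-group trainings (the demographically tailored
    setting); returns group -> model."""
    models = {}
    for g in GROUP_ORDER:
        subset = [r for r in train_samples if r.group == g]
        if not subset:
            continue
        sub_cfg = replace(config, curriculum="base", seed=config.seed, label=None)
        models[g], _ = train_centralized(subset, sub_cfg)
    return models


@dataclass
class ExperimentResult:
    label: str
    report: FairnessReport
    scores: dict[str, float]  # per-sample test IoU
    p_value: float | None = None
    t_stat: float | None = None

    def to_row(self) -> dict:
        row = {
            "configuration": self.label,
            "mean_iou": self.report.mean_iou,
            "iou_sd": self.report.iou_sd,
            "rg_mean_ser": self.report.rg_mean_ser,
            "mmd": self.report.mmd,
            "p_vs_reference": "" if self.p_value is None else self.p_value,
        }
        return row


def run_experiment(
    samples: list[SampleRecord],
    config: ExperimentConfig,
    reference: ExperimentResult | None = None,
    teacher_perf: dict[str, float] | None = None,
    out_dir: str | Path | None = None,
    log_curriculum: bool = False,
) -> ExperimentResult:
    """Execute the full centralized pipeline for one configuration.

    Trains on the ``train`` split, scores per-sample IoU on the ``test``
    split, and (if a reference result is supplied) runs a paired t-test on
    the per-sample IoU aligned by sample id.  The demographically tailored
    setting trains four per-group models and routes each test sample to its
    group's model.
    """
    train = [r for r in samples if r.split == "train"]
    test = [r for r in samples if r.split == "test"]
    if not train or not test:
        raise ValueError("samples must carry train and test split labels")
    if config.curriculum == "tcl" and teacher_perf is None:
        teacher_cfg = replace(config, curriculum="base", loss="ce", label=None)
        teacher, _ = train_centralized(train, teacher_cfg)
        teacher_perf = evaluate(teacher, train)
    if config.curriculum == "ds":
        models = train_demographic_specific(train, config)
        scores: dict[str, float] = {}
        for g, model in models.items():
            routed = [r for r in test if r.group == g]
            if routed:
                scores.update(evaluate(model, routed))
        leftover = [r for r in test if r.group not in models]
        if leftover:
            logger.warning("%d test samples had no group model; scored 0", len(leftover))
            scores.update({r.sample_id: 0.0 for r in leftover})
        model = next(iter(models.values()))
    else:
        run_log: list = []
        model, _ = train_centralized(
            train, config, teacher_perf=teacher_perf,
            log=run_log, log_orders=log_curriculum,
        )
        scores = evaluate(model, test)
    report = fairness_report(scores, metadata_groups(test))
    t = p = None
    if reference is not None:
        common = sorted(set(scores) & set(reference.scores))
        if len(common) >= 2:
            t, p = paired_t_test(
                [scores[i] for i in common], [reference.scores[i] for i in common]
            )
        else:
            logger.warning("reference shares <2 samples; p-value omitted")
    result = ExperimentResult(
        label=config.label, report=report, scores=scores, p_value=p, t_stat=t
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "checkpoint.npz")
        pd.DataFrame(
            sorted(scores.items()), columns=["sample_id", "iou"]
        ).to_csv(out / "per_sample_iou.csv", index=False)
        (out / "fairness_report.json").write_text(report.to_json(indent=2))
        if config.curriculum != "ds":
            groups = metadata_groups(train)
            with open(out / "run_log.jsonl", "w") as fh:
                for entry in run_log:
                    fh.write(json.dumps({k: v for k, v in entry.items() if k != "order"}) + "\n")
            if log_curriculum:
                rows = [
                    {"epoch": e["epoch"], "position": pos, "sample_id": sid,
                     "group": groups[sid].code}
                    for e in run_log
                    for pos, sid in enumerate(e.get("order", []))
                ]
                pd.DataFrame(rows).to_csv(out / "curriculum_orders.csv", index=False)
    return result


@dataclass
class ResultsTable:
    """Rows of experiment results in the standard column order."""

    results: list[ExperimentResult] = field(default_factory=list)

    COLUMNS = ("configuration", "mean_iou", "iou_sd", "rg_mean_ser", "mmd", "p_vs_reference")

    def add(self, result: ExperimentResult) -> None:
        self.results.append(result)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results], columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        return pd.read_csv(path, keep_default_na=False)

    def __str__(self) -> str:
        with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
            return self.to_frame().to_string(index=False)
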