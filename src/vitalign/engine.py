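"""Class-incremental training loop.

Classes are partitioned into stages; each stage is trained with one of three
strategies:

* ``finetuning`` — plain cross-entropy on the new classes (lambda forced to 0);
* ``freezing`` — after the first stage only the classification head updates;
* ``attention_alignment`` — cross-entropy plus the configured distributional
  distance between the live model's attention stack and that of a frozen
  snapshot of the previous stage, evaluated on the same batch.

No sample from a past stage is ever read (zero-exemplar regime); the only
carrier of past knowledge is the snapshot.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics as M
from .data import DatasetSplit
from .errors import (ConfigurationError, InvalidLabelError,
                     InvalidSequenceError, TrainingDivergenceError)
from .losses import AlignmentLossConfig, composite_loss
from .optim import make_optimizer
from .vit import ModelSnapshot, ViTConfig, ViTModel

STRATEGIES = ("finetuning", "freezing", "attention_alignment")


@dataclass(frozen=True)
class TaskSequence:
    """Ordered partition of class labels into stages."""

    stages: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        flat = [c for s in self.stages for c in s]
        if len(set(flat)) != len(flat):
            raise InvalidSequenceError("stages are not pairwise disjoint")
        if any(len(s) == 0 for s in self.stages):
            raise InvalidSequenceError("empty stage in task sequence")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def stage_sizes(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.stages)

    def all_classes(self) -> list[int]:
        return [c for s in self.stages for c in s]


def split_classes(class_labels, n_stages: int, seed: int = 0,
                  shuffle: bool = False) -> TaskSequence:
    """Contiguous balanced partition of the label order into stages.

    Stage sizes are as equal as possible with larger stages first, e.g.
    13 classes over 3 stages gives (5, 4, 4).
    """
    labels = list(class_labels)
    if n_stages < 1 or n_stages > len(labels):
        raise ConfigurationError(
            f"stage count {n_stages} invalid for {len(labels)} classes")
    if shuffle:
        order = np.random.default_rng(seed).permutation(len(labels))
        labels = [labels[i] for i in order]
    base, rem = divmod(len(labels), n_stages)
    stages, lo = [], 0
    for k in range(n_stages):
        size = base + (1 if k < rem else 0)
        stages.append(tuple(labels[lo:lo + size]))
        lo += size
    return TaskSequence(stages=tuple(stages))


@dataclass
class TrainConfig:
    epochs_per_stage: int = 10
    batch_size: int = 32
    optimizer: str = "adamax"
    learning_rate: float = 5e-4
    seed: int = 0
    strategy: str = "attention_alignment"
    alignment: AlignmentLossConfig = field(default_factory=AlignmentLossConfig)
    cosine_decay: bool = True

    def __post_init__(self):
        if self.epochs_per_stage < 1:
            raise ConfigurationError("epochs_per_stage must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")


@dataclass
class StageReport:
    stage_index: int
    seen_classes: list[int]
    stage_classes: list[int]
    accuracy: float                      # top-1 over all seen test data
    per_stage_accuracies: list[float]    # acc on each earlier stage's classes
    average_accuracy: float
    per_class: dict                      # class -> metric dict
    confusion: list[list[int]]
    loss_log: list[dict]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _stage_lr(base_lr: float, step: int, total_steps: int,
              cosine: bool) -> float:
    if not cosine or total_steps <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * step / total_steps))


def run_stage(model: ViTModel, snapshot: ModelSnapshot | None,
              images: np.ndarray, labels: np.ndarray,
              config: TrainConfig, stage_index: int = 0,
              allowed_labels=None) -> tuple[ViTModel, list[dict]]:
    """Train one stage in place; returns the model and a per-step loss log.

    ``labels`` are model-head indices. ``allowed_labels`` (when given) is the
    zero-exemplar guard: any sample labelled outside the current stage raises.
    """
    labels = np.asarray(labels)
    if allowed_labels is not None:
        allowed = set(int(a) for a in allowed_labels)
        outside = sorted(set(int(l) for l in labels) - allowed)
        if outside:
            raise InvalidLabelError(
                f"zero-exemplar violation: labels {outside} lie outside the "
                f"current stage {sorted(allowed)}")
    if labels.size and (labels.min() < 0 or labels.max() >= model.k_classes):
        raise InvalidLabelError(
            f"label {labels.max()} outside head of width {model.k_classes}")

    align_cfg = config.alignment
    use_reference = (config.strategy == "attention_alignment"
                     and snapshot is not None and align_cfg.lam > 0.0)
    if config.strategy == "finetuning":
        align_cfg = dataclasses.replace(align_cfg, lam=0.0)

    if config.strategy == "freezing" and stage_index >= 1:
        head = set(model.head_parameter_names())
        trainable = {k: p for k, p in model.params.items() if k in head}
    else:
        trainable = model.params
    opt = make_optimizer(config.optimizer, trainable, config.learning_rate)

    rng = np.random.default_rng([config.seed, 7, stage_index])
    n = len(images)
    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs_per_stage
    log: list[dict] = []
    step = 0
    for _epoch in range(config.epochs_per_stage):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = images[idx], labels[idx]
            logits, attn, _ = model.forward(xb, train=True)
            reference = snapshot.forward(xb)[1] if use_reference else None
            breakdown = composite_loss(logits, yb, attn, reference, align_cfg)
            if not np.isfinite(breakdown.total.item()):
                raise TrainingDivergenceError(
                    f"non-finite loss at stage {stage_index} step {step}")
            model.zero_grad()
            breakdown.total.backward()
            opt.set_lr(_stage_lr(config.learning_rate, step, total_steps,
                                 config.cosine_decay))
            opt.step()
            log.append({"step": step, **breakdown.as_floats()})
            step += 1
    return model, log


def evaluate_stage(model: ViTModel, dataset: DatasetSplit,
                   sequence: TaskSequence, stage_index: int,
                   label_map: dict[int, int], loss_log: list[dict]
                   ) -> StageReport:
    """Score the model on the union of test data of all classes seen so far."""
    seen = [c for s in sequence.stages[:stage_index + 1] for c in s]
    test_x, test_y = dataset.subset_test(seen)
    preds = model.predict(test_x)
    true = np.array([label_map[int(c)] for c in test_y])
    seen_idx = [label_map[c] for c in seen]
    cm = M.confusion(true, preds, seen_idx)
    per_class, _macro, top1 = M.classification_metrics(cm)
    per_stage_acc = []
    for j in range(stage_index + 1):
        stage_cls = set(label_map[c] for c in sequence.stages[j])
        mask = np.isin(true, list(stage_cls))
        per_stage_acc.append(float((preds[mask] == true[mask]).mean()))
    return StageReport(
        stage_index=stage_index,
        seen_classes=[int(c) for c in seen],
        stage_classes=[int(c) for c in sequence.stages[stage_index]],
        accuracy=top1,
        per_stage_accuracies=per_stage_acc,
        average_accuracy=M.average_accuracy(per_stage_acc),
        per_class={str(k): dataclasses.asdict(v) for k, v in per_class.items()},
        confusion=cm.counts.tolist(),
        loss_log=loss_log,
    )


def run_experiment(dataset: DatasetSplit, sequence: TaskSequence,
                   train_config: TrainConfig,
                   model_config: ViTConfig | None = None,
                   out_dir=None) -> list[StageReport]:
    """Full class-incremental run: train stage by stage, snapshot between
    stages, report on all seen classes after each stage."""
    model_config = model_config or ViTConfig()
    all_classes = sequence.all_classes()
    missing = set(all_classes) - set(range(dataset.n_classes))
    if missing:
        raise InvalidSequenceError(
            f"sequence references unknown classes {sorted(missing)}")
    # head index = order of first appearance across stages
    label_map = {c: i for i, c in enumerate(all_classes)}

    model = ViTModel(model_config, n_classes=len(sequence.stages[0]),
                     seed=train_config.seed)
    snapshot: ModelSnapshot | None = None
    reports: list[StageReport] = []
    seen_count = 0
    for t, stage in enumerate(sequence.stages):
        seen_count += len(stage)
        if t > 0:
            model.expand_head(seen_count)
        xs, ys = dataset.subset_train(stage)
        mapped = np.array([label_map[int(c)] for c in ys])
        allowed = [label_map[c] for c in stage]
        model, log = run_stage(model, snapshot, xs, mapped, train_config,
                               stage_index=t, allowed_labels=allowed)
        snapshot = model.snapshot()
        report = evaluate_stage(model, dataset, sequence, t, label_map, log)
        reports.append(report)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            report.save(out_dir / f"stage_{t}.json")
            model.save(out_dir / f"model_stage_{t}.npz")
    if out_dir is not None:
        _write_curve(reports, Path(out_dir) / "average_accuracy.csv")
    return reports


def _write_curve(reports: list[StageReport], path: Path) -> None:
    lines = ["stage,accuracy,average_accuracy"]
    for r in reports:
        lines.append(f"{r.stage_index},{r.accuracy:.6f},"
                     f"{r.average_accuracy:.6f}")
    path.write_text("\n".join(lines) + "\n")
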