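"""Classification and continual-learning metrics.

Per-class precision/sensitivity/F1 are one-vs-rest off a confusion matrix;
"accuracy" comes in two readings: the one-vs-rest (TP+TN)/total form and
plain top-1 (trace/total). Average accuracy is the unweighted mean of
per-stage test accuracies, the standard continual-learning score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidLabelError


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes), rows = true class
    labels: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = [str(c) for c in self.labels]
        return pd.DataFrame(self.counts, index=idx, columns=idx)


@dataclass
class MetricRecord:
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    zero_division_flags: dict = field(default_factory=dict)


def confusion(true_labels, predicted_labels, classes) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise InvalidLabelError(
            f"label lists differ in length: {true_labels.shape} vs "
            f"{predicted_labels.shape}")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            bad = t if t not in index else p
            raise InvalidLabelError(f"label {bad!r} outside class set")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=classes)


def classification_metrics(cm: ConfusionMatrix
                           ) -> tuple[dict, MetricRecord, float]:
    """Return (per-class records, macro record, top-1 accuracy).

    0/0 ratios are reported as 0 and flagged in ``zero_division_flags``.
    """
    total = cm.total
    if total == 0:
        raise EmptyInputError("confusion matrix holds no samples")
    counts = cm.counts
    per_class: dict = {}
    macros = {"accuracy": [], "precision": [], "sensitivity": [], "f1": []}
    for i, label in enumerate(cm.labels):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        tn = total - tp - fp - fn
        flags = {}

        def ratio(num, den, name):
            if den == 0:
                flags[name] = True
                return 0.0
            return float(num) / float(den)

        precision = ratio(tp, tp + fp, "precision")
        sensitivity = ratio(tp, tp + fn, "sensitivity")
        f1 = ratio(2.0 * sensitivity * precision, sensitivity + precision, "f1")
        accuracy = float(tp + tn) / total
        rec = MetricRecord(accuracy=accuracy, precision=precision,
                           sensitivity=sensitivity, f1=f1,
                           zero_division_flags=flags)
        per_class[label] = rec
        for k in macros:
            macros[k].append(getattr(rec, k))
    macro = MetricRecord(**{k: float(np.mean(v)) for k, v in macros.items()})
    top1 = float(np.trace(counts)) / total
    return per_class, macro, top1


def average_accuracy(per_stage_accuracies) -> float:
    """Unweighted mean of per-stage accuracies."""
    vals = list(per_stage_accuracies)
    if not vals:
        raise EmptyInputError("average_accuracy of an empty list")
    arr = np.asarray(vals, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise InvalidLabelError("accuracies must lie in [0, 1]")
    return float(arr.mean())


def export_features(model, images: np.ndarray, labels: np.ndarray,
                    sample_ids=None, batch_size: int = 64) -> pd.DataFrame:
    """One row per sample: id, label, then the D pre-head feature columns."""
    from . import tensor as T

    if sample_ids is None:
        sample_ids = np.arange(len(images))
    feats = []
    with T.no_grad():
        for lo in range(0, len(images), batch_size):
            _, _, f = model.forward(images[lo:lo + batch_size])
            feats.append(f.data)
    features = np.concatenate(feats, axis=0) if feats else \
        np.zeros((0, model.config.embed_dim))
    df = pd.DataFrame(features,
                      columns=[f"f{i}" for i in range(features.shape[1])])
    df.insert(0, "label", np.asarray(labels))
    df.insert(0, "sample_id", np.asarray(sample_ids))
    return df
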