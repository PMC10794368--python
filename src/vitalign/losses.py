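"""Distributional distances between attention maps and the training objective.

Two parallel APIs live here:

* plain-numpy distances on 1-D probability vectors (``tv_distance`` etc.) —
  the reference definitions used by metrics and tests;
* a differentiable batched path used by :func:`attention_alignment_loss`,
  which treats every (batch, head, query) row of an attention map as one
  distribution over keys and accumulates the chosen distance across blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import tensor as T
from .errors import ConfigurationError, DimensionError, InvalidLabelError
from .tensor import Tensor

logger = logging.getLogger(__name__)

DISTANCES = ("tv", "js", "hellinger", "bhattacharyya")

#: Scaling applied to the Euclidean distance of square roots so that
#: disjoint supports map to exactly 1.
HELLINGER_NORMALIZATION = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class AlignmentLossConfig:
    distance: str = "tv"
    lam: float = 1.0
    reduction: str = "mean"
    epsilon: float = 1e-8
    blocks: tuple[int, ...] | None = None  # None selects every block

    def __post_init__(self):
        if self.distance not in DISTANCES:
            raise ConfigurationError(
                f"distance must be one of {DISTANCES}, got {self.distance!r}")
        if self.lam < 0:
            raise ConfigurationError(f"lambda must be >= 0, got {self.lam}")
        if self.reduction not in ("mean", "sum"):
            raise ConfigurationError(
                f"reduction must be 'mean' or 'sum', got {self.reduction!r}")
        if not 0.0 < self.epsilon <= 1e-3:
            raise ConfigurationError(
                f"epsilon must lie in (0, 1e-3], got {self.epsilon}")


# ---------------------------------------------------------------------------
# vector API (numpy, non-differentiable reference definitions)
# ---------------------------------------------------------------------------

def _check_pair(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise DimensionError(f"length mismatch: {p.shape} vs {q.shape}")
    return p, q


def normalize_rows(raw, epsilon: float = 1e-8):
    """Map arbitrary non-negative weights to row-stochastic form.

    Takes absolute values, then divides each row by its (epsilon-guarded)
    sum. Accepts a numpy array (rows = last axis; exact-zero rows become
    uniform) or a :class:`Tensor` (differentiable; zero rows cannot occur
    post-softmax so no uniform fixup is applied).
    """
    if isinstance(raw, Tensor):
        a = raw.abs()
        return a / (a.sum(axis=-1, keepdims=True) + epsilon)
    a = np.abs(np.asarray(raw, dtype=np.float64))
    s = a.sum(axis=-1, keepdims=True)
    zero = s <= 0.0
    if np.any(zero):
        logger.debug("normalize_rows: %d all-zero rows set to uniform",
                     int(zero.sum()))
        n = a.shape[-1]
        a = np.where(zero, 1.0 / n, a)
        s = a.sum(axis=-1, keepdims=True)
    return a / (s + epsilon)


def tv_distance(p, q) -> float:
    """Total variation distance, half the L1 gap; bounded in [0, 1]."""
    p, q = _check_pair(p, q)
    return float(0.5 * np.abs(p - q).sum())


def js_divergence(p, q, epsilon: float = 1e-8) -> float:
    """Jensen-Shannon divergence in nats, bounded by ln 2."""
    p, q = _check_pair(p, q)
    m = 0.5 * (p + q)
    kl_pm = np.sum(p * np.log((p + epsilon) / (m + epsilon)))
    kl_qm = np.sum(q * np.log((q + epsilon) / (m + epsilon)))
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def hellinger_distance(p, q) -> float:
    """Euclidean distance of square roots, scaled to [0, 1]."""
    p, q = _check_pair(p, q)
    return float(HELLINGER_NORMALIZATION
                 * np.linalg.norm(np.sqrt(p) - np.sqrt(q)))


def bhattacharyya_distance(p, q, epsilon: float = 1e-8) -> float:
    """Negative log of the Bhattacharyya coefficient, clamped to stay finite."""
    p, q = _check_pair(p, q)
    coeff = np.sqrt(p * q).sum()
    return float(-np.log(max(coeff, epsilon)))


def vector_distance(name: str, p, q, epsilon: float = 1e-8) -> float:
    if name == "tv":
        return tv_distance(p, q)
    if name == "js":
        return js_divergence(p, q, epsilon)
    if name == "hellinger":
        return hellinger_distance(p, q)
    if name == "bhattacharyya":
        return bhattacharyya_distance(p, q, epsilon)
    raise ConfigurationError(f"unknown distance {name!r}")


# ---------------------------------------------------------------------------
# differentiable batched path
# ---------------------------------------------------------------------------

def _rowwise_distance(q_rows: Tensor, p_rows: Tensor, name: str,
                      epsilon: float) -> Tensor:
    """Per-row distance between two (rows, keys) tensors; returns (rows,)."""
    if name == "tv":
        return (q_rows - p_rows).abs().sum(axis=-1) * 0.5
    if name == "js":
        m = (q_rows + p_rows) * 0.5
        kl_q = (q_rows * ((q_rows + epsilon) / (m + epsilon)).log()).sum(axis=-1)
        kl_p = (p_rows * ((p_rows + epsilon) / (m + epsilon)).log()).sum(axis=-1)
        return (kl_q + kl_p) * 0.5
    if name == "hellinger":
        diff = q_rows.clip_min(0.0).sqrt() - p_rows.clip_min(0.0).sqrt()
        return ((diff * diff).sum(axis=-1) + 1e-300).sqrt() \
            * HELLINGER_NORMALIZATION
    if name == "bhattacharyya":
        coeff = (q_rows * p_rows).clip_min(0.0).sqrt().sum(axis=-1)
        return -(coeff.clip_min(epsilon).log())
    raise ConfigurationError(f"unknown distance {name!r}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def attention_alignment_loss(current: Sequence[Tensor],
                             reference: Sequence[Tensor],
                             config: AlignmentLossConfig) -> Tensor:
    """Accumulated distance between two attention stacks.

    Every (batch, head, query) row of each selected block is one probability
    distribution over keys; rows are re-normalized, the configured distance
    is evaluated per row, reduced per ``config.reduction`` within a block and
    summed over blocks.
    """
    current = [_as_tensor(a) for a in current]
    reference = [_as_tensor(a) for a in reference]
    if len(current) != len(reference):
        raise DimensionError(
            f"stack depth mismatch: {len(current)} vs {len(reference)}")
    blocks = config.blocks if config.blocks is not None \
        else tuple(range(len(current)))
    for b in blocks:
        if not 0 <= b < len(current):
            raise DimensionError(f"block index {b} outside stack of depth "
                                 f"{len(current)}")
        if current[b].shape != reference[b].shape:
            raise DimensionError(
                f"block {b}: shape mismatch {current[b].shape} vs "
                f"{reference[b].shape}")

    total = Tensor(0.0)
    for b in blocks:
        n_keys = current[b].shape[-1]
        q_rows = normalize_rows(current[b].reshape(-1, n_keys), config.epsilon)
        p_rows = normalize_rows(reference[b].reshape(-1, n_keys),
                                config.epsilon)
        per_row = _rowwise_distance(q_rows, p_rows, config.distance,
                                    config.epsilon)
        total = total + (per_row.mean() if config.reduction == "mean"
                         else per_row.sum())
    return total


@dataclass
class LossBreakdown:
    """Components of the composite objective, kept as graph nodes."""

    cross_entropy: Tensor
    attention: Tensor
    total: Tensor
    lam: float

    def as_floats(self) -> dict[str, float]:
        return {"cross_entropy": self.cross_entropy.item(),
                "attention": self.attention.item(),
                "total": self.total.item(), "lambda": self.lam}


def composite_loss(logits: Tensor, labels: np.ndarray,
                   current: Sequence[Tensor] | None,
                   reference: Sequence[Tensor] | None,
                   config: AlignmentLossConfig) -> LossBreakdown:
    """Cross-entropy plus lambda times the attention-alignment term.

    With no reference stack (first stage) the attention term is zero and the
    total is exactly the cross-entropy; likewise when lambda is zero.
    """
    try:
        ce = T.cross_entropy(logits, labels)
    except ValueError as exc:
        raise InvalidLabelError(str(exc)) from None
    if reference is not None:
        att = attention_alignment_loss(current, reference, config)
        # lam == 0 keeps the total bit-identical to the cross-entropy
        total = ce if config.lam == 0.0 else ce + att * config.lam
    else:
        att = Tensor(0.0)
        total = ce
    return LossBreakdown(cross_entropy=ce, attention=att, total=total,
                         lam=config.lam)
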