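"""Composite segmentation loss: inverse-frequency-weighted cross-entropy
plus the multiclass Lovász-softmax surrogate of the Jaccard loss,

    L = α · L_CE + β · L_Lovász.

Class weights are computed from the class frequencies of the downsampled
training clouds; points with the ignore label (-1) contribute to nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import CLASS_NAMES, IGNORE
from .nn import Tensor


@dataclass
class LossConfig:
    alpha: float = 1.0                    # cross-entropy weight
    beta: float = 1.0                     # Lovász weight
    class_weights: np.ndarray | None = None
    ignore_label: int = IGNORE
    num_classes: int = 3

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or (self.alpha == 0 and self.beta == 0):
            raise ValueError("alpha, beta must be >= 0 and not both 0")
        if self.class_weights is not None:
            self.class_weights = np.asarray(self.class_weights, dtype=np.float64)
            if (self.class_weights <= 0).any():
                raise ValueError("class weights must be positive")


def class_weights_from_frequency(label_collection, num_classes: int = 3) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    w_c = N_total / (C · N_c) over all labels in the collection (a single
    array or an iterable of arrays), ignoring label -1; the raw weights are
    rescaled so their mean is 1.
    """
    labels = np.concatenate([np.asarray(a).ravel() for a in
                             (label_collection if isinstance(label_collection, (list, tuple))
                              else [label_collection])])
    labels = labels[labels != IGNORE]
    counts = np.bincount(labels, minlength=num_classes).astype(np.float64)
    for c in range(num_classes):
        if counts[c] == 0:
            raise ValueError(
                f"class {c} ({CLASS_NAMES.get(c, '?')}) absent from the label collection")
    raw = counts.sum() / (num_classes * counts)
    return raw / raw.mean()


def weighted_cross_entropy(logits: Tensor | np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray | None = None,
                           ignore_label: int = IGNORE) -> Tensor:
    """Weight-normalized mean of w_y · (−log softmax(logits)[y]).

    Normalization is by the sum of applied weights (not the point count) so
    the scale is stable under class imbalance.
    """
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    labels = np.asarray(labels)
    valid = labels != ignore_label
    if not valid.any():
        raise ValueError("all points carry the ignore label")
    idx = np.flatnonzero(valid)
    y = labels[idx]
    c = logits.shape[1]
    w = np.ones(c) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    logp = logits[idx].log_softmax(axis=1)
    onehot = np.zeros((len(idx), c))
    onehot[np.arange(len(idx)), y] = w[y]
    return -(logp * onehot).sum() * (1.0 / w[y].sum())


def _lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Lovász extension of the Jaccard loss w.r.t. sorted errors."""
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / union
    if len(gt_sorted) > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def lovasz_softmax(probs: Tensor | np.ndarray, labels: np.ndarray,
                   ignore_label: int = IGNORE) -> Tensor:
    """Multiclass Lovász-softmax loss, averaged over classes present in
    the labels.  ``probs`` rows must be softmax outputs."""
    probs = probs if isinstance(probs, Tensor) else Tensor(probs)
    labels = np.asarray(labels)
    valid = labels != ignore_label
    if not valid.any():
        raise ValueError("no valid points")
    idx = np.flatnonzero(valid)
    p = probs[idx]
    y = labels[idx]
    losses = []
    for c in sorted(set(int(v) for v in y)):
        fg = (y == c).astype(np.float64)
        pc = p[:, c]
        errors = Tensor(fg) - pc
        errors = errors * np.sign(errors.data)            # |fg - p_c|, fixed region
        order = np.argsort(-errors.data, kind="stable")
        grad = _lovasz_grad(fg[order])
        losses.append((errors[order] * Tensor(grad)).sum())
    total = losses[0]
    for l in losses[1:]:
        total = total + l
    return total * (1.0 / len(losses))


def el_loss(logits: Tensor | np.ndarray, labels: np.ndarray,
            config: LossConfig | None = None) -> Tensor:
    """α·weighted-CE + β·Lovász-softmax on one batch of logits."""
    config = config or LossConfig()
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    terms = []
    if config.alpha > 0:
        terms.append(config.alpha * weighted_cross_entropy(
            logits, labels, config.class_weights, config.ignore_label))
    if config.beta > 0:
        terms.append(config.beta * lovasz_softmax(
            logits.softmax(axis=1), labels, config.ignore_label))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total
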