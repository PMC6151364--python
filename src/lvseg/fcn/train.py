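"""Class-balanced loss and the two-stage training loop.

LV foreground occupies a small fraction of most echo slices, so the loss
weights the two classes by their prevalence: with Y+ foreground and Y-
background pixels in the ground truth and a = Y- / (Y+ + Y-),

    Loss = -a * sum_fg log P(y=1) - (1 - a) * sum_bg log P(y=0).

The rarer the foreground, the closer a is to 1 and the more each foreground
pixel counts.  Training runs in two stages: first the backbone is frozen and
only the skip streams / score / upsampling layers learn (so the newly added
parts get a sane initialization next to a possibly pretrained encoder), then
the whole network is fine-tuned.  The learning rate decreases linearly in
steps: lr(t) = lr0 * (1 - floor(t / decay_every) * decay_every / max_iter).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .data import SliceStack, to_three_channel
from .model import FusionFCN
from .nn import SGD

__all__ = ["TrainConfig", "LossTerms", "weighted_ce_loss", "train", "predict_stack",
           "mean_iou"]

_EPS = 1e-12  # log clamp; the loss is undefined at P = 0


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule (published defaults; shrink for desk-scale runs)."""

    lr0: float = 1e-4
    momentum: float = 0.99
    batch_size: int = 256
    max_iter: int = 10000
    stage1_iter: int = 1000
    decay_every: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stage1_iter < self.max_iter:
            raise ValueError("require 0 < stage1_iter < max_iter")
        if self.lr0 <= 0 or self.batch_size < 1 or self.decay_every < 1:
            raise ValueError("invalid optimization constants")

    def lr_at(self, t: int) -> float:
        """Step-wise linearly decreasing learning rate at iteration t (0-based)."""
        return self.lr0 * (1.0 - (t // self.decay_every) * self.decay_every / self.max_iter)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class LossTerms:
    """The balanced cross-entropy value and its ingredients."""

    Y_plus: int
    Y_minus: int
    a: float
    loss: float


def weighted_ce_loss(probs: np.ndarray, truth: np.ndarray) -> LossTerms:
    """Class-balanced cross-entropy of per-pixel probabilities vs binary truth.

    ``probs`` is (2, H, W) (channel 0 = background, 1 = LV) or (H, W) giving
    P(y=1) directly; probabilities are clamped at 1e-12 before the log so a
    confident wrong pixel yields a large finite loss, never NaN.
    """
    truth = np.asarray(truth)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim == 2:
        p1 = probs
        p0 = 1.0 - probs
    elif probs.ndim == 3 and probs.shape[0] == 2:
        p0, p1 = probs[0], probs[1]
    else:
        raise ValueError(f"probs must be (H, W) or (2, H, W), got {probs.shape}")
    if p1.shape != truth.shape:
        raise ValueError("probability map and truth differ in shape")
    fg = truth > 0.5
    y_plus = int(fg.sum())
    y_minus = int(fg.size - y_plus)
    a = y_minus / (y_plus + y_minus)
    loss = -a * float(np.log(np.clip(p1[fg], _EPS, None)).sum()) \
           - (1.0 - a) * float(np.log(np.clip(p0[~fg], _EPS, None)).sum())
    return LossTerms(y_plus, y_minus, a, loss)


def _loss_and_grad_batch(
    probs: np.ndarray, truth: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean balanced CE over a batch and its gradient w.r.t. the class scores.

    The per-image balance weight a follows the per-image ground truth; the
    gradient of the softmax + weighted CE w.r.t. the score map is the usual
    (P - onehot) scaled by the pixel's class weight, normalized by pixel
    count so the learning rate is resolution-independent.
    """
    b, _, h, w = probs.shape
    fg = truth > 0.5
    y_plus = fg.sum(axis=(1, 2))
    a = (fg[0].size - y_plus) / fg[0].size  # per-image balance weight
    wpix = np.where(fg, a[:, None, None], 1.0 - a[:, None, None])
    p1 = np.clip(probs[:, 1], _EPS, None)
    p0 = np.clip(probs[:, 0], _EPS, None)
    loss = -(np.where(fg, np.log(p1), np.log(p0)) * wpix).sum() / (b * h * w)
    onehot = np.stack([~fg, fg], axis=1).astype(np.float64)
    dscores = wpix[:, None] * (probs - onehot) / (b * h * w)
    return float(loss), dscores


def mean_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean intersection-over-union of the two classes over a slice set."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    ious = []
    for cls in (False, True):
        pi, ti = pred == cls, truth == cls
        union = (pi | ti).sum()
        if union:
            ious.append((pi & ti).sum() / union)
    return float(np.mean(ious))


@dataclass
class TrainLog:
    iterations: list[int]
    losses: list[float]
    lrs: list[float]

    def to_csv(self, path: str | Path) -> Path:
        lines = ["iteration,loss,lr"]
        lines += [f"{i},{l:.8g},{r:.8g}" for i, l, r in
                  zip(self.iterations, self.losses, self.lrs)]
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)


def train(model: FusionFCN, stack: SliceStack, cfg: TrainConfig) -> TrainLog:
    """Two-stage SGD training of the fusion network on a labeled slice stack.

    Stage 1 (iterations < ``stage1_iter``): the encoder backbone is frozen and
    only the skip streams / score / upsampling parameters move.  Stage 2: the
    whole network fine-tunes.  A NaN loss aborts with a diagnostic.  The seed
    fixes batch order; together with the model's init seed (and
    single-threaded numerics) runs are bit-reproducible.
    """
    if len(stack) == 0:
        raise ValueError("empty slice stack")
    if stack.masks is None:
        raise ValueError("training requires masks")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), cfg.lr0, cfg.momentum)
    model.set_training(True)
    model.freeze_backbone(True)
    log = TrainLog([], [], [])
    images = stack.images
    masks = stack.masks
    for t in range(cfg.max_iter):
        if t == cfg.stage1_iter:
            model.freeze_backbone(False)
        idx = rng.integers(0, len(stack), size=min(cfg.batch_size, len(stack)))
        x = np.stack([to_three_channel(images[i]) for i in idx])
        y = masks[idx]
        probs = model.predict_probs(x)
        loss, dscores = _loss_and_grad_batch(probs, y)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss at iteration {t}; "
                f"reduce the learning rate"
            )
        opt.zero_grad()
        model.backward(dscores)
        opt.lr = cfg.lr_at(t)
        opt.step()
        log.iterations.append(t)
        log.losses.append(loss)
        log.lrs.append(opt.lr)
    model.set_training(False)
    return log


def predict_stack(model: FusionFCN, stack: SliceStack, batch_size: int = 16) -> SliceStack:
    """Per-slice argmax segmentation of a stack; slice order is preserved."""
    model.set_training(False)
    preds = []
    for i in range(0, len(stack), batch_size):
        x = np.stack([to_three_channel(im) for im in stack.images[i : i + batch_size]])
        probs = model.predict_probs(x)
        preds.append(np.argmax(probs, axis=1).astype(np.uint8))
    return SliceStack(
        stack.images,
        np.concatenate(preds),
        stack.z_index,
        stack.provenance + "+pred",
        stack.spacing,
        stack.origin,
    )
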