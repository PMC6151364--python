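"""The fusion fully-convolutional segmentation network.

Topology: a convolutional encoder whose pooling stages P1..P_depth halve
resolution at each step, and one *skip stream* per selected pooling stage.
Each stream passes its feature map through a residual block (4 conv-BN-ReLU
layers with an identity shortcut), projects it to the two class channels
(LV / background) with a 1x1 convolution, and upsamples back to input
resolution with a learned transposed convolution.  The final score map is the
sum of all stream score maps — fusing low-level (fine, shallow) and
high-level (coarse, deep) features.  The two deepest streams (P3, P4) form
the baseline fusion and are always present; P1 and P2 can be added on top.

The encoder is the "backbone": its parameters are the ones a pretrained
model would initialize and that the two-stage training schedule freezes
first.  The streams, score projections and upsamplers are the "head".
Channel widths are configurable so the same topology trains at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .nn import (
    BatchNorm2d,
    Conv2d,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
    ResidualBlock,
    Sequential,
    Upsample2d,
)

__all__ = ["NetConfig", "FusionFCN", "build_network"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters of the fusion network."""

    base_width: int = 8
    depth: int = 4
    skip_streams: tuple[int, ...] = (1, 2, 3, 4)
    residual_per_stream: bool = True
    convs_per_stage: int = 2
    n_classes: int = 2
    input_channels: int = 3

    def __post_init__(self) -> None:
        if not self.skip_streams:
            raise ValueError("skip_streams must be non-empty")
        streams = set(self.skip_streams)
        if not streams <= set(range(1, self.depth + 1)):
            raise ValueError(f"skip_streams must be within 1..{self.depth}")
        # the two deepest stages form the baseline fusion and are mandatory
        streams |= {self.depth - 1, self.depth}
        object.__setattr__(self, "skip_streams", tuple(sorted(streams)))
        if self.n_classes != 2:
            raise ValueError("this network is a 2-class (LV vs background) segmenter")
        if self.input_channels != 3:
            raise ValueError("input is 3-channel (replicated gray) by contract")

    def stage_width(self, n: int) -> int:
        return self.base_width * min(2 ** (n - 1), 4)

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["skip_streams"] = list(d["skip_streams"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "skip_streams" in d:
            d["skip_streams"] = tuple(d["skip_streams"])
        return cls(**d)


class FusionFCN:
    """Encoder + per-stage skip streams fused at full resolution."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.stages: list[Sequential] = []
        cin = cfg.input_channels
        for n in range(1, cfg.depth + 1):
            cout = cfg.stage_width(n)
            parts: list[Layer] = []
            for j in range(cfg.convs_per_stage):
                parts += [
                    Conv2d(cin if j == 0 else cout, cout, 3, rng, f"enc{n}.conv{j}"),
                    BatchNorm2d(cout, name=f"enc{n}.bn{j}"),
                    ReLU(),
                ]
            parts.append(MaxPool2d())
            self.stages.append(Sequential(*parts))
            cin = cout
        self.streams: dict[int, Sequential] = {}
        for n in cfg.skip_streams:
            w = cfg.stage_width(n)
            parts: list[Layer] = []
            if cfg.residual_per_stream:
                parts.append(ResidualBlock(w, 4, 3, rng, f"p{n}.res"))
            parts.append(Conv2d(w, cfg.n_classes, 1, rng, f"p{n}.score"))
            parts.append(Upsample2d(cfg.n_classes, cfg.n_classes, 2**n, rng, f"p{n}.up"))
            self.streams[n] = Sequential(*parts)

    # --- parameter groups -------------------------------------------------
    def backbone_parameters(self) -> list[Param]:
        return [p for s in self.stages for p in s.params()]

    def head_parameters(self) -> list[Param]:
        return [p for s in self.streams.values() for p in s.params()]

    def parameters(self) -> list[Param]:
        return self.backbone_parameters() + self.head_parameters()

    def parameter_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def set_training(self, flag: bool) -> None:
        for s in self.stages:
            s.set_training(flag)
        for s in self.streams.values():
            s.set_training(flag)

    def freeze_backbone(self, frozen: bool = True) -> None:
        for p in self.backbone_parameters():
            p.trainable = not frozen

    # --- forward / backward ----------------------------------------------
    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        m = 2**self.cfg.depth
        h, w = x.shape[2], x.shape[3]
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x, (h, w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 3, H, W) image batch -> (B, 2, H, W) class scores.

        H and W are zero-padded up to a multiple of 2**depth internally and
        the scores cropped back.
        """
        if x.ndim != 4 or x.shape[1] != self.cfg.input_channels:
            raise ValueError(f"expected (B, {self.cfg.input_channels}, H, W), got {x.shape}")
        x, (h, w) = self._pad(x)
        feats: dict[int, np.ndarray] = {}
        for n, stage in enumerate(self.stages, start=1):
            x = stage.forward(x)
            feats[n] = x
        out = None
        for n, stream in self.streams.items():
            s = stream.forward(feats[n])
            out = s if out is None else out + s
        return out[:, :, :h, :w]

    def backward(self, dout: np.ndarray) -> None:
        m = 2**self.cfg.depth
        ph, pw = (-dout.shape[2]) % m, (-dout.shape[3]) % m
        if ph or pw:
            dout = np.pad(dout, ((0, 0), (0, 0), (0, ph), (0, pw)))
        dfeats: dict[int, np.ndarray] = {}
        for n, stream in self.streams.items():
            dfeats[n] = stream.backward(dout)
        grad = None
        for n in range(self.cfg.depth, 0, -1):
            g = dfeats.get(n)
            if grad is not None:
                g = g + grad if g is not None else grad
            grad = self.stages[n - 1].backward(g)

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, (B, 2, H, W); channels sum to 1."""
        scores = self.forward(x)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    # --- weight interchange ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = False) -> list[str]:
        """Load externally supplied tensors by name; returns names not found.

        This is the hook through which pretrained backbone weights can be
        injected; shapes must match exactly.
        """
        missing = []
        by_name = {p.name: p for p in self.parameters()}
        for name, val in state.items():
            p = by_name.get(name)
            if p is None:
                missing.append(name)
                continue
            if p.value.shape != np.shape(val):
                raise ValueError(f"shape mismatch for {name}: {p.value.shape} vs {np.shape(val)}")
            p.value[...] = val
        if strict and missing:
            raise KeyError(f"unmatched tensors: {missing}")
        return missing

    def save_npz(self, path: str | Path) -> Path:
        np.savez(str(path), **self.state_dict())
        return Path(path)

    def load_npz(self, path: str | Path) -> None:
        with np.load(str(path)) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_network(cfg: NetConfig, seed: int = 0) -> FusionFCN:
    """Construct the fusion network for a configuration (seeded init)."""
    return FusionFCN(cfg, seed)
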