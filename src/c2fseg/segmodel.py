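"""Encoder-decoder segmentation network with weighted skip fusion.

A U-Net-style fully convolutional network in which each skip connection,
instead of concatenating the encoder feature E with the decoder feature D,
blends them element-wise with a fixed weight:

    fused = (1 - gamma) * E + gamma * D,     gamma = 0.2 by default

so the encoder's high-resolution evidence dominates the merged feature.
Setting ``use_fusion=False`` restores plain concatenation (the ablation
baseline).  The decoder upsamples by nearest-neighbour x2 followed by a 1x1
channel projection so the element-wise blend is shape-valid at every level.

Output heads: a sigmoid map for a single foreground class, a softmax over
background + K classes otherwise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm2d, Conv2d, MaxPool2, Param, ReLU, UpsampleNearest2

__all__ = [
    "FusionConfig",
    "NetConfig",
    "fuse_skip",
    "build_model",
    "SegModel",
    "predict_mask",
    "image_to_input",
]


@dataclass(frozen=True)
class FusionConfig:
    gamma: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class NetConfig:
    depth: int = 4
    base_channels: int = 32
    n_classes: int = 1
    fusion: FusionConfig = field(default_factory=FusionConfig)
    use_fusion: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1 or self.n_classes < 1:
            raise ValueError("base_channels and n_classes must be >= 1")

    @property
    def out_channels(self) -> int:
        """One sigmoid map for binary tasks, background + K softmax maps otherwise."""
        return 1 if self.n_classes == 1 else self.n_classes + 1


def fuse_skip(e: np.ndarray, d: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Weighted element-wise skip fusion (1 - gamma) * E + gamma * D."""
    e = np.asarray(e)
    d = np.asarray(d)
    if e.shape != d.shape:
        raise ValueError(f"encoder/decoder feature shapes differ: {e.shape} vs {d.shape}")
    g = cfg.gamma
    return (1.0 - g) * e + g * d


class _ConvBlock:
    """conv3-BN-ReLU twice."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.layers = [
            Conv2d(cin, cout, 3, rng, f"{name}.c1"), BatchNorm2d(cout, name=f"{name}.b1"), ReLU(),
            Conv2d(cout, cout, 3, rng, f"{name}.c2"), BatchNorm2d(cout, name=f"{name}.b2"), ReLU(),
        ]

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class SegModel:
    """The fully convolutional encoder-decoder; see module docstring."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        base, depth = cfg.base_channels, cfg.depth
        chans = [base * 2 ** i for i in range(depth)]
        self.enc = []
        cin = 3
        for i, c in enumerate(chans):
            self.enc.append(_ConvBlock(cin, c, rng, f"enc{i}"))
            cin = c
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _ConvBlock(chans[-1], base * 2 ** depth, rng, "mid")
        self.ups = [UpsampleNearest2() for _ in range(depth)]
        # projection from the channel width below level i down to level i's width
        below = [base * 2 ** (i + 1) for i in range(depth)]
        self.projs = [Conv2d(below[i], chans[i], 1, rng, f"proj{i}") for i in range(depth)]
        dec_in = [c if cfg.use_fusion else 2 * c for c in chans]
        self.dec = [_ConvBlock(dec_in[i], chans[i], rng, f"dec{i}") for i in range(depth)]
        self.final = Conv2d(chans[0], cfg.out_channels, 1, rng, "final")

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for blk in [*self.enc, self.bottleneck, *self.projs, *self.dec]:
            out.extend(blk.params())
        out.extend(self.final.params())
        return out

    def _bn_layers(self) -> list[BatchNorm2d]:
        out = []
        for blk in [*self.enc, self.bottleneck, *self.dec]:
            out.extend(l for l in blk.layers if isinstance(l, BatchNorm2d))
        return out

    def state_dict(self) -> dict:
        return {
            "params": [p.value.copy() for p in self.params()],
            "bn": [(bn.running_mean.copy(), bn.running_var.copy()) for bn in self._bn_layers()],
        }

    def load_state_dict(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"], strict=True):
            p.value[...] = v
        for bn, (m, v) in zip(self._bn_layers(), state["bn"], strict=True):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def clone_state(self) -> dict:
        return copy.deepcopy(self.state_dict())

    # -- forward / backward ----------------------------------------------
    def _check_size(self, h: int, w: int) -> None:
        f = 2 ** self.cfg.depth
        if h % f or w % f:
            pad_h = (f - h % f) % f
            pad_w = (f - w % f) % f
            raise ValueError(
                f"input size {h}x{w} not divisible by 2^depth={f}; "
                f"pad to {h + pad_h}x{w + pad_w}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits (N, out_channels, H, W) from inputs (N, 3, H, W) in [0, 1]."""
        n, c, h, w = x.shape
        self._check_size(h, w)
        g = self.cfg.fusion.gamma
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for i in reversed(range(self.cfg.depth)):
            x = self.ups[i].forward(x, train)
            x = self.projs[i].forward(x, train)
            if self.cfg.use_fusion:
                x = (1.0 - g) * skips[i] + g * x
            else:
                x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[i].forward(x, train)
        return self.final.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from a loss gradient w.r.t. logits."""
        g = self.cfg.fusion.gamma
        depth = self.cfg.depth
        chans = [self.cfg.base_channels * 2 ** i for i in range(depth)]
        d = self.final.backward(dlogits)
        dskips = [None] * depth
        for i in range(depth):
            d = self.dec[i].backward(d)
            if self.cfg.use_fusion:
                dskips[i] = (1.0 - g) * d
                d = g * d
            else:
                dskips[i] = d[:, : chans[i]]
                d = d[:, chans[i]:]
            d = self.projs[i].backward(d)
            d = self.ups[i].backward(d)
        d = self.bottleneck.backward(d)
        for i in reversed(range(depth)):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            d = self.enc[i].backward(d)

    # -- inference --------------------------------------------------------
    def probabilities(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probability maps: sigmoid (K=1) or channel softmax (K>1)."""
        logits = self.forward(x.astype(np.float32), train)
        if self.cfg.out_channels == 1:
            return 1.0 / (1.0 + np.exp(-logits))
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def make_optimizer(self, lr: float = 0.005) -> Adam:
        return Adam(self.params(), lr=lr)


def build_model(cfg: NetConfig, seed: int = 0) -> SegModel:
    """Construct a seeded model from its configuration."""
    return SegModel(cfg, seed=seed)


def image_to_input(image: np.ndarray) -> np.ndarray:
    """HxWx3 image (uint8 or float) -> (3, H, W) float32 normalized to [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    x = image.astype(np.float32)
    if image.dtype != np.float32 and image.dtype != np.float64:
        x = x / 255.0
    elif x.max() > 1.0 + 1e-6:
        x = x / 255.0
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def predict_mask(model: SegModel, image: np.ndarray, threshold: float = 0.7) -> np.ndarray:
    """Label mask from an RGB image via the trained model.

    Single class: foreground where the sigmoid map >= threshold.  Multi-class:
    argmax over the foreground class maps, assigned to background where the
    winning probability falls below the threshold.
    """
    x = image_to_input(image)[None]
    probs = model.probabilities(x, train=False)[0]
    if model.cfg.out_channels == 1:
        return (probs[0] >= threshold).astype(np.uint8)
    fg = probs[1:]
    win = fg.argmax(axis=0)
    winp = np.take_along_axis(fg, win[None], axis=0)[0]
    mask = (win + 1).astype(np.uint8)
    mask[winp < threshold] = 0
    return mask
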