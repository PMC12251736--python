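"""Detector building blocks.

Contains the standard YOLOv8 blocks (Conv = conv+BN+SiLU, Bottleneck, C2f,
SPPF, the decoupled anchor-free Detect head) plus the three blocks this
package is really about:

* :func:`spd_transform` / :class:`SPD` — lossless space-to-depth: 2x2
  spatial blocks move into channels, halving resolution and quadrupling
  depth, so a following convolution sees fine detail without a lossy
  stride.
* :class:`SimAM` — parameter-free attention.  Each neuron gets a weight
  from the closed-form energy ``e_t = 4*(var+lambda) / ((t-mu)^2 +
  2*var + 2*lambda)`` (statistics per sample and channel); the output is
  ``x * sigmoid(1/e)``.
* :class:`SSPDConv` — SPD -> pointwise (or 3x3) conv -> SimAM, a drop-in
  replacement for a stride-2 convolution.
* :class:`ESPPFCSPC` — a cross-stage-partial wrapper around the serial
  SPPF max-pool pyramid, with the two 3x3 convolutions of the main branch
  dilated to widen the receptive field at constant parameter count.

Blocks are registerable by name (:data:`BLOCK_REGISTRY`) so architectures
can be edited declaratively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import functional as F
from .autograd import Tensor, concat
from .modules import BatchNorm2d, Conv2d, Module, ModuleList, Sequential


def autopad(k: int, d: int = 1) -> int:
    """'same' padding for odd kernel k at dilation d."""
    return d * (k - 1) // 2


class Conv(Module):
    """Convolution + BatchNorm + SiLU, the YOLOv8 workhorse."""

    def __init__(self, c1, c2, k=1, s=1, d=1, rng=None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, stride=s, padding=autopad(k, d), dilation=d, rng=rng)
        self.bn = BatchNorm2d(c2)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


# ---------------------------------------------------------------------------
# space-to-depth
# ---------------------------------------------------------------------------

def spd_transform(x: Tensor, scale: int = 2) -> Tensor:
    """Space-to-depth: (N, C, H, W) -> (N, scale^2*C, H/s, W/s), lossless.

    Sub-maps are concatenated in row-major offset order
    (0,0), (1,0), (0,1), (1,1) [(row offset, col offset) for scale=2];
    :func:`spd_inverse` restores the input exactly.  Spatial dims must be
    divisible by ``scale`` — no implicit padding.
    """
    n, c, h, w = x.shape
    if h % scale or w % scale:
        raise ValueError(f"spatial dims {h}x{w} not divisible by scale {scale}")
    subs = [x[:, :, i::scale, j::scale] for i in range(scale) for j in range(scale)]
    return concat(subs, axis=1)


def spd_inverse(y: Tensor | np.ndarray, scale: int = 2) -> np.ndarray:
    """Exact inverse of :func:`spd_transform` (numpy only)."""
    d = y.data if isinstance(y, Tensor) else np.asarray(y)
    n, c4, h, w = d.shape
    if c4 % (scale * scale):
        raise ValueError("channel count is not a multiple of scale^2")
    c = c4 // (scale * scale)
    out = np.empty((n, c, h * scale, w * scale), dtype=d.dtype)
    k = 0
    for i in range(scale):
        for j in range(scale):
            out[:, :, i::scale, j::scale] = d[:, k * c : (k + 1) * c]
            k += 1
    return out


class SPD(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return spd_transform(x, self.scale)


# ---------------------------------------------------------------------------
# SimAM attention
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimAMConfig:
    """``lam`` is the energy-function regularizer (guards zero-variance
    channels); the originating attention work uses 1e-4."""

    lam: float = 1e-4

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def simam_attention(x: Tensor, cfg: SimAMConfig = SimAMConfig()) -> Tensor:
    """Parameter-free 3-D attention.

    Per sample and channel with mean ``mu`` and (biased) variance ``var``,
    each neuron ``t`` has energy ``e = 4*(var+lam) / ((t-mu)^2 + 2*var +
    2*lam)`` and is rescaled by ``sigmoid(1/e)``.  A constant channel has
    ``e = 2`` everywhere, i.e. uniform weight ``sigmoid(0.5)``.  Neurons
    further from the channel mean always receive larger weights.
    """
    mu = x.mean(axis=(2, 3), keepdims=True)
    d = x - mu
    var = (d * d).mean(axis=(2, 3), keepdims=True)
    inv_e = ((d * d) + 2.0 * var + 2.0 * cfg.lam) / (4.0 * (var + cfg.lam))
    return x * inv_e.sigmoid()


class SimAM(Module):
    def __init__(self, cfg: SimAMConfig = SimAMConfig()):
        super().__init__()
        self.cfg = cfg

    def forward(self, x):
        return simam_attention(x, self.cfg)


class SSPDConv(Module):
    """SPD -> k x k conv (4*C1 -> C2, stride 1) -> SimAM.

    Output is (S/2) x (S/2) x C2, a drop-in replacement for a stride-2
    convolution.  ``k=1`` is the pointwise form; ``k=3`` is a heavier
    variant exposed for architecture sizing.
    """

    def __init__(self, c1, c2, k: int = 1, simam: SimAMConfig = SimAMConfig(),
                 use_simam: bool = True, rng=None):
        super().__init__()
        self.spd = SPD(2)
        self.conv = Conv(4 * c1, c2, k=k, rng=rng)
        self.att = SimAM(simam) if use_simam else None

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"SSPDConv needs even spatial dims, got {h}x{w}")
        y = self.conv(self.spd(x))
        return self.att(y) if self.att is not None else y


# ---------------------------------------------------------------------------
# YOLOv8 blocks
# ---------------------------------------------------------------------------

class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5, k=3, rng=None):
        super().__init__()
        ch = int(c2 * e) if e != 1.0 else c2
        self.cv1 = Conv(c1, ch, k, rng=rng)
        self.cv2 = Conv(ch, c2, k, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage-partial block with n bottlenecks (YOLOv8)."""

    def __init__(self, c1, c2, n=1, shortcut=False, e=0.5, rng=None):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, rng=rng)
        self.m = ModuleList(
            Bottleneck(self.c, self.c, shortcut, e=1.0, rng=rng) for _ in range(n)
        )

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, : self.c], y[:, self.c :]]
        for m in self.m:
            parts.append(m(parts[-1]))
        return self.cv2(concat(parts, axis=1))


class SPPF(Module):
    """Serial max-pool pyramid (k, stride 1, same padding, applied 3x)."""

    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        ch = c1 // 2
        self.cv1 = Conv(c1, ch, 1, rng=rng)
        self.cv2 = Conv(ch * 4, c2, 1, rng=rng)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(F.max_pool2d(y[-1], self.k, stride=1, padding=self.k // 2))
        return self.cv2(concat(y, axis=1))


@dataclass(frozen=True)
class ESPPFCSPCConfig:
    in_channels: int = 256
    out_channels: int = 256
    hidden_channels: int = 96
    pool_kernel: int = 5
    dilation_rate: int = 2

    def __post_init__(self):
        if self.pool_kernel % 2 == 0:
            raise ValueError("pool_kernel must be odd")
        if self.dilation_rate < 1:
            raise ValueError("dilation_rate must be >= 1")


class ESPPFCSPC(Module):
    """CSP-wrapped SPPF pyramid with dilated 3x3 convolutions.

    Main branch: 1x1 -> dilated 3x3 -> 1x1, then three serial max-pools
    (kernel ``pool_kernel``, stride 1, same padding); the pre-pool map and
    the three pooled maps are concatenated, fused by a 1x1, then a second
    dilated 3x3.  Shortcut branch: a single 1x1.  Branches are concatenated
    and fused to ``out_channels``.  Spatial size is preserved throughout;
    ``dilation_rate=1`` recovers plain SPPFCSPC.
    """

    def __init__(self, cfg: ESPPFCSPCConfig = ESPPFCSPCConfig(), rng=None):
        super().__init__()
        c1, c2, ch, d = cfg.in_channels, cfg.out_channels, cfg.hidden_channels, cfg.dilation_rate
        self.cfg = cfg
        self.cv1 = Conv(c1, ch, 1, rng=rng)
        self.cv3 = Conv(ch, ch, 3, d=d, rng=rng)
        self.cv4 = Conv(ch, ch, 1, rng=rng)
        self.cv5 = Conv(4 * ch, ch, 1, rng=rng)
        self.cv6 = Conv(ch, ch, 3, d=d, rng=rng)
        self.cv2 = Conv(c1, ch, 1, rng=rng)  # shortcut branch
        self.cv7 = Conv(2 * ch, c2, 1, rng=rng)

    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}"
            )
        k = self.cfg.pool_kernel
        y = self.cv4(self.cv3(self.cv1(x)))
        pools = [y]
        for _ in range(3):
            pools.append(F.max_pool2d(pools[-1], k, stride=1, padding=k // 2))
        main = self.cv6(self.cv5(concat(pools, axis=1)))
        short = self.cv2(x)
        return self.cv7(concat([main, short], axis=1))


# ---------------------------------------------------------------------------
# detection head
# ---------------------------------------------------------------------------

class Detect(Module):
    """Decoupled anchor-free YOLOv8 head over three feature levels.

    Per level: a box branch predicting ``4 * reg_max`` distribution logits
    (distances left/top/right/bottom in stride units, discretized into
    ``reg_max`` bins) and a class branch predicting ``nc`` logits.  The
    final 1x1 convolutions carry biases; everything else is conv+BN+SiLU.
    """

    def __init__(self, nc: int, ch: tuple, reg_max: int = 16, rng=None):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box = ModuleList(
            Sequential(Conv(c, c2, 3, rng=rng), Conv(c2, c2, 3, rng=rng),
                       Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng))
            for c in ch
        )
        self.cls = ModuleList(
            Sequential(Conv(c, c3, 3, rng=rng), Conv(c3, c3, 3, rng=rng),
                       Conv2d(c3, nc, 1, bias=True, rng=rng))
            for c in ch
        )
        # standard detection-head prior: rare-positive class bias, unit box bias
        for seq in self.cls:
            seq[-1].bias.data[:] = float(np.log(0.01 / 0.99))
        for seq in self.box:
            seq[-1].bias.data[:] = 1.0

    def forward(self, feats):
        return [(self.box[i](f), self.cls[i](f)) for i, f in enumerate(feats)]


BLOCK_REGISTRY = {
    "Conv": Conv,
    "C2f": C2f,
    "SPPF": SPPF,
    "SPD": SPD,
    "SimAM": SimAM,
    "SSPDConv": SSPDConv,
    "ESPPFCSPC": ESPPFCSPC,
    "Detect": Detect,
}
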