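"""Detector assembly and model statistics.

:func:`build_model` assembles a YOLOv8n-topology baseline or a modified
variant ("yolo-ssm") in which configurable backbone downsampling stages are
replaced by :class:`~leafdet.nn.blocks.SSPDConv` and the SPPF pyramid by
:class:`~leafdet.nn.blocks.ESPPFCSPC`.

The shipped ``yolo-ssm`` preset places SSPDConv (3x3 form) at the stem and
at the deepest backbone downsample and uses an ESPPFCSPC hidden width of
96.  This placement was calibrated so that the assembled model's parameter
and FLOP budget sits about one million parameters / one GFLOP above the
baseline — the published operating point of this architecture family — see
``docs/methods.md`` for the sizing arithmetic.

:func:`model_stats` reports the exact trainable-parameter count and forward
GFLOPs under a fixed 2x multiply-accumulate convention (convolutions only),
identical for every model so differences are convention-free.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .nn.autograd import Tensor, concat, no_grad
from .nn.blocks import (
    C2f,
    Conv,
    Detect,
    ESPPFCSPC,
    ESPPFCSPCConfig,
    SPPF,
    SSPDConv,
    SimAMConfig,
)
from .nn.functional import upsample_nearest2x
from .nn.modules import Conv2d, Module, ModuleList

#: YOLOv8n stage widths; ``width_multiple`` scales these.
_BASE_CHANNELS = (16, 32, 64, 128, 256)
#: YOLOv8n C2f repeat counts (backbone stages 2..5); scaled by depth_multiple.
_BASE_DEPTHS = (1, 2, 2, 1)
#: layer indices of the five backbone downsampling convolutions (stem first)
_DOWNSAMPLE_LAYERS = (0, 1, 3, 5, 7)


@dataclass(frozen=True)
class ModelConfig:
    """Declarative detector description.

    ``sspdconv_placement`` lists backbone downsampling stages (0 = stem,
    1..4 = the deeper stride-2 convolutions) to replace with SSPDConv.
    """

    num_classes: int = 9
    input_size: int = 640
    width_multiple: float = 1.0
    depth_multiple: float = 1.0
    sspdconv_placement: tuple = ()
    sspdconv_kernel: int = 1
    use_simam: bool = True
    use_esppfcspc: bool = False
    esppfcspc_hidden: int = 96
    esppfcspc_dilation: int = 2
    pool_kernel: int = 5
    box_loss_kind: str = "ciou"
    reg_max: int = 16
    simam_lambda: float = 1e-4
    # composite-loss weights (YOLOv8 convention)
    box_weight: float = 7.5
    cls_weight: float = 0.5
    dfl_weight: float = 1.5

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.box_loss_kind not in ("ciou", "mpdiou"):
            raise ValueError(f"unknown box loss {self.box_loss_kind!r}")
        if self.sspdconv_kernel not in (1, 3):
            raise ValueError("sspdconv_kernel must be 1 or 3")
        for s in self.sspdconv_placement:
            if s not in range(5):
                raise ValueError(f"sspdconv_placement stage {s} outside 0..4")

    @property
    def channels(self) -> tuple:
        return tuple(max(2, round(c * self.width_multiple)) for c in _BASE_CHANNELS)

    @property
    def depths(self) -> tuple:
        return tuple(max(1, round(n * self.depth_multiple)) for n in _BASE_DEPTHS)


#: the baseline: plain YOLOv8n topology with CIoU
YOLOV8N = ModelConfig()

#: the calibrated improved-detector preset (see module docstring)
YOLO_SSM = ModelConfig(
    sspdconv_placement=(0, 4),
    sspdconv_kernel=3,
    use_esppfcspc=True,
    esppfcspc_hidden=96,
    box_loss_kind="mpdiou",
)

#: CPU-scale preset used by the toy training loop
TOY = ModelConfig(width_multiple=0.25, input_size=160)

PRESETS = {"yolov8n": YOLOV8N, "yolo-ssm": YOLO_SSM, "toy": TOY}


def toy_variant(cfg: ModelConfig) -> ModelConfig:
    """Shrink any config to the toy scale (width 0.25, input 160)."""
    return replace(cfg, width_multiple=0.25, input_size=160)


@dataclass
class LayerInfo:
    index: int
    name: str
    out_shape: tuple | None = None


class DetectionModel(Module):
    """Assembled detector: backbone + FPN/PAN neck + decoupled head.

    ``forward`` returns, per feature level (strides 8/16/32), a pair of
    raw maps: box-distribution logits ``(N, 4*reg_max, H, W)`` and class
    logits ``(N, nc, H, W)``.
    """

    strides = (8, 16, 32)

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.channels
        n1, n2, n3, n4 = cfg.depths
        simam = SimAMConfig(cfg.simam_lambda)

        def down(stage: int, c_in: int, c_out: int) -> Module:
            if stage in cfg.sspdconv_placement:
                return SSPDConv(c_in, c_out, k=cfg.sspdconv_kernel, simam=simam,
                                use_simam=cfg.use_simam, rng=rng)
            return Conv(c_in, c_out, 3, s=2, rng=rng)

        if cfg.use_esppfcspc:
            pyramid = ESPPFCSPC(
                ESPPFCSPCConfig(c[4], c[4], cfg.esppfcspc_hidden,
                                cfg.pool_kernel, cfg.esppfcspc_dilation),
                rng=rng,
            )
        else:
            pyramid = SPPF(c[4], c[4], cfg.pool_kernel, rng=rng)

        # (module, input layer indices); -1 = previous layer
        self._spec = [
            (down(0, 3, c[0]), [-1]),              # 0  P1/2
            (down(1, c[0], c[1]), [-1]),           # 1  P2/4
            (C2f(c[1], c[1], n1, True, rng=rng), [-1]),   # 2
            (down(2, c[1], c[2]), [-1]),           # 3  P3/8
            (C2f(c[2], c[2], n2, True, rng=rng), [-1]),   # 4
            (down(3, c[2], c[3]), [-1]),           # 5  P4/16
            (C2f(c[3], c[3], n3, True, rng=rng), [-1]),   # 6
            (down(4, c[3], c[4]), [-1]),           # 7  P5/32
            (C2f(c[4], c[4], n4, True, rng=rng), [-1]),   # 8
            (pyramid, [-1]),                       # 9
            ("upsample", [-1]),                    # 10
            ("concat", [-1, 6]),                   # 11
            (C2f(c[3] + c[4], c[3], n1, False, rng=rng), [-1]),  # 12
            ("upsample", [-1]),                    # 13
            ("concat", [-1, 4]),                   # 14
            (C2f(c[2] + c[3], c[2], n1, False, rng=rng), [-1]),  # 15 P3 out
            (Conv(c[2], c[2], 3, s=2, rng=rng), [-1]),           # 16
            ("concat", [-1, 12]),                  # 17
            (C2f(c[2] + c[3], c[3], n1, False, rng=rng), [-1]),  # 18 P4 out
            (Conv(c[3], c[3], 3, s=2, rng=rng), [-1]),           # 19
            ("concat", [-1, 9]),                   # 20
            (C2f(c[3] + c[4], c[4], n1, False, rng=rng), [-1]),  # 21 P5 out
        ]
        self.layers = ModuleList(m for m, _ in self._spec if isinstance(m, Module))
        self.head = Detect(cfg.num_classes, (c[2], c[3], c[4]), cfg.reg_max, rng=rng)
        self.feature_layers = (15, 18, 21)
        self.layer_info = [
            LayerInfo(i, m if isinstance(m, str) else type(m).__name__)
            for i, (m, _) in enumerate(self._spec)
        ]

    def forward(self, x: Tensor):
        outputs = []
        for i, (m, srcs) in enumerate(self._spec):
            ins = [outputs[s] if s >= 0 else (x if i == 0 else outputs[i - 1]) for s in srcs]
            if m == "upsample":
                y = upsample_nearest2x(ins[0])
            elif m == "concat":
                y = concat(ins, axis=1)
            else:
                y = m(ins[0])
            outputs.append(y)
            self.layer_info[i].out_shape = tuple(y.shape)
        feats = [outputs[i] for i in self.feature_layers]
        return self.head(feats)

    # -- statistics ----------------------------------------------------------

    def count_macs(self, input_size: int | None = None) -> int:
        """Multiply-accumulate count of one forward pass at ``input_size``
        (convolution layers only), measured by tracing a real forward."""
        size = input_size or self.cfg.input_size
        mode = self.training
        self.eval()
        with no_grad():
            self.forward(Tensor(np.zeros((1, 3, size, size), np.float32)))
        self.train(mode)
        return int(sum(m.last_macs for m in self.modules() if isinstance(m, Conv2d)))


def config_to_yaml(cfg: ModelConfig, path) -> None:
    """Write a config as an editable YAML file (block placements included)."""
    d = asdict(cfg)
    d["sspdconv_placement"] = list(d["sspdconv_placement"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path) -> ModelConfig:
    """Load a declarative model config written by :func:`config_to_yaml`."""
    d = yaml.safe_load(Path(path).read_text())
    d["sspdconv_placement"] = tuple(d.get("sspdconv_placement", ()))
    return ModelConfig(**d)


def build_model(cfg: ModelConfig, seed: int = 0) -> DetectionModel:
    """Deterministically assemble a detector from its config."""
    return DetectionModel(cfg, seed=seed)


def model_stats(model: DetectionModel, input_size: int | None = None):
    """(params in millions, forward GFLOPs) at ``input_size``.

    Parameters are the exact trainable total; GFLOPs use the 2x MAC
    convention on convolution layers.  Both are reported to full precision
    — round to one decimal for tabulation.
    """
    params_m = model.num_params() / 1e6
    gflops = 2.0 * model.count_macs(input_size) / 1e9
    return params_m, gflops
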