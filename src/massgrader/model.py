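"""MassNet and baseline regression networks for image-based mass prediction.

MassNet alternates stride-2 convolutions (each followed by batch
normalization and SiLU) with cross-stage-partial bottleneck blocks
(BottleneckCSPC): the block splits its channels, runs one half through a
stack of residual bottlenecks, concatenates with the untouched half and
fuses with a 1x1 convolution. Adaptive average pooling collapses the final
feature map to a fixed-length vector regardless of input size, and a fully
connected head emits a single scalar mass in standardized units.

Baselines ("alexnet-reg", "vgg11-reg", "resnet18-reg", "mobilenet-reg")
keep the standard feature trunks of their families with the classifier
replaced by a global-average-pool + single-output linear head, trained from
scratch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as ag

__all__ = [
    "ModelConfig",
    "MassPredictor",
    "build_massnet",
    "build_baseline",
    "predict_mass",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "BASELINES",
]

BASELINES = ("alexnet-reg", "mobilenet-reg", "resnet18-reg", "vgg11-reg")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture plan for MassNet.

    ``stage_plan`` entries are (channel width, bottleneck repeats); each stage
    is a stride-2 convolution to that width followed by a BottleneckCSPC
    block. ``head_widths`` are the hidden fully connected widths; the final
    output dimension is always 1.
    """

    input_size: int = 224
    stem_channels: tuple[int, int] = (32, 64)
    stage_plan: tuple[tuple[int, int], ...] = ((128, 1), (256, 2), (512, 2))
    pooled_dim: int = 512
    head_widths: tuple[int, ...] = (128,)

    def __post_init__(self):
        if self.pooled_dim != self.stage_plan[-1][0]:
            raise ValueError(
                "pooled_dim must equal the final stage width "
                f"({self.stage_plan[-1][0]}), got {self.pooled_dim}"
            )
        n_strides = len(self.stem_channels) + len(self.stage_plan)
        if self.input_size < 2**n_strides:
            raise ValueError(
                f"input_size {self.input_size} collapses below 1x1 after "
                f"{n_strides} stride-2 reductions"
            )

    @classmethod
    def desk(cls) -> "ModelConfig":
        """Small profile for 96x96 images trainable in minutes on one CPU."""
        return cls(
            input_size=96,
            stem_channels=(16, 32),
            stage_plan=((48, 1), (96, 1), (128, 1)),
            pooled_dim=128,
            head_widths=(64,),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            input_size=int(d["input_size"]),
            stem_channels=tuple(d["stem_channels"]),
            stage_plan=tuple(tuple(p) for p in d["stage_plan"]),
            pooled_dim=int(d["pooled_dim"]),
            head_widths=tuple(d["head_widths"]),
        )


class ConvBnSiLU(nn.Module):
    """Convolution -> batch norm -> SiLU, the unit every MassNet conv uses."""

    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 expand with a residual connection (width preserved)."""

    def __init__(self, c, rng=None):
        super().__init__()
        mid = max(c // 2, 1)
        self.cv1 = ConvBnSiLU(c, mid, k=1, rng=rng)
        self.cv2 = ConvBnSiLU(mid, c, k=3, rng=rng)

    def forward(self, x):
        return ag.add(x, self.cv2(self.cv1(x)))


class BottleneckCSPC(nn.Module):
    """Cross-stage partial block: split channels, bottleneck one half, fuse.

    The input's channels are split in two; one half passes through ``n``
    residual bottlenecks while the other crosses the stage untouched. The
    halves are concatenated and fused by a 1x1 convolution back to the full
    width, preserving gradient flow at roughly half the bottleneck cost.
    """

    def __init__(self, c, n=1, rng=None):
        super().__init__()
        if c % 2:
            raise ValueError("CSPC width must be even")
        self.half = c // 2
        self.blocks = nn.ModuleList(Bottleneck(self.half, rng=rng) for _ in range(n))
        self.fuse = ConvBnSiLU(c, c, k=1, rng=rng)

    def forward(self, x):
        part = ag.narrow(x, 0, self.half, axis=1)
        skip = ag.narrow(x, self.half, self.half, axis=1)
        for block in self.blocks:
            part = block(part)
        return self.fuse(ag.concat([part, skip], axis=1))


class MassNet(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        layers = []
        cin = 3
        for cout in config.stem_channels:
            layers.append(ConvBnSiLU(cin, cout, k=3, stride=2, rng=rng))
            cin = cout
        for width, repeats in config.stage_plan:
            layers.append(ConvBnSiLU(cin, width, k=3, stride=2, rng=rng))
            layers.append(BottleneckCSPC(width, repeats, rng=rng))
            cin = width
        self.features = nn.Sequential(*layers)
        self.pool = nn.GlobalAvgPool2d()
        head = []
        hin = config.pooled_dim
        for w in config.head_widths:
            head += [nn.Linear(hin, w, rng=rng), nn.SiLU()]
            hin = w
        head.append(nn.Linear(hin, 1, rng=rng))
        self.head = nn.Sequential(*head)

    def forward(self, x):
        return self.head(self.pool(self.features(x)))


@dataclass
class MassPredictor:
    """A trained or trainable image -> scalar-mass function.

    ``net`` operates on standardized inputs and emits standardized outputs;
    the normalization constants (per-channel image mean/sd on [0, 1] pixels,
    and target mass mean/sd in grams) are part of the predictor and are set
    by the training loop.
    """

    arch: str
    net: nn.Module
    config: ModelConfig | None = None
    x_mean: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.float32))
    x_std: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=np.float32))
    y_mean: float = 0.0
    y_std: float = 1.0

    def normalize_images(self, images: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) uint8/float images -> standardized (N, 3, H, W)."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] != 3:
            raise ValueError(f"expected 3-channel images, got shape {x.shape}")
        x = x / 255.0
        x = (x - self.x_mean[None, None, None, :]) / self.x_std[None, None, None, :]
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def build_massnet(
    config: ModelConfig | None = None, seed: int = 0
) -> MassPredictor:
    """Instantiate MassNet with He-initialized weights, deterministic in seed."""
    cfg = config or ModelConfig()
    rng = np.random.default_rng(seed)
    return MassPredictor(arch="massnet", net=MassNet(cfg, rng), config=cfg)


def predict_mass(model: MassPredictor, images: np.ndarray) -> np.ndarray | float:
    """Predict mass in grams for one image (H, W, 3) or a batch (N, H, W, 3).

    Inference runs in evaluation mode (batch norm uses running statistics),
    so repeated calls on the same image are bit-identical.
    """
    single = np.asarray(images).ndim == 3
    x = model.normalize_images(images)
    was_training = model.net.training
    model.net.eval()
    out = model.net(Tensor(x)).data.reshape(-1)
    if was_training:
        model.net.train()
    grams = out * model.y_std + model.y_mean
    if not np.all(np.isfinite(grams)):
        raise FloatingPointError("non-finite mass prediction")
    return float(grams[0]) if single else grams.astype(np.float64)


def count_parameters(model: MassPredictor | nn.Module) -> int:
    net = model.net if isinstance(model, MassPredictor) else model
    return int(sum(p.data.size for p in net.parameters()))


# ---------------------------------------------------------------------------
# baselines


class _ResBasicBlock(nn.Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.act = nn.ReLU()
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, stride=stride, padding=0, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x):
        out = self.bn2(self.conv2(self.act(self.bn1(self.conv1(x)))))
        skip = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return self.act(ag.add(out, skip))


class _DepthwiseSeparable(nn.Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.dw = nn.Conv2d(cin, cin, 3, stride=stride, groups=cin, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cin)
        self.pw = nn.Conv2d(cin, cout, 1, padding=0, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act(self.bn2(self.pw(self.act(self.bn1(self.dw(x))))))


def _alexnet(rng):
    return nn.Sequential(
        nn.Conv2d(3, 64, 11, stride=4, padding=2, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(64, 192, 5, padding=2, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(192, 384, 3, rng=rng),
        nn.ReLU(),
        nn.Conv2d(384, 256, 3, rng=rng),
        nn.ReLU(),
        nn.Conv2d(256, 256, 3, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.GlobalAvgPool2d(),
        nn.Linear(256, 1, rng=rng),
    )


def _vgg11(rng):
    layers = []
    cin = 3
    for entry in (64, "M", 128, "M", 256, 256, "M", 512, 512, "M", 512, 512, "M"):
        if entry == "M":
            layers.append(nn.MaxPool2d(2, 2))
        else:
            layers += [nn.Conv2d(cin, entry, 3, rng=rng), nn.ReLU()]
            cin = entry
    layers += [nn.GlobalAvgPool2d(), nn.Linear(512, 1, rng=rng)]
    return nn.Sequential(*layers)


def _resnet18(rng):
    layers = [
        nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng),
        nn.BatchNorm2d(64),
        nn.ReLU(),
        nn.MaxPool2d(3, 2, padding=1),
    ]
    cin = 64
    for cout, stride in (
        (64, 1), (64, 1),
        (128, 2), (128, 1),
        (256, 2), (256, 1),
        (512, 2), (512, 1),
    ):
        layers.append(_ResBasicBlock(cin, cout, stride, rng))
        cin = cout
    layers += [nn.GlobalAvgPool2d(), nn.Linear(512, 1, rng=rng)]
    return nn.Sequential(*layers)


def _mobilenet(rng):
    layers = [
        nn.Conv2d(3, 32, 3, stride=2, bias=False, rng=rng),
        nn.BatchNorm2d(32),
        nn.ReLU(),
    ]
    cin = 32
    for cout, stride in (
        (64, 1), (128, 2), (128, 1), (256, 2), (256, 1), (512, 2),
        (512, 1), (512, 1), (512, 1), (512, 1), (512, 1), (1024, 2), (1024, 1),
    ):
        layers.append(_DepthwiseSeparable(cin, cout, stride, rng))
        cin = cout
    layers += [nn.GlobalAvgPool2d(), nn.Linear(1024, 1, rng=rng)]
    return nn.Sequential(*layers)


_BASELINE_BUILDERS = {
    "alexnet-reg": _alexnet,
    "vgg11-reg": _vgg11,
    "resnet18-reg": _resnet18,
    "mobilenet-reg": _mobilenet,
}


def build_baseline(name: str, seed: int = 0) -> MassPredictor:
    """Standard trunk of the named family with a single-output regression head."""
    if name not in _BASELINE_BUILDERS:
        raise ValueError(
            f"unknown baseline {name!r}; options: {', '.join(sorted(_BASELINE_BUILDERS))}"
        )
    rng = np.random.default_rng(seed)
    return MassPredictor(arch=name, net=_BASELINE_BUILDERS[name](rng))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: MassPredictor, path: Path | str) -> None:
    """Persist weights plus normalization constants and the ModelConfig."""
    path = Path(path)
    meta = {
        "arch": model.arch,
        "config": model.config.to_dict() if model.config else None,
        "y_mean": float(model.y_mean),
        "y_std": float(model.y_std),
    }
    state = model.net.state_dict()
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        __x_mean__=model.x_mean,
        __x_std__=model.x_std,
        **state,
    )


def load_checkpoint(path: Path | str) -> MassPredictor:
    path = Path(path)
    if not path.exists():
        alt = path.with_suffix(path.suffix + ".npz")
        if alt.exists():
            path = alt
        else:
            raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["arch"] == "massnet":
            model = build_massnet(ModelConfig.from_dict(meta["config"]))
        else:
            model = build_baseline(meta["arch"])
        model.net.load_state_dict(
            {k: data[k] for k in data.files if not k.startswith("__")}
        )
        model.x_mean = data["__x_mean__"].astype(np.float32)
        model.x_std = data["__x_std__"].astype(np.float32)
    model.y_mean = float(meta["y_mean"])
    model.y_std = float(meta["y_std"])
    model.net.eval()
    return model


def architecture_summary(model: MassPredictor) -> dict:
    """JSON-ready architecture summary (tag, config, parameter count)."""
    return {
        "arch": model.arch,
        "config": model.config.to_dict() if model.config else None,
        "n_parameters": count_parameters(model),
    }
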