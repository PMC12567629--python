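"""WideResNet family in 1-D and 2-D with exact parameter accounting.

The networks follow the pre-activation WideResNet recipe: a width-16 stem
convolution, three groups of ``(depth - 4) / 6`` residual blocks at widths
``16k / 32k / 64k`` with stride-2 downsampling entering groups 2 and 3, a
1x1 (size-1 in 1-D) projection shortcut applied to the pre-activated input
wherever the shape changes, then a final BN + ReLU, global average pooling
and a single biased linear classifier.  Convolutions are bias-free, kernel
size 3 throughout (3x3 in 2-D).  Time-series models use 1-D convolutions,
image models 2-D ones; they otherwise share the same block structure, so a
"WRN d-k" name means the same thing in both dimensionalities.

Parameter counts are the architecture-fidelity oracle for this module: the
1-D family at 3 input channels and 14 classes comes out at 0.06 M (16-1),
0.54 M (16-3), 0.13 M (28-1) and 1.12 M (28-3); the matching 2-D models at
0.18 M, 1.55 M, 0.37 M and 3.29 M.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "WRNConfig",
    "WideResNet",
    "build_wrn",
    "count_params",
    "compression_ratio",
    "flatten_params",
    "load_params",
    "interpolate_params",
    "save_checkpoint",
    "load_checkpoint",
    "state_dict",
    "load_state_dict",
    "flops_report",
]


@dataclass(frozen=True)
class WRNConfig:
    """Description of one WideResNet.

    ``input_size`` is the window length for 1-D models and ``(H, W)`` for
    2-D models; it never affects the parameter count (global average
    pooling), only the forward shapes.
    """

    depth: int = 16
    width: int = 1
    dimensionality: str = "1d"  # "1d" | "2d"
    in_channels: int = 3
    n_classes: int = 14
    input_size: object = 500

    def __post_init__(self):
        if (self.depth - 4) % 6 != 0 or self.depth < 10:
            raise ValueError(
                f"depth must satisfy (depth - 4) % 6 == 0, got {self.depth}"
            )
        if self.width < 1:
            raise ValueError(f"width must be >= 1, got {self.width}")
        if self.dimensionality not in ("1d", "2d"):
            raise ValueError(f"dimensionality must be '1d' or '2d'")
        if self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("in_channels >= 1 and n_classes >= 2 required")

    @property
    def blocks_per_group(self) -> int:
        return (self.depth - 4) // 6

    @property
    def widths(self) -> tuple[int, int, int]:
        k = self.width
        return (16 * k, 32 * k, 64 * k)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @staticmethod
    def from_json(s: str) -> "WRNConfig":
        d = json.loads(s)
        if isinstance(d.get("input_size"), list):
            d["input_size"] = tuple(d["input_size"])
        return WRNConfig(**d)


class _PreactBlock(nn.Module):
    def __init__(self, conv_cls, c_in, c_out, stride, rng):
        super().__init__()
        self.bn1 = self.add_module("bn1", nn.BatchNorm(c_in))
        self.relu1 = self.add_module("relu1", nn.ReLU())
        self.conv1 = self.add_module("conv1", conv_cls(c_in, c_out, 3, stride, rng=rng))
        self.bn2 = self.add_module("bn2", nn.BatchNorm(c_out))
        self.relu2 = self.add_module("relu2", nn.ReLU())
        self.conv2 = self.add_module("conv2", conv_cls(c_out, c_out, 3, 1, rng=rng))
        if stride != 1 or c_in != c_out:
            self.proj = self.add_module("proj", conv_cls(c_in, c_out, 1, stride, rng=rng))
        else:
            self.proj = None
        self._shortcut_identity = self.proj is None

    def forward(self, x, train):
        a = self.relu1.forward(self.bn1.forward(x, train), train)
        shortcut = x if self._shortcut_identity else self.proj.forward(a, train)
        out = self.conv1.forward(a, train)
        out = self.conv2.forward(self.relu2.forward(self.bn2.forward(out, train), train), train)
        return out + shortcut

    def backward(self, dout):
        da = self.conv1.backward(
            self.bn2.backward(self.relu2.backward(self.conv2.backward(dout)))
        )
        if not self._shortcut_identity:
            da = da + self.proj.backward(dout)
        dx = self.bn1.backward(self.relu1.backward(da))
        if self._shortcut_identity:
            dx = dx + dout
        return dx


class WideResNet(nn.Module):
    """A realized WRN with explicit forward/backward passes."""

    def __init__(self, cfg: WRNConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        conv_cls = nn.Conv1d if cfg.dimensionality == "1d" else nn.Conv2d
        w1, w2, w3 = cfg.widths
        n = cfg.blocks_per_group
        self.stem = self.add_module("stem", conv_cls(cfg.in_channels, 16, 3, 1, rng=rng))
        self.blocks: list[_PreactBlock] = []
        c_in = 16
        for gi, (width, stride) in enumerate(((w1, 1), (w2, 2), (w3, 2))):
            for bi in range(n):
                blk = _PreactBlock(conv_cls, c_in, width, stride if bi == 0 else 1, rng)
                self.add_module(f"group{gi + 1}.block{bi}", blk)
                self.blocks.append(blk)
                c_in = width
        self.bn_final = self.add_module("bn_final", nn.BatchNorm(w3))
        self.relu_final = self.add_module("relu_final", nn.ReLU())
        self.pool = self.add_module("pool", nn.GlobalAvgPool())
        self.fc = self.add_module("fc", nn.Linear(w3, cfg.n_classes, rng=rng))

    # -- passes -----------------------------------------------------------
    def forward(self, x, train=False, return_features=False):
        """Map a channels-first batch ([B, C, L] or [B, C, H, W]) to
        [B, n_classes] logits.  Internally the engine is channels-last."""
        x = np.asarray(x, dtype=np.float32)
        x = np.ascontiguousarray(np.moveaxis(x, 1, -1))
        out = self.stem.forward(x, train)
        for blk in self.blocks:
            out = blk.forward(out, train)
        out = self.relu_final.forward(self.bn_final.forward(out, train), train)
        feats = self.pool.forward(out, train)
        logits = self.fc.forward(feats, train)
        if return_features:
            return logits, feats
        return logits

    def backward(self, dlogits):
        d = self.pool.backward(self.fc.backward(dlogits))
        d = self.bn_final.backward(self.relu_final.backward(d))
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        return self.stem.backward(d)

    # -- BN statistics re-estimation --------------------------------------
    def reestimate_bn(self, batches):
        """Replace every BN layer's running statistics with the average of
        per-batch statistics over ``batches`` (an iterable of input arrays).
        Used after weight-space interpolation, where interpolated running
        statistics are meaningless."""
        bns = [m for m in self.modules() if isinstance(m, nn.BatchNorm)]
        for bn in bns:
            bn.start_accumulate()
        for x in batches:
            self.forward(x, train=False)
        for bn in bns:
            bn.finish_accumulate()


def build_wrn(cfg: WRNConfig, seed: int = 0) -> WideResNet:
    """Instantiate a WRN with seeded He-normal initialization."""
    return WideResNet(cfg, seed=seed)


def count_params(net: WideResNet) -> int:
    """Exact count of trainable scalars (BN running stats excluded)."""
    return net.num_params()


def params_millions(net: WideResNet) -> float:
    return round(count_params(net) / 1e6, 2)


def compression_ratio(student_params: int, teacher1_params: int, teacher2_params: int) -> float:
    """Student size relative to the sum of both teachers, in percent."""
    if teacher1_params <= 0 or teacher2_params <= 0 or student_params <= 0:
        raise ValueError("parameter counts must be positive")
    return round(100.0 * student_params / (teacher1_params + teacher2_params), 2)


# -- weight-vector utilities ----------------------------------------------

def flatten_params(net: WideResNet) -> np.ndarray:
    return np.concatenate([p.data.ravel() for p in net.parameters()])


def load_params(net: WideResNet, vector: np.ndarray) -> WideResNet:
    vector = np.asarray(vector, dtype=np.float32)
    if vector.size != net.num_params():
        raise ValueError(
            f"vector length {vector.size} != parameter count {net.num_params()}"
        )
    offset = 0
    for p in net.parameters():
        n = p.data.size
        p.data[...] = vector[offset : offset + n].reshape(p.data.shape)
        offset += n
    return net


def interpolate_params(x_a: np.ndarray, x_b: np.ndarray, eta: float) -> np.ndarray:
    """Linear path (1 - eta) x_a + eta x_b through weight space."""
    x_a = np.asarray(x_a)
    x_b = np.asarray(x_b)
    if x_a.shape != x_b.shape:
        raise ValueError("parameter vectors must have equal length")
    return (1.0 - eta) * x_a + eta * x_b


# -- checkpoints -----------------------------------------------------------

def state_dict(net: WideResNet) -> dict:
    state = {"param." + k: v.data.copy() for k, v in net.named_parameters()}
    state.update({"buffer." + k: v.copy() for k, v in net.named_buffers()})
    return state


def load_state_dict(net: WideResNet, state: dict) -> WideResNet:
    for k, p in net.named_parameters():
        p.data[...] = state["param." + k]
    for k, b in net.named_buffers():
        b[...] = state["buffer." + k]
    return net


def save_checkpoint(path, net: WideResNet):
    """Single-archive checkpoint: named parameters + buffers + config."""
    arrays = state_dict(net)
    arrays["__config__"] = np.frombuffer(
        net.cfg.to_json().encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path, cfg: WRNConfig | None = None) -> WideResNet:
    """Load a checkpoint; if ``cfg`` is given it must equal the stored one."""
    with np.load(path) as data:
        stored = WRNConfig.from_json(bytes(data["__config__"]).decode("utf-8"))
        if cfg is not None and cfg != stored:
            raise ValueError(f"checkpoint config {stored} != requested {cfg}")
        net = build_wrn(stored, seed=0)
        state = {k: data[k] for k in data.files if k != "__config__"}
    return load_state_dict(net, state)


# -- informational FLOP report ---------------------------------------------

def flops_report(cfg: WRNConfig) -> int:
    """Multiply-accumulate count of one forward pass (informational only;
    printed FLOP conventions vary and this one is multiply-accumulate)."""
    net = build_wrn(cfg, seed=0)
    if cfg.dimensionality == "1d":
        x = np.zeros((1, cfg.in_channels, int(cfg.input_size)), dtype=np.float32)
    else:
        h, w = cfg.input_size if isinstance(cfg.input_size, tuple) else (cfg.input_size, cfg.input_size)
        x = np.zeros((1, cfg.in_channels, int(h), int(w)), dtype=np.float32)
    macs = 0

    def conv_macs(mod, out_spatial):
        return mod.weight.data.shape[1] * mod.c_out * out_spatial

    def spatial(t):  # channels-last maps inside the engine
        return int(np.prod(t.shape[1:-1]))

    # walk the same path as forward, tracking spatial size
    x = np.ascontiguousarray(np.moveaxis(x, 1, -1))
    out = net.stem.forward(x, False)
    macs += conv_macs(net.stem, spatial(out))
    for blk in net.blocks:
        a = blk.relu1.forward(blk.bn1.forward(out, False), False)
        o1 = blk.conv1.forward(a, False)
        macs += conv_macs(blk.conv1, spatial(o1))
        o2 = blk.conv2.forward(blk.relu2.forward(blk.bn2.forward(o1, False), False), False)
        macs += conv_macs(blk.conv2, spatial(o2))
        if blk.proj is not None:
            sp = blk.proj.forward(a, False)
            macs += conv_macs(blk.proj, spatial(sp))
            out = o2 + sp
        else:
            out = o2 + out
    macs += net.cfg.widths[2] * cfg.n_classes
    return macs
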