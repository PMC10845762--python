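"""The two patch-to-patch network architectures.

Both are encoder--decoder networks with two structural traits:

* down-sampling by 2x2 strided convolution instead of max-pooling, so the
  fine detail of the input is carried by learned weights rather than
  discarded by a hard maximum; and
* a global additive skip from the network input to its output, so the network
  learns a residual correction and the untrained (zero-weight) network is the
  identity map.

``ModifiedUNet`` (sinogram domain, 64x64 patches by default) uses classic
concatenative encoder->decoder skips.  ``ModifiedResUNet`` (image domain,
48x48 patches by default) replaces concatenation by *additive* cross-stage
connections and puts a residual block inside every stage.

Depth and channel width are capacity knobs, not part of the structural
contract; defaults are desk-scale (depth 3, 16 base channels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv2d, Param, ReLU, Upsample2x

__all__ = [
    "NetConfig",
    "ModifiedUNet",
    "ModifiedResUNet",
    "build_modified_unet",
    "build_modified_resunet",
    "save_model",
    "load_model",
]

_KINDS = ("modified_unet", "modified_resunet")


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``patch_size`` is the training patch side (64 for the sinogram network,
    48 for the image network) and must be divisible by ``2**depth``.
    """

    kind: str = "modified_unet"
    depth: int = 3
    base_channels: int = 16
    patch_size: int = 64

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")
        if self.patch_size % (2**self.depth):
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 2^depth={2**self.depth}"
            )


class _Model:
    """Shared plumbing: parameters, normalization, batched inference."""

    config: NetConfig

    def __init__(self, config: NetConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.norm_lo = 0.0
        self.norm_hi = 1.0
        # leading input channels carrying intensities (normalized); the rest
        # are masks/features already on a unit scale
        self.value_channels = 1

    @property
    def depth(self) -> int:
        return self.config.depth

    @property
    def patch_size(self) -> int:
        return self.config.patch_size

    def params(self) -> list[Param]:
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def set_normalization(self, lo: float, hi: float) -> None:
        """Store the linear intensity map applied before/after the network."""
        if not hi > lo:
            raise ValueError("normalization requires hi > lo")
        self.norm_lo, self.norm_hi = float(lo), float(hi)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_lo) / (self.norm_hi - self.norm_lo)

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return z * (self.norm_hi - self.norm_lo) + self.norm_lo

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference on a ``(n, in_channels, h, w)`` stack.

        The intensity normalization applies to the leading ``value_channels``
        channels; auxiliary channels (masks, gap maps) pass through unscaled.
        Output has one channel.
        """
        x = np.asarray(x, dtype=np.float64)
        vc = self.value_channels
        out = np.empty((x.shape[0], 1, x.shape[2], x.shape[3]))
        for i in range(0, x.shape[0], batch_size):
            z = x[i : i + batch_size].astype(self.dtype).copy()
            z[:, :vc] = self.normalize(x[i : i + batch_size, :vc]).astype(self.dtype)
            out[i : i + batch_size] = self.denormalize(self.forward(z).astype(np.float64))
        return out


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, cin: int, cout: int, rng, dtype):
        self.c1 = Conv2d(cin, cout, 3, rng=rng, dtype=dtype)
        self.r1 = ReLU()
        self.c2 = Conv2d(cout, cout, 3, rng=rng, dtype=dtype)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))


class _ResBlock:
    """x -> conv3x3 -> ReLU -> conv3x3 -> (+x) -> ReLU."""

    def __init__(self, ch: int, rng, dtype):
        self.c1 = Conv2d(ch, ch, 3, rng=rng, dtype=dtype)
        self.r1 = ReLU()
        self.c2 = Conv2d(ch, ch, 3, rng=rng, dtype=dtype)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        z = self.c2.forward(self.r1.forward(self.c1.forward(x)))
        return self.r2.forward(x + z)

    def backward(self, dy):
        ds = self.r2.backward(dy)
        return ds + self.c1.backward(self.r1.backward(self.c2.backward(ds)))


class _Down:
    """2x2 strided convolution (the pooling replacement) -> ReLU."""

    def __init__(self, cin: int, cout: int, rng, dtype):
        self.conv = Conv2d(cin, cout, 2, stride=2, pad=0, rng=rng, dtype=dtype)
        self.relu = ReLU()

    def params(self):
        return self.conv.params()

    def forward(self, x):
        return self.relu.forward(self.conv.forward(x))

    def backward(self, dy):
        return self.conv.backward(self.relu.backward(dy))


class _Up:
    """Nearest-neighbor 2x up-sampling -> conv3x3 -> ReLU."""

    def __init__(self, cin: int, cout: int, rng, dtype):
        self.up = Upsample2x()
        self.conv = Conv2d(cin, cout, 3, rng=rng, dtype=dtype)
        self.relu = ReLU()

    def params(self):
        return self.conv.params()

    def forward(self, x):
        return self.relu.forward(self.conv.forward(self.up.forward(x)))

    def backward(self, dy):
        return self.up.backward(self.conv.backward(self.relu.backward(dy)))


class ModifiedUNet(_Model):
    """U-Net with strided-conv pooling, concatenative encoder->decoder skips
    and a global input->output additive residual.

    The input may carry auxiliary channels beyond the value channel (the
    sinogram network receives the binary originally-missing mask as a second
    channel so it can tell measured from interpolated bins); the output is
    always one channel and the global residual adds the value channel.
    """

    def __init__(self, config: NetConfig, in_channels: int = 1, seed: int = 0, dtype=np.float32):
        super().__init__(config, dtype)
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        d, b = config.depth, config.base_channels
        ch = [b * 2**i for i in range(d + 1)]
        self.enc = [
            _ConvBlock(in_channels if i == 0 else ch[i], ch[i], rng, dtype) for i in range(d)
        ]
        self.down = [_Down(ch[i], ch[i + 1], rng, dtype) for i in range(d)]
        self.bottleneck = _ConvBlock(ch[d], ch[d], rng, dtype)
        self.up = [_Up(ch[i + 1], ch[i], rng, dtype) for i in range(d)]
        self.dec = [_ConvBlock(2 * ch[i], ch[i], rng, dtype) for i in range(d)]
        # near-identity start: a small (not zero) final conv keeps the global
        # residual dominant at initialization while letting gradients reach
        # the interior layers from step one
        self.final = Conv2d(ch[0], 1, 3, rng=rng, dtype=dtype)
        self.final.weight.value *= 0.05
        self._ch = ch

    def params(self):
        out = []
        for m in (*self.enc, *self.down, self.bottleneck, *self.up, *self.dec):
            out += m.params()
        return out + self.final.params()

    def forward(self, x):
        d = self.config.depth
        skips = []
        h = x
        for i in range(d):
            h = self.enc[i].forward(h)
            skips.append(h)
            h = self.down[i].forward(h)
        h = self.bottleneck.forward(h)
        for i in reversed(range(d)):
            h = self.up[i].forward(h)
            h = self.dec[i].forward(np.concatenate([h, skips[i]], axis=1))
        return x[:, :1] + self.final.forward(h)

    def backward(self, dy):
        d = self.config.depth
        dh = self.final.backward(dy)
        dskips = [None] * d
        for i in range(d):
            dcat = self.dec[i].backward(dh)
            ch = self._ch[i]
            dskips[i] = dcat[:, ch:]
            dh = self.up[i].backward(dcat[:, :ch])
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(d)):
            dh = self.down[i].backward(dh) + dskips[i]
            dh = self.enc[i].backward(dh)
        dx = dh  # network path
        dx[:, :1] += dy  # global residual over the value channel
        return dx


class ModifiedResUNet(_Model):
    """U-Net backbone with residual blocks in every stage, *additive*
    cross-stage connections (no concatenation) and a global input->output
    residual."""

    def __init__(self, config: NetConfig, in_channels: int = 1, seed: int = 0, dtype=np.float32):
        super().__init__(config, dtype)
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        d, b = config.depth, config.base_channels
        ch = [b * 2**i for i in range(d + 1)]
        self.stem = Conv2d(in_channels, ch[0], 3, rng=rng, dtype=dtype)
        self.enc = [_ResBlock(ch[i], rng, dtype) for i in range(d)]
        self.down = [_Down(ch[i], ch[i + 1], rng, dtype) for i in range(d)]
        self.bottleneck = _ResBlock(ch[d], rng, dtype)
        self.up = [_Up(ch[i + 1], ch[i], rng, dtype) for i in range(d)]
        self.dec = [_ResBlock(ch[i], rng, dtype) for i in range(d)]
        self.final = Conv2d(ch[0], 1, 3, rng=rng, dtype=dtype)
        self.final.weight.value *= 0.05

    def params(self):
        out = self.stem.params()
        for m in (*self.enc, *self.down, self.bottleneck, *self.up, *self.dec):
            out += m.params()
        return out + self.final.params()

    def forward(self, x):
        d = self.config.depth
        h = self.stem.forward(x)
        skips = []
        for i in range(d):
            h = self.enc[i].forward(h)
            skips.append(h)
            h = self.down[i].forward(h)
        h = self.bottleneck.forward(h)
        for i in reversed(range(d)):
            h = self.up[i].forward(h) + skips[i]  # additive cross-stage link
            h = self.dec[i].forward(h)
        return x[:, :1] + self.final.forward(h)

    def backward(self, dy):
        d = self.config.depth
        dh = self.final.backward(dy)
        dskips = [None] * d
        for i in range(d):
            dsum = self.dec[i].backward(dh)
            dskips[i] = dsum
            dh = self.up[i].backward(dsum)
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(d)):
            dh = self.down[i].backward(dh) + dskips[i]
            dh = self.enc[i].backward(dh)
        dx = self.stem.backward(dh)
        dx[:, :1] += dy
        return dx


def build_modified_unet(
    config: NetConfig, seed: int = 0, dtype=np.float32, in_channels: int = 1
) -> ModifiedUNet:
    if config.kind != "modified_unet":
        raise ValueError(f"config.kind is {config.kind!r}, expected 'modified_unet'")
    return ModifiedUNet(config, in_channels=in_channels, seed=seed, dtype=dtype)


def build_modified_resunet(
    config: NetConfig, seed: int = 0, dtype=np.float32, in_channels: int = 1
) -> ModifiedResUNet:
    if config.kind != "modified_resunet":
        raise ValueError(f"config.kind is {config.kind!r}, expected 'modified_resunet'")
    return ModifiedResUNet(config, in_channels=in_channels, seed=seed, dtype=dtype)


def save_model(model: _Model, path) -> None:
    """Serialize architecture config, normalization and weights (npz)."""
    c = model.config
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez(
        path,
        kind=c.kind,
        depth=c.depth,
        base_channels=c.base_channels,
        patch_size=c.patch_size,
        in_channels=getattr(model, "in_channels", 1),
        value_channels=model.value_channels,
        norm=np.array([model.norm_lo, model.norm_hi]),
        **arrays,
    )


def load_model(path) -> _Model:
    with np.load(path, allow_pickle=False) as data:
        config = NetConfig(
            kind=str(data["kind"]),
            depth=int(data["depth"]),
            base_channels=int(data["base_channels"]),
            patch_size=int(data["patch_size"]),
        )
        builder = build_modified_unet if config.kind == "modified_unet" else build_modified_resunet
        in_channels = int(data["in_channels"]) if "in_channels" in data else 1
        model = builder(config, in_channels=in_channels)
        if "value_channels" in data:
            model.value_channels = int(data["value_channels"])
        lo, hi = data["norm"]
        model.set_normalization(float(lo), float(hi))
        for i, p in enumerate(model.params()):
            value = data[f"param_{i}"]
            if value.shape != p.value.shape:
                raise ValueError(f"weight {i} shape mismatch: {value.shape} vs {p.value.shape}")
            p.value = value.astype(p.value.dtype)
            p.grad = np.zeros_like(p.value)
    return model
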