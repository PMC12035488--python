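"""Four-fold super-resolution network for metabolite maps.

The model maps a 2-channel 32x32 input (low-resolution metabolite map
concatenated with a low-resolution FLAIR slice) to a 1-channel 128x128
metabolite map.  Architecture: a shallow 3x3 convolution, a body of
``n_pairs`` (HFAB -> GDFN) block pairs with two long skip connections from
the shallow features (one to the body midpoint, one to the body end), and a
sub-pixel upsampling head (two conv + pixel-shuffle x2 stages).

Blocks
------
HFAB (high-frequency attention block)
    A residual block whose attention branch — BatchNorm, 3x3 channel-reducing
    convolution, an ERB, a 3x3 channel-restoring convolution, BatchNorm,
    sigmoid — produces a per-position gate in [0, 1] that rescales features
    toward edges and other high-frequency content:
    ``out = x * gate + x``.
ERB (enhanced residual block)
    1x1 channel expansion, 3x3 convolution (ReLU), 1x1 contraction, residual.
GDFN (gated feed-forward block)
    Two parallel 1x1-projection + 3x3-depthwise branches; the first is passed
    through a GELU and gates the second by element-wise product before a 1x1
    projection back and a residual add.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for training convenience)
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    GELU,
    Layer,
    PixelShuffle,
    ReLU,
    Sequential,
    Sigmoid,
)

#: Channel width whose default parameter count lands on the ~650k budget.
DEFAULT_BASE_CHANNELS = 48


@dataclass
class SRConfig:
    """Hyper-parameters of the super-resolution model."""

    n_pairs: int = 8
    base_channels: int = DEFAULT_BASE_CHANNELS
    upscale_factor: int = 4
    in_channels: int = 2
    out_channels: int = 1
    erb_expansion: int = 2
    gdfn_expansion: int = 2
    attn_reduction: int = 2
    # sigmoid bounds the output to (0, 1), the codomain of normalized maps,
    # and saturates exactly where they are zero (background); a linear head
    # with clipping at evaluation is available but leaves background ripple
    output_activation: str = "sigmoid"  # or "linear"
    seed: int = 0

    def __post_init__(self):
        if self.output_activation not in ("linear", "sigmoid"):
            raise ValueError("output_activation must be 'linear' or 'sigmoid'")
        if self.upscale_factor != 4:
            raise ValueError("upscale_factor is fixed at 4")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.base_channels % self.attn_reduction != 0:
            raise ValueError("base_channels must be divisible by attn_reduction")


class ERB(Layer):
    """Enhanced residual block: 1x1 expand -> 3x3 (ReLU) -> 1x1 contract + skip."""

    def __init__(self, channels: int, expansion: int, rng, dtype=np.float32):
        mid = channels * expansion
        self.expand = Conv2d(channels, mid, 1, rng, dtype)
        self.conv = Conv2d(mid, mid, 3, rng, dtype)
        self.act = ReLU()
        self.contract = Conv2d(mid, channels, 1, rng, dtype)
        self.inner = Sequential(self.expand, self.conv, self.act, self.contract)

    def parameters(self):
        return self.inner.parameters()

    def forward(self, x, train=False):
        return x + self.inner.forward(x, train=train)

    def backward(self, grad):
        return grad + self.inner.backward(grad)


class HFAB(Layer):
    """High-frequency attention block: sigmoid-gated residual rescaling."""

    def __init__(self, channels: int, reduction: int, erb_expansion: int, rng,
                 dtype=np.float32):
        mid = channels // reduction
        # small init on the restoring conv and a negative gate bias keep the
        # residual body near-identity at initialization (activations would
        # otherwise grow multiplicatively across the stacked pairs)
        self.branch = Sequential(
            BatchNorm2d(channels, dtype=dtype),
            Conv2d(channels, mid, 3, rng, dtype),
            ERB(mid, erb_expansion, rng, dtype),
            Conv2d(mid, channels, 3, rng, dtype, init_scale=0.1),
            BatchNorm2d(channels, dtype=dtype, beta_init=-2.0),
            Sigmoid(),
        )
        #: gate tensor of the most recent forward pass (instrumentation hook)
        self.last_gate: np.ndarray | None = None
        self._x: np.ndarray | None = None

    def parameters(self):
        return self.branch.parameters()

    def forward(self, x, train=False):
        gate = self.branch.forward(x, train=train)
        self.last_gate = gate
        self._x = x
        return x * gate + x

    def backward(self, grad):
        gate, x = self.last_gate, self._x
        gx_branch = self.branch.backward(grad * x)
        return grad * (1.0 + gate) + gx_branch


class GDFN(Layer):
    """Gated depthwise-conv feed-forward block."""

    def __init__(self, channels: int, expansion: int, rng, dtype=np.float32):
        mid = channels * expansion
        self.proj_gate = Conv2d(channels, mid, 1, rng, dtype)
        self.dw_gate = DepthwiseConv2d(mid, 3, rng, dtype)
        self.act = GELU()
        self.proj_val = Conv2d(channels, mid, 1, rng, dtype)
        self.dw_val = DepthwiseConv2d(mid, 3, rng, dtype)
        self.proj_out = Conv2d(mid, channels, 1, rng, dtype, init_scale=0.1)

    def parameters(self):
        return (self.proj_gate.parameters() + self.dw_gate.parameters()
                + self.proj_val.parameters() + self.dw_val.parameters()
                + self.proj_out.parameters())

    def forward(self, x, train=False):
        g = self.act.forward(self.dw_gate.forward(self.proj_gate.forward(x, train), train))
        v = self.dw_val.forward(self.proj_val.forward(x, train), train)
        self._g, self._v = g, v
        return x + self.proj_out.forward(g * v, train)

    def backward(self, grad):
        gh = self.proj_out.backward(grad)
        gg = self.act.backward(gh * self._v)
        gv = gh * self._g
        gx = self.proj_gate.backward(self.dw_gate.backward(gg))
        gx = gx + self.proj_val.backward(self.dw_val.backward(gv))
        return grad + gx


def upsample_head(channels: int, out_channels: int, factor: int, rng,
                  dtype=np.float32, output_activation: str = "linear") -> Sequential:
    """Sub-pixel upsampling head: (conv x4 channels -> shuffle x2) stages.

    ``factor`` must be a power of two; each stage doubles the spatial size.
    The output is linear by default; a sigmoid head bounds it to (0, 1) and
    saturates cleanly on the zero background of normalized maps.
    """
    if factor < 1 or factor & (factor - 1) != 0:
        raise ValueError("upscale factor must be a power of two")
    layers: list[Layer] = []
    f = factor
    while f > 1:
        layers += [Conv2d(channels, channels * 4, 3, rng, dtype), PixelShuffle(2), ReLU()]
        f //= 2
    layers.append(Conv2d(channels, out_channels, 3, rng, dtype))
    if output_activation == "sigmoid":
        layers.append(Sigmoid())
    return Sequential(*layers)


class SRNet(Layer):
    """The full super-resolution model (see module docstring)."""

    def __init__(self, config: SRConfig, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.shallow = Conv2d(config.in_channels, c, 3, rng, dtype)
        self.pairs: list[tuple[HFAB, GDFN]] = []
        for _ in range(config.n_pairs):
            self.pairs.append((
                HFAB(c, config.attn_reduction, config.erb_expansion, rng, dtype),
                GDFN(c, config.gdfn_expansion, rng, dtype),
            ))
        # long skips: shallow features re-enter after pair `mid` and after the body
        self.mid_index = config.n_pairs // 2 - 1 if config.n_pairs > 1 else None
        self.head = upsample_head(c, config.out_channels, config.upscale_factor,
                                  rng, dtype, config.output_activation)

    # -- plumbing ---------------------------------------------------------
    def parameters(self):
        params = self.shallow.parameters()
        for hfab, gdfn in self.pairs:
            params += hfab.parameters() + gdfn.parameters()
        return params + self.head.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x, train=False):
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (B, {self.config.in_channels}, H, W) input, got {x.shape}")
        # engine layout is channel-first (C, B, H, W); transpose at the boundary
        xc = np.ascontiguousarray(x.transpose(1, 0, 2, 3))
        s = self.shallow.forward(xc, train=train)
        h = s
        for i, (hfab, gdfn) in enumerate(self.pairs):
            h = gdfn.forward(hfab.forward(h, train=train), train=train)
            if i == self.mid_index:
                h = h + s
        h = h + s
        y = self.head.forward(h, train=train)
        return np.ascontiguousarray(y.transpose(1, 0, 2, 3))

    def backward(self, grad):
        g = self.head.backward(np.ascontiguousarray(grad.transpose(1, 0, 2, 3)))
        gs = g.copy()  # final long skip into the shallow features
        for i in reversed(range(len(self.pairs))):
            if i == self.mid_index:
                # the midpoint addition happened right after pair i's forward,
                # so its skip branch collects the gradient before pair i
                gs += g
            hfab, gdfn = self.pairs[i]
            g = hfab.backward(gdfn.backward(g))
        gx = self.shallow.backward(g + gs)
        return gx.transpose(1, 0, 2, 3)

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict:
        state = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        j = 0
        for layer in self._bn_layers():
            state[f"bn{j}_mean"] = layer.running_mean
            state[f"bn{j}_var"] = layer.running_var
            j += 1
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]
        for j, layer in enumerate(self._bn_layers()):
            layer.running_mean[...] = state[f"bn{j}_mean"]
            layer.running_var[...] = state[f"bn{j}_var"]

    def _bn_layers(self):
        for hfab, _ in self.pairs:
            for layer in hfab.branch.layers:
                if isinstance(layer, BatchNorm2d):
                    yield layer

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict(),
                 _config=np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path: str | Path) -> "SRNet":
        data = np.load(Path(path))
        config = SRConfig(**json.loads(bytes(data["_config"]).decode()))
        model = cls(config)
        model.load_state_dict({k: data[k] for k in data.files if k != "_config"})
        return model

    def summary(self) -> str:
        lines = [f"SRNet(n_pairs={self.config.n_pairs}, "
                 f"base_channels={self.config.base_channels})"]
        lines.append(f"  shallow: {sum(p.value.size for p in self.shallow.parameters())}")
        for i, (hfab, gdfn) in enumerate(self.pairs):
            n_h = sum(p.value.size for p in hfab.parameters())
            n_g = sum(p.value.size for p in gdfn.parameters())
            lines.append(f"  pair {i}: HFAB {n_h} + GDFN {n_g}")
        lines.append(f"  head: {sum(p.value.size for p in self.head.parameters())}")
        lines.append(f"  total trainable parameters: {self.n_parameters()}")
        return "\n".join(lines)


def build_model(config: SRConfig | None = None) -> SRNet:
    """Construct a seeded model from a configuration."""
    return SRNet(config or SRConfig())


def upscale(model: SRNet, lr_input: np.ndarray) -> np.ndarray:
    """Run inference on one 2-channel LR input; output clipped to [0, 1].

    Accepts (2, H, W) or (B, 2, H, W); returns (H*4, W*4) or (B, 1, H*4, W*4).
    """
    single = lr_input.ndim == 3
    x = lr_input[None] if single else lr_input
    y = model.forward(x.astype(np.float32), train=False)
    y = np.clip(y, 0.0, 1.0)
    return y[0, 0] if single else y
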