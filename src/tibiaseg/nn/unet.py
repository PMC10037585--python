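"""2D attention U-Net for coronal tibia slice segmentation.

Four encoder blocks (3x3 conv - batch norm - ReLU, twice; 2x2 max-pool
between stages, filters doubling from ``base_filters``), a bottleneck, and
four decoder blocks (x2 bilinear upsampling, filters halving), with one
attention gate per skip connection: the skip feature ``(N, F/2, 2H, 2W)`` is
gated by the coarser decoder feature ``(N, F, H, W)`` through 1x1
convolutions, ReLU, a sigmoid, and x2 bilinear upsampling of the resulting
coefficient map ``(N, 1, 2H, 2W)``, which multiplies the skip.  The head is a
1x1 convolution to one channel followed by a sigmoid, matching binary
cross-entropy training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autograd import Parameter, Tensor, no_grad

__all__ = [
    "ModelConfig",
    "AttentionGate",
    "AttentionUNet",
    "attention_gate",
    "count_stages",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    depth: int = 4
    base_filters: int = 16
    bilinear_upsampling: bool = True

    def __post_init__(self) -> None:
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


class Module:
    """Tiny module base: tracks child modules and parameters in order."""

    def __init__(self):
        self._params: list[Parameter] = []
        self._modules: list[Module] = []
        self.training = True

    def add_param(self, arr) -> Parameter:
        p = Parameter(arr)
        self._params.append(p)
        return p

    def add_module(self, m: "Module") -> "Module":
        self._modules.append(m)
        return m

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def train(self) -> None:
        self.training = True
        for m in self._modules:
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._modules:
            m.eval()

    def buffers(self) -> list[np.ndarray]:
        out = getattr(self, "_buffers", [])[:]
        for m in self._modules:
            out.extend(m.buffers())
        return out


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))  # He initialisation
        self.weight = self.add_param(
            (rng.standard_normal((cout, cin, k, k)) * std).astype(dtype)
        )
        self.bias = self.add_param(np.zeros(cout, dtype=dtype))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c, dtype=np.float32):
        super().__init__()
        self.gamma = self.add_param(np.ones(c, dtype=dtype))
        self.beta = self.add_param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._buffers = [self.running_mean, self.running_var]
        self.momentum = 0.1

    def __call__(self, x: Tensor) -> Tensor:
        return x.batchnorm2d(
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
        )


class ConvBlock(Module):
    """(3x3 conv, pad 1 -> batch norm -> ReLU) twice."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        super().__init__()
        self.c1 = self.add_module(Conv2d(cin, cout, 3, pad=1, rng=rng, dtype=dtype))
        self.b1 = self.add_module(BatchNorm2d(cout, dtype=dtype))
        self.c2 = self.add_module(Conv2d(cout, cout, 3, pad=1, rng=rng, dtype=dtype))
        self.b2 = self.add_module(BatchNorm2d(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return self.b2(self.c2(self.b1(self.c1(x)).relu())).relu()


class AttentionGate(Module):
    """Gate a skip connection by a coarser decoder ("gating") feature.

    ``filters`` is F, the gating channel count; the skip carries F/2 channels
    at twice the spatial size.
    """

    def __init__(self, filters: int, rng, dtype=np.float32):
        super().__init__()
        if filters % 2:
            raise ValueError("attention gate filter count must be even")
        self.filters = filters
        self.w_x = self.add_module(
            Conv2d(filters // 2, filters, 1, stride=2, rng=rng, dtype=dtype)
        )
        self.w_g = self.add_module(Conv2d(filters, filters, 1, rng=rng, dtype=dtype))
        self.psi = self.add_module(Conv2d(filters, 1, 1, rng=rng, dtype=dtype))

    def __call__(self, skip: Tensor, gating: Tensor) -> tuple[Tensor, Tensor]:
        n, cs, hs, ws = skip.shape
        ng, cg, hg, wg = gating.shape
        if (
            n != ng
            or cs != self.filters // 2
            or cg != self.filters
            or hs != 2 * hg
            or ws != 2 * wg
        ):
            raise ValueError(
                f"attention gate expects skip (N,{self.filters // 2},2H,2W) and "
                f"gating (N,{self.filters},H,W); got skip {skip.shape} and "
                f"gating {gating.shape}"
            )
        a = (self.w_x(skip) + self.w_g(gating)).relu()
        alpha = self.psi(a).sigmoid().upsample_bilinear2x()
        return skip * alpha, alpha


def attention_gate(
    input_signal, gating_signal, gate: AttentionGate
) -> tuple[np.ndarray, np.ndarray]:
    """Functional attention gate on plain arrays: returns (gated, alpha)."""
    out, alpha = gate(Tensor(np.asarray(input_signal)), Tensor(np.asarray(gating_signal)))
    return out.data, alpha.data


class _UpBlock(Module):
    """x2 bilinear upsample + 3x3 conv halving the channel count."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        super().__init__()
        self.conv = self.add_module(Conv2d(cin, cout, 3, pad=1, rng=rng, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x.upsample_bilinear2x())


class AttentionUNet(Module):
    """The full segmentation network (see module docstring)."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        if not config.bilinear_upsampling:
            raise NotImplementedError("only bilinear upsampling is implemented")
        self.config = config
        rng = np.random.default_rng(seed)
        b, d = config.base_filters, config.depth
        enc_ch = [b * 2**i for i in range(d)]

        self.encoders = [
            self.add_module(
                ConvBlock(config.in_channels if i == 0 else enc_ch[i - 1],
                          enc_ch[i], rng, dtype)
            )
            for i in range(d)
        ]
        self.bottleneck = self.add_module(
            ConvBlock(enc_ch[-1], enc_ch[-1] * 2, rng, dtype)
        )
        self.gates, self.ups, self.decoders = [], [], []
        cur = enc_ch[-1] * 2
        for i in reversed(range(d)):
            self.gates.append(self.add_module(AttentionGate(cur, rng, dtype)))
            self.ups.append(self.add_module(_UpBlock(cur, enc_ch[i], rng, dtype)))
            self.decoders.append(
                self.add_module(ConvBlock(2 * enc_ch[i], enc_ch[i], rng, dtype))
            )
            cur = enc_ch[i]
        self.head = self.add_module(Conv2d(enc_ch[0], 1, 1, rng=rng, dtype=dtype))
        #: diagnostic switch: bypass the gates (alpha = 1), giving a plain U-Net
        self.bypass_gates = False

    def _check_input(self, x) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected input (N,{self.config.in_channels},H,W), got {x.shape}"
            )
        div = 2**self.config.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial dims {x.shape[2]}x{x.shape[3]} must be divisible by {div}"
            )

    def forward_logits(self, x: Tensor) -> Tensor:
        self._check_input(x.data)
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = h.maxpool2x2()
        h = self.bottleneck(h)
        for gate, up, dec, skip in zip(
            self.gates, self.ups, self.decoders, reversed(skips)
        ):
            gated = skip if self.bypass_gates else gate(skip, h)[0]
            h = dec(up(h).concat(gated))
        return self.head(h)

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Probability maps in [0, 1] for a batch ``(N, 1, H, W)``.

        Runs in the module's current mode; call :meth:`eval` first for
        deterministic inference with running batch-norm statistics.
        """
        with no_grad():
            return self.forward_logits(Tensor(np.asarray(batch))).sigmoid().data

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        return self.forward(batch)


def recalibrate_batchnorm(model: AttentionUNet, batch: np.ndarray) -> None:
    """Replace all running batch-norm statistics with the exact statistics of
    one calibration batch.

    During training the exponentially averaged statistics lag behind the
    rapidly moving weights; recalibrating on a representative slice sample
    makes evaluation-mode inference consistent with the current weights.
    """
    def _set_momentum(m: Module, value: float) -> None:
        if isinstance(m, BatchNorm2d):
            m.momentum = value
        for child in m._modules:
            _set_momentum(child, value)

    was_training = model.training
    _set_momentum(model, 1.0)
    model.train()
    with no_grad():
        model.forward_logits(Tensor(np.asarray(batch)))
    _set_momentum(model, 0.1)
    if not was_training:
        model.eval()


def count_stages(model: AttentionUNet) -> tuple[int, int, tuple[int, ...]]:
    """(encoder stages, decoder stages, encoder filter counts per stage)."""
    b, d = model.config.base_filters, model.config.depth
    return d, d, tuple(b * 2**i for i in range(d))


def save_checkpoint(model: AttentionUNet, path: str | Path) -> None:
    """Serialise parameters, batch-norm statistics, and config to .npz."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.buffers())})
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> AttentionUNet:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = AttentionUNet(cfg)
        for i, p in enumerate(model.parameters()):
            p.data = data[f"p{i}"].copy()
        for i, b in enumerate(model.buffers()):
            b[...] = data[f"b{i}"]
    model.eval()
    return model
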