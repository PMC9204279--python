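"""Layer objects over the autodiff core: parameter containers with seeded init."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float32)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean[:] = state[f"__bn{i}.running_mean"]
                m.running_var[:] = state[f"__bn{i}.running_var"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2  # "same" padding for odd kernels
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(he_uniform(rng, (out_ch, fan_in), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    """3x3, stride-2 transposed convolution that exactly doubles H and W."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * 9
        self.weight = Tensor(he_uniform(rng, (in_ch, out_ch * 9), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.data.shape
        return ad.conv_transpose2d(x, self.weight, self.bias, (2 * H, 2 * W))


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Tensor(np.ones(ch, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, np.float32), requires_grad=True)
        self.running_mean = np.zeros(ch, np.float32)
        self.running_var = np.ones(ch, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm_2d(x, self.gamma, self.beta, self.running_mean,
                                self.running_var, self.momentum, self.eps,
                                self.training)


class Dense(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(he_uniform(rng, (in_f, out_f), in_f), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Dropout(Module):
    """Inverted dropout; the mask stream is owned by the layer for determinism."""

    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.rate, self.rng, self.training)
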