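"""Module system: parameter containers with train/eval modes.

Mirrors the torch ``nn.Module`` idiom (recursive parameter discovery,
``train()``/``eval()`` switches, state-dict export) so the network code
upstairs reads like any other conv-net definition.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Tensor


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        # underscore attributes are scratch state, never parameters
        if name.startswith("_"):
            object.__setattr__(self, name, value)
            return
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, m in self._modules.items():
            out.update(m.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        out.update({"buffer:" + k: v.copy() for k, v in self.buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        bufs = self.buffers()
        for k, v in state.items():
            if k.startswith("buffer:"):
                bufs[k[len("buffer:"):]][...] = v
            else:
                params[k].data[...] = np.asarray(v, dtype=np.float32)
        return self

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = _he_init(rng, (cout, cin, kernel, kernel), cin * kernel * kernel)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        super().__init__()
        self.weight = _he_init(rng, (cin, cout), cin)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Per-channel normalization; batch stats in train, running stats in eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def buffers(self, prefix: str = ""):
        return {prefix + "running_mean": self.running_mean,
                prefix + "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / c
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            sd = Tensor(1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps))
            xhat = (x - mu) * sd
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ConvBNReLU(Module):
    """The g(.|C_in, C_out, k, p) unit: conv -> batch-norm -> ReLU."""

    def __init__(self, cin: int, cout: int, kernel: int = 1, padding: int = 0,
                 stride: int = 1, *, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, padding, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()
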