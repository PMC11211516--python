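"""Layer abstractions and the Adam optimizer on top of the autodiff core.

Initialization draws from a caller-supplied ``numpy.random.Generator`` so
that every model build is reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "PReLU",
    "Dropout",
    "Adam",
]


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    #: names of non-trainable arrays that belong in checkpoints
    buffer_names: tuple[str, ...] = ()

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            for p in _collect(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for obj in self.__dict__.values():
            mods.extend(_collect_modules(obj))
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # checkpoint support -----------------------------------------------------

    def _buffers(self) -> list[tuple["Module", str]]:
        return [(m, name) for m in self.modules() for name in m.buffer_names]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        for i, (m, name) in enumerate(self._buffers()):
            state[f"b{i}"] = np.asarray(getattr(m, name)).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        buffers = self._buffers()
        if len(state) != len(params) + len(buffers):
            raise ValueError(
                f"checkpoint holds {len(state)} arrays, model has "
                f"{len(params)} parameters + {len(buffers)} buffers"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(np.float64)
        for i, (m, name) in enumerate(buffers):
            setattr(m, name, np.asarray(state[f"b{i}"], dtype=np.float64))


def _collect(obj) -> list[Tensor]:
    if isinstance(obj, Tensor) and obj.requires_grad:
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out = []
        for o in obj:
            out.extend(_collect(o))
        return out
    return []


def _collect_modules(obj) -> list[Module]:
    if isinstance(obj, Module):
        return obj.modules()
    if isinstance(obj, (list, tuple)):
        out = []
        for o in obj:
            out.extend(_collect_modules(o))
        return out
    return []


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    """Kaiming-uniform initialization, the convention for rectifier nets."""
    bound = np.sqrt(1.0 / max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (in_dim, out_dim), in_dim)
        self.bias = _param(rng, (out_dim,), in_dim) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
    ):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = _param(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.bias = _param(rng, (out_ch,), fan_in) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W); running stats used at eval."""

    buffer_names = ("running_mean", "running_var")

    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch), requires_grad=True)
        self.running_mean = np.zeros(num_ch)
        self.running_var = np.ones(num_ch)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class PReLU(Module):
    """Rectifier with a learned per-channel negative slope (init 0.25)."""

    def __init__(self, num_ch: int, init: float = 0.25):
        super().__init__()
        self.slope = Tensor(np.full(num_ch, init), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        shape = [1] * x.ndim
        if x.ndim >= 2:
            shape[1] = self.slope.shape[0]  # (N, C, ...) layout
        else:
            shape[0] = self.slope.shape[0]
        return x.relu() + self.slope.reshape(*shape) * x.clip_min0()


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Adam:
    """Adaptive-moment SGD (the conventional default for these models)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
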