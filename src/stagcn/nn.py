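"""Neural-network building blocks on top of :mod:`stagcn.autodiff`.

Feature maps use the layout ``(batch, channel, frame, node)`` throughout.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, einsum

__all__ = ["Module", "Conv1x1", "Linear", "BatchNorm", "Dropout", "SGD"]


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Tiny module base: parameter discovery by attribute walk, train/eval flag."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v
                        yield from v.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{path}.{i}.")
                    elif isinstance(v, Tensor) and v.requires_grad:
                        yield f"{path}.{i}", v

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ----------------------------------------------------------- state dict
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(path + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_buffers(f"{path}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield path, value

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=np.float64).reshape(params[name].shape)
            elif name in bufs:
                bufs[name][...] = np.asarray(arr, dtype=np.float64).reshape(bufs[name].shape)
            else:
                raise KeyError(f"unexpected checkpoint entry {name!r}")


class Conv1x1(Module):
    """Pointwise (per frame, per node) channel-mixing convolution."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(
            he_uniform(rng, (in_channels, out_channels), in_channels), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = einsum("bcfn,co->bofn", x, self.weight)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            he_uniform(rng, (in_features, out_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return einsum("bc,co->bo", x, self.weight) + self.bias.reshape(1, -1)


class BatchNorm(Module):
    """Per-channel batch normalization over (batch, frame, node).

    Expects ``(B, C, F, N)`` input; in training mode uses batch statistics
    and updates running estimates, in eval mode uses the running estimates.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode. Draws masks from a shared RNG."""

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


class SGD:
    """Plain stochastic gradient descent (momentum and weight decay off by default)."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                v *= self.momentum
                v += g
                g = v
            p.data = p.data - self.lr * g

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
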