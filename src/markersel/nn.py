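"""Feed-forward building blocks: linear layers, batch normalization, Adam.

Layers follow the conventions used throughout the package's architectures:
hidden layers are ``Linear -> BatchNorm -> LeakyReLU`` with Kaiming-normal
weight initialization, batch-norm scale initialized to one and biases to
zero.  ``Module.state_arrays`` gives a flat name -> array view of every
parameter and running statistic, which is what the checkpoint format
serializes.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, constant, leaky_relu

__all__ = ["Module", "Linear", "BatchNorm1d", "HiddenBlock", "Adam", "kaiming_normal"]


def kaiming_normal(rng: np.random.Generator, fan_in: int, fan_out: int,
                   negative_slope: float = 0.01) -> np.ndarray:
    """Kaiming-normal weight draw with the leaky-ReLU gain."""
    gain = np.sqrt(2.0 / (1.0 + negative_slope ** 2))
    std = gain / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=(fan_in, fan_out))


class Module:
    """Base class: parameter discovery, train/eval switching, state export."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
                yield from value.submodules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.submodules()

    def train(self) -> None:
        for m in self.submodules():
            if isinstance(m, BatchNorm1d):
                m.training = True

    def eval(self) -> None:
        for m in self.submodules():
            if isinstance(m, BatchNorm1d):
                m.training = False

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat dict of every parameter and buffer, keyed by attribute path."""
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data
            elif isinstance(value, np.ndarray):
                state[key] = value
            elif isinstance(value, Module):
                state.update(value.state_arrays(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_arrays(prefix=f"{key}.{i}."))
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                value.data = np.array(state[key], dtype=np.float64)
            elif isinstance(value, np.ndarray):
                setattr(self, name, np.array(state[key], dtype=np.float64))
            elif isinstance(value, Module):
                value.load_state_arrays(state, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, prefix=f"{key}.{i}.")


class Linear(Module):
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        self.weight = Tensor(kaiming_normal(rng, fan_in, fan_out, negative_slope),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(fan_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.scale = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            n = x.data.shape[0]
            unbiased = var.data[0] * (n / max(n - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data[0])
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            norm = centered / (var + self.eps).sqrt()
        else:
            mu = constant(self.running_mean)
            sd = constant(np.sqrt(self.running_var + self.eps))
            norm = (x - mu) / sd
        return norm * self.scale + self.shift


class HiddenBlock(Module):
    """Linear -> BatchNorm -> LeakyReLU, the hidden-layer unit used everywhere."""

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        self.linear = Linear(fan_in, fan_out, rng, negative_slope)
        self.norm = BatchNorm1d(fan_out)
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor) -> Tensor:
        return leaky_relu(self.norm(self.linear(x)), self.negative_slope)


class Adam:
    """Adaptive-moment gradient descent with the usual default moments."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
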