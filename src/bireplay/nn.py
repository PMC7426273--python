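"""Neural-network building blocks on top of the package's tensor engine.

Layers follow the usual conventions: inputs are batched along the first
axis, images are channel-first (NCHW), hidden activations are rectified
linear and the output layer of a classifier is linear (softmax lives in the
loss / inference layer).
"""

from __future__ import annotations

import copy

import numpy as np

from ._autodiff import Tensor, conv2d, conv_transpose2d

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "MLP",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data, name: str | None = None):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Base class: tracks sub-modules and parameters by attribute."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).items().__iter__():
            _, v = value
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for key, v in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
                    elif isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{name}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()

    def eval(self) -> None:
        self.training = False
        for v in vars(self).values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()

    def copy(self) -> "Module":
        """Deep copy with detached gradients (frozen snapshot)."""
        dup = copy.deepcopy(self)
        for p in dup.parameters():
            p.grad = None
        return dup

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.data.shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)

    def output_size(self, h: int) -> int:
        return (h + 2 * self.padding - self.weight.shape[2]) // self.stride + 1


class ConvTranspose2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 4,
        stride: int = 2,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization; uses running statistics once in eval mode."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(-1)
            )
            inv = (var + self.eps) ** -0.5
            xhat = centered * inv
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            inv = Tensor(1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, -1, 1, 1)
            xhat = (x - mean) * inv
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class MLP(Module):
    """Stack of fully connected layers with ReLU hidden activations.

    ``__call__`` accepts optional per-sample multiplicative masks on each
    hidden layer's activations (used for context gating); masks are numpy
    arrays of shape (batch, width) or (width,).
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator | None = None,
                 final_activation: str | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.layers = [Linear(a, b, rng=rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.sizes = list(sizes)
        self.final_activation = final_activation

    @property
    def hidden_widths(self) -> list[int]:
        return self.sizes[1:-1]

    def __call__(self, x: Tensor, masks: list[np.ndarray] | None = None,
                 return_hidden: bool = False):
        h = x
        hiddens = []
        n_hidden = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < n_hidden:
                h = h.relu()
                if masks is not None and masks[i] is not None:
                    h = h * Tensor(np.asarray(masks[i], dtype=np.float64))
                hiddens.append(h)
        if self.final_activation == "relu":
            h = h.relu()
        elif self.final_activation == "sigmoid":
            h = h.sigmoid()
        if return_hidden:
            return h, hiddens
        return h


class Adam:
    """ADAM optimizer (Kingma & Ba) over a list of parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
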