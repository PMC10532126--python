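"""Neural-network layers and optimisers built on the `_tensor` autograd engine.

Minimal but conventional: ``Module`` with recursive parameter discovery and
a train/eval switch, ``Conv3d`` (fan-out He initialisation), ``BatchNorm3d``
(normalisation expressed through differentiable primitives, running
statistics for inference), ``Linear``, ``Dropout`` (inverted scaling) and
``SGD`` / ``Adam`` optimisers with an externally driven learning rate.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, batch_norm, conv3d

__all__ = [
    "Module",
    "ModuleList",
    "Conv3d",
    "BatchNorm3d",
    "Linear",
    "ReLU",
    "Dropout",
    "Sequential",
    "SGD",
    "Adam",
]


class Module:
    """Base class: parameter discovery, mode switching, state (de)serialisation."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args):
        return self.forward(*args)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- flat state dict (parameters + buffers), for checkpointing ---------

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data
            elif isinstance(value, np.ndarray):
                state[key] = value
            elif isinstance(value, Module):
                state.update(value.state_arrays(f"{key}."))
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                if value.data.shape != state[key].shape:
                    raise ValueError(
                        f"state mismatch for {key}: {value.data.shape} vs {state[key].shape}"
                    )
                value.data = state[key].astype(value.data.dtype)
            elif isinstance(value, np.ndarray):
                setattr(self, name, state[key])
            elif isinstance(value, Module):
                value.load_state_arrays(state, f"{key}.")


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._modules = list(modules)
        for i, m in enumerate(self._modules):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._modules)

    def __getitem__(self, i):
        return self._modules[i]

    def __len__(self):
        return len(self._modules)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._seq = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x

    def __len__(self):
        return len(self._seq)

    def __getitem__(self, i):
        return self._seq[i]


class Conv3d(Module):
    """3-D convolution over (N, C, T, H, W); He fan-out initialisation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        stride: tuple[int, int, int] = (1, 1, 1),
        pad: tuple[int, int, int] | str = "same",
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kt, kh, kw = kernel
        if pad == "same":
            pad = ((kt - 1) // 2, (kh - 1) // 2, (kw - 1) // 2)
        self.stride = tuple(stride)
        self.pad = tuple(pad)
        fan_out = out_channels * kt * kh * kw
        scale = np.sqrt(2.0 / fan_out)
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_channels, in_channels, kt, kh, kw)).astype(
                np.float32
            ),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )

    def parameters(self):
        params = [self.weight]
        if self.bias is not None:
            params.append(self.bias)
        return params

    def state_arrays(self, prefix: str = ""):
        state = {f"{prefix}weight": self.weight.data}
        if self.bias is not None:
            state[f"{prefix}bias"] = self.bias.data
        return state

    def load_state_arrays(self, state, prefix: str = ""):
        self.weight.data = state[f"{prefix}weight"].astype(np.float32)
        if self.bias is not None:
            self.bias.data = state[f"{prefix}bias"].astype(np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm3d(Module):
    """Per-channel batch normalisation over (N, T, H, W) statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        shape = (1, channels, 1, 1, 1)
        self.gamma = Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(shape, dtype=np.float32)
        self.running_var = np.ones(shape, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batch_norm(x, self.gamma, self.beta, eps=self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.astype(np.float32)
            self.running_var = (1 - m) * self.running_var + m * var.astype(np.float32)
            return out
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        return x * Tensor(scale) + Tensor(shift)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, (in_features, out_features)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; identity in eval mode, deterministic under its rng."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Optimisers
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    """Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
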