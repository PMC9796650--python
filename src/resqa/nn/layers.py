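"""Neural-network layers and the Adam optimizer on top of the autodiff core.

Data layout is (L, channels) — residues along axis 0 — and every model is
one "batch", so batch normalisation standardises each channel over the
length axis during training and uses stored running statistics at
inference.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d_same

__all__ = ["Module", "Linear", "Conv1d", "BatchNorm1d", "Dropout",
           "LeakyReLU", "ResidualBlock", "MLP2", "Adam"]


class Module:
    """Base class: parameter collection, train/eval mode, state export."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus buffers, in traversal order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.parameters():
            p.data = np.asarray(next(it), dtype=float).reshape(p.data.shape)
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                m.running_mean = np.asarray(next(it), dtype=float).ravel()
                m.running_var = np.asarray(next(it), dtype=float).ravel()


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape)


class Linear(Module):
    """Fully connected layer; Glorot init keeps deep update stacks (the
    graph blocks concatenate wide inputs) from amplifying activations."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, n_in: int, n_out: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd (same padding)")
        self.kernel = kernel
        self.weight = Tensor(_he(rng, n_in * kernel,
                                 (n_in * kernel, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.weight, self.bias, self.kernel)


class BatchNorm1d(Module):
    """Channel normalisation over the length axis.

    A batch is one model, so inference also normalises with the input's own
    per-model statistics (running statistics are still tracked and saved in
    checkpoints for diagnostics); the per-model mode avoids the train/eval
    mismatch that running averages over models of different sizes would
    introduce.
    """

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean_axis0()                      # (1, C)
        xc = x - mu
        var = (xc * xc).mean_axis0()             # biased, (1, C)
        if self.training:
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        inv = (var + self.eps).pow(-0.5)
        return xc * inv * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a generator must be attached before training."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without rng")
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ResidualBlock(Module):
    """Two Conv1d-BatchNorm-Dropout-LeakyReLU layers with an identity skip:
    the block input is added to the second activation's output."""

    def __init__(self, channels: int, kernel: int, dropout: float,
                 slope: float, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(channels, channels, kernel, rng)
        self.bn1 = BatchNorm1d(channels)
        self.drop1 = Dropout(dropout)
        self.conv2 = Conv1d(channels, channels, kernel, rng)
        self.bn2 = BatchNorm1d(channels)
        self.drop2 = Dropout(dropout)
        self.act = LeakyReLU(slope)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.act(self.drop1(self.bn1(self.conv1(x))))
        h = self.act(self.drop2(self.bn2(self.conv2(h))))
        return x + h


class MLP2(Module):
    """Linear-ReLU-Linear update function, the phi of the graph blocks."""

    def __init__(self, n_in: int, hidden: int, n_out: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(n_in, hidden, rng)
        self.fc2 = Linear(hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class Adam:
    """Adam with optional global-norm gradient clipping (guards the deep
    update stacks against loss spikes from single hard models)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params
                                if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
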