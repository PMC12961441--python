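"""Network building blocks: Linear, PointBN, MLP, with a torch-like Module API."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    """Base class tracking parameters and submodules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> dict:
        """Flat dict of parameter name -> Tensor."""
        out = {}
        for k, v in self._params.items():
            out[k] = v
        for mk, m in self._modules.items():
            for k, v in m.parameters().items():
                out[f"{mk}.{k}"] = v
        return out

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def state_dict(self) -> dict:
        d = {k: p.data.copy() for k, p in self.parameters().items()}
        for k, b in self.buffers().items():
            d["buffer:" + k] = b.copy()
        return d

    def load_state_dict(self, d: dict) -> None:
        params = self.parameters()
        bufs = self.buffers()
        for k, v in d.items():
            if k.startswith("buffer:"):
                bufs[k[7:]][...] = v
            else:
                params[k].data[...] = v

    def buffers(self) -> dict:
        out = {}
        for mk, m in self._modules.items():
            for k, v in m.buffers().items():
                out[f"{mk}.{k}"] = v
        if isinstance(self, PointBN):
            out["running_mean"] = self.running_mean
            out["running_var"] = self.running_var
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(self.mods):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def __len__(self):
        return len(self.mods)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_dim, out_dim))
        else:
            bound = np.sqrt(6.0 / (in_dim + out_dim))  # Glorot uniform
            w = rng.uniform(-bound, bound, size=(in_dim, out_dim))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class PointBN(Module):
    """Batch normalization over the point dimension (axis 0 .. ndim-2).

    Statistics are taken over all points of the cloud(s) in the batch per
    channel, which keeps the operation permutation-invariant.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xhat = xc * (var + self.eps) ** (-0.5)
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** (-0.5)
        return xhat * self.gamma + self.beta


class MLP(Module):
    """Linear stack with ReLU between layers (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 zero_init_last: bool = False, batch_norm: bool = False):
        super().__init__()
        layers = []
        for i in range(len(dims) - 1):
            last = i == len(dims) - 2
            layers.append(Linear(dims[i], dims[i + 1], rng, zero_init=zero_init_last and last))
            if not last:
                if batch_norm:
                    layers.append(PointBN(dims[i + 1]))
                layers.append("relu")
        self.layers = ModuleList([l for l in layers if isinstance(l, Module)])
        self._plan = layers

    def forward(self, x: Tensor) -> Tensor:
        for l in self._plan:
            x = x.relu() if l == "relu" else l(x)
        return x


class AdamW:
    """AdamW with decoupled weight decay (the optimizer used for training)."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.05):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


class MultiStepLR:
    """Decay the optimizer lr by `gamma` after each milestone epoch."""

    def __init__(self, optimizer: AdamW, milestones: list[int], gamma: float = 0.05):
        self.opt = optimizer
        self.base_lr = optimizer.lr
        self.milestones = sorted(milestones)
        self.gamma = gamma

    def lr_at(self, epoch: int) -> float:
        k = sum(1 for m in self.milestones if epoch > m)
        return self.base_lr * self.gamma ** k

    def set_epoch(self, epoch: int) -> None:
        self.opt.lr = self.lr_at(epoch)
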