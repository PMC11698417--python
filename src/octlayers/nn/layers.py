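"""Neural-network building blocks on top of the autograd tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

__all__ = ["Parameter", "Module", "ModuleList", "Conv2d", "BatchNorm2d", "Linear"]


class Parameter(Tensor):
    """A trainable tensor (leaf of the autograd graph)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container: parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data[...] = arr
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unknown parameter {name!r}")

    def named_buffers(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(f"{prefix}{name}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield f"{prefix}{name}", val

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._mods = list(mods)
        for i, m in enumerate(self._mods):
            setattr(self, f"_m{i}", m)

    def append(self, m):
        setattr(self, f"_m{len(self._mods)}", m)
        self._mods.append(m)

    def __iter__(self):
        return iter(self._mods)

    def __getitem__(self, i):
        return self._mods[i]

    def __len__(self):
        return len(self._mods)


class Conv2d(Module):
    """Stride-1 convolution with zero 'same' padding, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) with running statistics."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        # fused: one pass forward, closed-form backward
        c = x.shape[1]
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.reshape(c).astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.reshape(c).astype(np.float32))
        else:
            mu = self.running_mean.reshape(1, c, 1, 1).astype(x.data.dtype)
            var = self.running_var.reshape(1, c, 1, 1).astype(x.data.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        gamma, beta = self.gamma, self.beta
        out = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)
        nelem = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        batch_stats = self.training

        def backward(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            gxh = g * xhat
            if gamma.requires_grad:
                gamma._accum(gxh.sum(axis=axes))
            if not x.requires_grad:
                return
            gs = g * gamma.data.reshape(1, c, 1, 1)
            if batch_stats:
                t1 = gs.mean(axis=axes, keepdims=True)
                t2 = (gs * xhat).mean(axis=axes, keepdims=True)
                x._accum(inv * (gs - t1 - xhat * t2))
            else:
                x._accum(inv * gs)

        return Tensor._make(out, (x, gamma, beta), backward)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, (out_f, in_f)))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, in_f)
        return x @ self.weight.transpose(1, 0) + self.bias.reshape(1, -1)
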