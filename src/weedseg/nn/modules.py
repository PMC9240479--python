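"""Layer abstractions over the autograd engine.

Mirrors the familiar Module / Parameter idiom: a Module owns named
parameters and submodules, exposes ``parameters()`` / ``state_dict()``
and a train/eval switch that gates batch-norm statistics.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield prefix + k, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix=""):
        for k, b in self._buffers.items():
            yield prefix + k, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def train(self, mode=True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self):
        out = {("param:" + k): p.data.copy() for k, p in self.named_parameters()}
        out.update({("buffer:" + k): b.copy() for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data[...] = arr
            else:
                buffers[name][...] = arr

    def num_parameters(self):
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride, self.pad = stride, pad

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    """Kernel size == stride (the 2x2 stride-2 upsampling case)."""

    def __init__(self, in_ch, out_ch, kernel=2, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (in_ch, out_ch, kernel, kernel), in_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self.stride = kernel

    def forward(self, x):
        return ag.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self._buffers["running_mean"] = np.zeros(ch, dtype=np.float32)
        self._buffers["running_var"] = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return ag.batchnorm2d(x, self.gamma, self.beta,
                              self._buffers["running_mean"], self._buffers["running_var"],
                              self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_f, out_f, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32))

    def forward(self, x):
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = [f"m{i}" for i in range(len(mods))]

    def forward(self, x):
        for name in self._order:
            x = self._modules[name](x)
        return x

    def __iter__(self):
        return (self._modules[n] for n in self._order)


class Adam:
    """Adam with decoupled parameter list; lr is mutable between steps."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
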