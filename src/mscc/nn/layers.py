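"""Layer modules built on the autodiff tensors.

Modules own their parameters (:class:`~mscc.nn.tensor.Tensor` with
``requires_grad=True``) and expose ``parameters()`` recursively.  Weight
initialisation is Glorot-uniform driven by an explicit
``numpy.random.Generator`` so every build is reproducible.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state export."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + k, v) for k, v in self._buffers.items()]
        for name, m in self._modules.items():
            out.extend(m.named_buffers(prefix + name + "."))
        return out

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self):
        self.training = True
        for m in self._modules.values():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._modules.values():
            m.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({"buf:" + k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data[...] = state[k]
        for k, b in self.named_buffers():
            b[...] = state["buf:" + k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, rng, dtype=np.float32):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan = cin * kh * kw
        self.weight = _glorot(rng, (cout, cin, kh, kw), fan, cout * kh * kw, dtype)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """Fixed 2x2 kernel, stride 2 (doubles the spatial size)."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        super().__init__()
        self.weight = _glorot(rng, (cin, cout, 2, 2), cin * 4, cout * 4, dtype)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def forward(self, x):
        return T.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, dtype=np.float32, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._buffers["running_mean"] = self.running_mean
        self._buffers["running_var"] = self.running_var
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return T.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)


class Linear(Module):
    def __init__(self, din, dout, rng, dtype=np.float32):
        super().__init__()
        self.weight = _glorot(rng, (din, dout), din, dout, dtype)
        self.bias = Tensor(np.zeros(dout, dtype=dtype), requires_grad=True)

    def forward(self, x):
        return T.linear(x, self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class MaxPool2x2(Module):
    def forward(self, x):
        return T.maxpool2x2(x)


class Flatten(Module):
    def forward(self, x):
        return T.reshape(x, (x.shape[0], -1))


class ConvBNReLU(Module):
    """Convolution -> batch norm -> ReLU, the repeated unit of every block."""

    def __init__(self, cin, cout, kernel, rng, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, rng, dtype)
        self.bn = BatchNorm2d(cout, dtype)

    def forward(self, x):
        return T.relu(self.bn(self.conv(x)))
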