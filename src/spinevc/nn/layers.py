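"""Layer/module abstractions over the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "ConvBNRelu"]


class Module:
    """Minimal module base: recursive parameter collection, train/eval
    mode, and a flat numpy state dict for checkpointing."""

    def __init__(self):
        self.training = True

    # -- mode -------------------------------------------------------------
    def train(self) -> "Module":
        for m in self._submodules():
            m.train()
        self.training = True
        return self

    def eval(self) -> "Module":
        for m in self._submodules():
            m.eval()
        self.training = False
        return self

    # -- introspection ----------------------------------------------------
    def _submodules(self):
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params = [v for v in vars(self).values()
                  if isinstance(v, Tensor) and v.requires_grad]
        for m in self._submodules():
            params.extend(m.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- checkpointing ----------------------------------------------------
    def _named_arrays(self, prefix: str = ""):
        for k, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield prefix + k, v.data
            elif isinstance(v, np.ndarray):
                yield prefix + k, v
            elif isinstance(v, Module):
                yield from v._named_arrays(prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_arrays(f"{prefix}{k}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named_arrays()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        targets = dict(self._iter_slots())
        missing = set(targets) - set(state)
        if missing:
            raise ValueError(f"state dict missing keys: {sorted(missing)[:5]} ...")
        for k, holder in targets.items():
            obj, attr = holder
            src = np.asarray(state[k])
            cur = getattr(obj, attr)
            if isinstance(cur, Tensor):
                if cur.data.shape != src.shape:
                    raise ValueError(f"shape mismatch for {k}: {cur.data.shape} vs {src.shape}")
                cur.data = src.astype(cur.data.dtype)
            else:
                setattr(obj, attr, src.astype(cur.dtype))

    def _iter_slots(self, prefix: str = ""):
        for k, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield prefix + k, (self, k)
            elif isinstance(v, np.ndarray):
                yield prefix + k, (self, k)
            elif isinstance(v, Module):
                yield from v._iter_slots(prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._iter_slots(f"{prefix}{k}.{i}.")

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as f:
            self.load_state_dict(dict(f))


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        self.dilation = int(dilation)
        fan_in = cin * kernel * kernel
        self.weight = Tensor(_he_init(rng, (cout, cin, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        return ag.batchnorm2d(x, self.gamma, self.beta, mean, var,
                              training=self.training, eps=self.eps)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0, np.sqrt(1.0 / fin), (fout, fin)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(fout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class ConvBNRelu(Module):
    """conv 3x3 (stride 1, 'same') -> BN -> ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel: int = 3, dilation: int = 1):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, rng, dilation=dilation)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))
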