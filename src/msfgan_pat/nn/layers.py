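"""Neural-network building blocks used by the generator and discriminator."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "SNConv2d",
    "BatchNorm2d",
    "PReLU",
    "Dense",
    "power_iteration_sigma",
]


class Module:
    """Minimal module container: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self.training = True

    def param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for k, v in self.named_buffers().items():
            out["buffer:" + k] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        buffers = self.named_buffers()
        for k, v in state.items():
            if k.startswith("buffer:"):
                buffers[k[len("buffer:"):]][...] = v
            else:
                params[k].data = v.astype(np.float32).copy()

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, v in getattr(self, "_buffers", {}).items():
            out[prefix + k] = v
        for name, child in self._children():
            out.update(child.named_buffers(prefix + name + "."))
        return out

    def buffer(self, name: str, data: np.ndarray) -> np.ndarray:
        if not hasattr(self, "_buffers"):
            self._buffers: dict[str, np.ndarray] = {}
        arr = np.asarray(data, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = cin * k * k
        w = np.zeros((cout, cin, k, k)) if zero_init else _he_normal(
            rng, (cout, cin, k, k), fan_in)
        self.w = self.param("w", w)
        self.b = self.param("b", np.zeros(cout)) if bias else None

    def _weight(self) -> Tensor:
        return self.w

    def forward(self, x: Tensor) -> Tensor:
        # feature tensors are channel-leading: (C, N, H, W)
        y = ag.corr2d(x, self._weight(), stride=self.stride,
                      padding=self.padding)
        if self.b is not None:
            y = y + ag.reshape(self.b, (-1, 1, 1, 1))
        return y


def power_iteration_sigma(w: np.ndarray, n_iter: int = 1,
                          u: np.ndarray | None = None):
    """Estimate the largest singular value of a (reshaped-2D) weight.

    Returns (sigma, u, v); ``u`` may be passed back in to continue the
    iteration across calls, which is how spectral normalization tracks
    the leading singular pair during training.
    """
    W = w.reshape(w.shape[0], -1)
    if u is None:
        rng = np.random.default_rng(0)
        u = rng.normal(size=W.shape[0]).astype(w.dtype)
        u /= np.linalg.norm(u) + 1e-12
    v = None
    for _ in range(max(n_iter, 1)):
        v = W.T @ u
        v /= np.linalg.norm(v) + 1e-12
        u = W @ v
        nu = np.linalg.norm(u)
        if nu < 1e-20:          # zero weight: leave u, sigma = 0
            return 0.0, u, v
        u /= nu
    sigma = float(u @ W @ v)
    return sigma, u, v


class SNConv2d(Conv2d):
    """Convolution whose weight is divided by its largest singular value.

    One power-iteration step is performed per training-mode forward call;
    the iteration vector persists across calls, so sigma converges as
    training proceeds and the layer stays (approximately) 1-Lipschitz.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        cout = self.w.shape[0]
        rng = np.random.default_rng(0)
        u0 = rng.normal(size=cout)
        u0 /= np.linalg.norm(u0)
        self.u = self.buffer("u", u0)

    def _weight(self) -> Tensor:
        n_iter = 1 if self.training else 0
        sigma, u, v = power_iteration_sigma(self.w.data, n_iter=max(n_iter, 1),
                                            u=self.u.copy())
        if self.training:
            self.u[...] = u
        if sigma == 0.0:
            return self.w
        # sigma as a differentiable function of w with u, v held fixed
        cout = self.w.shape[0]
        wmat = ag.reshape(self.w, (cout, -1))
        sig = ag.matmul(ag.reshape(Tensor(u.astype(np.float32)), (1, -1)),
                        ag.matmul(wmat, ag.reshape(
                            Tensor(v.astype(np.float32)), (-1, 1))))
        return self.w * ag.power(ag.reshape(sig, (1, 1, 1, 1)), -1.0)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.param("gamma", np.ones(c))
        self.beta = self.param("beta", np.zeros(c))
        self.running_mean = self.buffer("running_mean", np.zeros(c))
        self.running_var = self.buffer("running_var", np.ones(c))

    def forward(self, x: Tensor) -> Tensor:
        # x is (C, N, H, W): statistics run over batch and space
        if self.training:
            mu = ag.tmean(x, axis=(1, 2, 3), keepdims=True)
            var = ag.tmean(ag.power(x - mu, 2.0), axis=(1, 2, 3),
                           keepdims=True)
            m = self.momentum
            self.running_mean[...] = ((1 - m) * self.running_mean
                                      + m * mu.data.ravel())
            self.running_var[...] = ((1 - m) * self.running_var
                                     + m * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(-1, 1, 1, 1))
            var = Tensor(self.running_var.reshape(-1, 1, 1, 1))
        xhat = (x - mu) * ag.power(var + self.eps, -0.5)
        return (xhat * ag.reshape(self.gamma, (-1, 1, 1, 1))
                + ag.reshape(self.beta, (-1, 1, 1, 1)))


class PReLU(Module):
    def __init__(self, channels: int = 1, init: float = 0.25):
        super().__init__()
        shape = (channels, 1, 1, 1) if channels > 1 else (1,)
        self.a = self.param("a", np.full(shape, init))

    def forward(self, x: Tensor) -> Tensor:
        return ag.prelu(x, self.a)


class Dense(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        w = np.zeros((cin, cout)) if zero_init else _he_normal(
            rng, (cin, cout), cin)
        self.w = self.param("w", w)
        self.b = self.param("b", np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, self.w)
        if self.b is not None:
            y = y + ag.reshape(self.b, (1, -1))
        return y
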