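"""A small reverse-mode automatic-differentiation engine on numpy.

Provides exactly the tensor operations the hybrid classifier needs --
broadcasting arithmetic, matmul, the usual nonlinearities, 3x3
convolution, adaptive average pooling, batch/layer normalization,
softmax and cross-entropy -- together with ``Module`` bookkeeping, an
Adam optimizer and a step learning-rate schedule. Everything is float64
numpy under the hood; graphs are built eagerly and freed after
``backward``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "relu",
    "sigmoid",
    "tanh",
    "softmax",
    "cross_entropy",
    "concat",
    "Adam",
    "StepLR",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- shape helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes) -> "Tensor":
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a: int, b: int) -> "Tensor":
        return Tensor._make(
            self.data.swapaxes(a, b), (self,), lambda g: (g.swapaxes(a, b),)
        )

    def __getitem__(self, idx) -> "Tensor":
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __pow__(self, p: float) -> "Tensor":
        return Tensor._make(
            self.data**p, (self,), lambda g: (g * p * self.data ** (p - 1),)
        )

    def __matmul__(self, other) -> "Tensor":
        # both operands must be at least 2-D (no vector promotion)
        other = Tensor._coerce(other)
        a, b = self.data, other.data
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul operands must be at least 2-D")

        def backward(g):
            ga = _unbroadcast(np.matmul(g, b.swapaxes(-1, -2)), a.shape)
            gb = _unbroadcast(np.matmul(a.swapaxes(-1, -2), g), b.shape)
            return ga, gb

        return Tensor._make(np.matmul(a, b), (self, other), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


# -- elementwise nonlinearities ---------------------------------------
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._make(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._make(y, (x,), lambda g: (g * y * (1 - y),))


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return Tensor._make(y, (x,), lambda g: (g * (1 - y**2),))


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    return Tensor._make(y, (x,), lambda g: (g * y,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    return Tensor._make(
        y, (x,), lambda g: (y * (g - (g * y).sum(axis=axis, keepdims=True)),)
    )


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under softmax logits."""
    labels = np.asarray(labels, dtype=int)
    B = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(B), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(B), labels] -= 1.0
        return (g * p / B,)

    return Tensor._make(loss, (logits,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with symmetric padding.

    ``x`` is (B, Cin, H, W), ``w`` is (Cout, Cin, kh, kw); output spatial
    size is H + 2p - kh + 1 by W + 2p - kw + 1.
    """
    B, Cin, H, W = x.data.shape
    Cout, _, kh, kw = w.data.shape
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    out = np.zeros((B, Cout, Ho, Wo))
    for di in range(kh):
        for dj in range(kw):
            out += np.einsum(
                "oc,bcij->boij",
                w.data[:, :, di, dj],
                xp[:, :, di : di + Ho, dj : dj + Wo],
                optimize=True,
            )
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for di in range(kh):
            for dj in range(kw):
                gw[:, :, di, dj] = np.einsum(
                    "boij,bcij->oc", g, xp[:, :, di : di + Ho, dj : dj + Wo],
                    optimize=True,
                )
                gxp[:, :, di : di + Ho, dj : dj + Wo] += np.einsum(
                    "oc,boij->bcij", w.data[:, :, di, dj], g, optimize=True
                )
        gx = gxp[:, :, p : p + H, p : p + W] if p else gxp
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._make(out, parents, backward)


def adaptive_avg_pool2d(x: Tensor, out_size: int) -> Tensor:
    """Partition each map into an out_size x out_size grid of near-equal
    cells and average per cell (cell i spans floor(i*H/o) .. ceil((i+1)*H/o))."""
    B, C, H, W = x.data.shape
    o = out_size
    rows = [(math.floor(i * H / o), math.ceil((i + 1) * H / o)) for i in range(o)]
    cols = [(math.floor(j * W / o), math.ceil((j + 1) * W / o)) for j in range(o)]
    out = np.empty((B, C, o, o))
    for i, (r0, r1) in enumerate(rows):
        for j, (c0, c1) in enumerate(cols):
            out[:, :, i, j] = x.data[:, :, r0:r1, c0:c1].mean(axis=(2, 3))

    def backward(g):
        gx = np.zeros_like(x.data)
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                area = (r1 - r0) * (c1 - c0)
                gx[:, :, r0:r1, c0:c1] += g[:, :, i : i + 1, j : j + 1] / area
        return (gx,)

    return Tensor._make(out, (x,), backward)


# -- modules -----------------------------------------------------------
class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with train/eval state."""

    def __init__(self):
        self.training = True

    def modules(self, _seen: set | None = None):
        if _seen is None:
            _seen = set()
        if id(self) in _seen:
            return
        _seen.add(id(self))
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules(_seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules(_seen)
                    elif isinstance(item, (list, tuple)):
                        for sub in item:
                            if isinstance(sub, Module):
                                yield from sub.modules(_seen)

    def parameters(self) -> list[Parameter]:
        out, seen = [], set()
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    out.append(v)
        return out

    def named_parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def visit(mod, prefix):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    out[key] = v
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return out

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

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        padding: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        fan_in = in_channels * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel, kernel))
        )
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels))
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                1 - self.momentum
            ) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (
                1 - self.momentum
            ) * self.running_var + self.momentum * var.data.ravel()
        else:
            mu = Tensor(self.running_mean[None, :, None, None])
            var = Tensor(self.running_var[None, :, None, None])
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Adam:
    """Adaptive-moment estimation optimizer."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class StepLR:
    """Multiply the optimizer's learning rate by ``gamma`` every ``step_size``
    epochs, optionally floored."""

    def __init__(
        self,
        optimizer: Adam,
        step_size: int,
        gamma: float,
        floor: float | None = None,
    ):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self.floor = floor
        self.base_lr = optimizer.lr
        self.epoch = 0

    def step(self) -> None:
        self.epoch += 1
        lr = self.base_lr * self.gamma ** (self.epoch // self.step_size)
        if self.floor is not None:
            lr = max(lr, self.floor)
        self.optimizer.lr = lr
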