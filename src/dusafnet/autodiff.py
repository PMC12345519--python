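"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to express and train the classifier: a ``Tensor``
with a dynamically built tape, the handful of ops the architecture needs
(conv / batch-norm / pooling / matmul / softmax / masking), ``Module``
containers, and an Adam optimizer with a reduce-on-plateau schedule.
Everything is float32 and CPU-only.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "DepthwiseConv3x3",
    "BatchNorm2d",
    "Linear",
    "Adam",
    "ReduceLROnPlateau",
    "cross_entropy",
    "concat",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_shared")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._grad_shared = False
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # ---- graph traversal ------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # interior node: its gradient buffer is no longer needed
                t.grad = None
                t._grad_shared = False

    def _accum(self, grad):
        # first contribution is stored by reference (no copy); a second
        # contribution must not mutate the shared buffer, so it allocates
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=False)
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + grad
            self._grad_shared = False
        else:
            self.grad += grad

    # ---- elementwise ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = back
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = back
        return out

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def scale(self, s: float):
        return self * Tensor(np.float32(s))

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        if out.requires_grad:
            mask = self.data > 0
            out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        x = self.data
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    # ---- shape ----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(np.ascontiguousarray(self.data.transpose(axes)), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(tuple(inv)))
        return out

    def mean(self, axis, keepdims=False):
        axis = axis if isinstance(axis, tuple) else (axis,)
        out = Tensor(self.data.mean(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            n = int(np.prod([self.data.shape[a] for a in axis]))
            def back(g):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g / n, self.data.shape))
            out._backward = back
        return out

    def sum(self, axis, keepdims=False):
        axis = axis if isinstance(axis, tuple) else (axis,)
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def back(g):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = back
        return out

    # ---- linear algebra -------------------------------------------------
    def matmul(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))
        if out.requires_grad:
            def back(g):
                if self.requires_grad:
                    self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
                if other.requires_grad:
                    other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))
            out._backward = back
        return out

    __matmul__ = matmul

    def l2normalize(self, axis=-1, eps=1e-12):
        norm = np.sqrt((self.data**2).sum(axis=axis, keepdims=True) + eps)
        y = self.data / norm
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            def back(g):
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum((g - y * dot) / norm)
            out._backward = back
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def back(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))
    if out.requires_grad:
        def back(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))
        out._backward = back
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch from raw logits (fused log-softmax)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(loss, parents=(logits,))
    if out.requires_grad:
        def back(g):
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accum(g * p / n)
        out._backward = back
    return out


# ---------------------------------------------------------------- conv ops
def _im2col(x, kh, kw, stride, pad):
    """(B,C,H,W) -> contiguous (B, C, kh*kw, OH, OW) patch matrix.

    Built by one strided slice-copy per kernel offset, which is far
    cheaper than transposing a 6-D strided view.
    """
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    cols = np.empty((B, C, kh * kw, OH, OW), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j] = x[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride]
    return cols, OH, OW


def _col2im(dview, xshape, kh, kw, stride, pad):
    B, C, H, W = xshape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
    OH, OW = dview.shape[4], dview.shape[5]
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += dview[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation); w is (O, C, kh, kw).

    The im2col buffer is recomputed in the backward pass rather than kept
    on the tape: activations dominate memory on large inputs.
    """
    O, C, kh, kw = w.data.shape
    cols, OH, OW = _im2col(x.data, kh, kw, stride, pad)
    B = x.data.shape[0]
    cols2 = cols.reshape(B, C * kh * kw, OH * OW)
    w2 = w.data.reshape(O, C * kh * kw)
    out_data = np.matmul(w2, cols2).reshape(B, O, OH, OW)
    del cols, cols2
    if b is not None:
        out_data += b.data.reshape(1, O, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, parents=parents)
    if out.requires_grad:
        def back(g):
            g2 = g.reshape(B, O, OH * OW)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                rcols, _, _ = _im2col(x.data, kh, kw, stride, pad)
                rcols2 = rcols.reshape(B, C * kh * kw, OH * OW)
                dw = np.matmul(g2, rcols2.transpose(0, 2, 1)).sum(axis=0)
                w._accum(dw.reshape(w.data.shape))
                del rcols, rcols2
            if x.requires_grad:
                dcols = np.matmul(w2.T, g2)  # (B, Ckk, L)
                dview = dcols.reshape(B, C, kh, kw, OH, OW)
                x._accum(_col2im(dview, x.data.shape, kh, kw, stride, pad))
        out._backward = back
    return out


def depthwise_conv3x3(x: Tensor, w: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """Depthwise 3x3 convolution; w is (C, 3, 3)."""
    C = x.data.shape[1]
    cols, OH, OW = _im2col(x.data, 3, 3, stride, pad)  # (B,C,3,3,OH,OW)
    B = x.data.shape[0]
    cols2 = cols.reshape(B, C, 9, OH * OW)
    w2 = w.data.reshape(C, 9)
    out_data = np.einsum("bckl,ck->bcl", cols2, w2).reshape(B, C, OH, OW)
    del cols, cols2
    out = Tensor(out_data, parents=(x, w))
    if out.requires_grad:
        def back(g):
            g2 = g.reshape(B, C, OH * OW)
            if w.requires_grad:
                rcols, _, _ = _im2col(x.data, 3, 3, stride, pad)
                dw = np.einsum("bckl,bcl->ck", rcols.reshape(B, C, 9, OH * OW), g2)
                w._accum(dw.reshape(w.data.shape))
                del rcols
            if x.requires_grad:
                dcols = np.einsum("ck,bcl->bckl", w2, g2)
                dview = dcols.reshape(B, C, 3, 3, OH, OW)
                x._accum(_col2im(dview, x.data.shape, 3, 3, stride, pad))
        out._backward = back
    return out


def maxpool2d(x: Tensor, k: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    cols2, OH, OW = _im2col(xp, k, k, stride, 0)
    arg = cols2.argmax(axis=2).astype(np.int8)
    out_data = np.take_along_axis(cols2, arg[:, :, None].astype(np.intp), axis=2)[:, :, 0]
    del cols2
    out = Tensor(out_data, parents=(x,))
    if out.requires_grad:
        def back(g):
            dcols = np.zeros((B, C, k * k, OH, OW), dtype=np.float32)
            np.put_along_axis(dcols, arg[:, :, None].astype(np.intp), g[:, :, None], axis=2)
            dview = dcols.reshape(B, C, k, k, OH, OW)
            dxp = _col2im(dview, (B, C, H + 2 * pad, W + 2 * pad), k, k, stride, 0)
            x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)
        out._backward = back
    return out


def avgpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    y = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    out = Tensor(y, parents=(x,))
    if out.requires_grad:
        def back(g):
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            x._accum(gx)
        out._backward = back
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(mask)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    B, C, H, W = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (B * H * W) / max(B * H * W - 1, 1)
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, gamma, beta))
    if out.requires_grad:
        def back(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gs = gamma.data[None, :, None, None] / std[None, :, None, None]
                if training:
                    n = B * H * W
                    mean_g = g.mean(axis=(0, 2, 3), keepdims=True)
                    mean_gx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    x._accum(gs * (g - mean_g - xhat * mean_gx))
                else:
                    x._accum(gs * g)
        out._backward = back
    return out


# ------------------------------------------------------------------ modules
class Module:
    training = True

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # flat state dict: attribute paths -> arrays
    def state_dict(self, prefix="") -> dict[str, np.ndarray]:
        state = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        state[f"{key}.{i}"] = item.data
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix="") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = np.asarray(state[key], dtype=np.float32)
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float32)


def he_normal(rng, *shape, fan_in=None):
    if fan_in is None:
        fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, stride=1, pad=0, bias=False, rng=None):
        self.stride, self.pad = stride, pad
        self.weight = Parameter(he_normal(rng, c_out, c_in, k, k))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def state_dict(self, prefix=""):
        state = {f"{prefix}weight": self.weight.data}
        if self.bias is not None:
            state[f"{prefix}bias"] = self.bias.data
        return state

    def load_state_dict(self, state, prefix=""):
        self.weight.data = np.asarray(state[f"{prefix}weight"], dtype=np.float32)
        if self.bias is not None:
            self.bias.data = np.asarray(state[f"{prefix}bias"], dtype=np.float32)

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class DepthwiseConv3x3(Module):
    def __init__(self, c, rng=None):
        self.weight = Parameter(he_normal(rng, c, 3, 3, fan_in=9))

    def __call__(self, x):
        return depthwise_conv3x3(x, self.weight)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x):
        return batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class Linear(Module):
    def __init__(self, d_in, d_out, bias=True, rng=None):
        self.weight = Parameter(he_normal(rng, d_in, d_out, fan_in=d_in))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def state_dict(self, prefix=""):
        state = {f"{prefix}weight": self.weight.data}
        if self.bias is not None:
            state[f"{prefix}bias"] = self.bias.data
        return state

    def load_state_dict(self, state, prefix=""):
        self.weight.data = np.asarray(state[f"{prefix}weight"], dtype=np.float32)
        if self.bias is not None:
            self.bias.data = np.asarray(state[f"{prefix}bias"], dtype=np.float32)

    def __call__(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


# ---------------------------------------------------------------- optimizer
class Adam:
    def __init__(self, params: list[Parameter], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Multiply lr by ``factor`` after ``patience`` epochs without improvement."""

    def __init__(self, optimizer: Adam, factor=0.1, patience=10, min_lr=1e-6):
        self.opt = optimizer
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
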