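"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core used by the sequence backbone, the hypernetwork
decoder and the training engine.  It implements a small tape-based autodiff
engine: every :class:`Tensor` records the operation that produced it and a
closure that propagates gradients to its parents; :meth:`Tensor.backward`
walks the tape in reverse topological order.

Only the operations needed by this package are provided (broadcast
arithmetic, matmul, reductions, indexing, concatenation, the GELU /
softplus / softmax nonlinearities and a strided 1-D convolution primitive).
All computation is float64 for deterministic CPU behaviour.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- tape machinery -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        # reverse topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads to bound memory (keep leaves)
                if node._parents:
                    node.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation).

        The tanh is evaluated in single precision (absolute error ~1e-8,
        far below the approximation error of the tanh form itself), which
        roughly halves the cost of the dominant elementwise operation.
        """
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner.astype(np.float32)).astype(np.float64)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            if self.requires_grad:
                dt = (1.0 - t ** 2) * c * (1.0 + 3 * 0.044715 * x ** 2)
                self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), numerically stable; maps R -> (0, inf)."""
        x = self.data
        out_data = np.logaddexp(0.0, x)

        def backward(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-x)))

        return self._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other):
        other = Tensor._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                    self._accum(_unbroadcast(ga, self.data.shape))
                else:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    if self.data.ndim == 1:
                        ga = ga.sum(axis=tuple(range(ga.ndim - 1)))
                    self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                    other._accum(_unbroadcast(gb, other.data.shape))
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    if other.data.ndim == 1:
                        gb = gb.sum(axis=tuple(range(gb.ndim - 1)))
                    other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    # -- convolution ----------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """Strided 1-D convolution.

        self: (B, C_in, L); weight: (C_out, C_in, K); bias: (C_out,).
        Returns (B, C_out, L_out) with L_out = (L + 2*padding - K)//stride + 1.
        Implemented as im2col + matmul with an explicit col2im backward.
        """
        weight = Tensor._lift(weight)
        x = self.data
        B, C_in, L = x.shape
        C_out, C_in_w, K = weight.data.shape
        if C_in != C_in_w:
            raise ValueError(f"conv1d channel mismatch: {C_in} vs {C_in_w}")
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        Lp = x.shape[2]
        L_out = (Lp - K) // stride + 1
        if L_out <= 0:
            raise ValueError("conv1d: kernel longer than (padded) input")
        s0, s1, s2 = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x, shape=(B, L_out, C_in, K), strides=(s0, s2 * stride, s1, s2)
        ).reshape(B, L_out, C_in * K)
        w2 = weight.data.reshape(C_out, C_in * K)
        out = cols @ w2.T  # (B, L_out, C_out)
        if bias is not None:
            out = out + bias.data
        out_data = np.ascontiguousarray(out.transpose(0, 2, 1))

        parents = [self, weight] + ([bias] if bias is not None else [])

        def backward(g):
            # g: (B, C_out, L_out)
            gl = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, L_out, C_out)
            if weight.requires_grad:
                gw = np.einsum("blo,blk->ok", gl, cols)
                weight._accum(gw.reshape(C_out, C_in, K))
            if bias is not None and bias.requires_grad:
                bias._accum(gl.sum(axis=(0, 1)))
            if self.requires_grad:
                dcols = gl @ w2  # (B, L_out, C_in*K)
                dcols = dcols.reshape(B, L_out, C_in, K)
                dx = np.zeros((B, C_in, Lp))
                starts = np.arange(L_out) * stride
                for k in range(K):
                    # indices starts+k are unique for fixed k, so a direct
                    # fancy-index accumulation is safe (and fast)
                    dx[:, :, starts + k] += dcols[:, :, :, k].transpose(0, 2, 1)
                if padding:
                    dx = dx[:, :, padding:Lp - padding]
                self._accum(dx)

        return self._make(out_data, parents, backward)


    def maxpool1d(self, width: int = 2):
        """Non-overlapping max pooling over the last axis.

        Preserves sharp local feature activations (e.g. motif matches)
        through downsampling, unlike strided convolution.
        """
        x = self.data
        L = x.shape[-1]
        if L % width != 0:
            raise ValueError("maxpool1d requires length divisible by width")
        xr = x.reshape(*x.shape[:-1], L // width, width)
        arg = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            if self.requires_grad:
                gr = np.zeros_like(xr)
                np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
                self._accum(gr.reshape(x.shape))

        return self._make(out_data, (self,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    proto = tensors[0]
    return proto._make(out_data, tensors, backward)
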