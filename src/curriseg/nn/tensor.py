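"""A compact reverse-mode automatic differentiation engine over numpy arrays.

Supports exactly the operations the segmentation stack needs: broadcasted
arithmetic, matmul, reductions, elementwise nonlinearities, slicing/reshape,
2-D convolution, 2x2 max pooling, nearest-neighbour upsampling, spatial
padding (zero and reflect) and channel concatenation.  Gradients for every
op are verified against central finite differences in the test suite.

All floating point data is kept in float32; gradients are float32 as well.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (), _backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # ---------------------------------------------------------------- basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- autograd
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
        # free the graph: closures create reference cycles that otherwise
        # keep every intermediate array alive until a full gc pass; leaf
        # gradients (parameters) are preserved for the optimizer
        for node in topo:
            if node._backward is not None:
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(_as_array(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            self._accum(g)
            other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)
        out._backward = bwd
        return out

    # ---------------------------------------------------------- elementwise
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * out.data)
        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g / self.data)
        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * (self.data > 0))
        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through where unclamped, else zero."""
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * ((self.data >= lo) & (self.data <= hi)))
        out._backward = bwd
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * np.sign(self.data))
        out._backward = bwd
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else axis
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in
                     ((axis,) if isinstance(axis, int) else axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def logsumexp(self, axis: int) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        lse = m + np.log(np.exp(self.data - m).sum(axis=axis, keepdims=True))
        out = Tensor(np.squeeze(lse, axis=axis), self.requires_grad, (self,))

        def bwd(g):
            soft = np.exp(self.data - lse)
            self._accum(np.expand_dims(g, axis) * soft)
        out._backward = bwd
        return out

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bwd
        return out


# ----------------------------------------------------------------- functions

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = [t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]) for t in tensors]
    return concat(expanded, axis=axis)


def pad2d(x: Tensor, pad: tuple[int, int, int, int], mode: str = "zero") -> Tensor:
    """Pad the last two axes by (top, bottom, left, right)."""
    t, b, l, r = pad
    spec = [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)]
    if mode == "zero":
        out = Tensor(np.pad(x.data, spec), x.requires_grad, (x,))

        def bwd(g):
            sl = [slice(None)] * (x.ndim - 2) + [
                slice(t, g.shape[-2] - b), slice(l, g.shape[-1] - r)]
            x._accum(g[tuple(sl)])
        out._backward = bwd
        return out
    if mode == "reflect":
        H, W = x.shape[-2], x.shape[-1]
        # source index per padded position, built by padding index grids
        rows = np.pad(np.arange(H), (t, b), mode="reflect")
        cols = np.pad(np.arange(W), (l, r), mode="reflect")
        out = Tensor(x.data[..., rows[:, None], cols[None, :]],
                     x.requires_grad, (x,))

        def bwd(g):
            full = np.zeros_like(x.data)
            np.add.at(full.reshape(-1, H, W),
                      (slice(None), rows[:, None], cols[None, :]),
                      g.reshape(-1, g.shape[-2], g.shape[-1]))
            x._accum(full)
        out._backward = bwd
        return out
    raise ValueError(f"unknown pad mode {mode!r}")


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    x: [N, C, H, W]; weight: [O, C, kh, kw]; bias: [O].
    """
    if padding:
        x = pad2d(x, (padding,) * 4, "zero")
    N, C, H, W = x.shape
    O, Cw, kh, kw = weight.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C} vs weight {Cw}")
    Ho, Wo = H - kh + 1, W - kw + 1
    K = kh * kw
    # One GEMM against the flat (padded) input computes every kernel tap's
    # contribution at once; taps are then summed at their spatial shifts.
    # This avoids materializing an im2col buffer pass by pass.
    x_flat = x.data.reshape(N, C, H * W)
    w_taps = weight.data.transpose(2, 3, 0, 1).reshape(K * O, C)
    z = (w_taps @ x_flat).reshape(N, kh, kw, O, H, W)
    y = np.zeros((N, O, Ho, Wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            y += z[:, i, j, :, i:i + Ho, j:j + Wo]
    if bias is not None:
        y = y + bias.data.reshape(1, O, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        # scatter the output gradient to each tap's shifted position, then
        # both dW and dx reduce to one GEMM each against that buffer
        dz = np.zeros((N, kh, kw, O, H, W), dtype=DTYPE)
        for i in range(kh):
            for j in range(kw):
                dz[:, i, j, :, i:i + Ho, j:j + Wo] = g
        dz_flat = dz.reshape(N, K * O, H * W)
        if weight.requires_grad:
            gw = np.matmul(dz_flat, x_flat.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(gw.reshape(kh, kw, O, C).transpose(2, 3, 0, 1))
        if x.requires_grad:
            x._accum((w_taps.T @ dz_flat).reshape(N, C, H, W))
    out._backward = bwd
    return out


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties resolved to the first occurrence."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2d needs even spatial dims, got {H}x{W}")
    Ho, Wo = H // 2, W // 2
    xr = x.data.reshape(N, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5)
    xf = xr.reshape(N, C, Ho, Wo, 4)
    idx = xf.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bwd(g):
        gf = np.zeros_like(xf)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        dx = gf.reshape(N, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(N, C, H, W))
    out._backward = bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = Tensor(x.data.repeat(2, axis=-2).repeat(2, axis=-1),
                 x.requires_grad, (x,))

    def bwd(g):
        N = g.shape
        gr = g.reshape(N[:-2] + (N[-2] // 2, 2, N[-1] // 2, 2))
        x._accum(gr.sum(axis=(-3, -1)))
    out._backward = bwd
    return out


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    lse = x.logsumexp(axis=axis)
    return x - lse.reshape(lse.shape[:axis] + (1,) + lse.shape[axis:])


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps) ** 0.5
    return x / norm


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
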