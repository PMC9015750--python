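"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the sequence taggers need: broadcasting
arithmetic, matrix products, pointwise nonlinearities, reductions
(sum / max / logsumexp), gather-style indexing, concatenation and reshape.
Gradients are accumulated by a topological-order backward sweep.

Everything is float64 and CPU-bound by design: the models in this package
are desk-scale (tens of sentences, tiny hidden sizes), where exactness and
determinism matter more than throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concatenate", "Adam", "gradcheck"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            ad, bd = a.data, b.data
            if ad.ndim == 1 and bd.ndim == 2:      # (k,) @ (k,m) -> (m,)
                return (g @ bd.T, np.outer(ad, g))
            if ad.ndim == 2 and bd.ndim == 1:      # (n,k) @ (k,) -> (n,)
                return (np.outer(g, bd), ad.T @ g)
            if ad.ndim == 1 and bd.ndim == 1:      # dot
                return (g * bd, g * ad)
            return (g @ bd.T, ad.T @ g)            # (n,k)@(k,m)

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities ---------------------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    # -- reductions -------------------------------------------------------------

    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward(g):
            if axis is None:
                return (np.full_like(self.data, float(g)) if np.ndim(g) == 0
                        else g * np.ones_like(self.data),)
            return (np.expand_dims(g, axis) * np.ones_like(self.data),)

        return self._make(out_data, (self,), backward)

    def max(self, axis: int):
        """Max over one axis; ties propagate to the first argmax (max-pooling)."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis)

        def backward(g):
            grad = np.zeros_like(self.data)
            ix = list(np.indices(out_data.shape))
            ix.insert(axis if axis >= 0 else self.data.ndim + axis, idx)
            grad[tuple(ix)] = g
            return (grad,)

        return self._make(out_data, (self,), backward)

    def logsumexp(self, axis: int):
        m = np.max(self.data, axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        out_data = np.squeeze(m + np.log(s), axis=axis)
        softmax = np.exp(self.data - m) / s

        def backward(g):
            return (np.expand_dims(g, axis) * softmax,)

        return self._make(out_data, (self,), backward)

    # -- shape / indexing --------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(orig),))

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, key, g)
            return (grad,)

        return self._make(out_data, (self,), backward)

    # -- backward sweep -----------------------------------------------------------

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar output")
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad += g


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def gradcheck(fn, params: list[Tensor], eps: float = 1e-6, atol: float = 1e-5) -> bool:
    """Compare analytic gradients of scalar ``fn(params)`` with central differences."""
    out = fn()
    for p in params:
        p.grad = None
    out.backward()
    analytic = [p.grad.copy() if p.grad is not None else np.zeros_like(p.data)
                for p in params]
    for p, ga in zip(params, analytic):
        flat = p.data.ravel()
        gflat = ga.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = fn().item()
            flat[i] = orig - eps
            fm = fn().item()
            flat[i] = orig
            num = (fp - fm) / (2 * eps)
            if abs(num - gflat[i]) > atol * max(1.0, abs(num)):
                return False
    return True
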