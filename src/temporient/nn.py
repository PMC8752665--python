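"""Minimal reverse-mode autodiff on numpy, with the layers the package needs.

Scope is deliberately narrow: dense layers, embeddings, GRU/LSTM cells,
1-D convolution with global max pooling, dropout, softmax cross-entropy and
squared-error losses, and an RMSprop optimizer. Everything is float64 and
seed-deterministic; batches are the leading axis.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph: numpy data plus a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or bool(parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    # reduce a broadcast gradient back to the operand's shape
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    return Tensor(a.data + b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    return Tensor(a.data * b.data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """a @ b where a is (..., E) and b is a 2-D (E, F) matrix."""
    a, b = _wrap(a), _wrap(b)
    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.reshape(-1, a.data.shape[-1]).T @ g.reshape(-1, g.shape[-1]))
    return Tensor(a.data @ b.data, (a, b), bw)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    def bw(g):
        for t, piece in zip(tensors, np.split(g, np.cumsum(sizes)[:-1], axis=axis)):
            _accum(t, piece)
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))
    def bw(g):
        _accum(x, g * out * (1.0 - out))
    return Tensor(out, (x,), bw)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)
    def bw(g):
        _accum(x, g * (1.0 - out * out))
    return Tensor(out, (x,), bw)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    def bw(g):
        _accum(x, g * (x.data > 0.0))
    return Tensor(out, (x,), bw)


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup: (V, E) table gathered by an integer index array."""
    indices = np.asarray(indices)
    def bw(g):
        if not table.requires_grad:
            return
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, indices, g)
    return Tensor(table.data[indices], (table,), bw)


def tslice(x: Tensor, start: int, length: int) -> Tensor:
    """Slice the time axis (axis 1) of a (B, T, ...) tensor."""
    def bw(g):
        if not x.requires_grad:
            return
        if x.grad is None:
            x.grad = np.zeros_like(x.data)
        x.grad[:, start:start + length] += g
    return Tensor(x.data[:, start:start + length], (x,), bw)


def time_step(x: Tensor, t: int) -> Tensor:
    """Extract step t of a (B, T, E) tensor as (B, E)."""
    def bw(g):
        if not x.requires_grad:
            return
        if x.grad is None:
            x.grad = np.zeros_like(x.data)
        x.grad[:, t] += g
    return Tensor(x.data[:, t], (x,), bw)


def max_pool_time(x: Tensor) -> Tensor:
    """Global max over axis 1 of a (B, T, F) tensor."""
    arg = x.data.argmax(axis=1)  # (B, F)
    out = x.data.max(axis=1)
    def bw(g):
        if not x.requires_grad:
            return
        if x.grad is None:
            x.grad = np.zeros_like(x.data)
        b_idx, f_idx = np.meshgrid(np.arange(x.data.shape[0]),
                                   np.arange(x.data.shape[2]), indexing="ij")
        np.add.at(x.grad, (b_idx, arg, f_idx), g)
    return Tensor(out, (x,), bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return x
    mask = rng.binomial(1, 1.0 - rate, size=x.data.shape) / (1.0 - rate)
    return mul(x, Tensor(mask))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of (B, C) logits vs integer labels."""
    labels = np.asarray(labels, dtype=np.intp)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None)).mean()
    def bw(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        _accum(logits, g * d / n)
    return Tensor(loss, (logits,), bw)


def mean_squared_error(pred: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=np.float64).reshape(pred.data.shape)
    diff = pred.data - target
    def bw(g):
        _accum(pred, g * 2.0 * diff / diff.size)
    return Tensor((diff ** 2).mean(), (pred,), bw)


# ---------------------------------------------------------------------------
# layers


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.w = Tensor(glorot(rng, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)

    def params(self):
        return [self.w, self.b]


class GRUCell:
    """Gated recurrent unit; gates stacked as [update z | reset r | candidate]."""

    def __init__(self, rng, n_in: int, n_hidden: int):
        self.n_hidden = n_hidden
        self.wx = Tensor(glorot(rng, (n_in, 3 * n_hidden)), requires_grad=True)
        self.wh = Tensor(glorot(rng, (n_hidden, 3 * n_hidden)), requires_grad=True)
        self.b = Tensor(np.zeros(3 * n_hidden), requires_grad=True)

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.n_hidden
        gx = add(matmul(x, self.wx), self.b)
        gh = matmul(h, self.wh)

        def piece(t, i):
            data = t.data[:, i * H:(i + 1) * H]
            def bw(g):
                if t.grad is None:
                    t.grad = np.zeros_like(t.data)
                t.grad[:, i * H:(i + 1) * H] += g
            return Tensor(data, (t,), bw)

        z = sigmoid(add(piece(gx, 0), piece(gh, 0)))
        r = sigmoid(add(piece(gx, 1), piece(gh, 1)))
        cand = tanh(add(piece(gx, 2), mul(r, piece(gh, 2))))
        one_minus_z = add(Tensor(1.0), mul(Tensor(-1.0), z))
        return add(mul(one_minus_z, h), mul(z, cand))

    def params(self):
        return [self.wx, self.wh, self.b]


class LSTMCell:
    """LSTM; gates stacked as [input | forget | output | candidate]."""

    def __init__(self, rng, n_in: int, n_hidden: int):
        self.n_hidden = n_hidden
        self.wx = Tensor(glorot(rng, (n_in, 4 * n_hidden)), requires_grad=True)
        self.wh = Tensor(glorot(rng, (n_hidden, 4 * n_hidden)), requires_grad=True)
        b0 = np.zeros(4 * n_hidden)
        b0[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b0, requires_grad=True)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.n_hidden
        gates = add(add(matmul(x, self.wx), matmul(h, self.wh)), self.b)

        def piece(t, i):
            data = t.data[:, i * H:(i + 1) * H]
            def bw(g):
                if t.grad is None:
                    t.grad = np.zeros_like(t.data)
                t.grad[:, i * H:(i + 1) * H] += g
            return Tensor(data, (t,), bw)

        i_g = sigmoid(piece(gates, 0))
        f_g = sigmoid(piece(gates, 1))
        o_g = sigmoid(piece(gates, 2))
        cand = tanh(piece(gates, 3))
        c_new = add(mul(f_g, c), mul(i_g, cand))
        h_new = mul(o_g, tanh(c_new))
        return h_new, c_new

    def params(self):
        return [self.wx, self.wh, self.b]


def run_recurrent(cell, embedded: Tensor, mask: np.ndarray, reverse: bool = False) -> Tensor:
    """Run a GRU/LSTM over (B, T, E) input and return the final hidden state.

    ``mask`` is (B, T) with 1 on real tokens; masked steps keep the previous
    state, so right-padding never leaks into the summary.
    """
    B, T, _ = embedded.data.shape
    H = cell.n_hidden
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H))) if isinstance(cell, LSTMCell) else None
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        x_t = time_step(embedded, t)
        m = Tensor(mask[:, t:t + 1])
        keep = Tensor(1.0 - mask[:, t:t + 1])
        if c is not None:
            h_new, c_new = cell.step(x_t, h, c)
            c = add(mul(m, c_new), mul(keep, c))
        else:
            h_new = cell.step(x_t, h)
        h = add(mul(m, h_new), mul(keep, h))
    return h


class Conv1D:
    """Temporal convolution (B, T, E) -> (B, T-k+1, F) with ReLU applied by caller."""

    def __init__(self, rng, width: int, n_in: int, n_filters: int):
        self.width = width
        self.w = [Tensor(glorot(rng, (n_in, n_filters)), requires_grad=True)
                  for _ in range(width)]
        self.b = Tensor(np.zeros(n_filters), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        T = x.data.shape[1]
        T_out = T - self.width + 1
        if T_out < 1:
            raise ValueError(f"sequence length {T} shorter than filter width {self.width}")
        out = add(matmul(tslice(x, 0, T_out), self.w[0]), self.b)
        for j in range(1, self.width):
            out = add(out, matmul(tslice(x, j, T_out), self.w[j]))
        return out

    def params(self):
        return [*self.w, self.b]


class RMSProp:
    """RMSprop with the conventional 0.9 decay."""

    def __init__(self, params, lr: float = 0.01, decay: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.decay, self.eps = lr, decay, eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, c in zip(self.params, self.cache):
            if p.grad is None:
                continue
            c *= self.decay
            c += (1.0 - self.decay) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
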