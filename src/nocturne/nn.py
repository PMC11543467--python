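"""Minimal numpy neural networks for the recurrent and MLP classifiers.

A compact reverse-mode automatic-differentiation core (:class:`Tensor`)
backs hand-written GRU/LSTM cells, dense layers and dropout.  Training
follows the study protocol: Adam (learning rate 0.001), batch size 1,
class-weighted binary cross-entropy, and early stopping on the validation
F2 score.  Missing timesteps are masked: a masked step leaves the hidden
state unchanged, so imputed values carry no information into the recurrence.

The networks are deliberately small (tens of units); the cohort has tens of
labeled nights, so capacity beyond that only overfits.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph; ``backward()`` fills ``grad``."""

    __slots__ = ("data", "grad", "_backward", "_prev")

    def __init__(self, data, _prev=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self._backward = lambda: None
        self._prev = _prev

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def _backward():
            self.grad += _unbroadcast(out.grad, self.data.shape)
            other.grad += _unbroadcast(out.grad, other.data.shape)

        out._backward = _backward
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def _backward():
            self.grad += _unbroadcast(other.data * out.grad, self.data.shape)
            other.grad += _unbroadcast(self.data * out.grad, other.data.shape)

        out._backward = _backward
        return out

    def __neg__(self):
        return self * Tensor(-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, vec: "Tensor") -> "Tensor":
        """Matrix (2-D) times vector (1-D)."""
        out = Tensor(self.data @ vec.data, (self, vec))

        def _backward():
            self.grad += np.outer(out.grad, vec.data)
            vec.grad += self.data.T @ out.grad

        out._backward = _backward
        return out

    # -- nonlinearities -----------------------------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, (self,))

        def _backward():
            self.grad += s * (1 - s) * out.grad

        out._backward = _backward
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, (self,))

        def _backward():
            self.grad += (1 - t**2) * out.grad

        out._backward = _backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def _backward():
            self.grad += (self.data > 0) * out.grad

        out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(np.clip(self.data, 1e-12, None)), (self,))

        def _backward():
            self.grad += out.grad / np.clip(self.data, 1e-12, None)

        out._backward = _backward
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), (self,))

        def _backward():
            self.grad += np.ones_like(self.data) * out.grad

        out._backward = _backward
        return out

    @staticmethod
    def concat(parts: list["Tensor"]) -> "Tensor":
        out = Tensor(np.concatenate([p.data for p in parts]), tuple(parts))
        sizes = [p.data.shape[0] for p in parts]

        def _backward():
            ofs = 0
            for p, s in zip(parts, sizes):
                p.grad += out.grad[ofs : ofs + s]
                ofs += s

        out._backward = _backward
        return out

    # -- autodiff driver ----------------------------------------------------
    def backward(self) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in visited:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()


# --- layers -----------------------------------------------------------------

def _glorot(rng: np.random.Generator, n_out: int, n_in: int) -> Tensor:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-lim, lim, size=(n_out, n_in)))


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, n_out, n_in)
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return self.W.matmul(x) + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class GRUCell:
    """Gated recurrent unit with tanh candidate activation."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.Wz, self.Uz = _glorot(rng, n_hidden, n_in), _glorot(rng, n_hidden, n_hidden)
        self.Wr, self.Ur = _glorot(rng, n_hidden, n_in), _glorot(rng, n_hidden, n_hidden)
        self.Wh, self.Uh = _glorot(rng, n_hidden, n_in), _glorot(rng, n_hidden, n_hidden)
        self.bz = Tensor(np.zeros(n_hidden))
        self.br = Tensor(np.zeros(n_hidden))
        self.bh = Tensor(np.zeros(n_hidden))

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        z = (self.Wz.matmul(x) + self.Uz.matmul(h) + self.bz).sigmoid()
        r = (self.Wr.matmul(x) + self.Ur.matmul(h) + self.br).sigmoid()
        h_cand = (self.Wh.matmul(x) + self.Uh.matmul(r * h) + self.bh).tanh()
        return (Tensor(1.0) - z) * h + z * h_cand

    @property
    def params(self) -> list[Tensor]:
        return [self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br,
                self.Wh, self.Uh, self.bh]


class LSTMCell:
    """Long short-term memory cell with tanh activations."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.W = {}
        self.U = {}
        self.b = {}
        for gate in "ifog":
            self.W[gate] = _glorot(rng, n_hidden, n_in)
            self.U[gate] = _glorot(rng, n_hidden, n_hidden)
            # forget-gate bias 1: remember by default
            init = np.ones(n_hidden) if gate == "f" else np.zeros(n_hidden)
            self.b[gate] = Tensor(init)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        pre = {
            g: self.W[g].matmul(x) + self.U[g].matmul(h) + self.b[g]
            for g in "ifog"
        }
        i, f, o = pre["i"].sigmoid(), pre["f"].sigmoid(), pre["o"].sigmoid()
        g = pre["g"].tanh()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new

    @property
    def params(self) -> list[Tensor]:
        return [t for g in "ifog" for t in (self.W[g], self.U[g], self.b[g])]


def _masked(h_new: Tensor, h_prev: Tensor, m: float) -> Tensor:
    """Masked update: m=1 takes the new state, m=0 carries the old through."""
    if m >= 1.0:
        return h_new
    if m <= 0.0:
        return h_prev
    return Tensor(m) * h_new + Tensor(1.0 - m) * h_prev


def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)


# --- classifier architectures ----------------------------------------------

class RnnClassifier:
    """mask → bidirectional GRU(32) → dropout → LSTM(16) → dropout → dense σ."""

    def __init__(self, n_channels: int, rng: np.random.Generator,
                 gru_units: int = 32, lstm_units: int = 16,
                 dropout: float = 0.2):
        self.gru_fw = GRUCell(n_channels, gru_units, rng)
        self.gru_bw = GRUCell(n_channels, gru_units, rng)
        self.lstm = LSTMCell(2 * gru_units, lstm_units, rng)
        self.out = Dense(lstm_units, 1, rng)
        self.dropout = dropout
        self.gru_units, self.lstm_units = gru_units, lstm_units

    @property
    def params(self) -> list[Tensor]:
        return (self.gru_fw.params + self.gru_bw.params + self.lstm.params
                + self.out.params)

    def forward(self, x_seq: np.ndarray, mask: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        T = x_seq.shape[0]
        xs = [Tensor(x_seq[t]) for t in range(T)]
        h = Tensor(np.zeros(self.gru_units))
        fw = []
        for t in range(T):
            h = _masked(self.gru_fw.step(xs[t], h), h, mask[t])
            fw.append(h)
        h = Tensor(np.zeros(self.gru_units))
        bw = [None] * T
        for t in reversed(range(T)):
            h = _masked(self.gru_bw.step(xs[t], h), h, mask[t])
            bw[t] = h
        h = Tensor(np.zeros(self.lstm_units))
        c = Tensor(np.zeros(self.lstm_units))
        for t in range(T):
            seq_t = _dropout(Tensor.concat([fw[t], bw[t]]), self.dropout, rng)
            h_new, c_new = self.lstm.step(seq_t, h, c)
            h = _masked(h_new, h, mask[t])
            c = _masked(c_new, c, mask[t])
        return self.out(_dropout(h, self.dropout, rng)).sigmoid()


class RnnMlpClassifier:
    """LSTM(16) temporal branch ⊕ dense(16, relu) static branch →
    concat → dense(16, relu) → dense σ."""

    def __init__(self, n_channels: int, n_static: int,
                 rng: np.random.Generator, lstm_units: int = 16,
                 mlp_units: int = 16, dropout: float = 0.2):
        self.lstm = LSTMCell(n_channels, lstm_units, rng)
        self.static_mlp = Dense(n_static, mlp_units, rng)
        self.head = Dense(lstm_units + mlp_units, mlp_units, rng)
        self.out = Dense(mlp_units, 1, rng)
        self.lstm_units = lstm_units
        self.dropout = dropout

    @property
    def params(self) -> list[Tensor]:
        return (self.lstm.params + self.static_mlp.params + self.head.params
                + self.out.params)

    def forward(self, x_seq: np.ndarray, mask: np.ndarray,
                rng: np.random.Generator | None = None,
                static: np.ndarray | None = None) -> Tensor:
        T = x_seq.shape[0]
        h = Tensor(np.zeros(self.lstm_units))
        c = Tensor(np.zeros(self.lstm_units))
        for t in range(T):
            h_new, c_new = self.lstm.step(Tensor(x_seq[t]), h, c)
            h = _masked(h_new, h, mask[t])
            c = _masked(c_new, c, mask[t])
        s = self.static_mlp(Tensor(static)).relu()
        z = _dropout(Tensor.concat([h, s]), self.dropout, rng)
        return self.out(self.head(z).relu()).sigmoid()


class MlpClassifier:
    """dense(16, relu) → dense(16, relu) → dense σ, for flat feature vectors."""

    def __init__(self, n_in: int, rng: np.random.Generator, units: int = 16):
        self.l1 = Dense(n_in, units, rng)
        self.l2 = Dense(units, units, rng)
        self.out = Dense(units, 1, rng)

    @property
    def params(self) -> list[Tensor]:
        return self.l1.params + self.l2.params + self.out.params

    def forward(self, x: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        h = self.l2(self.l1(Tensor(x)).relu()).relu()
        return self.out(h).sigmoid()


def weighted_bce(p: Tensor, y: int, weight: float) -> Tensor:
    """Class-weighted binary cross-entropy for one sample."""
    if y == 1:
        return Tensor(-weight) * p.log().sum()
    return Tensor(-weight) * (Tensor(1.0) - p).log().sum()
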