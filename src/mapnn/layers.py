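"""Minimal neural-network primitives with explicit backpropagation.

The two-branch map-estimation network is small and static, so layers are
implemented directly in NumPy: each layer caches what its backward pass
needs, accumulates parameter gradients in-place, and returns the gradient
with respect to its input.  Weights are initialized from the uniform
fan-in/fan-out (Glorot) distribution and biases start at zero.  All
computation is deterministic given the seed and single-threaded BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(shape, fan_in, fan_out, rng):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    """Affine map over the last axis: y = x @ W + b."""

    def __init__(self, n_in, n_out, rng):
        self.W = glorot_uniform((n_in, n_out), n_in, n_out, rng)
        self.b = np.zeros(n_out)
        # gradient buffers are allocated once so optimizers can hold views
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def zero_grad(self):
        self.dW.fill(0.0)
        self.db.fill(0.0)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        x2 = self._x.reshape(-1, self.W.shape[0])
        d2 = dout.reshape(-1, self.W.shape[1])
        self.dW += x2.T @ d2
        self.db += d2.sum(axis=0)
        return dout @ self.W.T


class Conv1D:
    """1-D valid convolution, stride 1, over (batch, channels, length).

    Implemented as im2col + matrix multiplication so the heavy lifting runs
    in BLAS.  ``first_layer=True`` skips the (unused) input-gradient
    computation of the network's first layer.
    """

    def __init__(self, c_in, c_out, kernel, rng, first_layer=False):
        fan_in = c_in * kernel
        fan_out = c_out * kernel
        self.W = glorot_uniform((c_out, c_in, kernel), fan_in, fan_out, rng)
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.first_layer = first_layer
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def zero_grad(self):
        self.dW.fill(0.0)
        self.db.fill(0.0)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x):
        # (B, Cin, Lout, k) view -> (B*Lout, Cin*k) matrix
        xw = sliding_window_view(x, self.kernel, axis=2)
        B, C, L, k = xw.shape
        return np.ascontiguousarray(xw.transpose(0, 2, 1, 3)).reshape(B * L, C * k), L

    def forward(self, x):
        self._x = x
        cols, L = self._im2col(x)
        self._cols, self._L = cols, L
        Wm = self.W.reshape(self.W.shape[0], -1)  # (Cout, Cin*k)
        out = cols @ Wm.T  # (B*Lout, Cout)
        out = out.reshape(x.shape[0], L, -1).transpose(0, 2, 1)
        return out + self.b[None, :, None]

    def backward(self, dout):
        B, Cout, L = dout.shape
        d2 = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(B * L, Cout)
        self.dW += (d2.T @ self._cols).reshape(self.W.shape)
        self.db += d2.sum(axis=0)
        if self.first_layer:
            return None
        k = self.kernel
        pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
        pw = sliding_window_view(pad, k, axis=2)  # (B, Cout, Lin, k)
        Bp, Co, Li, _ = pw.shape
        cols = np.ascontiguousarray(pw.transpose(0, 2, 1, 3)).reshape(Bp * Li, Co * k)
        Wf = self.W[:, :, ::-1].transpose(0, 2, 1).reshape(Co * k, -1)  # (Cout*k, Cin)
        dx = cols @ Wf
        return dx.reshape(Bp, Li, -1).transpose(0, 2, 1)


class AvgPool1D:
    """Average pooling over the length axis; a trailing remainder is dropped."""

    def __init__(self, pool):
        self.pool = pool

    def zero_grad(self):
        pass

    def parameters(self):
        return []

    def forward(self, x):
        p = self.pool
        self._in_len = x.shape[2]
        L = (x.shape[2] // p) * p
        self._kept = L
        return x[:, :, :L].reshape(x.shape[0], x.shape[1], L // p, p).mean(axis=3)

    def backward(self, dout):
        p = self.pool
        dx = np.repeat(dout, p, axis=2) / p
        if self._kept < self._in_len:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, self._in_len - self._kept)))
        return dx


class ReLU:
    def zero_grad(self):
        pass

    def parameters(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten:
    """(B, C, L) -> (B, C*L)."""

    def zero_grad(self):
        pass

    def parameters(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam:
    """Adam optimizer over a fixed list of (param, grad) array pairs."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, scale=1.0):
        """Apply one update using the accumulated gradients times ``scale``."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            grad = g * scale
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
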