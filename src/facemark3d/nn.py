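"""Compact volumetric neural-network engine on numpy/BLAS.

Implements exactly the layer set the landmarking networks need — 3D
convolution (3^3 kernel, stride 1, pad 1, via im2col + matmul), 2^3 max
pooling, volumetric batch normalization, sigmoid/ReLU, fully connected
layers, pre-activation residual blocks — together with explicit reverse-mode
gradients and an Adam optimizer.  All parameters and activations are float32;
every layer's backward pass is validated against finite differences in the
test suite.

The engine is deliberately minimal: stride and kernel size are fixed to the
values the architecture uses, there is no autograd graph, and layers cache
exactly what their backward pass needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base layer: forward caches what backward needs."""

    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs; grads are accumulated in-place by backward."""
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Arrays to persist in checkpoints (parameters + running stats)."""
        return {}


# ---------------------------------------------------------------------------
# im2col helpers (kernel 3, stride 1, pad 1 keeps the spatial size)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    B, C, D, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    col = win.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(B, C * k ** 3, D * H * W)
    return np.ascontiguousarray(col)


def _col2im(dcol: np.ndarray, shape: tuple[int, ...], k: int, pad: int) -> np.ndarray:
    B, C, D, H, W = shape
    dxp = np.zeros((B, C, D + 2 * pad, H + 2 * pad, W + 2 * pad), dtype=dcol.dtype)
    dcol = dcol.reshape(B, C, k, k, k, D, H, W)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                dxp[:, :, a:a + D, b:b + H, c:c + W] += dcol[:, :, a, b, c]
    if pad:
        return dxp[:, :, pad:pad + D, pad:pad + H, pad:pad + W]
    return dxp


class Conv3d(Layer):
    """3^3 convolution, stride 1, pad 1 (spatial size preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 init_scale: float | None = None):
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 27
        std = init_scale if init_scale is not None else np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(c_out, fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        B, C, D, H, W = x.shape
        self._col = _im2col(x, 3, 1)
        y = self.W @ self._col  # (c_out, fan_in) @ (B, fan_in, P) -> (B, c_out, P)
        y += self.b[None, :, None]
        return y.reshape(B, self.c_out, D, H, W)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, _, D, H, W = grad.shape
        g = grad.reshape(B, self.c_out, D * H * W)
        self.dW += np.einsum("bop,bip->oi", g, self._col, optimize=True)
        self.db += g.sum(axis=(0, 2))
        dcol = self.W.T @ g  # (B, fan_in, P)
        self._col = None
        return _col2im(dcol, self._shape, 3, 1)

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state(self):
        return {"W": self.W, "b": self.b}


class MaxPool3d(Layer):
    """Non-overlapping 2^3 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"MaxPool3d needs even spatial dims, got {x.shape}")
        d, h, w = D // 2, H // 2, W // 2
        xr = (x.reshape(B, C, d, 2, h, 2, w, 2)
               .transpose(0, 1, 2, 4, 6, 3, 5, 7)
               .reshape(B, C, d * h * w, 8))
        self._argmax = xr.argmax(axis=3)
        self._inshape = x.shape
        out = np.take_along_axis(xr, self._argmax[..., None], axis=3)[..., 0]
        return out.reshape(B, C, d, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, D, H, W = self._inshape
        d, h, w = D // 2, H // 2, W // 2
        g = np.zeros((B, C, d * h * w, 8), dtype=grad.dtype)
        np.put_along_axis(g, self._argmax[..., None],
                          grad.reshape(B, C, d * h * w, 1), axis=3)
        return (g.reshape(B, C, d, h, w, 2, 2, 2)
                 .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                 .reshape(B, C, D, H, W))

    # inverse of the forward transpose: (B,C,d,h,w,2,2,2) -> (B,C,d,2,h,2,w,2)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1, 1)
        self._std = np.sqrt(var + self.eps).astype(F32)
        self._xhat = (x - mean.reshape(shape)) / self._std.reshape(shape)
        return (self.gamma.reshape(shape) * self._xhat
                + self.beta.reshape(shape)).astype(F32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.dgamma += (grad * self._xhat).sum(axis=axes)
        self.dbeta += grad.sum(axis=axes)
        if not self.training:
            return grad * (self.gamma / self._std).reshape(shape)
        n = grad.size // grad.shape[1]
        gxh = (grad * self._xhat).mean(axis=axes).reshape(shape)
        gm = grad.mean(axis=axes).reshape(shape)
        dx = (self.gamma.reshape(shape) / self._std.reshape(shape)
              * (grad - gm - self._xhat * gxh))
        return dx.astype(F32)

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # clip keeps exp in float32 range
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y.astype(F32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state(self):
        return {"W": self.W, "b": self.b}


class ResidualBlock3d(Layer):
    """Pre-activation residual block: x + conv(relu(bn(conv(relu(bn(x)))))).

    With zero weights in the second convolution the block is an exact
    identity, so a freshly stacked residual stage starts near identity and
    deepens the network without degrading the signal.
    """

    def __init__(self, c: int, rng: np.random.Generator):
        self.layers = [BatchNorm3d(c), ReLU(), Conv3d(c, c, rng),
                       BatchNorm3d(c), ReLU(), Conv3d(c, c, rng, init_scale=1e-3)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers:
            layer.training = self.training
            h = layer.forward(h)
        return x + h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return grad + g

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"sub{i}.{k}"] = v
        return out


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            layer.training = self.training
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"layer{i}.{k}"] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state()
        if set(own) != set(state):
            raise ValueError("checkpoint does not match network architecture")
        for key, arr in state.items():
            own[key][...] = arr

    def train(self) -> "Sequential":
        self.training = True
        return self

    def eval(self) -> "Sequential":
        self.training = False
        return self


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adaptive-moment optimizer; lr=0 leaves parameters exactly unchanged."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f at x (testing utility)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
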