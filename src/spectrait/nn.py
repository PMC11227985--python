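"""Small NumPy neural-network kernel for the 1-D DCGAN.

Implements exactly the layers the adversarial spectrum generator needs —
dense, strided 1-D convolution, fractional-stride (transposed) 1-D
convolution, batch normalization, ReLU / LeakyReLU / sigmoid — with
hand-written backward passes and an Adam optimizer.  Shapes follow the
(batch, channels, length) convention.  All computation is float64 and
fully deterministic for a given RNG.
"""

from __future__ import annotations

import numpy as np

EPS_BN = 1e-5


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_sd: float = 0.02) -> None:
        super().__init__()
        self.params = {"W": rng.normal(0, init_sd, size=(n_in, n_out)),
                       "b": np.zeros(n_out)}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["W"].T


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


def _conv_windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, L_out, k) strided view of a padded (N, C, Lp) array."""
    w = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    return w[:, :, ::stride, :]


class Conv1d(Layer):
    """Strided 1-D convolution (cross-correlation), 'same-halving' geometry:
    kernel 4, stride 2, pad 1 maps length L -> L/2."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, pad: int = 1,
                 init_sd: float = 0.02) -> None:
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = {"W": rng.normal(0, init_sd, size=(c_out, c_in, kernel)),
                       "b": np.zeros(c_out)}

    def forward(self, x, train=True):
        self._x_shape = x.shape
        N = x.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = _conv_windows(xp, self.kernel, self.stride)     # N,C,L_out,k
        self._L_out = win.shape[2]
        # contiguous (N*L_out, C*k) so the contraction is a single matmul
        self._w2 = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            N * self._L_out, -1)
        C_out = self.params["W"].shape[0]
        out = self._w2 @ self.params["W"].reshape(C_out, -1).T
        return (out.reshape(N, self._L_out, C_out).transpose(0, 2, 1)
                + self.params["b"][None, :, None])

    def backward(self, grad):
        N, C, L = self._x_shape
        C_out = self.params["W"].shape[0]
        L_out = self._L_out
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(N * L_out, C_out)
        self.grads = {
            "W": (g2.T @ self._w2).reshape(self.params["W"].shape),
            "b": grad.sum(axis=(0, 2)),
        }
        dwin = (g2 @ self.params["W"].reshape(C_out, -1)).reshape(
            N, L_out, C, self.kernel)
        dxp = np.zeros((N, C, L + 2 * self.pad))
        starts = np.arange(L_out) * self.stride
        for k in range(self.kernel):
            dxp[:, :, starts + k] += dwin[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, self.pad: self.pad + L]


class ConvTranspose1d(Layer):
    """Fractional-stride 1-D convolution; kernel 4, stride 2, pad 1 maps
    length L -> 2L (the mirror of :class:`Conv1d`)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, pad: int = 1,
                 init_sd: float = 0.02) -> None:
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = {"W": rng.normal(0, init_sd, size=(c_in, c_out, kernel)),
                       "b": np.zeros(c_out)}

    def _out_len(self, L_in: int) -> int:
        return (L_in - 1) * self.stride - 2 * self.pad + self.kernel

    def forward(self, x, train=True):
        N, C_in, L_in = x.shape
        W = self.params["W"]
        C_out = W.shape[1]
        L_out = self._out_len(L_in)
        self._x2 = np.ascontiguousarray(x.transpose(0, 2, 1)).reshape(N * L_in, C_in)
        # every (output channel, kernel tap) contribution in one matmul
        out_all = (self._x2 @ W.reshape(C_in, C_out * self.kernel)).reshape(
            N, L_in, C_out, self.kernel)
        yp = np.zeros((N, C_out, L_out + 2 * self.pad))
        starts = np.arange(L_in) * self.stride
        for k in range(self.kernel):
            yp[:, :, starts + k] += out_all[:, :, :, k].transpose(0, 2, 1)
        self._shape_in = (N, C_in, L_in)
        y = yp[:, :, self.pad: self.pad + L_out]
        return y + self.params["b"][None, :, None]

    def backward(self, grad):
        N, C_in, L_in = self._shape_in
        W = self.params["W"]
        C_out = W.shape[1]
        gp = np.pad(grad, ((0, 0), (0, 0), (self.pad, self.pad)))
        starts = np.arange(L_in) * self.stride
        gwin = np.empty((N, L_in, C_out, self.kernel))
        for k in range(self.kernel):
            gwin[:, :, :, k] = gp[:, :, starts + k].transpose(0, 2, 1)
        g2 = gwin.reshape(N * L_in, C_out * self.kernel)
        self.grads = {
            "W": (self._x2.T @ g2).reshape(W.shape),
            "b": grad.sum(axis=(0, 2)),
        }
        dx = (g2 @ W.reshape(C_in, -1).T).reshape(N, L_in, C_in).transpose(0, 2, 1)
        return np.ascontiguousarray(dx)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1) -> None:
        super().__init__()
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=True):
        axes = (0,) if x.ndim == 2 else (0, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1) if x.ndim == 2 else (1, -1, 1)
        self._xhat = (x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + EPS_BN)
        self._var = var
        self._axes = axes
        self._m = x.shape[0] if x.ndim == 2 else x.shape[0] * x.shape[2]
        return self.params["gamma"].reshape(shape) * self._xhat + self.params["beta"].reshape(shape)

    def backward(self, grad):
        shape = (1, -1) if grad.ndim == 2 else (1, -1, 1)
        axes, m = self._axes, self._m
        self.grads = {"gamma": (grad * self._xhat).sum(axis=axes),
                      "beta": grad.sum(axis=axes)}
        g = grad * self.params["gamma"].reshape(shape)
        inv_sd = 1.0 / np.sqrt(self._var.reshape(shape) + EPS_BN)
        return inv_sd / m * (
            m * g
            - g.sum(axis=axes).reshape(shape)
            - self._xhat * (g * self._xhat).sum(axis=axes).reshape(shape)
        )


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state(self) -> list[dict]:
        out = []
        for layer in self.layers:
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm1d):
                d["running_mean"] = layer.running_mean.copy()
                d["running_var"] = layer.running_var.copy()
            out.append(d)
        return out

    def load_state(self, state: list[dict]) -> None:
        for layer, d in zip(self.layers, state):
            for k in layer.params:
                layer.params[k] = d[k].copy()
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = d["running_mean"].copy()
                layer.running_var = d["running_var"].copy()


class Adam:
    def __init__(self, net: Sequential, lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                  for lay in net.layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                  for lay in net.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, lay in enumerate(self.net.layers):
            for k, g in lay.grads.items():
                self.m[i][k] = b1 * self.m[i][k] + (1 - b1) * g
                self.v[i][k] = b2 * self.v[i][k] + (1 - b2) * g * g
                mhat = self.m[i][k] / (1 - b1 ** self.t)
                vhat = self.v[i][k] / (1 - b2 ** self.t)
                lay.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss_and_grad(p: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on sigmoid probabilities against a constant label.

    Returns (mean loss, dL/dp).  The gradient is exact; the loss value clips
    p away from {0,1} only for the log.
    """
    p = np.asarray(p)
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    loss = float(np.mean(-(target * np.log(pc) + (1 - target) * np.log(1 - pc))))
    grad = (pc - target) / (pc * (1 - pc)) / p.size
    return loss, grad
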