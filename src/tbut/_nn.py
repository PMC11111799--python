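"""Minimal CPU neural-network layer stack used by the tiny Siamese backbone.

Implements exactly the pieces the compact convolutional encoder needs --
same-padding 3x3 convolution (im2col), ReLU, 2x2 max pooling, global average
pooling, fully-connected layers -- plus Adam and a step-decay learning-rate
schedule.  Forward passes cache what the backward pass needs; gradients
*accumulate* into ``.grad`` so a weight-shared (Siamese) network can backprop
both branches through one parameter set before stepping.

All tensors are float32 NCHW numpy arrays (single precision is plenty for
this scale and twice as fast on CPU); everything is deterministic given the
initialisation RNG.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

DTYPE = np.float32


class Parameter:
    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state that must be (de)serialised with the weights."""
        return []

    def set_training(self, mode: bool) -> None:
        self.training = mode

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W), zero-padded by 1 -> (N*H*W, C*9) patch matrix for 3x3 kernels."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, h, w, 3, 3), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding, He-initialised."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = Parameter(rng.normal(0.0, scale, size=(c_out, c_in * 9)))
        self.b = Parameter(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self._x_shape: Optional[tuple] = None
        self._cols: Optional[np.ndarray] = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x)
        self._x_shape, self._cols = x.shape, cols
        out = cols @ self.w.value.T + self.b.value
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.w.grad += dy_flat.T @ self._cols
        self.b.grad += dy_flat.sum(axis=0)
        # dX = "full" correlation of dy with spatially flipped kernels
        wk = self.w.value.reshape(self.c_out, self.c_in, 3, 3)
        wk_flip = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, self.c_out * 9)
        cols_dy = _im2col(dy)  # (n*h*w, c_out*9)
        dx = cols_dy @ wk_flip.T
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (inputs must have even H, W)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class BatchNorm1d(Layer):
    """Per-feature batch normalisation with running statistics for inference.

    Normalising the pooled encoder features keeps the embedding components at
    unit scale, which is what lets the sigmoid head calibrate within short
    low-learning-rate schedules.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._initialized = False

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            # seed the running stats from the first batch so short schedules
            # are not dominated by the (0, 1) initialisation
            m = 1.0 if not self._initialized else self.momentum
            self._initialized = True
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._invstd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        self.dgamma_dbeta(dy)
        if not self.training:
            return dy * self.gamma.value * self._invstd
        s1 = dy.sum(axis=0)
        s2 = (dy * self._xhat).sum(axis=0)
        return (self.gamma.value * self._invstd / n) * (n * dy - s1 - self._xhat * s2)

    def dgamma_dbeta(self, dy: np.ndarray) -> None:
        self.gamma.grad += (dy * self._xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(d_out, d_in)))
        self.b = Parameter(np.zeros(d_out))

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers for b in layer.buffers()]

    def set_training(self, mode: bool) -> None:
        for layer in self.layers:
            layer.set_training(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class StepLR:
    """Multiply the learning rate by ``gamma`` every ``step_size`` epochs."""

    def __init__(self, optimizer: Adam, step_size: int = 10, gamma: float = 0.5):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self.epoch = 0
        self._base_lr = optimizer.lr

    def step(self) -> None:
        self.epoch += 1
        self.optimizer.lr = self._base_lr * self.gamma ** (self.epoch // self.step_size)
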