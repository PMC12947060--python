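"""Minimal NumPy layers with explicit backpropagation.

Only what the residual U-Net needs: 3x3 convolutions (stride 1 or 2, zero
padding), 2x2 stride-2 transposed convolutions, batch normalisation and ReLU.
Arrays are float32 in channels-last layout (batch, height, width, channels);
convolutions are evaluated as k*k shifted matrix products, which avoids the
im2col copy and is the fastest pure-NumPy formulation at these sizes.  Each
layer owns ``params`` / ``grads`` dicts and caches what its backward pass
needs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ConvTranspose2x2", "BatchNorm2d", "ReLU", "Layer"]


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, zero padding k//2, stride 1 or 2 (output size
    ceil(H/stride)).  Weights are stored (k, k, c_in, c_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        self.params["W"] = (
            rng.standard_normal((kernel, kernel, c_in, c_out)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        k, s = self.k, self.stride
        p = k // 2
        B, H, W, C = x.shape
        Ho = -(-H // s)
        Wo = -(-W // s)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        Wt = self.params["W"]
        y = np.zeros((B, Ho, Wo, self.c_out), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                y += xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] @ Wt[i, j]
        y += self.params["b"]
        self._cache = (xp, (B, H, W, C), (Ho, Wo))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (B, H, W, C), (Ho, Wo) = self._cache
        k, s = self.k, self.stride
        p = k // 2
        Wt = self.params["W"]
        dW = np.empty_like(Wt)
        dy_flat = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + s * Ho:s, j:j + s * Wo:s, :]
                dW[i, j] = patch.reshape(-1, C).T @ dy_flat
        self.grads["W"] = dW
        self.grads["b"] = dy_flat.sum(axis=0)
        self._cache = None
        if s == 1:
            # dx is a full correlation of dy with the flipped kernel: read
            # shifted windows of padded dy instead of scattering into dxp
            dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
            dx = np.zeros((B, H, W, C), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    dx += dyp[:, 2 * p - i:2 * p - i + H, 2 * p - j:2 * p - j + W, :] @ Wt[i, j].T
            return dx
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + s * Ho:s, j:j + s * Wo:s, :] += dy @ Wt[i, j].T
        return dxp[:, p:p + H, p:p + W, :]


class ConvTranspose2x2(Layer):
    """2x2 stride-2 transposed convolution: doubles the spatial dimensions
    with non-overlapping output blocks.  Weights (c_in, 2, 2, c_out)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = (
            rng.standard_normal((c_in, 2, 2, c_out)) * np.sqrt(2.0 / c_in)
        ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        B, H, W, C = x.shape
        F = self.c_out
        y = x.reshape(-1, C) @ self.params["W"].reshape(C, 4 * F)
        y = y.reshape(B, H, W, 2, 2, F).transpose(0, 1, 3, 2, 4, 5).reshape(B, 2 * H, 2 * W, F)
        self._x = x
        return (y + self.params["b"]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        B, H, W, C = x.shape
        F = self.c_out
        dy6 = dy.reshape(B, H, 2, W, 2, F).transpose(0, 1, 3, 2, 4, 5).reshape(-1, 4 * F)
        self.grads["W"] = (x.reshape(-1, C).T @ dy6).reshape(C, 2, 2, F)
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        dx = (dy6 @ self.params["W"].reshape(C, 4 * F).T).reshape(B, H, W, C)
        self._x = None
        return dx.astype(np.float32)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape) if training else None
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[1] * shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.params["gamma"]
        # standard batchnorm backward
        dx = (inv / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2), keepdims=True)
        )
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0.0).astype(np.float32)
        self._mask = None
        return dx
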