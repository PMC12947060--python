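"""Composite SSIM + masked-MAE loss and its analytic gradient.

SSIM follows the standard Gaussian-window form: local means, variances and
covariance over an 11x11 Gaussian window (sigma 1.5), constants
C1 = (0.01 L)^2 and C2 = (0.03 L)^2 on dynamic range L, averaged over valid
(fully interior) windows.  The MAE term is the mean absolute error over the
masked region m of n activated pixels.  The total training loss is
L(yhat, y) = (1 - SSIM) + MAE.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import convolve1d

__all__ = ["gaussian_kernel1d", "ssim", "masked_mae", "composite_loss", "composite_loss_and_grad"]


def gaussian_kernel1d(win_size: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = np.arange(win_size) - win_size // 2
    k = np.exp(-0.5 * (r / sigma) ** 2)
    return (k / k.sum()).astype(np.float64)


def _filt(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Separable window filtering over the last two axes (batched)."""
    y = convolve1d(x, k, axis=-2, mode="constant")
    return convolve1d(y, k, axis=-1, mode="constant")


def _valid_slice(shape, win):
    r = win // 2
    return (..., slice(r, shape[-2] - r), slice(r, shape[-1] - r))


def _ssim_terms(yhat, y, k, data_range, win_size):
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    mu_x = _filt(yhat, k)
    mu_y = _filt(y, k)
    xx = _filt(yhat * yhat, k)
    yy = _filt(y * y, k)
    xy = _filt(yhat * y, k)
    var_x = xx - mu_x**2
    var_y = yy - mu_y**2
    cov = xy - mu_x * mu_y
    A1 = 2 * mu_x * mu_y + C1
    A2 = 2 * cov + C2
    B1 = mu_x**2 + mu_y**2 + C1
    B2 = var_x + var_y + C2
    S = (A1 * A2) / (B1 * B2)
    return S, mu_x, mu_y, A1, A2, B1, B2


def ssim(
    yhat: np.ndarray,
    y: np.ndarray,
    data_range: float = 1.0,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float | np.ndarray:
    """Mean SSIM over valid windows.  Accepts 2D images or batches
    (..., H, W); batched input returns one value per leading index."""
    yhat = np.asarray(yhat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if yhat.shape != y.shape:
        raise ValueError("shapes must match")
    if min(yhat.shape[-2:]) < win_size:
        raise ValueError(f"images smaller than the {win_size}x{win_size} SSIM window")
    k = gaussian_kernel1d(win_size, sigma)
    S = _ssim_terms(yhat, y, k, data_range, win_size)[0]
    Sv = S[_valid_slice(yhat.shape, win_size)]
    out = Sv.mean(axis=(-2, -1))
    return float(out) if out.ndim == 0 else out


def masked_mae(yhat: np.ndarray, y: np.ndarray, m: np.ndarray) -> float | np.ndarray:
    """Mean absolute error over the masked region m (per leading index for
    batched input).  Raises on an empty mask."""
    m = np.asarray(m, dtype=bool)
    if yhat.shape != y.shape or m.shape != yhat.shape:
        raise ValueError("shapes must match")
    n = m.sum(axis=(-2, -1))
    if np.any(n == 0):
        raise ValueError("empty mask: MAE over m is undefined")
    err = (np.abs(yhat - y) * m).sum(axis=(-2, -1)) / n
    return float(err) if np.ndim(err) == 0 else err


def composite_loss(
    yhat: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    data_range: float = 1.0,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """(1 - SSIM) + masked MAE, averaged over the batch.  An all-empty mask
    degenerates to the SSIM term only (with a warning)."""
    m = np.asarray(m, dtype=bool)
    s = ssim(yhat, y, data_range, win_size, sigma)
    n = m.sum(axis=(-2, -1))
    if np.all(n == 0):
        warnings.warn("empty loss mask: using the SSIM term only", stacklevel=2)
        mae = 0.0
    else:
        safe_n = np.maximum(n, 1)
        mae = (np.abs(yhat - y) * m).sum(axis=(-2, -1)) / safe_n
    return float(np.mean((1.0 - s) + mae))


def composite_loss_and_grad(
    yhat: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    data_range: float = 1.0,
    win_size: int = 11,
    sigma: float = 1.5,
):
    """Batch loss and its gradient with respect to ``yhat``.

    ``yhat``, ``y``: (B, H, W); ``m``: boolean (B, H, W).  Returns
    (loss: float, grad: (B, H, W) float32).
    """
    yhat = np.asarray(yhat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m = np.asarray(m, dtype=bool)
    B, H, W = yhat.shape
    k = gaussian_kernel1d(win_size, sigma)
    S, mu_x, mu_y, A1, A2, B1, B2 = _ssim_terms(yhat, y, k, data_range, win_size)

    r = win_size // 2
    valid = np.zeros((H, W), dtype=bool)
    valid[r:H - r, r:W - r] = True
    n_valid = valid.sum()
    Sv = np.where(valid, S, 0.0)
    ssim_per = Sv.sum(axis=(-2, -1)) / n_valid

    # dS/d(mu_x), dS/d(var_x), dS/d(cov), restricted to valid windows
    dS_dmu = np.where(valid, 2 * mu_y * A2 / (B1 * B2) - S * 2 * mu_x / B1, 0.0)
    dS_dvar = np.where(valid, -S / B2, 0.0)
    dS_dcov = np.where(valid, 2 * A1 / (B1 * B2), 0.0)

    # spread window-level terms back to pixels (Gaussian kernel is symmetric,
    # so correlation == convolution)
    g_ssim = (
        _filt(dS_dmu, k)
        + 2 * yhat * _filt(dS_dvar, k)
        - 2 * _filt(mu_x * dS_dvar, k)
        + y * _filt(dS_dcov, k)
        - _filt(mu_y * dS_dcov, k)
    ) / n_valid

    n = m.sum(axis=(-2, -1))
    safe_n = np.maximum(n, 1)
    mae_per = (np.abs(yhat - y) * m).sum(axis=(-2, -1)) / safe_n
    g_mae = np.sign(yhat - y) * m / safe_n[:, None, None]

    loss = float(np.mean((1.0 - ssim_per) + mae_per))
    grad = (-g_ssim + g_mae) / B
    return loss, grad.astype(np.float32)
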