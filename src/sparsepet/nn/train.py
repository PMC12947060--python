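"""Adam optimiser and the training loop.

Training follows the study protocol: Adam at initial learning rate 1e-3 with
a staircase exponential decay of 0.96 per epoch, batches of 64 sinograms,
at most 200 epochs, early stopping after 20 epochs without validation-loss
improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .loss import composite_loss, composite_loss_and_grad
from .unet import ResidualUNet

__all__ = ["TrainConfig", "Adam", "train", "batches_per_epoch"]


@dataclass
class TrainConfig:
    lr0: float = 1e-3
    decay_rate: float = 0.96  # staircase, applied once per epoch
    max_epochs: int = 200
    batch_size: int = 64
    patience: int = 20
    seed: int = 0
    ssim_win: int = 11
    ssim_sigma: float = 1.5

    def __post_init__(self) -> None:
        if min(self.lr0, self.decay_rate, self.max_epochs, self.batch_size, self.patience) <= 0:
            raise ValueError("all training parameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def batches_per_epoch(n_train: int, batch_size: int) -> int:
    return math.ceil(n_train / batch_size)


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k].astype(np.float32)
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)


def train(
    model: ResidualUNet,
    train_x: np.ndarray,
    train_y: np.ndarray,
    train_m: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    val_m: np.ndarray,
    cfg: TrainConfig,
    verbose: bool = False,
):
    """Train on normalised (x, y, mask) plane arrays; returns (model, history).

    History is a list of dicts (epoch, train_loss, val_loss, lr).  Training
    stops at max_epochs or when the validation loss has not improved for
    ``patience`` consecutive epochs.  Diverging (non-finite) loss aborts.
    """
    n = train_x.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.layers(), lr=cfg.lr0)
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(cfg.max_epochs):
        lr = cfg.lr0 * cfg.decay_rate**epoch
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            yhat = model.forward(train_x[idx], training=True)
            loss, grad = composite_loss_and_grad(
                yhat, train_y[idx], train_m[idx],
                win_size=cfg.ssim_win, sigma=cfg.ssim_sigma,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            model.backward(grad)
            opt.step()
            losses.append(loss)
        yhat_val = model.predict(val_x, batch_size=cfg.batch_size)
        val_loss = composite_loss(
            yhat_val, val_y, val_m, win_size=cfg.ssim_win, sigma=cfg.ssim_sigma
        )
        history.append(
            dict(epoch=epoch, train_loss=float(np.mean(losses)), val_loss=float(val_loss), lr=lr)
        )
        if verbose:
            print(f"epoch {epoch:3d}  train {np.mean(losses):.4f}  val {val_loss:.4f}  lr {lr:.2e}")
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history
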