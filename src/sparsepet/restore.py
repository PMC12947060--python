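"""Sinogram restoration: normalisation, the fitted restorer, copy-through.

Each sinogram plane is normalised to [0, 1] by its own maximum before entering
the network and denormalised by the same factor afterwards; the training
target is scaled by the *input's* factor, so the network can learn to rescale
whole planes whose counts are attenuated (the summed ring-difference-1 cross
planes).  After denormalisation, pixels not affected by the removed detectors
are copied bit-exactly from the input, and the output is clipped to be
non-negative.
"""

from __future__ import annotations

import numpy as np

from .binning import BinMask, SinogramStack
from .nn import NetConfig, ResidualUNet, TrainConfig, build_network
from .nn import train as nn_train

__all__ = ["normalize", "denormalize", "SinogramRestorer", "restore_stack"]


def normalize(planes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each plane to [0, 1] by its maximum.

    Returns (scaled, factors); all-zero planes get factor 1 (identity).
    Negative input is rejected.
    """
    planes = np.asarray(planes, dtype=np.float64)
    if np.any(planes < 0):
        raise ValueError("sinogram values must be non-negative")
    single = planes.ndim == 2
    if single:
        planes = planes[None]
    factors = planes.max(axis=(-2, -1))
    factors = np.where(factors > 0, factors, 1.0)
    scaled = planes / factors[:, None, None]
    if single:
        return scaled[0], factors[0]
    return scaled, factors


def denormalize(planes: np.ndarray, factors: np.ndarray) -> np.ndarray:
    planes = np.asarray(planes, dtype=np.float64)
    if planes.ndim == 2:
        return planes * factors
    return planes * np.asarray(factors)[:, None, None]


class SinogramRestorer:
    """Residual U-Net sinogram restorer with a scikit-learn-style interface.

    Parameters mirror NetConfig and TrainConfig.  ``fit`` takes distorted
    planes X, original planes y and the boolean affected mask m (all
    (N, H, W)); ``transform`` restores distorted planes.  Fitted state lives
    in trailing-underscore attributes (``model_``, ``history_``).
    """

    def __init__(
        self,
        depth: int = 4,
        base_filters: int = 32,
        res_blocks_per_level: tuple[int, ...] = (1, 2, 3, 4),
        lr0: float = 1e-3,
        decay_rate: float = 0.96,
        max_epochs: int = 200,
        batch_size: int = 64,
        patience: int = 20,
        seed: int = 0,
        validation_fraction: float = 0.15,
    ) -> None:
        self.depth = depth
        self.base_filters = base_filters
        self.res_blocks_per_level = res_blocks_per_level
        self.lr0 = lr0
        self.decay_rate = decay_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.seed = seed
        self.validation_fraction = validation_fraction

    # sklearn parameter plumbing -------------------------------------------

    _param_names = (
        "depth", "base_filters", "res_blocks_per_level", "lr0", "decay_rate",
        "max_epochs", "batch_size", "patience", "seed", "validation_fraction",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "SinogramRestorer":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------

    def _net_config(self) -> NetConfig:
        return NetConfig(self.depth, self.base_filters, tuple(self.res_blocks_per_level))

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr0=self.lr0, decay_rate=self.decay_rate, max_epochs=self.max_epochs,
            batch_size=self.batch_size, patience=self.patience, seed=self.seed,
        )

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        m: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        m_val: np.ndarray | None = None,
    ) -> "SinogramRestorer":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        m = np.asarray(m, dtype=bool)
        if X.shape != y.shape or X.shape != m.shape or X.ndim != 3:
            raise ValueError("X, y, m must be aligned (N, H, W) arrays")
        xn, f = normalize(X)
        yn = y / f[:, None, None]
        if X_val is None:
            # hold out a deterministic tail as the validation split
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(X.shape[0])
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            vi, ti = order[:n_val], order[n_val:]
            xv, yv, mv = xn[vi], yn[vi], m[vi]
            xn, yn, m = xn[ti], yn[ti], m[ti]
        else:
            xv, fv = normalize(np.asarray(X_val, dtype=np.float64))
            yv = np.asarray(y_val, dtype=np.float64) / fv[:, None, None]
            mv = np.asarray(m_val, dtype=bool)
        model = build_network(self._net_config(), seed=self.seed)
        model, history = nn_train(
            model,
            xn.astype(np.float32), yn.astype(np.float32), m,
            xv.astype(np.float32), yv.astype(np.float32), mv,
            self._train_config(),
        )
        self.model_: ResidualUNet = model
        self.history_: list[dict] = history
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X: np.ndarray, m: np.ndarray) -> np.ndarray:
        """Restore distorted planes; unaffected pixels (m false) are copied
        from the input bit-exactly and the output is clipped to >= 0."""
        if not hasattr(self, "model_"):
            raise RuntimeError("SinogramRestorer is not fitted")
        X = np.asarray(X, dtype=np.float64)
        m = np.asarray(m, dtype=bool)
        if X.shape != m.shape:
            raise ValueError("mask shape mismatch")
        single = X.ndim == 2
        if single:
            X, m = X[None], m[None]
        xn, f = normalize(X)
        pred = self.model_.predict(xn.astype(np.float32), batch_size=self.batch_size)
        out = denormalize(pred.astype(np.float64), f)
        out = np.clip(out, 0.0, None)
        out[~m] = X[~m]  # copy-through
        return out[0] if single else out

    def fit_transform(self, X, y, m, **kw) -> np.ndarray:
        return self.fit(X, y, m, **kw).transform(X, m)


def restore_stack(
    restorer: SinogramRestorer, distorted: SinogramStack, mask: BinMask
) -> SinogramStack:
    """Apply a fitted restorer to a whole stack."""
    if mask.surviving_fraction.shape != distorted.data.shape:
        raise ValueError("bin mask shape mismatch")
    out = restorer.transform(distorted.data, mask.affected)
    return distorted.with_data(out, "restored")
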