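"""Residual U-Net for sinogram restoration.

Asymmetric encoder-decoder: each encoder level applies an increasing number
of residual blocks (convolution + batch normalisation + ReLU with a residual
connection) followed by one stride-2 convolution that halves the spatial
dimensions and doubles the channels; each decoder level applies a stride-2
transposed convolution that doubles the spatial dimensions, merges the
matching encoder feature map by addition (skip connection), and applies one
residual block.  Two final convolutions produce the single-channel output.

Inputs are reflect-padded up to the next multiple of 2**depth and the output
is cropped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import BatchNorm2d, Conv2d, ConvTranspose2x2, Layer, ReLU

__all__ = ["NetConfig", "ResidualBlock", "ResidualUNet", "build_network"]


@dataclass(frozen=True)
class NetConfig:
    depth: int = 4
    base_filters: int = 32
    res_blocks_per_level: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        if len(self.res_blocks_per_level) != self.depth:
            raise ValueError("res_blocks_per_level must have one entry per level")
        if any(b < 1 for b in self.res_blocks_per_level):
            raise ValueError("residual block counts must be >= 1")
        if any(
            a > b
            for a, b in zip(self.res_blocks_per_level, self.res_blocks_per_level[1:])
        ):
            raise ValueError("res_blocks_per_level must be non-decreasing")

    def filters(self, level: int) -> int:
        return self.base_filters * 2**level


class ResidualBlock:
    """conv-BN-ReLU-conv-BN plus identity, then ReLU.  Channel-preserving."""

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        self.conv1 = Conv2d(channels, channels, 3, rng=rng)
        self.bn1 = BatchNorm2d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng=rng)
        self.bn2 = BatchNorm2d(channels)
        self.relu_out = ReLU()

    @property
    def layers(self) -> list[Layer]:
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        return self.relu_out.forward(h + x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dh = self.conv1.backward(dh)
        return dh + d


class ResidualUNet:
    """The restoration network; operates on (B, H, W) arrays in [0, 1]-ish
    normalised units and returns arrays of the same shape."""

    def __init__(self, cfg: NetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        F = cfg.base_filters
        self.stem = Conv2d(1, F, 3, rng=rng)
        self.enc_blocks: list[list[ResidualBlock]] = []
        self.down: list[tuple[Conv2d, BatchNorm2d, ReLU]] = []
        for k in range(cfg.depth):
            ch = cfg.filters(k)
            self.enc_blocks.append(
                [ResidualBlock(ch, rng) for _ in range(cfg.res_blocks_per_level[k])]
            )
            self.down.append(
                (Conv2d(ch, cfg.filters(k + 1), 3, stride=2, rng=rng),
                 BatchNorm2d(cfg.filters(k + 1)), ReLU())
            )
        self.bottleneck = ResidualBlock(cfg.filters(cfg.depth), rng)
        self.up: list[ConvTranspose2x2] = []
        self.dec_blocks: list[ResidualBlock] = []
        for k in reversed(range(cfg.depth)):
            self.up.append(ConvTranspose2x2(cfg.filters(k + 1), cfg.filters(k), rng=rng))
            self.dec_blocks.append(ResidualBlock(cfg.filters(k), rng))
        self.final1 = Conv2d(F, F, 3, rng=rng)
        self.final_relu = ReLU()
        self.final2 = Conv2d(F, 1, 3, rng=rng)

    # ---- plumbing ----------------------------------------------------------

    def layers(self) -> list[Layer]:
        out: list[Layer] = [self.stem]
        for blocks, (dc, dbn, drl) in zip(self.enc_blocks, self.down):
            for b in blocks:
                out.extend(b.layers)
            out.extend([dc, dbn, drl])
        out.extend(self.bottleneck.layers)
        for u, b in zip(self.up, self.dec_blocks):
            out.append(u)
            out.extend(b.layers)
        out.extend([self.final1, self.final_relu, self.final2])
        return out

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers() for p in layer.params.values())

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        mult = 2**self.cfg.depth
        B, H, W = x.shape
        ph = (-H) % mult
        pw = (-W) % mult
        if ph >= H or pw >= W:
            raise ValueError(
                f"input {H}x{W} too small to reflect-pad to a multiple of {mult}"
            )
        xp = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        return xp, (H, W)

    # ---- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        xp, (H, W) = self._pad(x)
        self._orig_hw = (H, W)
        self._pad_hw = xp.shape[1:]
        h = xp[..., None]
        h = self.stem.forward(h, training)
        skips = []
        for blocks, (dc, dbn, drl) in zip(self.enc_blocks, self.down):
            for b in blocks:
                h = b.forward(h, training)
            skips.append(h)
            h = drl.forward(dbn.forward(dc.forward(h, training), training), training)
        h = self.bottleneck.forward(h, training)
        for u, b, skip in zip(self.up, self.dec_blocks, reversed(skips)):
            h = u.forward(h, training)
            h = h + skip  # additive skip merge
            h = b.forward(h, training)
        h = self.final1.forward(h, training)
        h = self.final_relu.forward(h, training)
        h = self.final2.forward(h, training)
        return h[:, :H, :W, 0]

    def backward(self, dy: np.ndarray) -> None:
        H, W = self._orig_hw
        Hp, Wp = self._pad_hw
        d = np.zeros((dy.shape[0], Hp, Wp, 1), dtype=np.float32)
        d[:, :H, :W, 0] = dy
        d = self.final2.backward(d)
        d = self.final_relu.backward(d)
        d = self.final1.backward(d)
        dskips = []
        for u, b in zip(self.up[::-1], self.dec_blocks[::-1]):
            d = b.backward(d)
            dskips.append(d)  # gradient into the skip branch
            d = u.backward(d)
        d = self.bottleneck.backward(d)
        # dskips collected level 0 first; encoder unwinds from the deepest
        # level, so pair them reversed
        for blocks, (dc, dbn, drl), dskip in zip(
            self.enc_blocks[::-1], self.down[::-1], dskips[::-1]
        ):
            d = dc.backward(dbn.backward(drl.backward(d)))
            d = d + dskip
            for b in blocks[::-1]:
                d = b.backward(d)
        self.stem.backward(d)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = np.empty_like(x)
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = self.forward(x[i:i + batch_size], training=False)
        return out

    # ---- (de)serialisation ---------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers()):
            for name, p in layer.params.items():
                state[f"layer{i}/{name}"] = p
            if isinstance(layer, BatchNorm2d):
                state[f"layer{i}/running_mean"] = layer.running_mean
                state[f"layer{i}/running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i}/{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"layer{i}/running_mean"]
                layer.running_var[...] = state[f"layer{i}/running_var"]


def build_network(cfg: NetConfig, seed: int = 0) -> ResidualUNet:
    """Construct the residual U-Net for a configuration."""
    return ResidualUNet(cfg, seed=seed)
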