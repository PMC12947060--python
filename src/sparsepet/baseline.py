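"""Clough-Tocher interpolation baseline for incomplete sinograms.

Unaffected pixels act as scattered reference nodes; fully zeroed pixels are
predicted by piecewise-cubic Clough-Tocher interpolation on the reference
triangulation (nearest-reference fill outside the convex hull).  Summed
ring-difference-1 cross planes differ from the truth in *every* pixel, so no
reference points would remain: for those planes the attenuated-but-nonzero
pixels are left in place as reference points instead, which systematically
underestimates the plane's counts.  An optional global scaling factor (the
reciprocal mean surviving fraction) can boost a plane's count level; it is
off by default.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator

from .binning import BinMask, SinogramStack

__all__ = [
    "interpolate_plane",
    "global_scale_factor",
    "interpolate_stack",
    "CloughTocherSinogramInterpolator",
]


def global_scale_factor(fraction_plane: np.ndarray) -> float:
    """Count-level correction implied by uniform thinning: the reciprocal of
    the mean surviving fraction over contributing (affected or not) bins."""
    f = np.asarray(fraction_plane, dtype=np.float64)
    mean = f.mean()
    if mean <= 0:
        raise ValueError("mean surviving fraction is zero: scale factor undefined")
    return 1.0 / mean


def _scattered_fill(plane, reference, predict):
    """Clough-Tocher fill of ``predict`` pixels from ``reference`` pixels,
    nearest-reference outside the hull; constant mean fill when fewer than
    three non-collinear reference points exist."""
    out = plane.astype(np.float64).copy()
    if not predict.any():
        return out, False
    ref_idx = np.argwhere(reference)
    pred_idx = np.argwhere(predict)
    fallback = False
    if len(ref_idx) < 3 or np.linalg.matrix_rank(ref_idx - ref_idx[0]) < 2:
        fill = plane[reference].mean() if len(ref_idx) else 0.0
        out[predict] = fill
        return out, True
    vals = plane[reference].astype(np.float64)
    ct = CloughTocher2DInterpolator(ref_idx.astype(np.float64), vals)
    est = ct(pred_idx.astype(np.float64))
    bad = ~np.isfinite(est)
    if np.any(bad):
        nn = NearestNDInterpolator(ref_idx.astype(np.float64), vals)
        est[bad] = nn(pred_idx[bad].astype(np.float64))
    out[tuple(pred_idx.T)] = est
    np.clip(out, 0.0, None, out=out)
    return out, fallback


def interpolate_plane(
    plane: np.ndarray,
    fraction_plane: np.ndarray,
    mode: str = "auto",
    scaling: bool = False,
) -> np.ndarray:
    """Fill one distorted plane.

    mode 'zeroed_only': reference = unaffected pixels (fraction == 1),
    predict = affected pixels.  mode 'rd1_reference': reference = all pixels
    with surviving fraction > 0 (the attenuated low-count pixels act as
    reference points), predict = fraction == 0 pixels.  mode 'auto' selects
    'rd1_reference' when the plane contains fractional survival (the summed
    ring-difference-1 class) and 'zeroed_only' otherwise.
    """
    plane = np.asarray(plane, dtype=np.float64)
    f = np.asarray(fraction_plane, dtype=np.float64)
    if plane.shape != f.shape:
        raise ValueError("plane and mask must be aligned")
    if mode == "auto":
        fractional = np.any((f > 0) & (f < 1))
        mode = "rd1_reference" if fractional else "zeroed_only"
    if mode == "zeroed_only":
        reference = f == 1
        predict = f < 1
    elif mode == "rd1_reference":
        reference = f > 0
        predict = f == 0
    else:
        raise ValueError("mode must be 'auto', 'zeroed_only' or 'rd1_reference'")
    out, _ = _scattered_fill(plane, reference, predict)
    if scaling:
        out *= global_scale_factor(f)
    return out


def interpolate_stack(
    distorted: SinogramStack, mask: BinMask, scaling: bool = False
) -> SinogramStack:
    data = np.empty_like(distorted.data)
    for p in range(distorted.n_planes):
        data[p] = interpolate_plane(
            distorted.data[p], mask.surviving_fraction[p], "auto", scaling
        )
    return distorted.with_data(data, "interpolated")


class CloughTocherSinogramInterpolator:
    """Transform-only estimator wrapper around the interpolation baseline
    (deterministic; ``fit`` is a no-op kept for pipeline compatibility)."""

    def __init__(self, scaling: bool = False) -> None:
        self.scaling = scaling

    def get_params(self, deep: bool = True) -> dict:
        return {"scaling": self.scaling}

    def set_params(self, **params) -> "CloughTocherSinogramInterpolator":
        for k, v in params.items():
            if k != "scaling":
                raise ValueError(f"unknown parameter {k!r}")
            self.scaling = v
        return self

    def fit(self, X=None, y=None, m=None) -> "CloughTocherSinogramInterpolator":
        return self

    def transform(self, X: np.ndarray, fractions: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        fractions = np.asarray(fractions, dtype=np.float64)
        single = X.ndim == 2
        if single:
            X, fractions = X[None], fractions[None]
        out = np.stack(
            [
                interpolate_plane(x, f, "auto", self.scaling)
                for x, f in zip(X, fractions)
            ]
        )
        return out[0] if single else out
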