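"""Parallel-beam system matrix shared by the forward simulation and the
iterative reconstruction.

The projector works in sinogram-bin units: radial bins are unit-width, views
are the interleaved crystal-pair views of :mod:`sparsepet.binning` (view v
has normal angle pi*(2v - n/2)/n).  Lines are sampled at half-pixel steps
with bilinear interpolation, assembled once into a sparse CSR matrix
(bins x pixels) whose exact transpose serves as the back projector.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse

__all__ = ["system_matrix", "view_normal_angles"]


def view_normal_angles(n_crystals_per_ring: int, n_angles: int | None = None) -> np.ndarray:
    """Normal angle of each interleaved view (radians)."""
    n = n_crystals_per_ring
    if n_angles is None:
        n_angles = n // 2
    v = np.arange(n_angles)
    return np.pi * (2 * v - n // 2) / n


@lru_cache(maxsize=8)
def system_matrix(
    n_radial: int,
    n_crystals_per_ring: int,
    n_pixels: int,
    step: float = 0.5,
) -> sparse.csr_matrix:
    """CSR matrix A with shape (n_radial * n_angles, n_pixels**2).

    The image grid spans the radial field of view: pixel width =
    n_radial / n_pixels radial-bin units.  Row ordering is radial-major
    (bin = radial * n_angles + view), matching SinogramStack planes raveled
    in C order.
    """
    n_angles = n_crystals_per_ring // 2
    gammas = view_normal_angles(n_crystals_per_ring, n_angles)
    half = n_radial // 2
    px = n_radial / n_pixels  # radial-bin units per pixel
    # pixel centre coordinates in radial-bin units, origin at image centre
    centre = (n_pixels - 1) / 2.0

    track_len = n_radial * 1.5
    n_steps = int(np.ceil(track_len / (step * px)))
    t = (np.arange(n_steps) - (n_steps - 1) / 2.0) * step * px  # bin units

    rows, cols, vals = [], [], []
    for v, gamma in enumerate(gammas):
        nx, ny = np.cos(gamma), np.sin(gamma)
        dx, dy = -ny, nx  # line direction
        for q in range(-half, half + 1):
            # sample points in bin units -> pixel indices
            xs = q * nx + t * dx
            ys = q * ny + t * dy
            fx = xs / px + centre
            fy = ys / px + centre
            ix = np.floor(fx).astype(np.int64)
            iy = np.floor(fy).astype(np.int64)
            wx = fx - ix
            wy = fy - iy
            row = (q + half) * n_angles + v
            for ox, oy, w in (
                (0, 0, (1 - wx) * (1 - wy)),
                (1, 0, wx * (1 - wy)),
                (0, 1, (1 - wx) * wy),
                (1, 1, wx * wy),
            ):
                px_i = ix + ox
                py_i = iy + oy
                ok = (px_i >= 0) & (px_i < n_pixels) & (py_i >= 0) & (py_i < n_pixels) & (w > 0)
                if not np.any(ok):
                    continue
                rows.append(np.full(ok.sum(), row, dtype=np.int64))
                cols.append((px_i[ok] * n_pixels + py_i[ok]).astype(np.int64))
                vals.append(w[ok] * step * px)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_radial * n_angles, n_pixels * n_pixels),
    )
    return A.tocsr()
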