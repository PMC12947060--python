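"""Synthetic phantoms and original/distorted sinogram pairs.

Stands in for clinical pelvis acquisitions: each phantom is an ellipse-based
3D activity map with a smooth textured background, one compact high-uptake
("bladder-like") region and at least one cold region, projected to the
Michelogram plane scheme and Poisson-sampled.  Detector cancellation is
applied by per-bin binomial thinning with the bin mask's surviving fractions,
which is exact in distribution for independent Poisson counts per line of
response; a per-LOR event path exists for small geometries as the validation
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinMask, MichelogramScheme, SinogramStack, default_n_radial
from .geometry import ChessboardPattern, ScannerGeometry
from .projector import system_matrix

__all__ = [
    "Phantom",
    "SimulationConfig",
    "REDUCED_GEOMETRY",
    "generate_phantom",
    "project_to_sinograms",
    "sample_counts_and_distort",
    "simulate_dataset",
]

#: Reduced test-scale geometry (33 radial x 32 angles, 241 planes).
REDUCED_GEOMETRY = ScannerGeometry(
    n_rings=16, n_crystals_per_ring=64, crystal_pitch_transaxial=4.0,
    crystal_pitch_axial=5.3, ring_radius=80.0,
)

LABEL_OUTSIDE, LABEL_BACKGROUND, LABEL_HOT, LABEL_COLD = 0, 1, 2, 3


@dataclass
class Phantom:
    """Activity map (slice, x, y) with an integer ROI label map.

    Labels: 0 outside the body, 1 background, 2 high-uptake ("bladder-like"),
    3 cold.
    """

    activity: np.ndarray
    labels: np.ndarray
    voxel_size: float = 4.0

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.activity.shape != self.labels.shape:
            raise ValueError("labels must align with activity")
        if np.any(self.activity < 0):
            raise ValueError("activity must be non-negative")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    ``count_level`` is the mean expected total counts per direct plane; the
    default keeps affected-bin means at O(1-10) counts, emulating typical
    injected radioactivity at the sinogram level.
    """

    n_phantoms: int = 3
    count_level: float = 2.0e4
    seed: int = 0
    n_pixels: int = 64
    hot_contrast: float = 6.0
    voxel_size: float = 4.0
    geometry: ScannerGeometry = field(default_factory=lambda: REDUCED_GEOMETRY)
    pattern: ChessboardPattern = field(default_factory=ChessboardPattern)

    def __post_init__(self) -> None:
        if self.count_level <= 0:
            raise ValueError("count_level must be > 0")
        if self.n_phantoms < 1:
            raise ValueError("n_phantoms must be >= 1")

    @property
    def scheme(self) -> MichelogramScheme:
        return MichelogramScheme(self.geometry.n_rings)

    @property
    def n_radial(self) -> int:
        return default_n_radial(self.geometry.n_crystals_per_ring)


def _ellipsoid(zz, xx, yy, centre, semi):
    return (
        ((zz - centre[0]) / semi[0]) ** 2
        + ((xx - centre[1]) / semi[1]) ** 2
        + ((yy - centre[2]) / semi[2]) ** 2
    ) <= 1.0


def generate_phantom(config: SimulationConfig, rng: np.random.Generator) -> Phantom:
    """Seeded ellipse-based phantom.

    Body: large axially-extended ellipsoid with a smoothly varying background
    (baseline 1.0 modulated by a few broad random Gaussian blobs); one hot
    ellipsoid at ``hot_contrast`` : 1 versus background; one cold (zero
    uptake) ellipsoid.
    """
    R = config.geometry.n_rings
    npx = config.n_pixels
    z = np.arange(R, dtype=np.float64)
    x = np.arange(npx, dtype=np.float64)
    zz, xx, yy = np.meshgrid(z, x, x, indexing="ij")
    cz, cxy = (R - 1) / 2.0, (npx - 1) / 2.0

    body = _ellipsoid(zz, xx, yy, (cz, cxy, cxy), (R * 0.55, npx * 0.42, npx * 0.34))

    # smooth background texture: baseline + broad Gaussian blobs
    activity = np.ones_like(zz)
    for _ in range(4):
        c = (
            rng.uniform(0.2, 0.8) * R,
            rng.uniform(0.3, 0.7) * npx,
            rng.uniform(0.3, 0.7) * npx,
        )
        w = (rng.uniform(0.3, 0.6) * R, rng.uniform(0.15, 0.3) * npx, rng.uniform(0.15, 0.3) * npx)
        amp = rng.uniform(-0.3, 0.4)
        activity += amp * np.exp(
            -(((zz - c[0]) / w[0]) ** 2 + ((xx - c[1]) / w[1]) ** 2 + ((yy - c[2]) / w[2]) ** 2)
        )
    activity = np.clip(activity, 0.3, None)

    labels = np.where(body, LABEL_BACKGROUND, LABEL_OUTSIDE).astype(np.int16)

    # hot "bladder-like" region: compact ellipsoid near the body centre
    hot_centre = (
        cz + rng.uniform(-0.15, 0.15) * R,
        cxy + rng.uniform(-0.12, 0.12) * npx,
        cxy + rng.uniform(-0.12, 0.12) * npx,
    )
    hot_semi = (rng.uniform(0.12, 0.2) * R, rng.uniform(0.08, 0.13) * npx, rng.uniform(0.08, 0.13) * npx)
    hot = _ellipsoid(zz, xx, yy, hot_centre, hot_semi) & body
    bg_mean = activity[body].mean()
    activity[hot] = config.hot_contrast * bg_mean

    # cold region away from the hot one
    side = 1.0 if hot_centre[1] <= cxy else -1.0
    cold_centre = (
        cz + rng.uniform(-0.2, 0.2) * R,
        cxy + side * rng.uniform(0.18, 0.26) * npx,
        cxy + rng.uniform(-0.18, 0.18) * npx,
    )
    cold_semi = (rng.uniform(0.1, 0.18) * R, rng.uniform(0.05, 0.1) * npx, rng.uniform(0.05, 0.1) * npx)
    cold = _ellipsoid(zz, xx, yy, cold_centre, cold_semi) & body & ~hot
    activity[cold] = 0.0

    labels[hot] = LABEL_HOT
    labels[cold] = LABEL_COLD
    activity[~body] = 0.0
    return Phantom(activity, labels, voxel_size=config.voxel_size)


def project_to_sinograms(
    phantom: Phantom,
    geometry: ScannerGeometry,
    scheme: MichelogramScheme,
    n_radial: int | None = None,
    count_level: float | None = None,
) -> SinogramStack:
    """Noise-free expected sinograms (linear in activity).

    Direct planes project the phantom slice of their ring; oblique planes
    project the linear interpolation of the two contributing slice positions,
    weighted by the number of contributing ring-pair directions (2 for summed
    ring-difference-1 planes).  If ``count_level`` is given, the stack is
    scaled so the mean direct-plane total equals it.
    """
    n = geometry.n_crystals_per_ring
    if n_radial is None:
        n_radial = default_n_radial(n)
    if phantom.activity.shape[0] != geometry.n_rings:
        raise ValueError("phantom must have one slice per ring")
    npx = phantom.activity.shape[1]
    A = system_matrix(n_radial, n, npx)
    infos = scheme.plane_infos()
    data = np.zeros((len(infos), n_radial, n // 2), dtype=np.float64)
    # cache projections of the R ring slices
    slice_proj = np.stack(
        [
            (A @ phantom.activity[r].ravel()).reshape(n_radial, n // 2)
            for r in range(geometry.n_rings)
        ]
    )
    for p, info in enumerate(infos):
        ax = info["axial"]  # half-ring units
        if ax % 2 == 0:
            proj = slice_proj[ax // 2]
        else:
            proj = 0.5 * (slice_proj[ax // 2] + slice_proj[ax // 2 + 1])
        data[p] = len(info["ring_pairs"]) * proj
    if count_level is not None:
        direct = [p for p, i in enumerate(infos) if i["kind"] == "direct"]
        mean_total = data[direct].sum() / len(direct)
        if mean_total > 0:
            data *= count_level / mean_total
    return SinogramStack(data, scheme, provenance="expectation")


def sample_counts_and_distort(
    expectation: SinogramStack,
    bin_mask: BinMask,
    rng: np.random.Generator,
) -> tuple[SinogramStack, SinogramStack]:
    """Poisson-sample the expectation, then apply detector cancellation by
    per-bin binomial thinning with the surviving fractions."""
    if bin_mask.surviving_fraction.shape != expectation.data.shape:
        raise ValueError("bin mask shape mismatch")
    original = rng.poisson(expectation.data).astype(np.float64)
    distorted = rng.binomial(
        original.astype(np.int64), bin_mask.surviving_fraction
    ).astype(np.float64)
    return (
        SinogramStack(original, expectation.scheme, "original"),
        SinogramStack(distorted, expectation.scheme, "distorted"),
    )


def simulate_dataset(
    config: SimulationConfig,
    bin_mask: BinMask,
    rng: np.random.Generator | None = None,
):
    """Generate ``n_phantoms`` phantom/original/distorted triples."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_phantoms):
        ph = generate_phantom(config, rng)
        exp = project_to_sinograms(
            ph, config.geometry, config.scheme, config.n_radial, config.count_level
        )
        orig, dist = sample_counts_and_distort(exp, bin_mask, rng)
        out.append((ph, orig, dist))
    return out
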