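"""Shared fixtures.

The expensive end-to-end benchmark (generate -> train -> restore ->
interpolate on the reduced 16-ring geometry) runs once per session; the
acceptance tests and several unit tests share its artefacts.
"""

from __future__ import annotations

import numpy as np
import pytest

from sparsepet import (
    REDUCED_GEOMETRY,
    ChessboardPattern,
    ScannerGeometry,
    SimulationConfig,
    SinogramRestorer,
    build_bin_mask,
    build_chessboard_mask,
    generate_phantom,
    project_to_sinograms,
    sample_counts_and_distort,
)
from sparsepet.baseline import interpolate_stack

TINY_GEOMETRY = ScannerGeometry(
    n_rings=4,
    n_crystals_per_ring=16,
    crystal_pitch_transaxial=4.0,
    crystal_pitch_axial=5.3,
    ring_radius=30.0,
)

SMALL_GEOMETRY = ScannerGeometry(
    n_rings=8,
    n_crystals_per_ring=32,
    crystal_pitch_transaxial=4.0,
    crystal_pitch_axial=5.3,
    ring_radius=40.0,
)


@pytest.fixture(scope="session")
def tiny_geometry() -> ScannerGeometry:
    return TINY_GEOMETRY


@pytest.fixture(scope="session")
def small_geometry() -> ScannerGeometry:
    return SMALL_GEOMETRY


@pytest.fixture(scope="session")
def pattern11() -> ChessboardPattern:
    return ChessboardPattern(1, 1, "standard")


@pytest.fixture(scope="session")
def benchmark_run():
    """Seeded reduced-geometry benchmark shared by the acceptance tests.

    Simulates seven phantoms on the 16-ring x 64-crystal geometry (241 planes
    each), trains the restorer on six of them (1446 training sinograms, so an
    epoch is long enough for the per-epoch learning-rate decay to behave as
    in full-scale training), and restores / interpolates the held-out test
    phantom (index 3 - the rng is consumed sequentially, so that phantom is
    independent of how many training phantoms follow it).  Returns a dict
    with the stacks, the mask and the trained restorer.
    """
    cfg = SimulationConfig(n_phantoms=7, seed=7, geometry=REDUCED_GEOMETRY)
    rng = np.random.default_rng(cfg.seed)
    cmask = build_chessboard_mask(cfg.geometry, cfg.pattern)
    bmask = build_bin_mask(cfg.geometry, cfg.scheme, cmask, cfg.n_radial)

    originals, distorteds = [], []
    for _ in range(cfg.n_phantoms):
        ph = generate_phantom(cfg, rng)
        exp = project_to_sinograms(ph, cfg.geometry, cfg.scheme, cfg.n_radial, cfg.count_level)
        orig, dist = sample_counts_and_distort(exp, bmask, rng)
        originals.append(orig)
        distorteds.append(dist)

    test_index = 3
    train_idx = [i for i in range(cfg.n_phantoms) if i != test_index]
    X = np.concatenate([distorteds[i].data for i in train_idx])
    y = np.concatenate([originals[i].data for i in train_idx])
    m = np.tile(bmask.affected, (len(train_idx), 1, 1))

    restorer = SinogramRestorer(
        depth=2,
        base_filters=8,
        res_blocks_per_level=(1, 2),
        max_epochs=55,
        patience=20,
        seed=0,
    )
    restorer.fit(X, y, m)

    test_orig = originals[test_index]
    test_dist = distorteds[test_index]
    restored = test_dist.with_data(
        restorer.transform(test_dist.data, bmask.affected), "restored"
    )
    interpolated = interpolate_stack(test_dist, bmask)

    return {
        "config": cfg,
        "crystal_mask": cmask,
        "bin_mask": bmask,
        "restorer": restorer,
        "train_originals": [originals[i] for i in train_idx],
        "original": test_orig,
        "distorted": test_dist,
        "restored": restored,
        "interpolated": interpolated,
    }
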