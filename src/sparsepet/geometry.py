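"""Cylindrical PET detector geometry and chessboard cancellation patterns.

Index conventions (used everywhere in the package): rings and crystals are
0-based; the crystal index increases counter-clockwise viewed from the scanner
front; ring 0 is at the front of the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScannerGeometry",
    "ChessboardPattern",
    "CrystalMask",
    "LOR",
    "SIGNA_LIKE",
    "build_chessboard_mask",
    "lor_survives",
    "retained_lor_fraction",
    "retained_pair_fraction_closed_form",
]


@dataclass(frozen=True)
class ScannerGeometry:
    """Cylindrical scanner: ``n_rings`` crystal rings of ``n_crystals_per_ring``
    crystals each, with transaxial/axial crystal pitches and ring radius in mm.

    ``n_crystals_per_ring`` must be even so a chessboard closes seamlessly
    around the cylinder.
    """

    n_rings: int
    n_crystals_per_ring: int
    crystal_pitch_transaxial: float = 4.0
    crystal_pitch_axial: float = 5.3
    ring_radius: float = 311.8

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValueError("n_rings must be a positive integer")
        if self.n_crystals_per_ring < 2 or self.n_crystals_per_ring % 2 != 0:
            raise ValueError("n_crystals_per_ring must be a positive even integer")
        for name in ("crystal_pitch_transaxial", "crystal_pitch_axial", "ring_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_crystals(self) -> int:
        return self.n_rings * self.n_crystals_per_ring


#: Full-scale profile emulating a GE Signa PET/MR-class scanner.  The ring and
#: per-ring crystal counts are scanner constants inferred from the standard
#: sinogram format (45 rings reproduce the 1981-plane scheme); see docs.
SIGNA_LIKE = ScannerGeometry(
    n_rings=45,
    n_crystals_per_ring=448,
    crystal_pitch_transaxial=4.0,
    crystal_pitch_axial=5.3,
    ring_radius=311.8,
)


@dataclass(frozen=True)
class ChessboardPattern:
    """Chessboard cancellation: alternating kept/removed blocks of
    ``block_rings`` x ``block_crystals`` crystals in (ring, crystal) index
    space.  ``phase`` selects the standard pattern or its exact complement.
    """

    block_rings: int = 1
    block_crystals: int = 1
    phase: str = "standard"

    def __post_init__(self) -> None:
        if self.block_rings < 1 or self.block_crystals < 1:
            raise ValueError("block sizes must be >= 1")
        if self.phase not in ("standard", "complementary"):
            raise ValueError("phase must be 'standard' or 'complementary'")

    @property
    def phase_bit(self) -> int:
        return 0 if self.phase == "standard" else 1

    def complement(self) -> "ChessboardPattern":
        other = "complementary" if self.phase == "standard" else "standard"
        return ChessboardPattern(self.block_rings, self.block_crystals, other)


@dataclass
class CrystalMask:
    """Boolean kept/removed state per (ring, crystal)."""

    kept: np.ndarray
    geometry: ScannerGeometry

    def __post_init__(self) -> None:
        self.kept = np.asarray(self.kept, dtype=bool)
        expected = (self.geometry.n_rings, self.geometry.n_crystals_per_ring)
        if self.kept.shape != expected:
            raise ValueError(f"mask shape {self.kept.shape} != geometry {expected}")

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def complement(self) -> "CrystalMask":
        return CrystalMask(~self.kept, self.geometry)


@dataclass(frozen=True)
class LOR:
    """Unordered line of response between two distinct crystals.

    Canonical ordering: ring_a < ring_b, or crystal_a < crystal_b within a
    ring; the constructor normalises.
    """

    ring_a: int
    crystal_a: int
    ring_b: int
    crystal_b: int

    def __post_init__(self) -> None:
        if (self.ring_a, self.crystal_a) == (self.ring_b, self.crystal_b):
            raise ValueError("LOR endpoints must be distinct crystals")
        if (self.ring_a, self.crystal_a) > (self.ring_b, self.crystal_b):
            a = (self.ring_a, self.crystal_a)
            b = (self.ring_b, self.crystal_b)
            object.__setattr__(self, "ring_a", b[0])
            object.__setattr__(self, "crystal_a", b[1])
            object.__setattr__(self, "ring_b", a[0])
            object.__setattr__(self, "crystal_b", a[1])

    @property
    def ring_difference(self) -> int:
        return abs(self.ring_b - self.ring_a)


def build_chessboard_mask(
    geometry: ScannerGeometry, pattern: ChessboardPattern
) -> CrystalMask:
    """Kept/removed map for a chessboard pattern on ``geometry``.

    kept(r, c) = ((r // block_rings + c // block_crystals) % 2 == phase_bit).
    Rejects geometries where the transaxial block tiling does not close
    seamlessly around the ring, i.e. where n_crystals_per_ring is not
    divisible by 2 * block_crystals.
    """
    if geometry.n_crystals_per_ring % (2 * pattern.block_crystals) != 0:
        raise ValueError(
            "invalid sparsity design: n_crystals_per_ring "
            f"({geometry.n_crystals_per_ring}) is not divisible by "
            f"2*block_crystals ({2 * pattern.block_crystals}); the chessboard "
            "does not tile seamlessly around the ring"
        )
    r = np.arange(geometry.n_rings)[:, None] // pattern.block_rings
    c = np.arange(geometry.n_crystals_per_ring)[None, :] // pattern.block_crystals
    kept = ((r + c) % 2) == pattern.phase_bit
    return CrystalMask(kept, geometry)


def _check_crystal(geometry: ScannerGeometry, ring: int, crystal: int) -> None:
    if not (0 <= ring < geometry.n_rings):
        raise IndexError(f"ring index {ring} out of range [0, {geometry.n_rings})")
    if not (0 <= crystal < geometry.n_crystals_per_ring):
        raise IndexError(
            f"crystal index {crystal} out of range [0, {geometry.n_crystals_per_ring})"
        )


def lor_survives(lor: LOR, mask: CrystalMask) -> bool:
    """True iff both endpoint crystals of ``lor`` are kept under ``mask``."""
    g = mask.geometry
    _check_crystal(g, lor.ring_a, lor.crystal_a)
    _check_crystal(g, lor.ring_b, lor.crystal_b)
    return bool(mask.kept[lor.ring_a, lor.crystal_a] and mask.kept[lor.ring_b, lor.crystal_b])


def retained_pair_fraction_closed_form(n_kept: int, n_total: int) -> float:
    """Fraction of unordered crystal pairs with both endpoints kept:
    K(K-1) / (N(N-1))."""
    if n_total < 2:
        raise ValueError("need at least two crystals")
    return n_kept * (n_kept - 1) / (n_total * (n_total - 1))


def retained_lor_fraction(
    geometry: ScannerGeometry,
    mask: CrystalMask,
    max_ring_difference: int | None = None,
    method: str = "stream",
) -> float:
    """Fraction of valid LORs (unordered crystal pairs) surviving ``mask``.

    The default acceptance rule counts all unordered crystal pairs with ring
    difference <= ``max_ring_difference`` (default n_rings - 1, i.e. all
    pairs).  ``method='stream'`` accumulates per ring pair without
    materialising the pair set; ``method='brute'`` enumerates every pair and
    is restricted to small geometries (<= 10^4 crystals) as an oracle.
    """
    if mask.geometry != geometry:
        raise ValueError("mask geometry does not match")
    R = geometry.n_rings
    if max_ring_difference is None:
        max_ring_difference = R - 1
    kept = mask.kept

    if method == "brute":
        if geometry.n_crystals > 10_000:
            raise ValueError("brute-force pair enumeration limited to <= 1e4 crystals")
        flat_kept = kept.ravel()
        rings = np.repeat(np.arange(R), geometry.n_crystals_per_ring)
        n = flat_kept.size
        total = 0
        survived = 0
        for i in range(n):
            for j in range(i + 1, n):
                if abs(rings[i] - rings[j]) > max_ring_difference:
                    continue
                total += 1
                if flat_kept[i] and flat_kept[j]:
                    survived += 1
        return survived / total

    if method != "stream":
        raise ValueError("method must be 'stream' or 'brute'")

    # Stream over ring pairs; within each ring pair the pair counts are
    # closed-form in the per-ring kept counts.
    k = kept.sum(axis=1).astype(np.int64)  # kept crystals per ring
    m = geometry.n_crystals_per_ring
    total = 0
    survived = 0
    for r in range(R):
        # same-ring pairs
        total += m * (m - 1) // 2
        survived += int(k[r]) * (int(k[r]) - 1) // 2
        for r2 in range(r + 1, min(R, r + max_ring_difference + 1)):
            total += m * m
            survived += int(k[r]) * int(k[r2])
    return survived / total
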