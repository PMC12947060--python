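"""Michelogram plane scheme, crystal-pair-to-sinogram-bin mapping, bin masks.

Plane ordering (fixed, documented, and written to HDF5 metadata):
segment-major.  The ring-difference-0/1 group comes first as 2R-1 planes
interleaved by axial position (direct plane of ring r at index 2r, the summed
ring-difference-1 cross plane between rings r and r+1 at index 2r+1), followed
by segments +2, -2, +3, -3, ... each ordered by its minimum ring.

Transaxial binning uses the standard interleaved view scheme: for crystals
(ca, cb) on a ring of n crystals the view is
``((ca + cb + n/2 + 1) mod n) // 2`` and the radial index is the integer
offset ``u = n/2 - d`` of the canonical crystal-index difference d, signed by
the geometric side of the view axis.  No arc correction is applied, so radial
samples are uniform in crystal-difference units rather than in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .geometry import LOR, CrystalMask, ScannerGeometry

__all__ = [
    "MichelogramScheme",
    "SinogramIndex",
    "SinogramStack",
    "BinMask",
    "OutOfFOVError",
    "plane_count",
    "crystal_pair_to_bin",
    "build_bin_mask",
    "bin_counts",
    "default_n_radial",
]

PROVENANCES = ("original", "distorted", "restored", "interpolated", "expectation")


class OutOfFOVError(ValueError):
    """A crystal pair falls outside the radial field of view or the maximum
    ring difference of the scheme."""


def default_n_radial(n_crystals_per_ring: int) -> int:
    """Radial bin count: 357 for the full 448-crystal profile (the scanner
    format's constant); otherwise n/2 + 1, forced odd, so the centre bin is
    defined."""
    if n_crystals_per_ring == 448:
        return 357
    n_radial = n_crystals_per_ring // 2 + 1
    if n_radial % 2 == 0:
        n_radial += 1
    return min(n_radial, n_crystals_per_ring - 1)


@dataclass(frozen=True)
class MichelogramScheme:
    """Plane scheme with optional summing of ring-difference-1 cross planes."""

    n_rings: int
    max_ring_difference: int = -1  # -1 -> n_rings - 1
    summed_rd1: bool = True

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.max_ring_difference == -1:
            object.__setattr__(self, "max_ring_difference", self.n_rings - 1)
        if not (0 <= self.max_ring_difference <= self.n_rings - 1):
            raise ValueError("max_ring_difference out of range")

    # ---- plane bookkeeping -------------------------------------------------

    @property
    def n_planes(self) -> int:
        return plane_count(self)

    def plane_infos(self) -> list[dict]:
        """One record per plane: kind ('direct'|'summed_rd1'|'oblique'),
        signed segment, axial position in half-ring units, and the directed
        ring pairs (first_ring, second_ring) whose LORs it collects."""
        R = self.n_rings
        infos: list[dict] = []
        # group 0: interleaved direct / summed rd=1
        if self.summed_rd1 and self.max_ring_difference >= 1:
            for ax in range(2 * R - 1):
                if ax % 2 == 0:
                    r = ax // 2
                    infos.append(
                        dict(kind="direct", segment=0, axial=ax, ring_pairs=[(r, r)])
                    )
                else:
                    r = ax // 2
                    infos.append(
                        dict(
                            kind="summed_rd1",
                            segment=1,
                            axial=ax,
                            ring_pairs=[(r, r + 1), (r + 1, r)],
                        )
                    )
            d_start = 2
        else:
            for r in range(R):
                infos.append(dict(kind="direct", segment=0, axial=2 * r, ring_pairs=[(r, r)]))
            d_start = 1
        for d in range(d_start, self.max_ring_difference + 1):
            for seg in (d, -d):
                for rmin in range(R - d):
                    if seg > 0:
                        pair = (rmin, rmin + d)
                    else:
                        pair = (rmin + d, rmin)
                    infos.append(
                        dict(kind="oblique", segment=seg, axial=2 * rmin + d, ring_pairs=[pair])
                    )
        return infos

    def plane_index(self, first_ring: int, second_ring: int) -> int:
        """Plane index of the directed ring pair (first canonical endpoint's
        ring, second's).  Raises OutOfFOVError beyond max_ring_difference."""
        R = self.n_rings
        d = second_ring - first_ring
        ad = abs(d)
        if ad > self.max_ring_difference:
            raise OutOfFOVError(
                f"ring difference {ad} exceeds max_ring_difference {self.max_ring_difference}"
            )
        if self.summed_rd1 and self.max_ring_difference >= 1:
            if ad == 0:
                return 2 * first_ring
            if ad == 1:
                return 2 * min(first_ring, second_ring) + 1
            offset = 2 * R - 1
            d_start = 2
        else:
            if ad == 0:
                return first_ring
            offset = R
            d_start = 1
        for e in range(d_start, ad):
            offset += 2 * (R - e)
        if d < 0:
            offset += R - ad
        return offset + min(first_ring, second_ring)


def plane_count(scheme: MichelogramScheme) -> int:
    """Number of 2D sinogram planes produced by the scheme (closed form)."""
    R = scheme.n_rings
    mrd = scheme.max_ring_difference
    count = R
    if mrd >= 1:
        count += (R - 1) if scheme.summed_rd1 else 2 * (R - 1)
    for d in range(2, mrd + 1):
        count += 2 * (R - d)
    return count


@dataclass(frozen=True)
class SinogramIndex:
    plane: int
    radial: int
    angle: int


@dataclass
class SinogramStack:
    """Ordered set of 2D sinogram planes (plane x radial x angular), counts."""

    data: np.ndarray
    scheme: MichelogramScheme
    provenance: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (plane, radial, angular)")
        if self.data.shape[0] != self.scheme.n_planes:
            raise ValueError(
                f"stack has {self.data.shape[0]} planes, scheme expects {self.scheme.n_planes}"
            )
        if np.any(self.data < 0):
            raise ValueError("sinogram values must be non-negative")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def n_radial(self) -> int:
        return self.data.shape[1]

    @property
    def n_angles(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, provenance: str) -> "SinogramStack":
        return SinogramStack(data, self.scheme, provenance)


@dataclass
class BinMask:
    """Per-bin surviving fraction in [0, 1] plus the derived binary affected
    mask m (true where the fraction is < 1).  Fractions are exact rationals
    from integer tallies; bins with no contributing LOR get fraction 1
    (unaffected by convention)."""

    surviving_fraction: np.ndarray
    scheme: MichelogramScheme

    def __post_init__(self) -> None:
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=np.float64)
        if np.any(self.surviving_fraction < 0) or np.any(self.surviving_fraction > 1):
            raise ValueError("surviving fractions must lie in [0, 1]")

    @property
    def affected(self) -> np.ndarray:
        return self.surviving_fraction < 1.0

    def n_activated(self, plane: int) -> int:
        return int(self.affected[plane].sum())


# ---------------------------------------------------------------------------
# transaxial crystal-pair -> (radial, view) mapping
# ---------------------------------------------------------------------------


def _transaxial_bin_arrays(
    ca: np.ndarray,
    cb: np.ndarray,
    n: int,
    n_radial: int,
    first_is_a: np.ndarray | None = None,
):
    """Vectorised transaxial mapping.

    Returns (radial, view, a_is_first, in_fov).  ``a_is_first`` reports which
    endpoint is the canonical first (True: a) so callers can resolve the
    segment sign; diametric ties (d == n/2) keep 'a' first.
    """
    ca = np.asarray(ca, dtype=np.int64)
    cb = np.asarray(cb, dtype=np.int64)
    n2 = n // 2
    m = (ca + cb + n2 + 1) % n
    view = m // 2

    d_ab = (ca - cb) % n
    # canonical difference in (0, n2]; d_ab == 0 (same transaxial position)
    # is tangential -> out of FOV
    a_first = (d_ab >= 1) & (d_ab <= n2)
    d = np.where(a_first, d_ab, (n - d_ab) % n)
    valid = d > 0
    u = n2 - d  # integer radial magnitude, 0 = centre

    # side sign: project the chord midpoint onto the view axis
    alpha_a = 2.0 * np.pi * (ca + 0.5) / n
    alpha_b = 2.0 * np.pi * (cb + 0.5) / n
    mx = 0.5 * (np.cos(alpha_a) + np.cos(alpha_b))
    my = 0.5 * (np.sin(alpha_a) + np.sin(alpha_b))
    gamma = np.pi * (2 * view - n2) / n
    dot = mx * np.cos(gamma) + my * np.sin(gamma)
    sign = np.where(dot >= 0, 1, -1)
    q = sign * u

    half = n_radial // 2
    in_fov = valid & (np.abs(q) <= half)
    radial = q + half
    return radial, view, a_first, in_fov


def crystal_pair_to_bin(
    lor: LOR,
    geometry: ScannerGeometry,
    scheme: MichelogramScheme,
    n_radial: int | None = None,
) -> SinogramIndex:
    """Deterministic mapping of a LOR to its sinogram bin.

    Raises OutOfFOVError for pairs beyond the maximum ring difference or the
    radial field of view.
    """
    n = geometry.n_crystals_per_ring
    if n_radial is None:
        n_radial = default_n_radial(n)
    for ring, crystal in ((lor.ring_a, lor.crystal_a), (lor.ring_b, lor.crystal_b)):
        if not (0 <= ring < geometry.n_rings):
            raise IndexError(f"ring index {ring} out of range")
        if not (0 <= crystal < n):
            raise IndexError(f"crystal index {crystal} out of range")
    radial, view, a_first, in_fov = _transaxial_bin_arrays(
        np.array([lor.crystal_a]), np.array([lor.crystal_b]), n, n_radial
    )
    if not in_fov[0]:
        raise OutOfFOVError("crystal pair outside the radial field of view")
    if a_first[0]:
        first_ring, second_ring = lor.ring_a, lor.ring_b
    else:
        first_ring, second_ring = lor.ring_b, lor.ring_a
    # diametric tie: smaller ring acts as the first endpoint
    d_ab = (lor.crystal_a - lor.crystal_b) % n
    if d_ab == n // 2 and lor.ring_a != lor.ring_b:
        first_ring, second_ring = min(lor.ring_a, lor.ring_b), max(lor.ring_a, lor.ring_b)
    plane = scheme.plane_index(first_ring, second_ring)
    return SinogramIndex(plane=plane, radial=int(radial[0]), angle=int(view[0]))


# ---------------------------------------------------------------------------
# bin masks
# ---------------------------------------------------------------------------


def _directed_pair_grids(n: int, kind: str):
    """Crystal-index grids (cA, cB) of the LORs a directed ring pair
    contributes, as flat arrays.

    kind 'direct'  : unordered same-ring pairs, ca < cb;
    kind 'lt'      : first ring < second ring -> pairs where the first ring's
                     crystal is the canonical transaxial first endpoint,
                     including diametric ties;
    kind 'gt'      : first ring > second ring -> canonical-first pairs
                     excluding diametric ties (those belong to 'lt').
    """
    n2 = n // 2
    if kind == "direct":
        ca, cb = np.triu_indices(n, k=1)
        return ca.astype(np.int64), cb.astype(np.int64)
    ca, cb = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ca = ca.ravel().astype(np.int64)
    cb = cb.ravel().astype(np.int64)
    d = (ca - cb) % n
    if kind == "lt":
        sel = (d >= 1) & (d <= n2)
    elif kind == "gt":
        sel = (d >= 1) & (d < n2)
    else:
        raise ValueError(kind)
    return ca[sel], cb[sel]


def _tally_ring_pair(
    kept_a: np.ndarray,
    kept_b: np.ndarray,
    n: int,
    n_radial: int,
    kind: str,
    cache: dict,
):
    """(survived, total) integer tallies on the (radial, view) grid for one
    directed ring pair; memoised on the kept-row bytes since the tally depends
    only on those."""
    key = (kept_a.tobytes(), kept_b.tobytes(), kind)
    if key in cache:
        return cache[key]
    ca, cb = _directed_pair_grids(n, kind)
    radial, view, _, in_fov = _transaxial_bin_arrays(ca, cb, n, n_radial)
    ca, cb = ca[in_fov], cb[in_fov]
    radial, view = radial[in_fov], view[in_fov]
    total = np.zeros((n_radial, n // 2), dtype=np.int64)
    survived = np.zeros_like(total)
    np.add.at(total, (radial, view), 1)
    surv = kept_a[ca] & kept_b[cb]
    np.add.at(survived, (radial[surv], view[surv]), 1)
    cache[key] = (survived, total)
    return survived, total


def build_bin_mask(
    geometry: ScannerGeometry,
    scheme: MichelogramScheme,
    crystal_mask: CrystalMask,
    n_radial: int | None = None,
) -> BinMask:
    """Per-bin surviving fraction: (# contributing LORs surviving) /
    (# contributing LORs), with empty bins set to 1 (unaffected)."""
    if crystal_mask.geometry != geometry:
        raise ValueError("crystal mask geometry mismatch")
    if scheme.n_rings != geometry.n_rings:
        raise ValueError("scheme ring count mismatch")
    n = geometry.n_crystals_per_ring
    if n_radial is None:
        n_radial = default_n_radial(n)
    n_angles = n // 2
    infos = scheme.plane_infos()
    frac = np.ones((len(infos), n_radial, n_angles), dtype=np.float64)
    cache: dict = {}
    kept = np.ascontiguousarray(crystal_mask.kept)
    for p, info in enumerate(infos):
        survived = np.zeros((n_radial, n_angles), dtype=np.int64)
        total = np.zeros_like(survived)
        for r_first, r_second in info["ring_pairs"]:
            if r_first == r_second:
                kind = "direct"
            elif r_first < r_second:
                kind = "lt"
            else:
                kind = "gt"
            s, t = _tally_ring_pair(kept[r_first], kept[r_second], n, n_radial, kind, cache)
            survived = survived + s
            total = total + t
        nz = total > 0
        frac[p][nz] = survived[nz] / total[nz]
    return BinMask(frac, scheme)


def bin_counts(
    lors: list[LOR],
    counts: np.ndarray,
    geometry: ScannerGeometry,
    scheme: MichelogramScheme,
    n_radial: int | None = None,
    provenance: str = "original",
) -> SinogramStack:
    """Accumulate per-LOR counts into a sinogram stack (additive; out-of-FOV
    LORs are dropped).  Intended for small oracle geometries."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (len(lors),):
        raise ValueError("counts must align with lors")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = geometry.n_crystals_per_ring
    if n_radial is None:
        n_radial = default_n_radial(n)
    data = np.zeros((scheme.n_planes, n_radial, n // 2), dtype=np.float64)
    for lor, c in zip(lors, counts):
        try:
            idx = crystal_pair_to_bin(lor, geometry, scheme, n_radial)
        except OutOfFOVError:
            continue
        data[idx.plane, idx.radial, idx.angle] += c
    return SinogramStack(data, scheme, provenance)


def all_lors(geometry: ScannerGeometry, max_ring_difference: int | None = None) -> Iterator[LOR]:
    """Every unordered crystal pair within the ring-difference limit (small
    geometries only; used by oracle paths)."""
    if geometry.n_crystals > 10_000:
        raise ValueError("exhaustive LOR enumeration limited to small geometries")
    R, n = geometry.n_rings, geometry.n_crystals_per_ring
    mrd = R - 1 if max_ring_difference is None else max_ring_difference
    crystals = [(r, c) for r in range(R) for c in range(n)]
    for i in range(len(crystals)):
        for j in range(i + 1, len(crystals)):
            (ra, ca), (rb, cb) = crystals[i], crystals[j]
            if abs(ra - rb) > mrd:
                continue
            yield LOR(ra, ca, rb, cb)
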