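"""Michelogram plane scheme, crystal-pair binning, bin masks."""

import itertools

import numpy as np
import pytest

from sparsepet import (
    LOR,
    SIGNA_LIKE,
    ChessboardPattern,
    MichelogramScheme,
    bin_counts,
    build_bin_mask,
    build_chessboard_mask,
    crystal_pair_to_bin,
    default_n_radial,
    plane_count,
)
from sparsepet.binning import OutOfFOVError, all_lors
from sparsepet.geometry import CrystalMask

from conftest import SMALL_GEOMETRY, TINY_GEOMETRY


def brute_force_plane_count(R: int) -> int:
    """Enumerate Michelogram cells (r_first, r_second); merge rd=+-1 pairs."""
    planes = set()
    for ra in range(R):
        for rb in range(R):
            if abs(ra - rb) == 1:
                planes.add(("rd1", min(ra, rb)))  # merged pairwise
            else:
                planes.add(("sep", ra, rb))
    return len(planes)


class TestPlaneCount:
    def test_45_rings_gives_1981(self):
        assert plane_count(MichelogramScheme(45)) == 1981

    def test_single_ring(self):
        assert plane_count(MichelogramScheme(1)) == 1

    def test_three_rings(self):
        assert plane_count(MichelogramScheme(3)) == 7

    @pytest.mark.parametrize("R", range(1, 51))
    def test_closed_form_vs_brute_force(self, R):
        assert plane_count(MichelogramScheme(R)) == brute_force_plane_count(R)

    def test_reduced_geometry_planes(self):
        assert plane_count(MichelogramScheme(16)) == 241

    def test_plane_infos_consistent(self):
        scheme = MichelogramScheme(5)
        infos = scheme.plane_infos()
        assert len(infos) == plane_count(scheme)
        # every ring pair appears exactly once across all planes
        seen = [rp for info in infos for rp in info["ring_pairs"]]
        assert len(seen) == len(set(seen)) == 25
        # summed rd1 planes carry exactly two directed ring pairs
        for info in infos:
            if info["kind"] == "summed_rd1":
                assert len(info["ring_pairs"]) == 2
            else:
                assert len(info["ring_pairs"]) == 1

    def test_plane_index_round_trip(self):
        scheme = MichelogramScheme(6)
        infos = scheme.plane_infos()
        for p, info in enumerate(infos):
            for ra, rb in info["ring_pairs"]:
                assert scheme.plane_index(ra, rb) == p

    def test_restricted_max_ring_difference(self):
        # R=5, max_rd=2: 5 direct + 4 summed rd1 + 2*3 separate rd2
        assert plane_count(MichelogramScheme(5, max_ring_difference=2)) == 15


class TestCrystalPairToBin:
    def test_swapped_endpoints_identical(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        a = crystal_pair_to_bin(LOR(0, 3, 2, 10), g, scheme)
        b = crystal_pair_to_bin(LOR(2, 10, 0, 3), g, scheme)
        assert a == b

    def test_rd1_mirror_same_summed_plane(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        a = crystal_pair_to_bin(LOR(1, 3, 2, 10), g, scheme)
        b = crystal_pair_to_bin(LOR(2, 3, 1, 10), g, scheme)
        assert a.plane == b.plane

    def test_out_of_fov_rejected(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings, max_ring_difference=1)
        with pytest.raises(OutOfFOVError):
            crystal_pair_to_bin(LOR(0, 0, 3, 8), g, scheme)
        # adjacent crystals lie outside the radial field of view
        with pytest.raises(OutOfFOVError):
            crystal_pair_to_bin(LOR(0, 0, 0, 1), g, MichelogramScheme(g.n_rings))

    def test_out_of_range_rejected(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        with pytest.raises(IndexError):
            crystal_pair_to_bin(LOR(0, 0, 9, 8), g, scheme)

    def test_multiplicity_map_4x16(self):
        """Contributing-pair count per bin equals a brute-force tally."""
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        n_radial = default_n_radial(g.n_crystals_per_ring)
        tally = np.zeros((scheme.n_planes, n_radial, g.n_crystals_per_ring // 2))
        for lor in all_lors(g):
            try:
                idx = crystal_pair_to_bin(lor, g, scheme)
            except OutOfFOVError:
                continue
            tally[idx.plane, idx.radial, idx.angle] += 1
        # direct planes: every in-FOV bin receives exactly one pair.  Oblique
        # planes can hold multiplicity 2 only at the central radial bin, where
        # both orientations of a diametric cross-ring pair land in the
        # (r_min, r_max) plane by the tie rule (the mirror plane gets 0).
        infos = scheme.plane_infos()
        centre = tally.shape[1] // 2
        for p, info in enumerate(infos):
            counts = set(np.unique(tally[p]))
            off_centre = set(np.unique(np.delete(tally[p], centre, axis=0)))
            if info["kind"] == "direct":
                assert counts <= {0.0, 1.0}
            elif info["kind"] == "summed_rd1":
                assert counts <= {0.0, 2.0}
            else:
                assert off_centre <= {0.0, 1.0}
                assert counts <= {0.0, 1.0, 2.0}
        # total pairs conserved (in-FOV)
        in_fov = sum(
            1
            for lor in all_lors(g)
            if _in_fov(lor, g, scheme)
        )
        assert tally.sum() == in_fov


def _in_fov(lor, g, scheme):
    try:
        crystal_pair_to_bin(lor, g, scheme)
        return True
    except OutOfFOVError:
        return False


class TestBinCounts:
    def test_all_zero(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        lors = list(all_lors(g))
        stack = bin_counts(lors, np.zeros(len(lors)), g, scheme)
        assert stack.data.sum() == 0

    def test_single_lor(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        lor = LOR(0, 0, 1, 8)
        stack = bin_counts([lor], np.array([7.0]), g, scheme)
        idx = crystal_pair_to_bin(lor, g, scheme)
        assert stack.data[idx.plane, idx.radial, idx.angle] == 7.0
        assert stack.data.sum() == 7.0

    def test_count_conservation_random(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        rng = np.random.default_rng(11)
        lors = list(all_lors(g))
        counts = rng.integers(0, 50, len(lors)).astype(float)
        stack = bin_counts(lors, counts, g, scheme)
        in_fov_total = sum(
            c for lor, c in zip(lors, counts) if _in_fov(lor, g, scheme)
        )
        assert stack.data.sum() == pytest.approx(in_fov_total, rel=1e-12)


class TestBinMask:
    def test_all_kept_mask_is_unaffected(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        mask = CrystalMask(np.ones((g.n_rings, g.n_crystals_per_ring), dtype=bool), g)
        bmask = build_bin_mask(g, scheme, mask)
        assert np.all(bmask.surviving_fraction == 1.0)
        assert not bmask.affected.any()

    def test_fractions_match_brute_force_8x32(self):
        g = SMALL_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        cmask = build_chessboard_mask(g, ChessboardPattern(1, 1, "standard"))
        bmask = build_bin_mask(g, scheme, cmask)
        n_radial = default_n_radial(g.n_crystals_per_ring)
        survived = np.zeros((scheme.n_planes, n_radial, g.n_crystals_per_ring // 2))
        total = np.zeros_like(survived)
        for lor in all_lors(g):
            try:
                idx = crystal_pair_to_bin(lor, g, scheme)
            except OutOfFOVError:
                continue
            total[idx.plane, idx.radial, idx.angle] += 1
            if cmask.kept[lor.ring_a, lor.crystal_a] and cmask.kept[lor.ring_b, lor.crystal_b]:
                survived[idx.plane, idx.radial, idx.angle] += 1
        expected = np.ones_like(total)
        nz = total > 0
        expected[nz] = survived[nz] / total[nz]
        assert np.array_equal(bmask.surviving_fraction, expected)

    def test_distortion_classes_small(self):
        """Direct and |rd|>1 planes: fractions only in {0,1}; summed rd=1
        planes: every bin fraction < 1 (zeros and strict fractions)."""
        g = SMALL_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        cmask = build_chessboard_mask(g, ChessboardPattern(1, 1, "standard"))
        bmask = build_bin_mask(g, scheme, cmask)
        for p, info in enumerate(scheme.plane_infos()):
            fr = bmask.surviving_fraction[p]
            if info["kind"] == "summed_rd1":
                assert np.all(fr < 1.0)
                assert np.any((fr > 0) & (fr < 1))
            else:
                assert set(np.unique(fr)) <= {0.0, 1.0}

    def test_affected_definition(self):
        g = TINY_GEOMETRY
        scheme = MichelogramScheme(g.n_rings)
        cmask = build_chessboard_mask(g, ChessboardPattern(1, 1, "standard"))
        bmask = build_bin_mask(g, scheme, cmask)
        assert np.array_equal(bmask.affected, bmask.surviving_fraction < 1.0)
        assert bmask.n_activated(0) == int(bmask.affected[0].sum())


class TestDefaultNRadial:
    def test_full_scale(self):
        assert default_n_radial(448) == 357

    def test_reduced_odd(self):
        n = default_n_radial(64)
        assert n % 2 == 1
        assert n == 33

    def test_small(self):
        assert default_n_radial(16) % 2 == 1
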