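"""Contour agreement and proximity metrics against analytic and brute-force
oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from adaptqa.grids import BinaryStructure, StructureSet, distance_map, expand
from adaptqa.metrics import (
    clip_to_target,
    compare_structure_sets,
    dice,
    hausdorff,
    mean_surface_distance,
    min_distance,
    overlap_volume,
    ring,
    surface_mask,
    volume_difference,
)
from .conftest import make_geometry, random_blob, sphere


def brute_surface_metrics(a, b):
    """Exhaustive pairwise oracle for symmetric MSD and HD (mm)."""
    spacing = np.asarray(a.geometry.spacing_mm)
    pa = np.argwhere(surface_mask(a)) * spacing
    pb = np.argwhere(surface_mask(b)) * spacing
    d = cdist(pa, pb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    msd = (d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size)
    hd = max(d_ab.max(), d_ba.max())
    return msd, hd


class TestDice:
    def test_identity_is_one(self, geom16, rng):
        s = random_blob(geom16, rng)
        assert dice(s, s) == 1.0

    def test_disjoint_is_zero(self, geom16):
        a = np.zeros(geom16.shape, dtype=bool)
        b = np.zeros(geom16.shape, dtype=bool)
        a[:4], b[8:] = True, True
        assert dice(BinaryStructure("a", geom16, a), BinaryStructure("b", geom16, b)) == 0.0

    def test_symmetric(self, geom16, rng):
        a, b = random_blob(geom16, rng, "a"), random_blob(geom16, rng, "b")
        assert dice(a, b) == dice(b, a)

    def test_both_empty_warns_one(self, geom16):
        e = BinaryStructure("e", geom16, np.zeros(geom16.shape, dtype=bool))
        s = BinaryStructure("s", geom16, np.ones(geom16.shape, dtype=bool))
        with pytest.warns(UserWarning):
            assert dice(e, e) == 1.0
        assert dice(e, s) == 0.0

    def test_nested_structures_formula(self, geom16, rng):
        b = random_blob(geom16, rng, "b")
        inner = BinaryStructure("a", geom16, b.mask & (np.indices(geom16.shape)[0] < 8))
        if inner.is_empty:
            pytest.skip("degenerate draw")
        expected = 2 * inner.voxel_count / (inner.voxel_count + b.voxel_count)
        assert dice(inner, b) == pytest.approx(expected)

    def test_offset_spheres_analytic_lens(self):
        # two r=10 mm spheres, centers 10 mm apart: Dice = (4r+d)(2r-d)^2/(16 r^3)
        g = make_geometry(72, 0.5)
        a = sphere(g, (12.75, 17.75, 17.75), 10.0, "a")
        b = sphere(g, (22.75, 17.75, 17.75), 10.0, "b")
        assert dice(a, b) == pytest.approx(0.3125, rel=0.02)


class TestSurfaceDistances:
    def test_identical_structures_zero(self, geom16, rng):
        s = random_blob(geom16, rng)
        assert mean_surface_distance(s, s) == 0.0
        assert hausdorff(s, s) == 0.0

    def test_concentric_spheres(self):
        g = make_geometry(32, 1.0)
        c = (15.5,) * 3
        a, b = sphere(g, c, 10.0, "a"), sphere(g, c, 12.0, "b")
        assert mean_surface_distance(a, b) == pytest.approx(2.0, abs=0.5)
        assert hausdorff(a, b) == pytest.approx(2.0, abs=0.5)

    def test_symmetric_under_swap(self, geom24, rng):
        a, b = random_blob(geom24, rng, "a"), random_blob(geom24, rng, "b")
        assert mean_surface_distance(a, b) == pytest.approx(mean_surface_distance(b, a))
        assert hausdorff(a, b) == pytest.approx(hausdorff(b, a))

    def test_matches_brute_force_oracle(self, geom24, rng):
        a, b = random_blob(geom24, rng, "a"), random_blob(geom24, rng, "b")
        msd_o, hd_o = brute_surface_metrics(a, b)
        assert mean_surface_distance(a, b) == pytest.approx(msd_o, abs=1e-6)
        assert hausdorff(a, b) == pytest.approx(hd_o, abs=1e-6)

    def test_hd_at_least_msd(self, geom24, rng):
        a, b = random_blob(geom24, rng, "a"), random_blob(geom24, rng, "b")
        assert hausdorff(a, b) >= mean_surface_distance(a, b)

    def test_empty_input_raises(self, geom16, rng):
        e = BinaryStructure("e", geom16, np.zeros(geom16.shape, dtype=bool))
        s = random_blob(geom16, rng)
        with pytest.raises(ValueError, match="empty"):
            mean_surface_distance(e, s)
        with pytest.raises(ValueError, match="empty"):
            hausdorff(s, e)


class TestVolumeDifference:
    def test_antisymmetric(self, geom16, rng):
        a, b = random_blob(geom16, rng, "a"), random_blob(geom16, rng, "b")
        assert volume_difference(a, b) == -volume_difference(b, a)

    def test_sphere_shells_analytic(self):
        g = make_geometry(64, 0.5)
        c = (15.75,) * 3
        auto, man = sphere(g, c, 12.0, "auto"), sphere(g, c, 10.0, "man")
        expected = 4 / 3 * np.pi * (12**3 - 10**3) / 1000
        assert volume_difference(auto, man) == pytest.approx(expected, rel=0.02)


class TestClipAndRing:
    def test_clip_far_oar_empty(self, geom24, rng):
        g = make_geometry(40, 2.0)
        ptv = sphere(g, (20, 20, 20), 8.0, "PTV")
        oar = sphere(g, (70, 70, 70), 6.0, "oar")
        assert clip_to_target(oar, ptv, 30.0).is_empty

    def test_clip_contained_oar_unchanged(self, geom24, rng):
        ptv = random_blob(geom24, rng, "PTV")
        oar = random_blob(geom24, rng, "oar")
        clipped = clip_to_target(oar, ptv, 1000.0)
        assert np.array_equal(clipped.mask, oar.mask)

    def test_clip_voxelwise_oracle(self, geom24, rng):
        ptv = random_blob(geom24, rng, "PTV")
        oar = random_blob(geom24, rng, "oar")
        d = 6.0
        clipped = clip_to_target(oar, ptv, d)
        expected = oar.mask & (distance_map(ptv) <= d + 1e-9)
        assert np.array_equal(clipped.mask, expected)

    def test_clip_volumes_nondecreasing_in_distance(self, geom24, rng):
        ptv = random_blob(geom24, rng, "PTV")
        oar = random_blob(geom24, rng, "oar")
        vols = [clip_to_target(oar, ptv, d).volume_cc for d in (5, 10, 30)]
        assert vols[0] <= vols[1] <= vols[2]

    def test_ring_partition_identity(self, geom24, rng):
        ptv = random_blob(geom24, rng, "PTV")
        r1 = ring(ptv, 0, 10)
        r2 = ring(ptv, 10, 30)
        r3 = ring(ptv, 0, 30)
        assert not np.any(r1.mask & r2.mask)
        assert np.array_equal(r1.mask | r2.mask, r3.mask)

    def test_ring_excludes_ptv(self, geom24, rng):
        ptv = random_blob(geom24, rng, "PTV")
        assert not np.any(ring(ptv, 0, 12).mask & ptv.mask)

    def test_ring_shell_volume_analytic(self):
        g = make_geometry(96, 0.5)
        ptv = sphere(g, (23.75,) * 3, 10.0, "PTV")
        shell = ring(ptv, 0, 10)
        expected = 4 / 3 * np.pi * (20**3 - 10**3) / 1000
        assert shell.volume_cc == pytest.approx(expected, rel=0.02)

    def test_ring_bad_bounds_rejected(self, geom16, rng):
        ptv = random_blob(geom16, rng, "PTV")
        with pytest.raises(ValueError):
            ring(ptv, 10, 10)
        with pytest.raises(ValueError):
            ring(ptv, -1, 10)


class TestProximity:
    def test_separated_spheres_gap(self):
        g = make_geometry(40, 2.0)
        t = sphere(g, (30, 40, 40), 10.0, "t")
        o = sphere(g, (60, 40, 40), 10.0, "o")
        assert min_distance(t, o) == pytest.approx(10.0, abs=1.0)

    def test_overlap_gives_negative(self, geom24, rng):
        t = random_blob(geom24, rng, "t")
        o = BinaryStructure("o", geom24, t.mask.copy())
        assert min_distance(t, o) < 0

    def test_matches_brute_force_signed_minimum(self, geom16, rng):
        from .conftest import brute_force_distance_map

        t, o = random_blob(geom16, rng, "t"), random_blob(geom16, rng, "o")
        expected = brute_force_distance_map(t, signed=True)[o.mask].min()
        assert min_distance(t, o) == pytest.approx(expected, abs=1e-6)

    def test_overlap_volume_bounds_and_monotone(self, geom24, rng):
        ptv = random_blob(geom24, rng, "PTV")
        oar = random_blob(geom24, rng, "oar")
        v5 = overlap_volume(ptv, 5, oar)
        v10 = overlap_volume(ptv, 10, oar)
        assert 0 <= v5 <= v10 <= oar.volume_cc
        assert v10 <= min(expand(ptv, 10).volume_cc, oar.volume_cc)

    def test_contained_oar_full_overlap(self, geom24, rng):
        ptv = random_blob(geom24, rng, "PTV")
        oar = random_blob(geom24, rng, "oar")
        assert overlap_volume(ptv, 1000.0, oar) == pytest.approx(oar.volume_cc)


def _two_organ_sets(geom, rng, dilate=False):
    from scipy import ndimage

    man = StructureSet(geometry=geom)
    man.add(sphere(geom, (23, 23, 23), 8.0, "GTV"), "GTV")
    man.add(sphere(geom, (23, 23, 23), 12.0, "PTV"), "PTV")
    for name, c in (("stomach", (43, 23, 23)), ("duodenum", (23, 41, 23)), ("bowel", (23, 23, 43))):
        man.add(sphere(geom, c, 9.0, name), "OAR")
    auto = StructureSet(geometry=geom)
    for name, s in man.structures.items():
        mask = s.mask
        if dilate and man.roles[name] == "OAR":
            mask = ndimage.binary_dilation(mask, iterations=1)
        auto.add(BinaryStructure(name, geom, mask.copy()), man.roles[name])
    return man, auto


class TestCompareStructureSets:
    def test_identical_sets_identity_metrics(self, rng):
        g = make_geometry(36, 2.0)
        man, auto = _two_organ_sets(g, rng)
        table = compare_structure_sets(man, auto)
        assert len(table) == 16  # (3 organs + GIO) x (whole + 3 clips)
        nonempty = table[~table.empty_flag]
        assert (nonempty.dc == 1.0).all()
        assert (nonempty.msd_mm == 0.0).all()
        assert (nonempty.hd_mm == 0.0).all()
        assert (table.vol_diff_cc.fillna(0) == 0.0).all()

    def test_dilated_auto_overestimates_everywhere(self, rng):
        g = make_geometry(36, 2.0)
        man, auto = _two_organ_sets(g, rng, dilate=True)
        table = compare_structure_sets(man, auto)
        nonempty = table[~table.empty_flag]
        assert (nonempty.vol_diff_cc > 0).all()
        assert (nonempty.dc < 1.0).all()

    def test_missing_structure_listed(self, rng):
        g = make_geometry(36, 2.0)
        man, auto = _two_organ_sets(g, rng)
        del auto.structures["bowel"]
        with pytest.raises(KeyError, match="bowel"):
            compare_structure_sets(man, auto)

    def test_vol_diff_column_consistency(self, rng):
        g = make_geometry(36, 2.0)
        man, auto = _two_organ_sets(g, rng, dilate=True)
        table = compare_structure_sets(man, auto)
        assert np.allclose(table.vol_diff_cc, table.vol_auto_cc - table.vol_man_cc)
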