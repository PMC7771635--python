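import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from atriaquant import labeling as L
from atriaquant.io import LabelMap, Volume
from atriaquant.segmentation import dice


def sphere_mask(shape, center, radius):
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), -1).astype(float)
    return np.linalg.norm(idx - np.asarray(center, dtype=float), axis=-1) <= radius


def sphere_cylinder_mask(shape=(80, 80, 80), center=(40, 40, 40), R=18.0, r=4.0, length=16.0):
    """Sphere with one cylinder along +z; junction plane at z = center_z + R."""
    c = np.asarray(center, dtype=float)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), -1).astype(float)
    sphere = np.linalg.norm(idx - c, axis=-1) <= R
    radial = np.linalg.norm(idx[..., :2] - c[:2], axis=-1)
    cyl = (radial <= r) & (idx[..., 2] >= c[2]) & (idx[..., 2] <= c[2] + R + length)
    return sphere | cyl


class TestRegionGrow:
    def test_uniform_sphere_recovered_exactly(self):
        # oracle: threshold + connected components
        mask = sphere_mask((40, 40, 40), (20, 20, 20), 10)
        img = np.where(mask, 100.0, 5.0)
        v = Volume(img, (1, 1, 1), (0, 0, 0))
        grown = L.region_grow(v, L.Seed((20, 20, 20), 10.0))
        assert np.array_equal(grown.data == 1, mask)

    def test_zero_tolerance_keeps_only_exact_matches(self, rng):
        img = rng.integers(0, 50, (20, 20, 20)).astype(float)
        img[10, 10, 10] = 200.0
        img[10, 10, 11] = 200.0
        v = Volume(img, (1, 1, 1), (0, 0, 0))
        grown = L.region_grow(v, L.Seed((10, 10, 10), 0.0))
        inside = np.argwhere(grown.data == 1)
        assert {tuple(i) for i in inside} == {(10, 10, 10), (10, 10, 11)}

    def test_disconnected_blob_excluded(self):
        img = np.zeros((40, 40, 40))
        a = sphere_mask((40, 40, 40), (12, 12, 12), 6)
        b = sphere_mask((40, 40, 40), (30, 30, 30), 6)
        img[a] = img[b] = 100.0
        v = Volume(img, (1, 1, 1), (0, 0, 0))
        grown = L.region_grow(v, L.Seed((12, 12, 12), 10.0))
        assert np.array_equal(grown.data == 1, a)

    def test_background_seed_raises(self):
        img = np.zeros((20, 20, 20))
        img[sphere_mask((20, 20, 20), (10, 10, 10), 5)] = 100.0
        with pytest.raises(ValueError):
            L.region_grow(Volume(img, (1, 1, 1), (0, 0, 0)), L.Seed((0, 0, 0), 1.0))


class TestCenterline:
    def test_sphere_plus_cylinder_has_one_branch(self):
        lm = LabelMap(sphere_cylinder_mask().astype(np.int16), (1, 1, 1), (0, 0, 0))
        cl = L.build_centerline(lm)
        assert len(cl.branches) == 1

    def test_plain_sphere_has_no_branches(self):
        lm = LabelMap(sphere_mask((48, 48, 48), (24, 24, 24), 16).astype(np.int16), (1, 1, 1), (0, 0, 0))
        cl = L.build_centerline(lm)
        assert len(cl.branches) == 0

    def test_standard_phantom_has_five_branches(self, small_phantom):
        _, _, _, truth = small_phantom
        bp = truth.labels.copy_with((truth.labels.data > 0).astype(np.int16))
        cl = L.build_centerline(bp)
        assert len(cl.branches) == 5

    def test_disconnected_mask_rejected(self):
        data = np.zeros((30, 30, 30), dtype=np.int16)
        data[sphere_mask((30, 30, 30), (8, 8, 8), 4)] = 1
        data[sphere_mask((30, 30, 30), (22, 22, 22), 4)] = 1
        with pytest.raises(ValueError, match="single"):
            L.build_centerline(LabelMap(data, (1, 1, 1), (0, 0, 0)))

    def test_medial_radii_match_distance_transform(self):
        # Voronoi/medial oracle on a small mask: inscribed radii at skeleton
        # voxels equal the interior distance transform there (within a voxel)
        mask = sphere_cylinder_mask((40, 40, 40), (20, 20, 20), R=9.0, r=3.0, length=8.0)
        lm = LabelMap(mask.astype(np.int16), (1, 1, 1), (0, 0, 0))
        cl = L.build_centerline(lm)
        dt = ndimage.distance_transform_edt(mask)
        at_skel = dt[tuple(cl.skeleton_idx.T)]
        assert np.allclose(cl.skeleton_radii, at_skel, atol=1.0)


class TestOstium:
    def test_junction_located_within_2mm(self):
        lm = LabelMap(sphere_cylinder_mask().astype(np.int16), (1, 1, 1), (0, 0, 0))
        cl = L.build_centerline(lm)
        b = L.locate_ostium(cl, 0)
        assert not b.flagged
        # analytic junction: sphere surface along +z at z = 40 + 18 = 58
        assert abs(b.ostium_pos[2] - 58.0) <= 2.5
        assert abs(abs(b.ostium_normal[2]) - 1.0) < 0.3

    def test_fraction_one_saturates_to_branch_root(self):
        lm = LabelMap(sphere_cylinder_mask().astype(np.int16), (1, 1, 1), (0, 0, 0))
        cl = L.build_centerline(lm)
        coarse = L.locate_ostium(cl, 0, fraction=1.0, refine=False)
        assert coarse.ostium_index == 0

    def test_mirrored_veins_give_symmetric_ostia(self):
        shape = (80, 80, 60)
        c = np.array([40.0, 40.0, 30.0])
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), -1).astype(float)
        body = np.linalg.norm(idx - c, axis=-1) <= 15.0
        for sign in (+1, -1):
            radial = np.linalg.norm(idx[..., 1:] - c[1:], axis=-1)
            tube = (radial <= 3.5) & (sign * (idx[..., 0] - c[0]) >= 0) & (np.abs(idx[..., 0] - c[0]) <= 15 + 14)
            body |= tube
        lm = LabelMap(body.astype(np.int16), (1, 1, 1), (0, 0, 0))
        cl = L.build_centerline(lm)
        assert len(cl.branches) == 2
        o = [L.locate_ostium(cl, i).ostium_pos for i in range(2)]
        # ostia mirror through the body centre plane x = 40
        assert abs((o[0][0] - 40.0) + (o[1][0] - 40.0)) <= 2.0


class TestClipVeins:
    def test_phantom_vein_dice(self, small_phantom):
        _, _, _, truth = small_phantom
        bp = truth.labels.copy_with((truth.labels.data > 0).astype(np.int16))
        cl = L.build_centerline(bp)
        for i in range(len(cl.branches)):
            L.locate_ostium(cl, i)
        lm = L.clip_veins(bp, cl)
        assert dice(lm.data == 2, truth.labels.data == 2) >= 0.9

    def test_zero_branches_is_identity(self):
        mask = sphere_mask((48, 48, 48), (24, 24, 24), 16)
        lm = LabelMap(mask.astype(np.int16), (1, 1, 1), (0, 0, 0))
        cl = L.build_centerline(lm)
        out = L.clip_veins(lm, cl)
        assert np.array_equal(out.data, lm.data)

    def test_clipping_is_idempotent(self, small_phantom):
        _, _, _, truth = small_phantom
        bp = truth.labels.copy_with((truth.labels.data > 0).astype(np.int16))
        cl = L.build_centerline(bp)
        for i in range(len(cl.branches)):
            L.locate_ostium(cl, i)
        once = L.clip_veins(bp, cl)
        twice = L.clip_veins(once, cl)
        assert np.array_equal(once.data, twice.data)

    def test_label_conservation(self, small_phantom):
        _, _, _, truth = small_phantom
        bp = truth.labels.copy_with((truth.labels.data > 0).astype(np.int16))
        cl = L.build_centerline(bp)
        for i in range(len(cl.branches)):
            L.locate_ostium(cl, i)
        lm = L.clip_veins(bp, cl)
        assert (lm.data > 0).sum() == (bp.data > 0).sum()

    def test_body_stays_connected(self, small_phantom):
        _, _, _, truth = small_phantom
        bp = truth.labels.copy_with((truth.labels.data > 0).astype(np.int16))
        cl = L.build_centerline(bp)
        for i in range(len(cl.branches)):
            L.locate_ostium(cl, i)
        lm = L.clip_veins(bp, cl)
        n = ndimage.label(lm.data == 1, ndimage.generate_binary_structure(3, 3))[1]
        assert n == 1


class TestMvSphere:
    def test_unit_circumcircle(self):
        s = L.fit_mv_sphere((1, 0, 0), (0, 1, 0), (-1, 0, 0))
        assert np.allclose(s.center, (0, 0, 0), atol=1e-12)
        assert s.radius == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(1.0, 30.0),
    )
    def test_recovers_parameterized_circle(self, seed, radius):
        rng = np.random.default_rng(seed)
        center = rng.uniform(-40, 40, 3)
        # random orthonormal in-plane frame
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        u, v = q[:, 0], q[:, 1]
        angles = np.sort(rng.uniform(0, 2 * np.pi, 3))
        if np.min(np.diff(angles)) < 0.2:  # keep points well separated
            angles = np.array([0.0, 2.1, 4.2])
        pts = [center + radius * (np.cos(a) * u + np.sin(a) * v) for a in angles]
        s = L.fit_mv_sphere(*pts)
        assert np.allclose(s.center, center, atol=1e-8)
        assert s.radius == pytest.approx(radius, abs=1e-8)
        for p in pts:
            assert np.linalg.norm(p - s.center) == pytest.approx(s.radius, abs=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            L.fit_mv_sphere((0, 0, 0), (1, 1, 1), (2, 2, 2))


class TestLabelMv:
    def _pool(self):
        mask = sphere_mask((40, 40, 40), (20, 20, 20), 12)
        return LabelMap(mask.astype(np.int16), (1, 1, 1), (0, 0, 0))

    def test_sphere_outside_pool_is_noop_with_warning(self):
        lm = self._pool()
        s = L.MvSphere(None, None, None, np.array([100.0, 100.0, 100.0]), 3.0)
        with pytest.warns(UserWarning):
            out = L.label_mv(lm, s)
        assert np.array_equal(out.data, lm.data)

    def test_count_matches_exhaustive_distance_scan(self):
        lm = self._pool()
        s = L.MvSphere(None, None, None, np.array([20.0, 20.0, 9.0]), 6.0)
        out = L.label_mv(lm, s)
        # oracle: brute-force voxel scan
        idx = np.argwhere(lm.data == 1)
        expect = int((np.linalg.norm(idx - s.center, axis=1) <= s.radius).sum())
        assert int((out.data == 3).sum()) == expect

    def test_growing_radius_is_monotone(self):
        lm = self._pool()
        counts = []
        for r in (2.0, 4.0, 6.0, 8.0):
            s = L.MvSphere(None, None, None, np.array([20.0, 20.0, 9.0]), r)
            counts.append(int((L.label_mv(lm, s).data == 3).sum()))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_label_conservation(self):
        lm = self._pool()
        s = L.MvSphere(None, None, None, np.array([20.0, 20.0, 9.0]), 6.0)
        out = L.label_mv(lm, s)
        assert (out.data > 0).sum() == (lm.data > 0).sum()


class TestEndToEndLabeling:
    def test_dice_against_truth_beats_interobserver_bar(self, small_phantom):
        spec, mra, _, truth = small_phantom
        from atriaquant.io import minmax_normalize

        center = tuple(int(s // 2) for s in mra.shape)
        lm = L.auto_label(minmax_normalize(mra), L.Seed(center, 0.5))
        # valve labeled from the known orifice geometry (three border points)
        cz = (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing) / 2.0
        mv_center = cz + np.array([0.0, 0.0, -spec.body_semiaxes[2]])
        r = spec.mv_orifice_radius
        pts = [mv_center + r * np.array(d) for d in [(1, 0, 0), (0, 1, 0), (-1, 0, 0)]]
        lm = L.label_mv(lm, L.fit_mv_sphere(*pts))
        assert dice(lm.data == 1, truth.labels.data == 1) >= 0.9
        assert dice(lm.data == 2, truth.labels.data == 2) >= 0.7
        assert dice(lm.data == 3, truth.labels.data == 3) >= 0.7
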