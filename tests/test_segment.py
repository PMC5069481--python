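import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poroct.volio import VoxelVolume
from poroct.segment import (BinaryMask, RegionMask, otsu_threshold, binarize,
                            morphological_closing, despeckle, despeckle_upper,
                            volume_to_voxels, label_components, fit_cortical_roi,
                            fill_marrow, align_to_axis)


def brute_force_otsu(vals):
    """Independent oracle: exhaustive between-class-variance maximisation
    over the 256-bin histogram boundaries."""
    vals = np.asarray(vals, dtype=float)
    edges = np.histogram_bin_edges(vals, bins=256, range=(vals.min(), vals.max()))
    best_t, best_bcv = None, -1.0
    for t in edges[1:-1]:
        lo, hi = vals[vals < t], vals[vals >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        bcv = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if bcv > best_bcv + 1e-9:
            best_bcv, best_t = bcv, t
    return best_t


class TestOtsu:
    def test_bimodal_threshold_lies_between_modes(self, rng):
        vals = np.concatenate([np.full(500, 10.0), np.full(300, 200.0)])
        rng.shuffle(vals)
        vol = VoxelVolume(vals.reshape(8, 10, 10), 1.0)
        t = otsu_threshold(vol)
        assert 10 < t < 200

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([rng.normal(40, 12, 600), rng.normal(160, 25, 400)])
        vol = VoxelVolume(vals.reshape(10, 10, 10), 1.0)
        assert otsu_threshold(vol) == pytest.approx(brute_force_otsu(vals))

    def test_roi_restriction(self, rng):
        data = np.full((4, 8, 8), 100.0)
        data[:, :4] = rng.normal(30, 5, (4, 4, 8))
        data[:, 4:] = rng.normal(170, 5, (4, 4, 8))
        vol = VoxelVolume(data, 1.0)
        roi = RegionMask(np.zeros((4, 8, 8), bool), 1.0)
        roi.data[:, :4] = True  # only the dark half: threshold within it
        t = otsu_threshold(vol, roi)
        assert t < 60

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(VoxelVolume(np.full((3, 3, 3), 7.0), 1.0))


class TestBinarize:
    def test_threshold_below_min_gives_all_foreground(self, rng):
        vol = VoxelVolume(rng.uniform(50, 100, (4, 4, 4)), 1.0)
        assert binarize(vol, 10.0, "above").data.all()

    def test_above_is_complement_of_below(self, rng):
        vol = VoxelVolume(rng.uniform(0, 255, (5, 6, 7)), 1.0)
        above = binarize(vol, 128.0, "above").data
        below = binarize(vol, 128.0, "below").data
        assert np.array_equal(above, ~below)

    def test_phantom_pores_recovered_at_mid_threshold(self, small_cortical):
        _, vol, _ = small_cortical
        pores = binarize(vol, 110.0, "below")
        # the pore phase sits inside the wall plus the background outside
        assert pores.data.any()
        assert pores.phase_name == "pore"


class TestClosing:
    def test_solid_cube_unchanged(self):
        m = np.zeros((12, 12, 12), bool)
        m[2:10, 2:10, 2:10] = True
        closed = morphological_closing(BinaryMask(m, 1.0), 1)
        assert np.array_equal(closed.data, m)

    def test_single_voxel_gap_in_plate_filled(self):
        m = np.zeros((9, 9, 9), bool)
        m[3:6] = True            # 3-voxel-thick plate
        m[3:6, 4, 4] = False     # pinhole through it
        closed = morphological_closing(BinaryMask(m, 1.0), 1)
        assert closed.data[4, 4, 4]

    def test_idempotent(self, rng):
        # interior-supported mask: boundary extension semantics do not enter
        m = np.zeros((20, 20, 20), bool)
        m[4:16, 4:16, 4:16] = rng.random((12, 12, 12)) < 0.3
        once = morphological_closing(BinaryMask(m, 1.0), 1)
        twice = morphological_closing(once, 1)
        assert np.array_equal(once.data, twice.data)


class TestVoxelArithmetic:
    @pytest.mark.parametrize("vol_um3,voxel,expected", [
        (280.0, 2.0, 35),    # despeckling volume at 2 μm
        (280.0, 1.0, 280),   # and at 1 μm
        (8.0, 2.0, 1),
    ])
    def test_volume_to_voxels(self, vol_um3, voxel, expected):
        assert volume_to_voxels(vol_um3, voxel) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            volume_to_voxels(-1, 2)
        with pytest.raises(ValueError):
            volume_to_voxels(280, 0)


def _place_component(mask, n_voxels, start):
    """Grow a 6-connected component of exactly n voxels from start."""
    from collections import deque

    q = deque([start])
    placed = 0
    while q and placed < n_voxels:
        z, y, x = q.popleft()
        if not (0 <= z < mask.shape[0] and 0 <= y < mask.shape[1]
                and 0 <= x < mask.shape[2]) or mask[z, y, x]:
            continue
        mask[z, y, x] = True
        placed += 1
        q.extend([(z + 1, y, x), (z, y + 1, x), (z, y, x + 1)])


class TestDespeckle:
    def test_volume_threshold_at_2um(self):
        # 10 voxels = 80 μm³ removed; 50 voxels = 400 μm³ survives
        m = np.zeros((20, 20, 20), bool)
        _place_component(m, 10, (2, 2, 2))
        _place_component(m, 50, (12, 12, 12))
        out = despeckle(BinaryMask(m, 2.0), 280.0, "white")
        assert out.data.sum() == 50

    def test_exactly_at_threshold_survives(self):
        # "less than" is strict: a 35-voxel component at 2 μm is 280 μm³ exactly
        m = np.zeros((20, 20, 20), bool)
        _place_component(m, 35, (2, 2, 2))
        out = despeckle(BinaryMask(m, 2.0), 280.0, "white")
        assert out.data.sum() == 35

    def test_zero_threshold_is_identity(self, rng):
        m = rng.random((10, 10, 10)) < 0.2
        out = despeckle(BinaryMask(m, 1.0), 0.0, "white")
        assert np.array_equal(out.data, m)

    def test_black_phase_fills_small_holes(self):
        m = np.ones((10, 10, 10), bool)
        m[4, 4, 4] = False   # 1-voxel hole: 1 μm³ < 10 μm³
        out = despeckle(BinaryMask(m, 1.0), 10.0, "black")
        assert out.data.all()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 500), v1=st.integers(0, 40), dv=st.integers(0, 40))
    def test_monotone_and_composable(self, seed, v1, dv):
        """Foreground shrinks with the threshold, and despeckling at v1 then
        v2 >= v1 equals despeckling at v2 directly."""
        rng = np.random.default_rng(seed)
        m = BinaryMask(rng.random((12, 12, 12)) < 0.25, 1.0)
        v2 = v1 + dv
        a = despeckle(m, float(v1), "white")
        b = despeckle(m, float(v2), "white")
        assert not (b.data & ~a.data).any()          # monotone
        ab = despeckle(a, float(v2), "white")
        assert np.array_equal(ab.data, b.data)       # composition

    def test_upper_bound_removes_large_components(self):
        m = np.zeros((40, 20, 20), bool)
        _place_component(m, 5000, (0, 0, 0))     # 5000 μm³ at 1 μm: canal-sized
        _place_component(m, 1000, (30, 10, 10))  # lacuna-sized
        out = despeckle_upper(BinaryMask(m, 1.0), 4000.0)
        assert out.data.sum() == 1000

    def test_upper_bound_infinite_is_identity(self, rng):
        m = rng.random((10, 10, 10)) < 0.2
        out = despeckle_upper(BinaryMask(m, 1.0), np.inf)
        assert np.array_equal(out.data, m)

    def test_lower_upper_composition_leaves_middle_band(self):
        m = np.zeros((60, 24, 24), bool)
        _place_component(m, 100, (0, 0, 0))
        _place_component(m, 1000, (20, 0, 0))
        _place_component(m, 5000, (40, 0, 0))
        out = despeckle_upper(despeckle(BinaryMask(m, 1.0), 280.0), 4000.0)
        assert out.data.sum() == 1000


def flood_fill_count(mask, connectivity):
    """Independent component-count oracle: explicit BFS flood fill."""
    from collections import deque

    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offs.append((dz, dy, dx))
    seen = np.zeros_like(mask)
    count = 0
    for idx in np.argwhere(mask):
        if seen[tuple(idx)]:
            continue
        count += 1
        q = deque([tuple(idx)])
        seen[tuple(idx)] = True
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) \
                        and mask[n] and not seen[n]:
                    seen[n] = True
                    q.append(n)
    return count


class TestLabelComponents:
    def test_two_cubes(self):
        m = np.zeros((10, 10, 10), bool)
        m[1:3, 1:3, 1:3] = True
        m[6:9, 6:9, 6:9] = True
        lc = label_components(BinaryMask(m, 2.0), 26)
        assert len(lc.table) == 2
        assert sorted(lc.table.voxels) == [8, 27]
        assert sorted(lc.table.volume_um3) == [64.0, 216.0]

    def test_connectivity_semantics(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = m[0, 0, 1] = True      # face neighbours
        m[2, 2, 2] = m[3, 3, 3] = True      # corner neighbours
        assert len(label_components(BinaryMask(m, 1.0), 6).table) == 3
        assert len(label_components(BinaryMask(m, 1.0), 26).table) == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        m = rng.random((14, 14, 14)) < 0.2
        lc = label_components(BinaryMask(m, 1.0), connectivity)
        assert len(lc.table) == flood_fill_count(m, connectivity)


class TestCorticalRoi:
    def test_ideal_tube_roi_is_the_annulus(self, rng):
        n, rout, rin = 64, 25, 15
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        rr = np.hypot(yy - c, xx - c)
        ann = (rr <= rout) & (rr >= rin)
        bone = BinaryMask(np.repeat(ann[None], 12, axis=0), 1.0)
        roi = fit_cortical_roi(bone, closing_radius_um=5.0)
        assert np.array_equal(roi.data, bone.data)

    def test_phantom_roi_recovers_pores_exactly(self, small_cortical):
        _, vol, truth = small_cortical
        bone = binarize(vol, 110.0, "above")
        roi = fit_cortical_roi(bone, 10.0)
        pores = roi.data & ~bone.data
        # ROI = bone + pores; pore volume within a few % of analytic truth
        true_pore = sum(truth.canal_volumes_um3) + sum(truth.lacuna_volumes_um3)
        assert pores.sum() == pytest.approx(true_pore, rel=0.03)
        # ROI volume within 2% of the analytic wall volume
        assert roi.data.sum() == pytest.approx(truth.wall_volume_um3, rel=0.02)
        # ROI minus bone is exactly the rasterised void set inside the wall:
        # every voxel darker than the threshold that lies within the ROI
        voids = (vol.data < 110.0) & roi.data
        assert np.array_equal(pores, voids)

    def test_empty_bone_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_cortical_roi(BinaryMask(np.zeros((4, 8, 8), bool), 1.0))

    def test_non_annular_rejected(self):
        solid = np.zeros((6, 20, 20), bool)
        solid[:, 5:15, 5:15] = True
        with pytest.raises(ValueError, match="annular"):
            fit_cortical_roi(BinaryMask(solid, 1.0), closing_radius_um=2.0)


class TestFillMarrow:
    def test_annulus_becomes_disc(self):
        n, rout, rin = 48, 18, 10
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        rr = np.hypot(yy - c, xx - c)
        ann = (rr <= rout) & (rr >= rin)
        roi = RegionMask(np.repeat(ann[None], 6, axis=0), 1.0)
        filled = fill_marrow(roi)
        disc = rr <= rout
        assert np.array_equal(filled.data[0], disc)
        # monotone and volume matches pi r^2 L
        assert filled.data.sum() >= roi.data.sum()
        assert filled.data.sum() == pytest.approx(np.pi * rout**2 * 6, rel=0.05)

    def test_empty_slice_rejected(self):
        m = np.zeros((3, 8, 8), bool)
        m[0, 2:6, 2:6] = True
        with pytest.raises(ValueError, match="no closed contour"):
            fill_marrow(RegionMask(m, 1.0))


class TestAlignToAxis:
    def test_aligned_tube_unchanged(self):
        n = 40
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        tube = (np.hypot(yy - c, xx - c) <= 8)
        data = np.where(np.repeat(tube[None], 60, axis=0), 200.0, 20.0)
        vol = VoxelVolume(data, 1.0)
        out = align_to_axis(vol, threshold=110.0)
        # principal axis already along axis 0: object preserved
        overlap = ((out.data >= 110) & (vol.data >= 110)).sum()
        assert overlap / (vol.data >= 110).sum() > 0.98

    def test_tilted_rod_straightened(self):
        zz, yy, xx = np.mgrid[0:60, 0:40, 0:40]
        # rod tilted ~10 degrees in the z-y plane
        axis_y = 20 + (zz - 30) * np.tan(np.radians(10))
        rod = (np.hypot(yy - axis_y, xx - 20) <= 4)
        vol = VoxelVolume(np.where(rod, 200.0, 20.0), 1.0)
        out = align_to_axis(vol, threshold=110.0)
        pts = np.argwhere(out.data >= 110).astype(float)
        pts -= pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(pts.T))
        tilt = np.degrees(np.arccos(abs(evecs[0, 2])))
        assert tilt < 1.0

    def test_sphere_rejected(self):
        zz, yy, xx = np.mgrid[0:30, 0:30, 0:30]
        ball = ((zz - 15)**2 + (yy - 15)**2 + (xx - 15)**2) <= 100
        vol = VoxelVolume(np.where(ball, 200.0, 20.0), 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            align_to_axis(vol, threshold=110.0)
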