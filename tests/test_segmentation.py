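"""Foreground clustering, object extraction, clump classification and the
seeded watershed regrowth."""
import numpy as np
import pytest
import skimage.draw as skd

from dicentric import segmentation as seg
from dicentric.segmentation import KMeansParams, MetaphaseImage, ObjectKind

from conftest import bfs_watershed_oracle, obj_from_mask, random_blob_mask


def brute_force_threshold(gray):
    """Optimal single-threshold 2-means partition of a 1-D sample: minimizes
    within-cluster sum of squares over all cut points."""
    vals = np.sort(gray.ravel().astype(float))
    best_t, best_cost = None, np.inf
    for cut in np.unique(vals)[:-1]:
        lo, hi = vals[vals <= cut], vals[vals > cut]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_t = cost, cut
    return best_t


class TestKMeansClusterImage:
    def test_two_tone_image_splits_exactly(self):
        px = np.full((40, 40), 220, dtype=np.uint8)
        px[:, :20] = 30
        lm = seg.kmeans_cluster_image(MetaphaseImage(px))
        assert (lm.labels[:, :20] == 1).all()  # dark half = foreground
        assert (lm.labels[:, 20:] == 0).all()

    def test_matches_brute_force_threshold_partition(self):
        rng = np.random.default_rng(0)
        px = np.where(
            rng.random((64, 64)) < 0.4,
            rng.normal(40, 10, (64, 64)),
            rng.normal(210, 10, (64, 64)),
        )
        px = np.clip(px, 0, 255).astype(np.uint8)
        lm = seg.kmeans_cluster_image(MetaphaseImage(px))
        t = brute_force_threshold(px)
        agree = ((px <= t) == (lm.labels == 1)).mean()
        assert agree >= 0.99

    def test_uniform_image_is_all_background_with_warning(self):
        px = np.full((32, 32), 128, dtype=np.uint8)
        with pytest.warns(UserWarning):
            lm = seg.kmeans_cluster_image(MetaphaseImage(px))
        assert lm.warning is not None
        assert (lm.labels == 0).all()

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        px = np.clip(rng.normal(128, 60, (48, 48)), 0, 255).astype(np.uint8)
        img = MetaphaseImage(px)
        a = seg.kmeans_cluster_image(img, KMeansParams(rng_seed=7))
        b = seg.kmeans_cluster_image(img, KMeansParams(rng_seed=7))
        assert (a.labels == b.labels).all()


class TestExtractObjects:
    def test_counts_specks_removed_and_sorted(self):
        m = np.zeros((20, 20), dtype=np.int32)
        m[2:4, 2:4] = 1      # 4 px
        m[10:12, 10:12] = 1  # 4 px
        m[17, 17] = 1        # 1-px speck
        objs = seg.extract_objects(m, min_area_px=2)
        assert len(objs) == 2
        assert [o.object_id for o in objs] == [1, 2]
        assert objs[0].area_px >= objs[1].area_px

    def test_empty_mask_gives_empty_list(self):
        assert seg.extract_objects(np.zeros((16, 16), dtype=np.int32), 1) == []

    def test_count_monotone_in_min_area(self):
        rng = np.random.default_rng(5)
        m = (rng.random((64, 64)) < 0.35).astype(np.int32)
        counts = [len(seg.extract_objects(m, a)) for a in (1, 2, 4, 8, 16, 32)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_bbox_and_crops_consistent(self):
        rng = np.random.default_rng(1)
        gray = rng.integers(0, 255, (30, 30)).astype(np.uint8)
        m = np.zeros((30, 30), dtype=np.int32)
        m[5:12, 8:20] = 1
        (obj,) = seg.extract_objects(m, 5, gray=gray)
        r0, c0, r1, c1 = obj.bbox
        assert (r0, c0, r1, c1) == (5, 8, 12, 20)
        assert (obj.gray_crop == gray[5:12, 8:20]).all()


class TestClassifyObject:
    def test_straight_band_is_single(self):
        m = np.zeros((20, 40), dtype=bool)
        m[8:13, 3:37] = True
        assert seg.classify_object(obj_from_mask(m)) is ObjectKind.SINGLE

    def test_end_to_side_contact_is_touching_clump(self):
        t = np.zeros((40, 40), dtype=bool)
        t[10:15, 5:35] = True
        t[15:32, 18:23] = True
        assert seg.classify_object(obj_from_mask(t)) is ObjectKind.TOUCHING_CLUMP

    def test_x_crossing_is_overlapping_clump(self):
        x = np.zeros((48, 48), dtype=bool)
        for r0, c0, r1, c1 in ((4, 4, 43, 43), (4, 43, 43, 4)):
            rr, cc = skd.line(r0, c0, r1, c1)
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    x[np.clip(rr + dr, 0, 47), np.clip(cc + dc, 0, 47)] = True
        assert seg.classify_object(obj_from_mask(x)) is ObjectKind.OVERLAPPING_CLUMP

    def test_enclosed_hole_flags_overlap(self):
        m = np.zeros((40, 40), dtype=bool)
        m[5:35, 5:35] = True
        m[12:28, 12:28] = False  # large enclosed hole
        assert seg.classify_object(obj_from_mask(m)) is ObjectKind.OVERLAPPING_CLUMP

    def test_bent_band_low_solidity_still_single(self):
        from dicentric.phantoms import make_chromosome

        mask, gray, _ = make_chromosome(70, 9, 0.5, [0.5], seed=4)
        obj = obj_from_mask(mask, np.clip(gray, 0, 255).astype(np.uint8))
        assert seg.classify_object(obj) is ObjectKind.SINGLE


def _t_clump():
    """Two bands in end-to-side contact, dark cores and lighter edges."""
    g = np.full((40, 40), 220, dtype=np.uint8)
    m = np.zeros((40, 40), dtype=bool)
    m[10:19, 4:36] = True
    m[19:36, 16:25] = True
    g[10:19, 4:36] = 120
    g[13:16, 4:36] = 60
    g[19:36, 16:25] = 120
    g[19:36, 19:22] = 60
    return obj_from_mask(m, g)


class TestResegmentClump:
    def test_two_band_clump_gives_two_seeds_inside_bands(self):
        obj = _t_clump()
        seeds = seg.resegment_clump(obj)
        assert len(seeds) == 2
        for s in seeds:
            assert not np.any(s & ~obj.mask)
        assert not np.any(seeds[0] & seeds[1])

    def test_three_band_clump_gives_three_seeds(self):
        g = np.full((60, 60), 220, dtype=np.uint8)
        m = np.zeros((60, 60), dtype=bool)
        m[20:29, 4:56] = True
        g[20:29, 4:56] = 120
        g[23:26, 4:56] = 60
        m[29:46, 12:21] = True
        g[29:46, 12:21] = 120
        g[29:46, 15:18] = 60
        m[3:20, 40:49] = True
        g[3:20, 40:49] = 120
        g[3:20, 43:46] = 60
        obj = obj_from_mask(m, g)
        assert seg.classify_object(obj) is seg.ObjectKind.TOUCHING_CLUMP
        seeds = seg.resegment_clump(obj)
        assert len(seeds) == 3

    def test_uniform_clump_cannot_split(self):
        m = np.zeros((20, 30), dtype=bool)
        m[5:15, 5:25] = True
        obj = obj_from_mask(m, np.full((20, 30), 60, dtype=np.uint8))
        with pytest.raises(seg.ClumpSplitError):
            seg.resegment_clump(obj)

    def test_connected_dark_cores_cannot_split(self):
        # one continuous dark core through the whole clump: nothing separates
        g = np.full((20, 40), 220, dtype=np.uint8)
        m = np.zeros((20, 40), dtype=bool)
        m[5:15, 2:38] = True
        g[5:15, 2:38] = 120
        g[9:12, 2:38] = 60
        with pytest.raises(seg.ClumpSplitError):
            seg.resegment_clump(obj_from_mask(m, g))


class TestWatershedGrow:
    def test_single_seed_identity(self):
        m = np.zeros((12, 12), dtype=bool)
        m[2:10, 3:11] = True
        obj = obj_from_mask(m)
        (out,) = seg.watershed_grow(obj, [m.copy()])
        full = np.zeros_like(m)
        r0, c0, r1, c1 = out.bbox
        full[r0:r1, c0:c1] = out.mask
        assert (full == m).all()
        assert out.kind is ObjectKind.SINGLE

    def test_rectangle_splits_into_halves(self):
        m = np.zeros((4, 10), dtype=bool)
        m[:, :] = True
        s1 = np.zeros_like(m)
        s1[1, 0] = True
        s2 = np.zeros_like(m)
        s2[1, 9] = True
        obj = obj_from_mask(m)
        a, b = seg.watershed_grow(obj, [s1, s2])
        assert a.area_px == 20 and b.area_px == 20
        assert a.bbox[3] == 5 and b.bbox[1] == 5  # split at the middle column

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            seg.watershed_grow(obj_from_mask(np.ones((4, 4), dtype=bool)), [])

    def test_seed_outside_mask_rejected(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1:5, 1:5] = True
        bad = np.zeros_like(m)
        bad[0, 0] = True
        with pytest.raises(ValueError):
            seg.watershed_grow(obj_from_mask(m), [bad])

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_bfs_oracle_and_conserves_mask(self, trial):
        rng = np.random.default_rng(100 + trial)
        mask = random_blob_mask(rng, size=48)
        coords = np.argwhere(mask)
        n_seeds = int(rng.integers(2, 5))
        picks = coords[rng.choice(len(coords), size=n_seeds, replace=False)]
        seeds = []
        for r, c in picks:
            s = np.zeros_like(mask)
            s[r, c] = True
            seeds.append(s)
        obj = obj_from_mask(mask)
        pieces = seg.watershed_grow(obj, seeds)
        got = np.zeros(mask.shape, dtype=np.int32)
        for i, p in enumerate(pieces, start=1):
            r0, c0, r1, c1 = p.bbox
            assert not np.any(got[r0:r1, c0:c1][p.mask])  # pairwise disjoint
            got[r0:r1, c0:c1][p.mask] = i
            assert p.mask[seeds[i - 1][r0:r1, c0:c1]].all()  # seed inside its region
        assert ((got > 0) == mask).all()  # conservation
        expected = bfs_watershed_oracle(mask, seeds)
        assert (got == expected).all()
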