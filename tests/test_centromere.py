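"""Equivalent-width profile (distance x inverted-gray) and the five-step
constriction detector with the A/B prominence rule."""
import numpy as np
import pytest

from dicentric import centromere as cen
from dicentric.centerline import Centerline
from dicentric.centromere import Classification, EqWidthParams

from conftest import obj_from_mask


def vertical_centerline_point(mask, gray, row, col):
    """A 3-point centerline through (row, col) running horizontally, so the
    normal at the middle point is vertical."""
    pts = np.array([[row, col - 1], [row, col], [row, col + 1]], dtype=float)
    normals = np.tile([1.0, 0.0], (3, 1))
    return Centerline(points=pts, normals=normals, length_px=2.0)


def profile_from_filtered(y):
    """Wrap an explicit filtered signal as a WidthProfile for detector tests."""
    y = np.asarray(y, dtype=float)
    x = np.arange(len(y))
    slope, intercept = np.polyfit(x, y, 1)
    trend = slope * x + intercept
    diff = trend - y
    return cen.WidthProfile(
        y_raw=y,
        y_filtered=y,
        trend_line=(slope, intercept),
        diff_curve=diff,
        diff_deriv=np.gradient(diff),
        centerline=None,
        params=EqWidthParams(T=1.0, T_rel=None),
    )


class TestPerpendicularSamples:
    def test_three_pixel_column_hand_case(self):
        gray = np.full((5, 5), 255, dtype=np.uint8)
        gray[1:4, 2] = [100, 50, 100]
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 2] = True
        obj = obj_from_mask(mask, gray)
        c = vertical_centerline_point(mask, gray, 2, 2)
        samples = sorted(cen.perpendicular_samples(c, obj, 1))
        assert samples == [(0.0, 205.0), (1.0, 155.0), (1.0, 155.0)]

    def test_width_one_mask_gives_single_pair(self):
        gray = np.full((5, 5), 90, dtype=np.uint8)
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        obj = obj_from_mask(mask, gray)
        c = vertical_centerline_point(mask, gray, 2, 2)
        assert cen.perpendicular_samples(c, obj, 1) == [(0.0, 165.0)]

    def test_saturated_white_pixels_score_zero(self):
        gray = np.full((5, 5), 255, dtype=np.uint8)
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 2] = True
        obj = obj_from_mask(mask, gray)
        c = vertical_centerline_point(mask, gray, 2, 2)
        assert all(g == 0.0 for _, g in cen.perpendicular_samples(c, obj, 1))


class TestEquivalentWidth:
    @pytest.mark.parametrize(
        "m,n,expected",
        [
            (1, 1, 310.0),  # 1*155 + 0*205 + 1*155
            (0, 0, 3.0),    # degenerates to the pixel count (plain width)
            (0, 1, 515.0),  # sum of G
            (2, 1, 310.0),
        ],
    )
    def test_hand_cases(self, m, n, expected):
        samples = [(1.0, 155.0), (0.0, 205.0), (1.0, 155.0)]
        assert cen.equivalent_width(samples, m, n) == pytest.approx(expected)

    def test_empty_samples_zero(self):
        assert cen.equivalent_width([], 1, 1) == 0.0


class TestBuildProfile:
    def _rect_fixture(self, gray_fn=None):
        H, W = 9, 41
        mask = np.zeros((H, W), dtype=bool)
        mask[2:7, :] = True
        gray = np.full((H, W), 60, dtype=np.uint8)
        if gray_fn is not None:
            for c in range(W):
                gray[2:7, c] = gray_fn(c)
        obj = obj_from_mask(mask, gray)
        pts = np.stack([np.full(W, 4.0), np.arange(W, dtype=float)], axis=1)
        normals = np.tile([1.0, 0.0], (W, 1))
        cline = Centerline(points=pts, normals=normals, length_px=float(W - 1))
        return obj, cline

    def test_constant_band_flat_difference_curve(self):
        obj, cline = self._rect_fixture()
        prof = cen.build_profile(obj, cline)
        assert np.allclose(prof.diff_curve, 0.0, atol=1e-9)
        assert np.allclose(prof.diff_deriv, 0.0, atol=1e-9)

    def test_linear_gray_ramp_absorbed_by_trend(self):
        obj, cline = self._rect_fixture(gray_fn=lambda c: 40 + 2 * c)
        prof = cen.build_profile(obj, cline)
        # end-reflection of the smoothing filter leaves a small residual;
        # the interior difference curve is flat to a fraction of a percent
        interior = prof.diff_curve[3:-3]
        assert np.abs(interior).max() <= 5e-3 * prof.y_filtered.max()

    def test_m0_n0_is_geometric_width(self):
        obj, cline = self._rect_fixture()
        prof = cen.build_profile(obj, cline, EqWidthParams(m=0, n=0, T=1.0, T_rel=None))
        assert np.allclose(prof.y_raw, 5.0)

    def test_short_centerline_rejected(self):
        obj, cline = self._rect_fixture()
        short = Centerline(points=cline.points[:3], normals=cline.normals[:3], length_px=2.0)
        with pytest.raises(ValueError):
            cen.build_profile(obj, short, EqWidthParams(filter_window=5))

    def test_profile_invariant_under_rot90_and_translation(self):
        rng = np.random.default_rng(0)
        H, W = 11, 41
        mask = np.zeros((H, W), dtype=bool)
        mask[3:9, :] = True
        gray = np.full((H, W), 220, dtype=np.uint8)
        gray[3:9, :] = rng.integers(40, 120, (6, W))
        obj = obj_from_mask(mask, gray)
        pts = np.stack([np.full(W, 5.0), np.arange(W, dtype=float)], axis=1)
        normals = np.tile([1.0, 0.0], (W, 1))
        cline = Centerline(points=pts, normals=normals, length_px=float(W - 1))
        base = cen.build_profile(obj, cline).y_raw

        # translation by (2, 3)
        mask_t = np.pad(mask, ((2, 0), (3, 0)))
        gray_t = np.pad(gray, ((2, 0), (3, 0)), constant_values=220)
        obj_t = obj_from_mask(mask_t, gray_t)
        cline_t = Centerline(points=pts + [2, 3], normals=normals, length_px=float(W - 1))
        assert np.allclose(cen.build_profile(obj_t, cline_t).y_raw, base)

        # exact 90-degree rotation of mask, gray and centerline geometry
        mask_r = np.rot90(mask)
        gray_r = np.rot90(gray)
        obj_r = obj_from_mask(mask_r, gray_r)
        pts_r = np.stack([(W - 1) - pts[:, 1], pts[:, 0]], axis=1)
        normals_r = np.tile([0.0, 1.0], (W, 1))
        cline_r = Centerline(points=pts_r, normals=normals_r, length_px=float(W - 1))
        assert np.allclose(cen.build_profile(obj_r, cline_r).y_raw, base)


class TestDetectCentromeres:
    def test_clear_single_dip_accepted(self):
        prof = profile_from_filtered([10, 10, 4, 10, 10])
        call = cen.detect_centromeres(prof, EqWidthParams(T=4.0, T_rel=None))
        assert call.n_centromeres == 1
        assert call.classification is Classification.MONOCENTRIC
        assert call.prominences[0] == (6.0, 6.0)

    def test_shallow_dip_rejected(self):
        prof = profile_from_filtered([10, 9, 8, 9, 10])
        call = cen.detect_centromeres(prof, EqWidthParams(T=4.0, T_rel=None))
        assert call.n_centromeres == 0
        assert call.classification is Classification.ACENTRIC_LIKE

    def test_asymmetric_prominences_follow_printed_rule(self):
        # A=5 > T, and both sides above T/2 -> accepted as printed
        prof = profile_from_filtered([10.0, 10.0, 5.0, 8.0, 8.0])
        call = cen.detect_centromeres(prof, EqWidthParams(T=4.0, T_rel=None))
        assert call.n_centromeres == 1
        assert call.prominences[0] == (5.0, 3.0)
        # same shape but B below T/2 -> rejected
        prof2 = profile_from_filtered([10.0, 10.0, 5.0, 6.5, 6.5])
        call2 = cen.detect_centromeres(prof2, EqWidthParams(T=4.0, T_rel=None))
        assert call2.n_centromeres == 0

    def test_two_dips_classified_dicentric(self):
        y = np.array([10, 10, 10, 3, 10, 10, 10, 10, 3, 10, 10, 10], dtype=float)
        call = cen.detect_centromeres(
            profile_from_filtered(y),
            EqWidthParams(T=4.0, T_rel=None, min_separation_frac=0.1),
        )
        assert call.classification is Classification.DICENTRIC
        assert call.indices == [3, 8]

    def test_close_dips_merged_keeping_deeper(self):
        y = np.array([10, 10, 4, 9, 3, 10, 10, 10, 10, 10], dtype=float)
        call = cen.detect_centromeres(
            profile_from_filtered(y),
            EqWidthParams(T=4.0, T_rel=None, min_separation_frac=0.4),
        )
        assert call.n_centromeres == 1
        assert call.indices == [4]  # the deeper of the two

    def test_deepening_a_dip_never_reduces_prominence(self):
        params = EqWidthParams(T=0.5, T_rel=None)
        prev_a = prev_b = 0.0
        for depth in (2.0, 4.0, 6.0, 8.0):
            y = np.array([10, 10, 10, 10 - depth, 10, 10, 10], dtype=float)
            call = cen.detect_centromeres(profile_from_filtered(y), params)
            assert call.n_centromeres == 1
            a, b = call.prominences[0]
            assert a >= prev_a and b >= prev_b
            prev_a, prev_b = a, b

    def test_doubling_threshold_shrinks_accepted_set(self):
        # with the proximity merge disabled (it may move which representative
        # of a minima cluster survives), raising T can only reject minima
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.random(40) * 10
            for T in (0.5, 1.0, 2.0, 4.0):
                lo = cen.detect_centromeres(
                    profile_from_filtered(y),
                    EqWidthParams(T=T, T_rel=None, min_separation_frac=0.001),
                )
                hi = cen.detect_centromeres(
                    profile_from_filtered(y),
                    EqWidthParams(T=2 * T, T_rel=None, min_separation_frac=0.001),
                )
                assert set(hi.indices) <= set(lo.indices)

    def test_end_margin_excludes_tip_dips(self):
        y = np.concatenate([[10, 2, 10], np.full(20, 10.0)])
        call = cen.detect_centromeres(
            profile_from_filtered(y),
            EqWidthParams(T=4.0, T_rel=None, end_margin_frac=0.15),
        )
        assert call.n_centromeres == 0


class TestScoreCell:
    def test_counts_dicentrics(self):
        mk = lambda n: cen.CentromereCall(
            indices=list(range(n)),
            prominences=[(1.0, 1.0)] * n,
            n_centromeres=n,
            classification={0: Classification.ACENTRIC_LIKE, 1: Classification.MONOCENTRIC,
                            2: Classification.DICENTRIC}.get(n, Classification.MULTICENTRIC),
        )
        score = cen.score_cell([mk(1), mk(1), mk(2), mk(2)], n_flagged=1)
        assert score.n_dicentrics == 2
        assert score.n_flagged == 1

    def test_empty_cell(self):
        assert cen.score_cell([]).n_dicentrics == 0


class TestPhantomDetection:
    def test_classification_matches_truth_on_clean_singles(self, singles_corpus):
        from dicentric.pipeline import process_image

        correct = 0
        for img, truth in singles_corpus:
            res = process_image(img)
            calls = [s.call for s in res.scored if s.call is not None]
            assert len(calls) == 1
            correct += calls[0].n_centromeres == truth.n_centromeres
        assert correct >= int(0.9 * len(singles_corpus))

    def test_detected_position_near_true_constriction(self, singles_corpus):
        from dicentric.pipeline import process_image

        img, truth = singles_corpus[1]  # a dicentric
        res = process_image(img)
        call = res.scored[0].call
        n = len(res.scored[0].centerline)
        fr = sorted(i / (n - 1) for i in call.indices)
        tr = sorted(truth.centromere_fracs)
        rev = sorted(1 - f for f in fr)
        tol = 0.12
        ok = all(abs(a - b) < tol for a, b in zip(fr, tr)) or all(
            abs(a - b) < tol for a, b in zip(rev, tr)
        )
        assert ok
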